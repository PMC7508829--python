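"""Simulated inferior-hybrid sets and FPVD cut-off calibration.

Real inferior hybrids are rarely documented by breeders, so the null set for
the FPVD scan is constructed exhaustively: every possible restorer x sterile
cross that was never released as a superior cultivar is treated as an
inferior hybrid.  Known sterility/fertility genes (which must differ between
the parents of every viable cross) then act as positive controls whose FPVD
peaks calibrate the cut-off used on the superior set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .fpvd import FPVDTrack
from .panel import HybridTable


def enumerate_inferior(
    restorers: list[str],
    steriles: list[str],
    superior: HybridTable | None = None,
    system: str = "3-line",
) -> HybridTable:
    """All restorer x sterile crosses minus the real superior pairs.

    Pair identity is unordered, so a superior pair is excluded regardless of
    which parent the pedigree file stored as female.  Superior pairs that fall
    outside the restorer x sterile Cartesian product are reported with a
    warning and counted in the result's ``meta["n_superior_outside"]``.
    """
    if not restorers or not steriles:
        raise ValueError("restorer and sterile id lists must be non-empty")
    overlap = set(restorers) & set(steriles)
    if overlap:
        raise ValueError(f"restorer and sterile lists overlap: {sorted(overlap)[:3]}")

    superior_pairs: set[frozenset] = set()
    n_outside = 0
    if superior is not None and len(superior):
        product_pairs = {
            frozenset((r, s)) for r in set(restorers) for s in set(steriles)
        }
        for pair in superior.unordered_pairs():
            if pair in product_pairs:
                superior_pairs.add(pair)
            else:
                n_outside += 1
        if n_outside:
            warnings.warn(
                f"{n_outside} superior pair(s) fall outside the "
                f"restorer x sterile product and were not excluded",
                stacklevel=2,
            )

    rows = []
    k = 0
    for s in steriles:
        for r in restorers:
            if frozenset((r, s)) in superior_pairs:
                continue
            rows.append((f"inf_{system}_{k:06d}", s, r, system, "simulated_inferior"))
            k += 1
    table = pd.DataFrame(rows, columns=["hybrid_id", "female_id", "male_id", "system", "status"])
    return HybridTable(
        table,
        meta={
            "n_superior_excluded": len(superior_pairs),
            "n_superior_outside": n_outside,
            "n_restorers": len(restorers),
            "n_steriles": len(steriles),
        },
    )


@dataclass
class CalibrationReport:
    """Peak FPVD inside each known sterility/fertility gene interval.

    ``genes`` has one row per interval: label, chrom, start, end (0-based
    half-open), n_sites, peak_fpvd, peak_pos.  Intervals with no defined FPVD
    site are kept with NaN peaks but excluded from the recommendation.
    """

    genes: pd.DataFrame
    recommended_cutoff: float | None
    floor: float = 0.5
    meta: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        recs = self.genes.to_dict(orient="records")
        return {
            "genes": recs,
            "recommended_cutoff": self.recommended_cutoff,
            "floor": self.floor,
            **self.meta,
        }


def calibrate_cutoff(
    track: FPVDTrack,
    known_genes: pd.DataFrame,
    floor: float = 0.5,
) -> CalibrationReport:
    """Recommend an FPVD cut-off from known-gene peaks in a null-set track.

    ``known_genes`` needs columns label, chrom, start, end (0-based
    half-open).  The recommendation is the minimum over gene peaks, rounded
    down to 2 decimals and never below ``floor``.
    """
    rows = []
    defined = track.defined()
    for rec in known_genes.itertuples(index=False):
        inside = defined[
            (defined["chrom"] == rec.chrom)
            & (defined["pos"] - 1 >= rec.start)
            & (defined["pos"] - 1 < rec.end)
        ]
        if inside.empty:
            rows.append((rec.label, rec.chrom, rec.start, rec.end, 0, float("nan"), -1))
        else:
            peak = inside.loc[inside["fpvd"].idxmax()]
            rows.append(
                (rec.label, rec.chrom, rec.start, rec.end, len(inside),
                 float(peak["fpvd"]), int(peak["pos"]))
            )
    genes = pd.DataFrame(
        rows, columns=["label", "chrom", "start", "end", "n_sites", "peak_fpvd", "peak_pos"]
    )
    with_sites = genes[genes["n_sites"] > 0]
    if with_sites.empty:
        recommended = None
    else:
        # floor to printed precision so the cut-off never exceeds any peak
        recommended = max(floor, math.floor(with_sites["peak_fpvd"].min() * 100) / 100)
    return CalibrationReport(genes=genes, recommended_cutoff=recommended, floor=floor)
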