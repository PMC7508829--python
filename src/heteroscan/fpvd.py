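"""Frequency of parental variation differences (FPVD).

For a set of hybrids and one variant site, each hybrid contributes an
indicator d that is 1 when its two parents carry different genotype calls at
the site and 0 when they carry the same call.  FPVD is the mean of d over the
hybrid set:

    FPVD = sum_k d_k / n

A site where the parents of every superior hybrid differ (FPVD near 1) is a
candidate heterosis locus.  Hybrids with a missing parental call at a site are
uninformative there; see ``denominator_mode`` for the two supported treatments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import HeteroscanError
from .panel import MISSING, GenotypePanel, HybridTable

#: sentinel returned by :func:`parental_diff` when either parent is uncalled
UNINFORMATIVE = "uninformative"

_VALID_CODES = frozenset((0, 1, 2, MISSING))

TRACK_COLUMNS = ["chrom", "pos", "vclass", "fpvd", "n_informative", "n_total"]


def parental_diff(genotype_female: int, genotype_male: int):
    """Per-hybrid, per-site difference indicator.

    Returns 1 if both parental calls are present and differ, 0 if both are
    present and equal, and :data:`UNINFORMATIVE` if either is missing.
    Heterozygous calls are compared as codes, so a het differs from either
    homozygote.
    """
    for g in (genotype_female, genotype_male):
        if g not in _VALID_CODES:
            raise HeteroscanError(f"invalid genotype code {g!r}")
    if genotype_female == MISSING or genotype_male == MISSING:
        return UNINFORMATIVE
    return int(genotype_female != genotype_male)


@dataclass
class FPVDTrack:
    """Per-site FPVD values for one hybrid set.

    ``table`` has columns chrom, pos, vclass, fpvd, n_informative, n_total;
    ``fpvd`` is NaN where fewer than ``min_informative_frac`` of the hybrids
    had both parents called.
    """

    label: str
    table: pd.DataFrame
    denominator_mode: str = "informative"
    min_informative_frac: float = 0.8

    def defined(self) -> pd.DataFrame:
        return self.table[self.table["fpvd"].notna()]

    def value_at(self, chrom: str, pos: int) -> float:
        hit = self.table[(self.table["chrom"] == chrom) & (self.table["pos"] == pos)]
        if hit.empty:
            raise LookupError(f"no site at {chrom}:{pos}")
        return float(hit["fpvd"].iloc[0])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path, label: str = "") -> "FPVDTrack":
        table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        return cls(label=label or str(path), table=table)


def fpvd_track(
    panel: GenotypePanel,
    hybrids: HybridTable,
    label: str = "",
    denominator_mode: str = "informative",
    min_informative_frac: float = 0.8,
    chunk_size: int = 4096,
) -> FPVDTrack:
    """Compute the FPVD at every panel site over one hybrid set.

    Parameters
    ----------
    denominator_mode:
        ``"informative"`` (default) divides the number of differing pairs by
        the number of hybrids with both parents called at the site;
        ``"literal"`` divides by the total hybrid count n, counting
        uninformative hybrids as d = 0.
    min_informative_frac:
        Sites where n_informative < this fraction of n are reported as NaN.
    chunk_size:
        Hybrids are processed in blocks of this many rows, so simulated sets
        of tens of thousands of crosses stay within memory.
    """
    if denominator_mode not in ("informative", "literal"):
        raise ValueError(f"unknown denominator_mode {denominator_mode!r}")
    if len(hybrids) == 0:
        raise ValueError("hybrid set is empty")
    f_idx = panel.accession_indices(hybrids.table["female_id"])
    m_idx = panel.accession_indices(hybrids.table["male_id"])

    n_total = len(hybrids)
    sum_d = np.zeros(panel.n_sites, dtype=np.int64)
    n_inf = np.zeros(panel.n_sites, dtype=np.int64)
    for start in range(0, n_total, chunk_size):
        sel = slice(start, min(start + chunk_size, n_total))
        gf = panel.calls[f_idx[sel]]
        gm = panel.calls[m_idx[sel]]
        informative = (gf != MISSING) & (gm != MISSING)
        diff = informative & (gf != gm)
        sum_d += diff.sum(axis=0)
        n_inf += informative.sum(axis=0)

    if denominator_mode == "informative":
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(n_inf > 0, sum_d / np.maximum(n_inf, 1), np.nan)
    else:
        values = sum_d / float(n_total)
    values = np.where(n_inf < min_informative_frac * n_total, np.nan, values)

    table = pd.DataFrame(
        {
            "chrom": panel.sites["chrom"].to_numpy(),
            "pos": panel.sites["pos"].to_numpy(),
            "vclass": panel.sites["vclass"].to_numpy(),
            "fpvd": values,
            "n_informative": n_inf,
            "n_total": n_total,
        }
    )
    return FPVDTrack(
        label=label,
        table=table,
        denominator_mode=denominator_mode,
        min_informative_frac=min_informative_frac,
    )
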