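"""Candidate heterosis loci from an FPVD track.

Every site whose FPVD reaches the cut-off seeds a window of +/- half_window
around it (100 kb total by default); overlapping or touching windows are
merged into one locus.  Loci are reported in 0-based half-open coordinates
and written as BED.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .fpvd import FPVDTrack


@dataclass
class Locus:
    chrom: str
    start: int  # 0-based half-open
    end: int
    n_snps_over_cutoff: int = 0
    n_indels_over_cutoff: int = 0
    peak_fpvd: float = float("nan")
    peak_pos: int = -1  # 1-based position of the peak site
    clipped: bool = False
    gene_ids: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals; book-ended intervals are merged too."""
    if not intervals:
        return []
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def call_loci(
    track: FPVDTrack,
    cutoff: float = 0.9,
    half_window: int = 50_000,
    chrom_lengths: dict[str, int] | None = None,
    calling_classes: tuple[str, ...] = ("SNP",),
) -> list[Locus]:
    """Window + merge cutoff-exceeding sites into candidate loci.

    Loci are seeded from sites of ``calling_classes`` (SNPs by default) with
    defined FPVD >= cutoff (non-strict, matching a "0.9+" rule); per-locus
    SNP and indel counts then count cutoff-exceeding sites of either class
    inside the merged interval.  Windows are clipped at chromosome edges and
    such loci carry ``clipped=True``.
    """
    if not (0 < cutoff <= 1):
        raise ValueError(f"cutoff must be in (0, 1], got {cutoff}")
    if half_window <= 0:
        raise ValueError(f"half_window must be positive, got {half_window}")
    chrom_lengths = chrom_lengths or {}

    defined = track.defined()
    over = defined[defined["fpvd"] >= cutoff]
    seeds = over[over["vclass"].isin(calling_classes)]

    loci: list[Locus] = []
    for chrom, chrom_seeds in seeds.groupby("chrom", sort=True):
        if chrom not in chrom_lengths:
            raise KeyError(
                f"no chromosome length for {chrom!r} (needed to clip windows)"
            )
        length = chrom_lengths[chrom]
        intervals = []
        for pos in chrom_seeds["pos"]:
            p0 = int(pos) - 1
            intervals.append((max(0, p0 - half_window), min(length, p0 + half_window)))
        chrom_over = over[over["chrom"] == chrom]
        chrom_defined = defined[defined["chrom"] == chrom]
        for start, end in merge_intervals(intervals):
            inside_over = chrom_over[
                (chrom_over["pos"] - 1 >= start) & (chrom_over["pos"] - 1 < end)
            ]
            inside_def = chrom_defined[
                (chrom_defined["pos"] - 1 >= start) & (chrom_defined["pos"] - 1 < end)
            ]
            peak = inside_def.loc[inside_def["fpvd"].idxmax()]
            loci.append(
                Locus(
                    chrom=chrom,
                    start=start,
                    end=end,
                    n_snps_over_cutoff=int((inside_over["vclass"] == "SNP").sum()),
                    n_indels_over_cutoff=int((inside_over["vclass"] == "indel").sum()),
                    peak_fpvd=float(peak["fpvd"]),
                    peak_pos=int(peak["pos"]),
                    clipped=(end - start) < 2 * half_window,
                )
            )
    return loci


def annotate_loci(loci: list[Locus], genes: pd.DataFrame) -> list[Locus]:
    """Attach the ids of genes intersecting each locus by >= 1 bp.

    ``genes`` needs columns gene_id, chrom, start, end (0-based half-open,
    sorted per chromosome).
    """
    for locus in loci:
        hits = genes[
            (genes["chrom"] == locus.chrom)
            & (genes["start"] < locus.end)
            & (genes["end"] > locus.start)
        ]
        locus.gene_ids = hits["gene_id"].tolist()
    return loci


def compare_locus_sets(a: list[Locus], b: list[Locus]) -> dict[str, int]:
    """Count, per set, how many loci intersect >= 1 locus of the other set."""

    def overlaps(x: Locus, y: Locus) -> bool:
        return x.chrom == y.chrom and x.start < y.end and y.start < x.end

    a_hit = sum(1 for x in a if any(overlaps(x, y) for y in b))
    b_hit = sum(1 for y in b if any(overlaps(y, x) for x in a))
    return {
        "a_total": len(a),
        "b_total": len(b),
        "a_overlapping": a_hit,
        "b_overlapping": b_hit,
    }


def loci_to_frame(loci: list[Locus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": l.chrom,
                "start": l.start,
                "end": l.end,
                "length": l.length,
                "n_snps_over_cutoff": l.n_snps_over_cutoff,
                "n_indels_over_cutoff": l.n_indels_over_cutoff,
                "peak_fpvd": l.peak_fpvd,
                "peak_pos": l.peak_pos,
                "clipped": l.clipped,
                "gene_ids": ",".join(l.gene_ids),
            }
            for l in loci
        ],
        columns=[
            "chrom", "start", "end", "length", "n_snps_over_cutoff",
            "n_indels_over_cutoff", "peak_fpvd", "peak_pos", "clipped", "gene_ids",
        ],
    )


def write_loci_bed(loci: list[Locus], path) -> None:
    with open(path, "w") as fh:
        for i, l in enumerate(loci):
            fh.write(f"{l.chrom}\t{l.start}\t{l.end}\tlocus_{i + 1}\t{l.peak_fpvd:.4g}\t.\n")
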