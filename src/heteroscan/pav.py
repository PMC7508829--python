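"""Gene presence/absence variation (PAV) from read-depth tracks.

A gene's covered fraction for an accession is the number of gene bases with
read depth strictly greater than a threshold (2 by default) divided by the
gene length.  Genes with near-zero covered fraction are called absent; runs
of consecutive absent genes flag candidate large deletions, such as a
multi-gene deletion removing a whole locus from an accession.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class DepthTrack:
    """Sparse per-base depths for one accession.

    ``data`` maps chromosome -> (positions, depths) with 1-based sorted
    positions; any position absent from the track has depth 0.
    """

    accession: str
    data: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    @classmethod
    def from_frame(cls, accession: str, frame: pd.DataFrame) -> "DepthTrack":
        data = {}
        for chrom, grp in frame.groupby("chrom", sort=True):
            grp = grp.sort_values("pos")
            data[str(chrom)] = (
                grp["pos"].to_numpy(dtype=np.int64),
                grp["depth"].to_numpy(dtype=np.int64),
            )
        return cls(accession=accession, data=data)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.data):
                pos, depth = self.data[chrom]
                for p, d in zip(pos, depth):
                    fh.write(f"{chrom}\t{p}\t{d}\n")


def read_depth_tsv(path, accession: str) -> DepthTrack:
    """Read a samtools-depth style TSV (chrom, pos, depth; no header)."""
    frame = pd.read_csv(
        path, sep="\t", names=["chrom", "pos", "depth"], dtype={"chrom": str}
    )
    return DepthTrack.from_frame(accession, frame)


def gene_coverage_fraction(
    track: DepthTrack, chrom: str, start: int, end: int, min_depth: int = 2
) -> float:
    """Fraction of gene bases with depth strictly > min_depth.

    ``start``/``end`` are 0-based half-open; positions missing from the
    sparse track count as depth 0.
    """
    if start >= end:
        raise ValueError(f"inverted or empty interval [{start}, {end})")
    if chrom not in track.data:
        return 0.0
    pos, depth = track.data[chrom]
    lo = np.searchsorted(pos, start + 1, side="left")
    hi = np.searchsorted(pos, end, side="right")
    covered = int((depth[lo:hi] > min_depth).sum())
    return covered / (end - start)


def coverage_matrix(
    tracks: dict[str, DepthTrack], genes: pd.DataFrame, min_depth: int = 2
) -> pd.DataFrame:
    """Accession x gene matrix of covered fractions.

    ``genes`` needs columns gene_id, chrom, start, end (0-based half-open).
    """
    data = {
        acc: [
            gene_coverage_fraction(track, g.chrom, g.start, g.end, min_depth)
            for g in genes.itertuples(index=False)
        ]
        for acc, track in tracks.items()
    }
    return pd.DataFrame.from_dict(
        data, orient="index", columns=genes["gene_id"].tolist()
    )


def call_pav(
    coverages: pd.DataFrame, absent_max: float = 0.05, present_min: float = 0.95
) -> pd.DataFrame:
    """Present/absent/partial calls from covered fractions.

    absent if fraction <= absent_max, present if >= present_min, else
    partial.  The exact boundary between "completely absent" and merely
    low-coverage genes is a judgement call; both thresholds are exposed.
    """
    if not (0 <= absent_max < present_min <= 1):
        raise ValueError(
            f"need 0 <= absent_max < present_min <= 1, got {absent_max}, {present_min}"
        )
    values = coverages.to_numpy(dtype=float)
    calls = np.where(
        values <= absent_max, "absent", np.where(values >= present_min, "present", "partial")
    )
    return pd.DataFrame(calls, index=coverages.index, columns=coverages.columns)


def flag_deletion_runs(
    calls: pd.DataFrame, genes: pd.DataFrame, min_run: int = 2
) -> pd.DataFrame:
    """Candidate deletions: maximal runs of >= min_run consecutive absent genes.

    Genes are ordered by (chrom, start); runs never cross chromosomes.  Each
    candidate spans from the first absent gene's start to the last one's end.
    """
    genes = genes.sort_values(["chrom", "start"]).reset_index(drop=True)
    rows = []
    for acc in calls.index:
        for chrom, grp in genes.groupby("chrom", sort=True):
            run: list[pd.Series] = []
            for g in grp.itertuples(index=False):
                if calls.loc[acc, g.gene_id] == "absent":
                    run.append(g)
                else:
                    if len(run) >= min_run:
                        rows.append(_run_row(acc, chrom, run))
                    run = []
            if len(run) >= min_run:
                rows.append(_run_row(acc, chrom, run))
    return pd.DataFrame(
        rows, columns=["accession", "chrom", "start", "end", "n_genes", "gene_ids"]
    )


def _run_row(acc: str, chrom: str, run: list) -> tuple:
    return (
        acc, chrom, int(run[0].start), int(run[-1].end), len(run),
        ",".join(g.gene_id for g in run),
    )
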