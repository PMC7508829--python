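"""Windowed Weir-Cockerham F_st scan and selective-sweep calling.

Per-site variance components follow Weir & Cockerham (1984) for two
populations with the heterozygosity correction; windows combine sites as the
ratio of summed numerators to summed denominators (ratio of averages), the
standard way to aggregate the estimator.  Windows in the top fraction of the
distribution are flagged and merged into sweep regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel


def _pop_stats(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (n called individuals, alt allele freq, het fraction)."""
    called = calls != MISSING
    n = called.sum(axis=0).astype(float)
    dosage = np.where(called, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, dosage / (2 * n), np.nan)
        h = np.where(n > 0, (calls == 1).sum(axis=0) / np.maximum(n, 1), np.nan)
    return n, p, h


def site_fst(
    panel: GenotypePanel, pop_a: list[str], pop_b: list[str]
) -> pd.DataFrame:
    """Per-site Weir-Cockerham (1984) components for two populations.

    Returns a frame with chrom, pos, vclass, the among-population component
    ``a`` (numerator), the total ``a + b + c`` (denominator) and the per-site
    ratio ``fst``.  Sites with fewer than two called individuals in either
    population are NaN.
    """
    if set(pop_a) & set(pop_b):
        raise ValueError("populations overlap")
    ga = panel.calls[panel.accession_indices(pop_a)]
    gb = panel.calls[panel.accession_indices(pop_b)]
    n1, p1, h1 = _pop_stats(ga)
    n2, p2, h2 = _pop_stats(gb)

    usable = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / 2.0
        nc = 2.0 * nbar - (n1**2 + n2**2) / (2.0 * nbar)
        pbar = (n1 * p1 + n2 * p2) / (2.0 * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
        hbar = (n1 * h1 + n2 * h2) / (2.0 * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 / 2.0 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - s2 / 2.0 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
        denom = a + b + c
        fst = np.where(denom != 0, a / denom, np.nan)
    a = np.where(usable, a, np.nan)
    denom = np.where(usable, denom, np.nan)
    fst = np.where(usable, fst, np.nan)
    return pd.DataFrame(
        {
            "chrom": panel.sites["chrom"].to_numpy(),
            "pos": panel.sites["pos"].to_numpy(),
            "vclass": panel.sites["vclass"].to_numpy(),
            "a": a,
            "denom": denom,
            "fst": fst,
        }
    )


@dataclass
class WindowedFst:
    """Tiled-window F_st values.

    ``windows`` columns: chrom, start, end (0-based half-open), fst (ratio of
    summed components, NaN for empty windows), fst_clipped (display value in
    [0,1]), n_sites, flag.
    """

    windows: pd.DataFrame
    window_size: int
    step: int

    def non_empty(self) -> pd.DataFrame:
        return self.windows[self.windows["n_sites"] > 0]

    def to_tsv(self, path) -> None:
        self.windows.to_csv(path, sep="\t", index=False, float_format="%.6g")


def window_fst(
    components: pd.DataFrame,
    chrom_lengths: dict[str, int],
    window_size: int = 10_000,
    step: int = 10_000,
) -> WindowedFst:
    """Aggregate per-site components into tiling windows (10 kb / 10 kb)."""
    rows = []
    usable = components[components["denom"].notna()]
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        sites = usable[usable["chrom"] == chrom]
        p0 = sites["pos"].to_numpy() - 1
        for start in range(0, length, step):
            end = min(start + window_size, length)
            inside = (p0 >= start) & (p0 < end)
            n_sites = int(inside.sum())
            if n_sites:
                num = float(sites.loc[inside, "a"].sum())
                den = float(sites.loc[inside, "denom"].sum())
                fst = num / den if den != 0 else np.nan
            else:
                fst = np.nan
            rows.append((chrom, start, end, fst, n_sites))
    windows = pd.DataFrame(rows, columns=["chrom", "start", "end", "fst", "n_sites"])
    windows["fst_clipped"] = windows["fst"].clip(0.0, 1.0)
    windows["flag"] = False
    return WindowedFst(windows=windows, window_size=window_size, step=step)


def sweep_regions(
    wfst: WindowedFst, top_fraction: float = 0.01
) -> tuple[WindowedFst, pd.DataFrame]:
    """Flag top-fraction windows and merge adjacent flags into sweep regions.

    The threshold is the (1 - top_fraction) quantile of non-empty window
    values; comparison is non-strict, so ties at the quantile are all
    flagged.  Adjacent or overlapping flagged windows on a chromosome merge
    into one region.
    """
    if not (0 < top_fraction < 1):
        raise ValueError(f"top_fraction must be in (0, 1), got {top_fraction}")
    non_empty = wfst.non_empty()
    values = non_empty["fst"].dropna()
    if values.empty:
        raise ValueError("no non-empty windows to rank")
    threshold = float(np.quantile(values, 1.0 - top_fraction))
    windows = wfst.windows.copy()
    windows["flag"] = (windows["n_sites"] > 0) & (windows["fst"] >= threshold)

    regions = []
    for chrom, grp in windows[windows["flag"]].groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        cur_start, cur_end, n = None, None, 0
        for row in grp.itertuples(index=False):
            if cur_start is not None and row.start <= cur_end:
                cur_end = max(cur_end, row.end)
                n += 1
            else:
                if cur_start is not None:
                    regions.append((chrom, cur_start, cur_end, n))
                cur_start, cur_end, n = row.start, row.end, 1
        if cur_start is not None:
            regions.append((chrom, cur_start, cur_end, n))
    region_df = pd.DataFrame(regions, columns=["chrom", "start", "end", "n_windows"])
    flagged = WindowedFst(windows=windows, window_size=wfst.window_size, step=wfst.step)
    flagged.windows.attrs["threshold"] = threshold
    return flagged, region_df
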