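"""Relatedness analyses: IBS distances, kinship, clustering, subgroup calls.

Identity-by-state (IBS) distance between two accessions is one minus the mean
per-site allele-sharing similarity (2 - |dosage_i - dosage_j|) / 2 over sites
where both are called.  Kinship uses a centered (VanRaden-type) realized
relationship matrix; pairs above a coefficient threshold form a relationship
graph whose connected components are breeding clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ReferentialIntegrityError
from .panel import MISSING, GenotypePanel, HybridTable


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray  # symmetric, zero diagonal, values in [0,1] or NaN
    source: str = "nuclear"
    no_call_accessions: list[str] = field(default_factory=list)

    def pair(self, i: str, j: str) -> float:
        lookup = {a: k for k, a in enumerate(self.ids)}
        try:
            return float(self.matrix[lookup[i], lookup[j]])
        except KeyError as exc:
            raise ReferentialIntegrityError(f"accession {exc.args[0]!r} not in matrix") from None

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances: all N(N-1)/2 unordered pairs."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.matrix[iu]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.matrix, index=self.ids, columns=self.ids).to_csv(path, sep="\t")


def _dosage_indicators(calls: np.ndarray) -> tuple[np.ndarray, ...]:
    called = (calls != MISSING).astype(np.float64)
    return tuple((calls == g).astype(np.float64) for g in (0, 1, 2)) + (called,)


def ibs_distance_matrix(panel: GenotypePanel, source: str = "nuclear") -> DistanceMatrix:
    """Pairwise IBS genetic distances over all accessions.

    Computed via genotype-class indicator cross-products, so it is exact and
    runs in a handful of matrix multiplications.  Pairs with no co-called
    site get NaN; accessions with zero called sites are flagged.
    """
    if panel.n_accessions == 0 or panel.n_sites == 0:
        raise ValueError("panel must have at least one accession and one site")
    a0, a1, a2, called = _dosage_indicators(panel.calls)
    n_co = called @ called.T
    # sum over co-called sites of |g_i - g_j|: weight 1 for {0,1} and {1,2}
    # mismatches, 2 for opposite homozygotes
    s_abs = (a0 @ a1.T + a1 @ a0.T + a1 @ a2.T + a2 @ a1.T) + 2.0 * (a0 @ a2.T + a2 @ a0.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.where(n_co > 0, s_abs / (2.0 * np.maximum(n_co, 1)), np.nan)
    np.fill_diagonal(dist, 0.0)
    zero_call = [a for a, row in zip(panel.accessions, called) if row.sum() == 0]
    return DistanceMatrix(
        ids=list(panel.accessions), matrix=dist, source=source,
        no_call_accessions=zero_call,
    )


def parental_distance_summary(
    dist: DistanceMatrix,
    hybrid_sets: dict[str, HybridTable],
    include_background: bool = True,
) -> pd.DataFrame:
    """Distribution of parent-pair distances per hybrid set vs all pairs.

    The background row uses every unordered accession pair (N(N-1)/2 of
    them); each hybrid set additionally gets a two-tailed Welch t-test
    p-value against the background.
    """
    background = dist.condensed()
    background = background[~np.isnan(background)]

    def describe(values: np.ndarray, label: str, p_value: float | None) -> dict:
        return {
            "set": label,
            "n": len(values),
            "mean": float(np.mean(values)),
            "median": float(np.median(values)),
            "q1": float(np.percentile(values, 25)),
            "q3": float(np.percentile(values, 75)),
            "min": float(np.min(values)),
            "max": float(np.max(values)),
            "welch_p_vs_background": p_value,
        }

    rows = []
    if include_background:
        rows.append(describe(background, "background_all_pairs", None))
    for label, hybrids in hybrid_sets.items():
        if len(hybrids) == 0:
            raise ValueError(f"hybrid set {label!r} is empty")
        values = np.array(
            [dist.pair(f, m) for f, m in zip(hybrids.table["female_id"], hybrids.table["male_id"])]
        )
        p = float(stats.ttest_ind(values, background, equal_var=False).pvalue)
        rows.append(describe(values, label, p))
    return pd.DataFrame(rows)


def kinship_matrix(panel: GenotypePanel, method: str = "centered") -> np.ndarray:
    """Realized relationship matrix from dosage genotypes.

    ``centered`` (default): missing calls imputed to the site mean dosage,
    sites mean-centered, K = W W' / n_sites.  ``standardized`` additionally
    divides each site by its dosage standard deviation.  Monomorphic sites
    carry no signal and are dropped; an all-monomorphic panel is an error.
    """
    if method not in ("centered", "standardized"):
        raise ValueError(f"unknown kinship method {method!r}")
    if panel.n_accessions < 2:
        raise ValueError("kinship needs at least two accessions")
    calls = panel.calls.astype(np.float64)
    mask = panel.calls != MISSING
    calls[~mask] = np.nan
    means = np.nanmean(calls, axis=0)
    inds = np.where(np.isnan(calls), means, calls)
    w = inds - means
    if method == "standardized":
        sd = np.nanstd(calls, axis=0)
    else:
        sd = np.ones(panel.n_sites)
    poly = sd > 0 if method == "standardized" else np.nanstd(calls, axis=0) > 0
    if not poly.any():
        raise ValueError("panel has no polymorphic site")
    w = w[:, poly]
    if method == "standardized":
        w = w / sd[poly]
    return (w @ w.T) / w.shape[1]


@dataclass
class KinshipGraph:
    ids: list[str]
    threshold: float
    edges: pd.DataFrame  # columns: source, target, coefficient
    clusters: list[list[str]]  # components with >= 2 members
    singletons: list[str]

    @property
    def n_relationships(self) -> int:
        return len(self.edges)


def kinship_clusters(
    kinship: np.ndarray, ids: list[str], threshold: float = 0.45
) -> KinshipGraph:
    """Threshold the kinship matrix and cluster by connected components.

    Edges require coefficient strictly greater than the threshold (0.45 by
    default, 10% below the theoretical first-degree value of 0.5).
    """
    kinship = np.asarray(kinship, dtype=float)
    if kinship.shape != (len(ids), len(ids)):
        raise ValueError("kinship matrix shape does not match ids")
    if not np.allclose(kinship, kinship.T, atol=1e-8):
        raise ValueError("kinship matrix is not symmetric")
    iu, ju = np.triu_indices(len(ids), k=1)
    keep = kinship[iu, ju] > threshold
    edges = pd.DataFrame(
        {
            "source": [ids[i] for i in iu[keep]],
            "target": [ids[j] for j in ju[keep]],
            "coefficient": kinship[iu[keep], ju[keep]],
        }
    )
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    graph.add_weighted_edges_from(edges.itertuples(index=False, name=None))
    clusters, singletons = [], []
    for comp in nx.connected_components(graph):
        members = sorted(comp, key=ids.index)
        (clusters if len(members) >= 2 else singletons).append(
            members if len(members) >= 2 else members[0]
        )
    clusters.sort(key=lambda c: (-len(c), ids.index(c[0])))
    return KinshipGraph(
        ids=list(ids), threshold=threshold, edges=edges,
        clusters=clusters, singletons=sorted(singletons, key=ids.index),
    )


def classify_subgroup(
    panel: GenotypePanel,
    ref_indI: str,
    ref_indII: str,
    tie_band: float = 0.02,
) -> pd.Series:
    """Nearest-reference subgroup call per accession.

    Each accession is labelled after the nearer of two anchor accessions
    (typical IndI vs typical IndII) by IBS distance; accessions whose margin
    |d_I - d_II| falls below ``tie_band`` are left unassigned.
    """
    ref_idx = panel.accession_indices([ref_indI, ref_indII])
    a0, a1, a2, called = _dosage_indicators(panel.calls)
    r0, r1, r2, rcalled = (m[ref_idx] for m in (a0, a1, a2, called))
    n_co = called @ rcalled.T
    s_abs = (a0 @ r1.T + a1 @ r0.T + a1 @ r2.T + a2 @ r1.T) + 2.0 * (a0 @ r2.T + a2 @ r0.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(n_co > 0, s_abs / (2.0 * np.maximum(n_co, 1)), np.nan)
    labels = np.where(d[:, 0] <= d[:, 1], "IndI", "IndII")
    margin = np.abs(d[:, 0] - d[:, 1])
    labels = np.where(np.isnan(margin) | (margin < tie_band), "unassigned", labels)
    return pd.Series(labels, index=panel.accessions, name="subgroup")


def crossing_pattern_counts(
    hybrids: HybridTable, labels: dict[str, str]
) -> pd.DataFrame:
    """Contingency table of restorer subgroup (rows) x sterile subgroup (cols).

    The male parent is the restorer and the female parent the sterile line;
    parents without a label fall in the "unassigned" margin.  Cell counts sum
    to the number of hybrids.
    """
    order = ["IndI", "IndII", "unassigned"]
    counts = pd.DataFrame(0, index=order, columns=order, dtype=int)
    for f, m in zip(hybrids.table["female_id"], hybrids.table["male_id"]):
        r = labels.get(m, "unassigned")
        s = labels.get(f, "unassigned")
        counts.loc[r, s] += 1
    counts.index.name = "restorer_subgroup"
    counts.columns.name = "sterile_subgroup"
    return counts
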