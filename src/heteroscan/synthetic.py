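"""Synthetic genotype panels with planted truth for end-to-end testing.

The generator emulates the structure of a hybrid-rice parental resequencing
panel: two diverged indica-like subgroups of near-fully inbred accessions,
role-structured parental sets (CMS/GMS sterile lines, 3R/2R restorers,
maintainers and conventional lines), superior-hybrid pairings concentrated on
inter-subgroup crosses, plus planted signals with known truth — heterosis
sites at which superior parent pairs differ at a chosen rate, a
sterility/fertility site fixed for alternative alleles between sterile lines
and restorers, and a multi-gene deletion visible in depth tracks.

Subgroup allele frequencies follow a Balding-Nichols perturbation of a shared
ancestral frequency, so ``subgroup_divergence`` acts as the F parameter
controlling background differentiation (and hence background FPVD).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .panel import MISSING, AccessionTable, GenotypePanel, HybridTable
from .pav import DepthTrack

#: default accession counts per role (~120 accessions, proportioned like a
#: real parental panel: steriles and restorers dominate)
DEFAULT_ROLES = {
    "CMS": 22, "GMS": 12, "3R": 30, "2R": 9, "3M": 10, "CR": 25, "GR": 12,
}

#: probability that an accession of a role belongs to IndI (the rest IndII);
#: sterile CMS lines are mostly IndI, restorers and GMS mostly IndII
ROLE_INDI_PROB = {
    "CMS": 0.88, "3M": 0.88, "GMS": 0.20, "3R": 0.10, "2R": 0.10,
    "CR": 0.50, "GR": 0.35,
}

#: crossing-pattern weights (restorer subgroup, sterile subgroup) -> prob;
#: superior crosses concentrate on IndII restorer x IndI sterile
DEFAULT_PATTERN_WEIGHTS = {
    ("IndII", "IndI"): 0.90,
    ("IndII", "IndII"): 0.05,
    ("IndI", "IndI"): 0.04,
    ("IndI", "IndII"): 0.01,
}


@dataclass
class PanelConfig:
    """Shape and noise parameters of a synthetic panel."""

    n_accessions_per_role: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_ROLES)
    )
    n_chromosomes: int = 2
    chrom_length_bp: int = 5_000_000
    n_snps: int = 20_000
    n_indels: int = 2_000
    subgroup_divergence: float = 0.3
    missing_rate: float = 0.02
    residual_het_rate: float = 0.01
    seed: int = 0
    # planted signals
    heterosis_targets: tuple[float, ...] = (1.0, 1.0, 0.95)
    deletion_length_bp: int = 408_000
    deletion_n_accessions: int = 2
    n_genes_in_deletion: int = 4
    n_background_genes_per_chrom: int = 6
    gene_length_bp: int = 3_000

    def validate(self) -> None:
        for role, count in self.n_accessions_per_role.items():
            if count < 0:
                raise ConfigurationError(f"n_accessions_per_role[{role!r}] is negative")
        for name in ("n_chromosomes", "chrom_length_bp"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("n_snps", "n_indels"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} is negative")
        if not (0.0 <= self.subgroup_divergence <= 1.0):
            raise ConfigurationError("subgroup_divergence outside [0, 1]")
        for name in ("missing_rate", "residual_het_rate"):
            if not (0.0 <= getattr(self, name) < 1.0):
                raise ConfigurationError(f"{name} outside [0, 1)")
        if self.deletion_length_bp >= self.chrom_length_bp:
            raise ConfigurationError("deletion_length_bp exceeds chromosome length")


@dataclass
class PlantedTruth:
    """Ground truth of every planted signal in a synthetic panel."""

    heterosis_sites: list[tuple[str, int, float]]  # (chrom, pos 1-based, target FPVD)
    sterility_site: tuple[str, int]
    deletion_accessions: list[str]
    deletion: tuple[str, int, int]  # (chrom, start, end) 0-based half-open
    deletion_genes: list[tuple[str, str, int, int]]  # (gene_id, chrom, start, end)
    #: per-subgroup alternate-allele frequency vectors (numpy arrays; kept out
    #: of the JSON dump)
    subgroup_freqs: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload.pop("subgroup_freqs", None)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=str)


def _chrom_name(i: int) -> str:
    return f"chr{i + 1:02d}"


_BASES = np.array(list("ACGT"))


def generate_panel(
    config: PanelConfig,
) -> tuple[GenotypePanel, AccessionTable, PlantedTruth]:
    """Draw a role- and subgroup-structured inbred panel with planted truth.

    Genotypes are near-homozygous dosages drawn per subgroup from
    Balding-Nichols diverged allele frequencies; missing calls are injected
    at ``missing_rate`` (sparing the planted sterility site so its fixation
    stays exact).  Heterosis sites are only *recorded* here; they are planted
    against a concrete hybrid table by :func:`plant_heterosis_sites`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    # accessions: roles, subgroups
    ids, roles, subgroups = [], [], []
    for role in sorted(config.n_accessions_per_role):
        for k in range(config.n_accessions_per_role[role]):
            ids.append(f"{role}_{k + 1:03d}")
            roles.append(role)
            p_indI = ROLE_INDI_PROB.get(role, 0.5)
            subgroups.append("IndI" if rng.random() < p_indI else "IndII")
    accessions = AccessionTable(
        pd.DataFrame({"id": ids, "role": roles, "subgroup": subgroups})
    )
    is_indI = np.array([s == "IndI" for s in subgroups])

    # sites: positions unique per chromosome, SNP/indel classes interleaved
    n_sites = config.n_snps + config.n_indels
    per_chrom = np.full(config.n_chromosomes, n_sites // config.n_chromosomes)
    per_chrom[: n_sites % config.n_chromosomes] += 1
    chroms, poss = [], []
    for c in range(config.n_chromosomes):
        pos = rng.choice(
            np.arange(1, config.chrom_length_bp + 1), size=per_chrom[c], replace=False
        )
        pos.sort()
        chroms.extend([_chrom_name(c)] * per_chrom[c])
        poss.extend(pos.tolist())
    vclass = np.array(["SNP"] * config.n_snps + ["indel"] * config.n_indels)
    rng.shuffle(vclass)
    refs, alts = _draw_alleles(rng, vclass)
    sites = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts, "vclass": vclass}
    )

    # Balding-Nichols subgroup frequencies around an ancestral frequency
    anc = rng.uniform(0.05, 0.95, size=n_sites)
    f = config.subgroup_divergence
    if f == 0.0:
        p_indI_freq = anc.copy()
        p_indII_freq = anc.copy()
    else:
        shape = (1.0 - f) / f
        p_indI_freq = rng.beta(anc * shape, (1.0 - anc) * shape)
        p_indII_freq = rng.beta(anc * shape, (1.0 - anc) * shape)

    # inbred genotypes: hom alt with subgroup prob, rare residual hets
    p_row = np.where(is_indI[:, None], p_indI_freq[None, :], p_indII_freq[None, :])
    calls = np.where(
        rng.random((len(ids), n_sites)) < p_row, 2, 0
    ).astype(np.int8)
    het = rng.random((len(ids), n_sites)) < config.residual_het_rate
    calls[het] = 1

    # planted sterility/fertility site: steriles fixed ref, restorers fixed alt
    role_arr = np.array(roles)
    sterile = np.isin(role_arr, ("CMS", "GMS"))
    restorer = np.isin(role_arr, ("3R", "2R"))
    snp_idx = np.flatnonzero(vclass == "SNP")
    sterility_j = int(snp_idx[len(snp_idx) // 3]) if len(snp_idx) else 0
    calls[sterile, sterility_j] = 0
    calls[restorer, sterility_j] = 2
    sterility_site = (str(sites["chrom"].iat[sterility_j]), int(sites["pos"].iat[sterility_j]))

    # missingness (sparing the sterility site)
    miss = rng.random((len(ids), n_sites)) < config.missing_rate
    miss[:, sterility_j] = False
    calls[miss] = MISSING

    # record intended heterosis sites: spaced SNPs away from the sterility site
    heterosis_sites = []
    if config.heterosis_targets and len(snp_idx):
        picks = np.linspace(0, len(snp_idx) - 1, len(config.heterosis_targets) + 2)[1:-1]
        for target, pk in zip(config.heterosis_targets, picks):
            j = int(snp_idx[int(pk)])
            if j == sterility_j:
                j = int(snp_idx[min(int(pk) + 1, len(snp_idx) - 1)])
            heterosis_sites.append(
                (str(sites["chrom"].iat[j]), int(sites["pos"].iat[j]), float(target))
            )

    # planted deletion: a contiguous block on the last chromosome, removed
    # from a few sterile-line accessions (mirrors a multi-gene deletion
    # carried by two CMS lines)
    del_chrom = _chrom_name(config.n_chromosomes - 1)
    del_start = int(config.chrom_length_bp * 0.55)
    del_end = del_start + config.deletion_length_bp
    candidates = [i for i, r in zip(ids, roles) if r == "CMS"] or ids
    deletion_accessions = list(candidates[: config.deletion_n_accessions])
    gene_len = config.gene_length_bp
    gap = (config.deletion_length_bp - config.n_genes_in_deletion * gene_len) // (
        config.n_genes_in_deletion + 1
    )
    deletion_genes = []
    cursor = del_start + gap
    for g in range(config.n_genes_in_deletion):
        deletion_genes.append((f"delgene_{g + 1:02d}", del_chrom, cursor, cursor + gene_len))
        cursor += gene_len + gap

    panel = GenotypePanel(accessions=ids, sites=sites, calls=calls)
    truth = PlantedTruth(
        heterosis_sites=heterosis_sites,
        sterility_site=sterility_site,
        deletion_accessions=deletion_accessions,
        deletion=(del_chrom, del_start, del_end),
        deletion_genes=deletion_genes,
        subgroup_freqs={"IndI": p_indI_freq, "IndII": p_indII_freq},
    )
    return panel, accessions, truth


def _draw_alleles(rng, vclass: np.ndarray) -> tuple[list[str], list[str]]:
    refs, alts = [], []
    for vc in vclass:
        ref_base = str(rng.choice(_BASES))
        if vc == "SNP":
            alt = str(rng.choice([b for b in _BASES if b != ref_base]))
            refs.append(ref_base)
            alts.append(alt)
        else:
            ins = rng.random() < 0.5
            extra = "".join(rng.choice(_BASES, size=int(rng.integers(1, 4))))
            if ins:
                refs.append(ref_base)
                alts.append(ref_base + extra)
            else:
                refs.append(ref_base + extra)
                alts.append(ref_base)
    return refs, alts


def generate_hybrid_table(
    accessions: AccessionTable,
    n_superior_3line: int,
    n_superior_2line: int,
    pattern_weights: dict[tuple[str, str], float] | None = None,
    seed: int = 0,
) -> HybridTable:
    """Sample distinct superior parent pairs with subgroup-pattern skew.

    3-line pairs come from 3R restorers x CMS steriles, 2-line pairs from
    (3R or 2R) x GMS.  Cell counts over (restorer subgroup x sterile
    subgroup) follow ``pattern_weights``; when a cell runs out of distinct
    pairs the remainder spills into the other cells.
    """
    rng = np.random.default_rng(seed)
    weights = pattern_weights or DEFAULT_PATTERN_WEIGHTS
    subgroup = accessions.subgroup_of()
    rows = []
    for system, n_wanted, restorer_roles, sterile_roles in (
        ("3-line", n_superior_3line, ("3R",), ("CMS",)),
        ("2-line", n_superior_2line, ("3R", "2R"), ("GMS",)),
    ):
        restorers = accessions.ids_with_role(*restorer_roles)
        steriles = accessions.ids_with_role(*sterile_roles)
        cells: dict[tuple[str, str], list[tuple[str, str]]] = {}
        for r in restorers:
            for s in steriles:
                cells.setdefault((subgroup[r], subgroup[s]), []).append((s, r))
        n_available = sum(len(v) for v in cells.values())
        if n_wanted > n_available:
            raise ValueError(
                f"{n_wanted} {system} pairs requested but only "
                f"{n_available} distinct eligible pairs exist"
            )
        for pairs in cells.values():
            order = rng.permutation(len(pairs))
            pairs[:] = [pairs[i] for i in order]
        cell_keys = sorted(cells, key=lambda k: -weights.get(k, 0.0))
        w = np.array([weights.get(k, 0.0) for k in cell_keys], dtype=float)
        if w.sum() == 0:
            w = np.ones(len(cell_keys))
        quotas = rng.multinomial(n_wanted, w / w.sum())
        chosen: list[tuple[str, str]] = []
        # take quota per cell, then spill any shortfall into remaining pairs
        leftovers: list[tuple[str, str]] = []
        for key, quota in zip(cell_keys, quotas):
            take = min(quota, len(cells[key]))
            chosen.extend(cells[key][:take])
            leftovers.extend(cells[key][take:])
        shortfall = n_wanted - len(chosen)
        if shortfall > 0:
            order = rng.permutation(len(leftovers))
            chosen.extend(leftovers[i] for i in order[:shortfall])
        for k, (s, r) in enumerate(chosen):
            rows.append((f"sup_{system}_{k + 1:04d}", s, r, system, "superior"))
    table = pd.DataFrame(
        rows, columns=["hybrid_id", "female_id", "male_id", "system", "status"]
    )
    return HybridTable(table)


def plant_heterosis_sites(
    panel: GenotypePanel,
    hybrids: HybridTable,
    sites: list[tuple[str, int, float]],
    seed: int = 0,
) -> GenotypePanel:
    """Rewrite parental genotypes so planted sites hit their target FPVD.

    At each site every female (sterile) parent is set hom-ref; a subset of
    male (restorer) parents chosen by subset-sum over their hybrid counts is
    set hom-alt so that the realized fraction of differing superior pairs
    equals the target within 1/n_hybrids.  Planted calls are concrete (never
    missing).
    """
    rng = np.random.default_rng(seed)
    calls = panel.calls.copy()
    females = hybrids.table["female_id"].tolist()
    males = hybrids.table["male_id"].tolist()
    n = len(hybrids)
    male_counts: dict[str, int] = {}
    for m in males:
        male_counts[m] = male_counts.get(m, 0) + 1
    male_ids = list(male_counts)

    f_idx = panel.accession_indices(sorted(set(females)))
    for chrom, pos, target in sites:
        j = panel.site_index(chrom, pos)  # raises LookupError for unknown site
        k_target = int(round(target * n))
        chosen = _subset_sum_choice(
            [male_counts[m] for m in male_ids], k_target, rng
        )
        calls[f_idx, j] = 0
        for m, pick in zip(male_ids, chosen):
            calls[panel.accession_indices([m])[0], j] = 2 if pick else 0
    return GenotypePanel(
        accessions=list(panel.accessions), sites=panel.sites, calls=calls
    )


def _subset_sum_choice(weights: list[int], target: int, rng) -> list[bool]:
    """Pick a subset of weights summing as close to target as possible.

    Exact dynamic program over achievable sums; ties between equally close
    sums and between alternative subsets are broken by the shuffled item
    order, keeping planting seed-reproducible but not degenerate.
    """
    order = rng.permutation(len(weights))
    total = sum(weights)
    target = max(0, min(target, total))
    # reachable[s] = index (into order) of last item used to reach sum s
    reachable = [-2] * (total + 1)
    reachable[0] = -1
    for oi, idx in enumerate(order):
        w = weights[idx]
        for s in range(total, w - 1, -1):
            if reachable[s] == -2 and reachable[s - w] != -2 and reachable[s - w] != oi:
                reachable[s] = oi
    # nearest achievable sum to target
    best = min(
        (s for s in range(total + 1) if reachable[s] != -2),
        key=lambda s: (abs(s - target), s),
    )
    chosen = [False] * len(weights)
    s = best
    while s > 0:
        oi = reachable[s]
        idx = order[oi]
        chosen[idx] = True
        s -= weights[idx]
    return chosen


def generate_gene_models(
    config: PanelConfig, truth: PlantedTruth, seed: int = 0
) -> pd.DataFrame:
    """Gene intervals: background genes per chromosome plus the deletion genes.

    Returns columns gene_id, chrom, start, end (0-based half-open), sorted.
    """
    rng = np.random.default_rng(seed)
    del_chrom, del_start, del_end = truth.deletion
    rows = [(gid, chrom, start, end) for gid, chrom, start, end in truth.deletion_genes]
    for c in range(config.n_chromosomes):
        chrom = _chrom_name(c)
        usable = config.chrom_length_bp - config.gene_length_bp
        k = 0
        while k < config.n_background_genes_per_chrom:
            start = int(rng.integers(0, usable))
            end = start + config.gene_length_bp
            if chrom == del_chrom and start < del_end and end > del_start:
                continue  # keep background genes outside the planted deletion
            rows.append((f"gene_{chrom}_{k + 1:02d}", chrom, start, end))
            k += 1
    frame = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])
    return frame.sort_values(["chrom", "start"]).reset_index(drop=True)


def generate_depth_track(
    panel_accessions: list[str],
    genes: pd.DataFrame,
    deletion: tuple[list[str], str, int, int],
    base_depth: int = 17,
    seed: int = 0,
    flank_bp: int = 200,
) -> dict[str, DepthTrack]:
    """Per-accession sparse depth tracks over gene bodies (plus flanks).

    Depth is ``base_depth`` with small bounded jitter (+/- 2) everywhere
    except inside the deletion for the deleted accessions, where positions
    are simply absent (depth 0).  Tracks are restricted to annotated gene
    neighbourhoods, which is all the PAV caller reads.
    """
    deleted_ids, del_chrom, del_start, del_end = deletion
    if del_start >= del_end:
        raise ValueError(f"deletion interval inverted: [{del_start}, {del_end})")
    rng = np.random.default_rng(seed)
    tracks: dict[str, DepthTrack] = {}
    for acc in panel_accessions:
        data: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
        is_deleted = acc in deleted_ids
        for g in genes.itertuples(index=False):
            start = max(0, g.start - flank_bp)
            pos = np.arange(start + 1, g.end + flank_bp + 1, dtype=np.int64)
            depth = base_depth + rng.integers(-2, 3, size=len(pos))
            if is_deleted and g.chrom == del_chrom:
                inside = (pos - 1 >= del_start) & (pos - 1 < del_end)
                pos, depth = pos[~inside], depth[~inside]
            if len(pos):
                data.setdefault(g.chrom, []).append((pos, depth))
        merged = {}
        for chrom, parts in data.items():
            pos = np.concatenate([p for p, _ in parts])
            depth = np.concatenate([d for _, d in parts])
            order = np.argsort(pos, kind="stable")
            pos, depth = pos[order], depth[order]
            uniq = np.concatenate(([True], pos[1:] != pos[:-1]))
            merged[chrom] = (pos[uniq], depth[uniq])
        tracks[acc] = DepthTrack(accession=acc, data=merged)
    return tracks
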