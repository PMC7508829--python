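"""End-to-end pipeline: synthesize -> filter -> FPVD -> calibrate -> loci ->
F_st -> relatedness -> PAV, with a JSON run manifest.

Every stage writes its outputs under the run's output directory and appends a
manifest entry (row counts, output paths).  All randomness is routed through
per-stage seeds derived from the run seed, so a rerun with the same
configuration reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError
from .fpvd import FPVDTrack, fpvd_track
from .fst import site_fst, sweep_regions, window_fst
from .io import (
    apply_site_filters,
    read_vcf_panel,
    write_accession_table,
    write_gff3_genes,
    write_hybrid_table,
    write_vcf,
)
from .loci import annotate_loci, call_loci, loci_to_frame, write_loci_bed
from .nullmodel import calibrate_cutoff, enumerate_inferior
from .panel import RESTORER_ROLES, STERILE_ROLES
from .pav import call_pav, coverage_matrix, flag_deletion_runs
from .relatedness import (
    classify_subgroup,
    crossing_pattern_counts,
    ibs_distance_matrix,
    kinship_clusters,
    kinship_matrix,
    parental_distance_summary,
)
from .synthetic import (
    PanelConfig,
    generate_depth_track,
    generate_gene_models,
    generate_hybrid_table,
    generate_panel,
    plant_heterosis_sites,
)

STAGES = (
    "synthesize", "filter", "fpvd", "calibrate",
    "loci", "fst", "relatedness", "pav",
)


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    out_dir: str = "heteroscan_run"
    seed: int = 0
    panel: PanelConfig = field(default_factory=PanelConfig)
    n_superior_3line: int = 40
    n_superior_2line: int = 15
    fpvd_cutoff: float = 0.9
    half_window: int = 50_000
    denominator_mode: str = "informative"
    maf_min: float = 0.01
    min_call_rate: float = 0.8
    fst_window: int = 10_000
    fst_step: int = 10_000
    fst_top_fraction: float = 0.01
    kinship_threshold: float = 0.45
    pav_absent_max: float = 0.05
    pav_present_min: float = 0.95
    depth_tsv_accessions: int = 3  # how many example depth TSVs to write

    def validate(self) -> None:
        if not (0 < self.fpvd_cutoff <= 1):
            raise ConfigurationError(f"fpvd_cutoff {self.fpvd_cutoff} outside (0, 1]")
        if self.half_window <= 0:
            raise ConfigurationError("half_window must be positive")
        if not (0 < self.fst_top_fraction < 1):
            raise ConfigurationError("fst_top_fraction outside (0, 1)")
        if not (0 <= self.pav_absent_max < self.pav_present_min <= 1):
            raise ConfigurationError("inconsistent PAV thresholds")
        if self.denominator_mode not in ("informative", "literal"):
            raise ConfigurationError(f"unknown denominator_mode {self.denominator_mode!r}")
        self.panel.validate()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        panel_raw = raw.pop("panel", {})
        if "n_accessions_per_role" in panel_raw:
            panel_raw["n_accessions_per_role"] = dict(panel_raw["n_accessions_per_role"])
        if "heterosis_targets" in panel_raw:
            panel_raw["heterosis_targets"] = tuple(panel_raw["heterosis_targets"])
        config = cls(**raw, panel=PanelConfig(**panel_raw))
        return config

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["panel"]["heterosis_targets"] = list(d["panel"]["heterosis_targets"])
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    chrom_lengths = {
        f"chr{i + 1:02d}": config.panel.chrom_length_bp
        for i in range(config.panel.n_chromosomes)
    }
    manifest: dict = {
        "tool": "heteroscan",
        "version": __version__,
        "python": platform.python_version(),
        "seed": seed,
        "config": config.to_dict(),
        "stages": [],
        "input_checksums": {},
    }

    def record(stage: str, outputs: dict[str, Path], counts: dict[str, int]) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "status": "completed",
                "outputs": {k: str(v) for k, v in outputs.items()},
                "row_counts": counts,
            }
        )

    try:
        # -- synthesize ----------------------------------------------------
        panel_cfg = dataclasses.replace(config.panel, seed=seed)
        panel, accessions, truth = generate_panel(panel_cfg)
        hybrids = generate_hybrid_table(
            accessions, config.n_superior_3line, config.n_superior_2line,
            seed=seed + 1,
        )
        panel = plant_heterosis_sites(
            panel, hybrids.subset(system="3-line"), truth.heterosis_sites,
            seed=seed + 2,
        )
        genes = generate_gene_models(panel_cfg, truth, seed=seed + 3)
        tracks = generate_depth_track(
            list(panel.accessions), genes,
            (truth.deletion_accessions, *truth.deletion), seed=seed + 4,
        )
        paths = {
            "vcf": out / "panel.vcf",
            "accessions": out / "accessions.tsv",
            "hybrids": out / "hybrids.tsv",
            "genes": out / "genes.gff3",
            "truth": out / "planted_truth.json",
        }
        write_vcf(panel, paths["vcf"], chrom_lengths)
        write_accession_table(accessions, paths["accessions"])
        write_hybrid_table(hybrids, paths["hybrids"])
        write_gff3_genes(genes, paths["genes"])
        truth.to_json(paths["truth"])
        for i, acc in enumerate(sorted(tracks)[: config.depth_tsv_accessions]):
            p = out / f"depth_{acc}.tsv"
            tracks[acc].to_tsv(p)
            paths[f"depth_{acc}"] = p
        manifest["input_checksums"] = {
            k: _sha256(v) for k, v in paths.items() if v.suffix != ".json"
        }
        record("synthesize", paths, {
            "accessions": len(accessions), "sites": panel.n_sites, "hybrids": len(hybrids),
        })

        # -- filter --------------------------------------------------------
        panel = read_vcf_panel(paths["vcf"])
        filtered = apply_site_filters(panel, config.maf_min, config.min_call_rate)
        fvcf = out / "panel.filtered.vcf"
        write_vcf(filtered, fvcf, chrom_lengths)
        record("filter", {"vcf": fvcf}, {
            "sites_in": panel.n_sites, "sites_out": filtered.n_sites,
        })

        # -- fpvd ----------------------------------------------------------
        sup3 = hybrids.subset(system="3-line", status="superior")
        sup2 = hybrids.subset(system="2-line", status="superior")
        tracks_out: dict[str, FPVDTrack] = {}
        outputs = {}
        for label, subset in (("superior_3line", sup3), ("superior_2line", sup2)):
            if len(subset) == 0:
                continue
            track = fpvd_track(
                filtered, subset, label=label,
                denominator_mode=config.denominator_mode,
            )
            p = out / f"fpvd_{label}.tsv"
            track.to_tsv(p)
            tracks_out[label] = track
            outputs[label] = p
        record("fpvd", outputs, {k: len(v.table) for k, v in tracks_out.items()})

        # -- calibrate -----------------------------------------------------
        inferior = {}
        for system, sup in (("3-line", sup3), ("2-line", sup2)):
            restorers = accessions.ids_with_role(*RESTORER_ROLES[system])
            steriles = accessions.ids_with_role(*STERILE_ROLES[system])
            inferior[system] = enumerate_inferior(restorers, steriles, sup, system)
        inf_track = fpvd_track(
            filtered, inferior["3-line"], label="inferior_3line",
            denominator_mode=config.denominator_mode,
        )
        inf_track.to_tsv(out / "fpvd_inferior_3line.tsv")
        ster_chrom, ster_pos = truth.sterility_site
        known = pd.DataFrame(
            [
                {
                    "label": "sterility_gene",
                    "chrom": ster_chrom,
                    "start": max(0, ster_pos - 1 - 25_000),
                    "end": ster_pos - 1 + 25_000,
                }
            ]
        )
        report = calibrate_cutoff(inf_track, known)
        calib_json = out / "calibration.json"
        calib_json.write_text(json.dumps(report.to_json_dict(), indent=1))
        report.genes.to_csv(out / "calibration.tsv", sep="\t", index=False)
        record("calibrate", {
            "inferior_track": out / "fpvd_inferior_3line.tsv", "report": calib_json,
        }, {
            "inferior_3line": len(inferior["3-line"]),
            "inferior_2line": len(inferior["2-line"]),
        })

        # -- loci ----------------------------------------------------------
        locus_counts = {}
        locus_outputs = {}
        for label, track in tracks_out.items():
            loci = call_loci(
                track, cutoff=config.fpvd_cutoff,
                half_window=config.half_window, chrom_lengths=chrom_lengths,
            )
            loci = annotate_loci(loci, genes)
            bed = out / f"loci_{label}.bed"
            tsv = out / f"loci_{label}.tsv"
            write_loci_bed(loci, bed)
            loci_to_frame(loci).to_csv(tsv, sep="\t", index=False)
            locus_counts[label] = len(loci)
            locus_outputs[label] = tsv
        record("loci", locus_outputs, locus_counts)

        # -- fst -----------------------------------------------------------
        comp = site_fst(
            filtered,
            accessions.ids_with_role("3R"),
            accessions.ids_with_role("CMS"),
        )
        wfst = window_fst(comp, chrom_lengths, config.fst_window, config.fst_step)
        flagged, regions = sweep_regions(wfst, config.fst_top_fraction)
        flagged.to_tsv(out / "fst_windows.tsv")
        regions.to_csv(out / "sweep_regions.bed", sep="\t", index=False, header=False)
        record("fst", {
            "windows": out / "fst_windows.tsv", "regions": out / "sweep_regions.bed",
        }, {"windows": len(flagged.windows), "sweep_regions": len(regions)})

        # -- relatedness ---------------------------------------------------
        dist = ibs_distance_matrix(filtered)
        dist.to_tsv(out / "ibs_distances.tsv")
        summary = parental_distance_summary(
            dist, {"superior_3line": sup3, "superior_2line": sup2}
        )
        summary.to_csv(out / "parental_distances.tsv", sep="\t", index=False)
        kin = kinship_matrix(filtered)
        graph = kinship_clusters(kin, list(filtered.accessions), config.kinship_threshold)
        graph.edges.to_csv(out / "kinship_edges.tsv", sep="\t", index=False)
        clusters = pd.DataFrame(
            [
                {"cluster": i + 1, "accession": a}
                for i, members in enumerate(graph.clusters)
                for a in members
            ]
        )
        clusters.to_csv(out / "kinship_clusters.tsv", sep="\t", index=False)
        ref_I = accessions.table.loc[accessions.table["subgroup"] == "IndI", "id"].iloc[0]
        ref_II = accessions.table.loc[accessions.table["subgroup"] == "IndII", "id"].iloc[0]
        labels = classify_subgroup(filtered, ref_I, ref_II)
        labels.to_csv(out / "subgroups.tsv", sep="\t", header=True)
        patterns = crossing_pattern_counts(sup3, labels.to_dict())
        patterns.to_csv(out / "crossing_patterns.tsv", sep="\t")
        record("relatedness", {
            "distances": out / "ibs_distances.tsv",
            "summary": out / "parental_distances.tsv",
            "clusters": out / "kinship_clusters.tsv",
            "patterns": out / "crossing_patterns.tsv",
        }, {
            "clusters": len(graph.clusters),
            "relationships": graph.n_relationships,
            "singletons": len(graph.singletons),
        })

        # -- pav -----------------------------------------------------------
        cov = coverage_matrix(tracks, genes)
        calls = call_pav(cov, config.pav_absent_max, config.pav_present_min)
        runs = flag_deletion_runs(calls, genes)
        cov.to_csv(out / "gene_coverage.tsv", sep="\t")
        calls.to_csv(out / "gene_pav.tsv", sep="\t")
        runs.to_csv(out / "deletion_candidates.bed", sep="\t", index=False, header=False)
        record("pav", {
            "coverage": out / "gene_coverage.tsv",
            "pav": out / "gene_pav.tsv",
            "deletions": out / "deletion_candidates.bed",
        }, {"genes": cov.shape[1], "deletion_candidates": len(runs)})
    except Exception as exc:
        manifest["stages"].append({"stage": "failed", "status": "failed", "error": str(exc)})
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def make_report(manifest: dict, out_dir: str | None = None) -> Path:
    """Render a markdown summary (+ per-chromosome FPVD plots) from a manifest.

    Sections whose stage outputs are missing are marked unavailable rather
    than failing.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir or Path(manifest["config"]["out_dir"]))
    out.mkdir(parents=True, exist_ok=True)
    by_stage = {s["stage"]: s for s in manifest["stages"]}
    lines = [
        "# heteroscan run report",
        "",
        f"- version: {manifest['version']}",
        f"- seed: {manifest['seed']}",
        "",
    ]

    fpvd_stage = by_stage.get("fpvd")
    if fpvd_stage and all(Path(p).exists() for p in fpvd_stage["outputs"].values()):
        lines.append("## FPVD scans\n")
        for label, path in fpvd_stage["outputs"].items():
            track = pd.read_csv(path, sep="\t", dtype={"chrom": str})
            fig_path = out / f"fpvd_{label}.png"
            chroms = sorted(track["chrom"].unique())
            fig, axes = plt.subplots(
                1, max(len(chroms), 1), figsize=(4 * max(len(chroms), 1), 2.5),
                squeeze=False, sharey=True,
            )
            for ax, chrom in zip(axes[0], chroms):
                sub = track[(track["chrom"] == chrom) & track["fpvd"].notna()]
                ax.plot(sub["pos"] / 1e6, sub["fpvd"], ".", ms=1)
                ax.set_title(chrom)
                ax.set_xlabel("Mb")
                ax.set_ylim(0, 1.05)
            axes[0][0].set_ylabel("FPVD")
            fig.tight_layout()
            fig.savefig(fig_path, dpi=100)
            plt.close(fig)
            lines.append(f"![{label}]({fig_path.name})\n")
    else:
        lines.append("## FPVD scans\n\n_unavailable_\n")

    for title, stage, key in (
        ("Candidate loci", "loci", None),
        ("Calibration", "calibrate", "report"),
        ("Sweep/locus cross-check", "fst", "windows"),
        ("Crossing patterns", "relatedness", "patterns"),
        ("Gene PAV", "pav", "pav"),
    ):
        lines.append(f"## {title}\n")
        stage_rec = by_stage.get(stage)
        if not stage_rec:
            lines.append("_unavailable_\n")
            continue
        targets = (
            [stage_rec["outputs"].get(key)] if key else list(stage_rec["outputs"].values())
        )
        targets = [t for t in targets if t]
        if not targets or not all(Path(t).exists() for t in targets):
            lines.append("_unavailable_\n")
            continue
        for t in targets:
            path = Path(t)
            if path.suffix == ".json":
                lines.append("```json\n" + path.read_text().strip() + "\n```\n")
            else:
                frame = pd.read_csv(path, sep="\t")
                lines.append("```\n" + frame.head(25).to_string(index=False) + "\n```\n")
        counts = stage_rec.get("row_counts", {})
        if counts:
            lines.append("counts: " + ", ".join(f"{k}={v}" for k, v in counts.items()) + "\n")

    report_path = out / "report.md"
    report_path.write_text("\n".join(lines))
    return report_path
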