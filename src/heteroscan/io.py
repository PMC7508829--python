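"""File I/O: VCF genotype panels, metadata tables, GFF3 gene models, filters.

VCF parsing goes through cyvcf2; only biallelic diploid GT records are
modelled.  External coordinates follow each format's convention (VCF 1-based,
BED/GFF-derived gene frames 0-based half-open internally).
"""

from __future__ import annotations

import gffutils
import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .errors import FormatError, ParseError, ValidationError
from .panel import (
    MISSING,
    AccessionTable,
    GenotypePanel,
    HybridTable,
    classify_variant,
)

# cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
_GT_TYPE_TO_CODE = np.array([0, 1, MISSING, 2], dtype=np.int8)


def read_vcf_panel(
    path, min_gq: float | None = 5.0, multiallelic: str = "error"
) -> GenotypePanel:
    """Read a VCF into a :class:`GenotypePanel`.

    GT fields map as 0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2, ./. -> missing;
    sites are classed SNP vs indel from allele lengths.  When the FORMAT
    block carries GQ, calls with GQ below ``min_gq`` are set to missing
    (mirroring a vcftools ``--minGQ`` pass); VCFs without GQ are read as-is.
    ``multiallelic`` is one of "error", "drop" or "split" (one biallelic
    record per alternate allele, other-alt calls set missing).
    """
    if multiallelic not in ("error", "drop", "split"):
        raise ValueError(f"unknown multiallelic policy {multiallelic!r}")
    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise ParseError(f"cannot open VCF {path}: {exc}") from exc

    accessions = list(vcf.samples)
    chroms, poss, refs, alts, classes, rows = [], [], [], [], [], []
    ploidy_checked = False
    for k, variant in enumerate(vcf):
        if len(variant.ALT) != 1:
            if multiallelic == "drop":
                continue
            if multiallelic == "error":
                raise FormatError(
                    f"multiallelic record at {variant.CHROM}:{variant.POS} "
                    f"(record {k + 1}); pass multiallelic='drop' or 'split'"
                )
        if not ploidy_checked and accessions:
            gts = variant.genotypes
            if any(len(g) != 3 for g in gts):
                raise FormatError(
                    f"non-diploid GT at {variant.CHROM}:{variant.POS}"
                )
            ploidy_checked = True
        if len(variant.ALT) == 1:
            codes = _GT_TYPE_TO_CODE[variant.gt_types]
            alt_list = [(variant.ALT[0], codes)]
        else:  # split
            alt_list = []
            gts = np.array([g[:2] for g in variant.genotypes])
            for ai, alt in enumerate(variant.ALT, start=1):
                called = (gts >= 0).all(axis=1)
                n_alt = (gts == ai).sum(axis=1)
                other = ((gts > 0) & (gts != ai)).any(axis=1)
                codes = np.where(~called | other, MISSING, n_alt).astype(np.int8)
                alt_list.append((alt, codes))
        has_gq = "GQ" in variant.FORMAT if variant.FORMAT else False
        if min_gq is not None and has_gq and variant.format("GQ") is not None:
            gq = variant.gt_quals
            low = gq < min_gq
        else:
            low = None
        for alt, codes in alt_list:
            codes = codes.copy()
            if low is not None:
                codes[low] = MISSING
            chroms.append(variant.CHROM)
            poss.append(variant.POS)
            refs.append(variant.REF)
            alts.append(alt)
            classes.append(classify_variant(variant.REF, alt))
            rows.append(codes)

    sites = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts, "vclass": classes}
    )
    calls = (
        np.stack(rows, axis=1)
        if rows
        else np.empty((len(accessions), 0), dtype=np.int8)
    )
    order = sites.sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
    return GenotypePanel(
        accessions=accessions,
        sites=sites.iloc[order].reset_index(drop=True),
        calls=calls[:, order],
    )


_CODE_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(
    panel: GenotypePanel, path, chrom_lengths: dict[str, int] | None = None
) -> None:
    """Write the panel as a minimal VCF v4.2 with GT-only genotypes."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=heteroscan\n")
        if chrom_lengths:
            for chrom in sorted(chrom_lengths):
                fh.write(f"##contig=<ID={chrom},length={chrom_lengths[chrom]}>\n")
        else:
            for chrom in pd.unique(panel.sites["chrom"]):
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.accessions)
            + "\n"
        )
        for j, site in enumerate(panel.sites.itertuples(index=False)):
            gts = "\t".join(_CODE_TO_GT[int(c)] for c in panel.calls[:, j])
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def apply_site_filters(
    panel: GenotypePanel, maf_min: float = 0.01, min_call_rate: float = 0.8
) -> GenotypePanel:
    """Retain sites with MAF strictly above ``maf_min`` (computed on called
    alleles) and call rate at least ``min_call_rate``."""
    maf = np.nan_to_num(panel.maf(), nan=0.0)  # all-missing sites fail MAF
    call_rate = panel.call_rate()
    keep = np.flatnonzero((maf > maf_min) & (call_rate >= min_call_rate))
    return panel.take_sites(keep)


# -- metadata tables --------------------------------------------------------

def read_accession_table(path) -> AccessionTable:
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"id", "role", "subgroup"}
    if not required <= set(table.columns):
        raise FormatError(
            f"accession table needs headers {sorted(required)}, got {list(table.columns)}"
        )
    return AccessionTable(table[["id", "role", "subgroup"]])


def write_accession_table(accessions: AccessionTable, path) -> None:
    accessions.table.to_csv(path, sep="\t", index=False)


def read_hybrid_table(path, accessions: AccessionTable) -> HybridTable:
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"hybrid_id", "female_id", "male_id", "system", "status"}
    if not required <= set(table.columns):
        raise FormatError(
            f"hybrid table needs headers {sorted(required)}, got {list(table.columns)}"
        )
    hybrids = HybridTable(table[["hybrid_id", "female_id", "male_id", "system", "status"]])
    hybrids.check_parents(accessions)
    return hybrids


def write_hybrid_table(hybrids: HybridTable, path) -> None:
    hybrids.table.to_csv(path, sep="\t", index=False)


# -- gene models ------------------------------------------------------------

def read_gff3_genes(path, feature: str = "gene") -> pd.DataFrame:
    """Gene intervals from a GFF3 file as a 0-based half-open frame.

    Returns columns gene_id, chrom, start, end sorted by (chrom, start).
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    rows = []
    for gene in db.features_of_type(feature, order_by=("seqid", "start")):
        gene_id = gene.attributes.get("ID", [gene.id])[0]
        rows.append((gene_id, gene.seqid, gene.start - 1, gene.end))
    frame = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])
    if frame["gene_id"].duplicated().any():
        raise ValidationError("duplicate gene ids in GFF3")
    return frame.sort_values(["chrom", "start"]).reset_index(drop=True)


def write_gff3_genes(genes: pd.DataFrame, path) -> None:
    """Write gene intervals (0-based half-open) as GFF3 gene features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.sort_values(["chrom", "start"]).itertuples(index=False):
            fh.write(
                f"{g.chrom}\theteroscan\tgene\t{g.start + 1}\t{g.end}\t.\t+\t.\t"
                f"ID={g.gene_id}\n"
            )
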