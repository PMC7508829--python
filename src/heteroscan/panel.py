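"""Core in-memory containers: genotype panels, accession metadata, hybrid pedigrees.

Genotype calls are stored as allele-dosage codes on the alternate allele:
0 (hom ref), 1 (het), 2 (hom alt), and :data:`MISSING` (= -1) for no-calls.
Site coordinates are 1-based (VCF convention) in the ``pos`` column; interval
outputs elsewhere in the package use 0-based half-open coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ReferentialIntegrityError, ValidationError

MISSING: int = -1

ROLES = ("CMS", "GMS", "3R", "2R", "3M", "CR", "GR")
SUBGROUPS = ("IndI", "IndII", "unassigned")

#: roles acting as the sterile (female) parent of each hybrid system
STERILE_ROLES = {"3-line": ("CMS",), "2-line": ("GMS",)}
#: roles acting as the restorer (male) parent of each hybrid system
RESTORER_ROLES = {"3-line": ("3R",), "2-line": ("3R", "2R")}

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "vclass"]


def classify_variant(ref: str, alt: str) -> str:
    """SNP if both alleles are single bases, indel otherwise."""
    return "SNP" if len(ref) == 1 and len(alt) == 1 else "indel"


@dataclass
class GenotypePanel:
    """An accession x site matrix of dosage-coded genotype calls.

    Parameters
    ----------
    accessions:
        Ordered accession ids (rows of ``calls``).
    sites:
        One row per variant site with columns ``chrom, pos, ref, alt, vclass``;
        ``pos`` is 1-based and rows are sorted by (chrom, pos).
    calls:
        int8 array of shape (n_accessions, n_sites) with codes
        {0, 1, 2, MISSING}.
    """

    accessions: list[str]
    sites: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.validate()

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        if len(set(self.accessions)) != len(self.accessions):
            raise ValidationError("duplicate accession ids in panel")
        missing_cols = [c for c in SITE_COLUMNS if c not in self.sites.columns]
        if missing_cols:
            raise ValidationError(f"site table lacks columns {missing_cols}")
        if self.calls.shape != (len(self.accessions), len(self.sites)):
            raise ValidationError(
                f"call matrix shape {self.calls.shape} does not match "
                f"{len(self.accessions)} accessions x {len(self.sites)} sites"
            )
        if len(self.sites):
            key = self.sites[["chrom", "pos"]]
            ordered = key.sort_values(["chrom", "pos"], kind="stable")
            if not np.array_equal(ordered.index.to_numpy(), np.arange(len(key))):
                raise ValidationError("sites are not sorted by (chrom, pos)")
            if self.sites.duplicated(["chrom", "pos", "alt"]).any():
                raise ValidationError("duplicate (chrom, pos, alt) site")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValidationError("genotype codes outside {0,1,2,missing}")

    # -- accessors ----------------------------------------------------------

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def accession_indices(self, ids) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.accessions)}
        try:
            return np.array([lookup[i] for i in ids], dtype=np.intp)
        except KeyError as exc:
            raise ReferentialIntegrityError(
                f"accession {exc.args[0]!r} not in panel"
            ) from None

    def site_index(self, chrom: str, pos: int) -> int:
        hits = np.flatnonzero(
            (self.sites["chrom"].to_numpy() == chrom)
            & (self.sites["pos"].to_numpy() == pos)
        )
        if len(hits) == 0:
            raise LookupError(f"no site at {chrom}:{pos}")
        return int(hits[0])

    def called_mask(self) -> np.ndarray:
        return self.calls != MISSING

    def call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per site."""
        return self.called_mask().mean(axis=0)

    def alt_freq(self) -> np.ndarray:
        """Alternate-allele frequency per site over called genotypes."""
        called = self.called_mask()
        n_called = called.sum(axis=0)
        dosage = np.where(called, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, dosage / (2.0 * n_called), np.nan)

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def take_sites(self, index: np.ndarray) -> "GenotypePanel":
        return GenotypePanel(
            accessions=list(self.accessions),
            sites=self.sites.iloc[index].reset_index(drop=True),
            calls=self.calls[:, index],
        )


@dataclass
class AccessionTable:
    """Accession metadata: unique id, breeding role, indica subgroup."""

    table: pd.DataFrame  # columns: id, role, subgroup

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True)
        for col in ("id", "role", "subgroup"):
            if col not in t.columns:
                raise ValidationError(f"accession table lacks column {col!r}")
        if t["id"].duplicated().any():
            dup = t.loc[t["id"].duplicated(), "id"].iloc[0]
            raise ValidationError(f"duplicate accession id {dup!r}")
        bad_role = ~t["role"].isin(ROLES)
        if bad_role.any():
            raise ValidationError(
                f"unknown role {t.loc[bad_role, 'role'].iloc[0]!r}"
            )
        bad_sub = ~t["subgroup"].isin(SUBGROUPS)
        if bad_sub.any():
            raise ValidationError(
                f"unknown subgroup {t.loc[bad_sub, 'subgroup'].iloc[0]!r}"
            )
        self.table = t

    def ids_with_role(self, *roles: str) -> list[str]:
        return self.table.loc[self.table["role"].isin(roles), "id"].tolist()

    def subgroup_of(self) -> dict[str, str]:
        return dict(zip(self.table["id"], self.table["subgroup"]))

    def __len__(self) -> int:
        return len(self.table)


HYBRID_COLUMNS = ["hybrid_id", "female_id", "male_id", "system", "status"]


@dataclass
class HybridTable:
    """Hybrid pedigree records.

    Each row names a hybrid, its female (sterile-line) parent, its male
    (restorer) parent, the breeding system (3-line or 2-line) and whether the
    hybrid is a real superior cultivar or a simulated inferior cross.
    """

    table: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True)
        for col in HYBRID_COLUMNS:
            if col not in t.columns:
                raise ValidationError(f"hybrid table lacks column {col!r}")
        bad_sys = ~t["system"].isin(("3-line", "2-line"))
        if bad_sys.any():
            raise ValidationError(
                f"unknown system {t.loc[bad_sys, 'system'].iloc[0]!r}"
            )
        bad_status = ~t["status"].isin(("superior", "simulated_inferior"))
        if bad_status.any():
            raise ValidationError(
                f"unknown status {t.loc[bad_status, 'status'].iloc[0]!r}"
            )
        # pair identity is unordered within one (system, status) set
        pair = [frozenset(p) for p in zip(t["female_id"], t["male_id"])]
        dup = pd.DataFrame({"system": t["system"], "status": t["status"], "pair": pair}).duplicated()
        if dup.any():
            row = t.loc[dup.idxmax()]
            raise ValidationError(
                f"duplicate parent pair ({row['female_id']}, {row['male_id']}) "
                f"in {row['system']}/{row['status']} set"
            )
        self.table = t

    def check_parents(self, accessions: AccessionTable) -> None:
        known = set(accessions.table["id"])
        for col in ("female_id", "male_id"):
            unknown = set(self.table[col]) - known
            if unknown:
                raise ReferentialIntegrityError(
                    f"hybrid parent {sorted(unknown)[0]!r} not in accession table"
                )

    def subset(self, system: str | None = None, status: str | None = None) -> "HybridTable":
        t = self.table
        if system is not None:
            t = t[t["system"] == system]
        if status is not None:
            t = t[t["status"] == status]
        return HybridTable(t.reset_index(drop=True), meta=dict(self.meta))

    def unordered_pairs(self) -> set[frozenset]:
        return {frozenset(p) for p in zip(self.table["female_id"], self.table["male_id"])}

    def __len__(self) -> int:
        return len(self.table)
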