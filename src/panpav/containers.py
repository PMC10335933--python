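"""Shared in-memory containers for genotypes, variants and phenotypes.

Coordinates are 0-based half-open everywhere inside the package; conversion
to/from 1-based formats (VCF, GFF3) happens only in :mod:`panpav.io`.
Missing genotypes are encoded as -1 in integer dosage matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: canonical accession group labels, in evolutionary order
GROUP_ORDER = ("wild", "landrace", "cultivar")

SV_TYPES = ("INS", "DEL", "INV", "TRA")


@dataclass
class SnpMatrix:
    """Biallelic SNP dosages (0/1/2, -1 missing) with sorted positions.

    ``dosage`` is accessions x markers.  ``ref``/``alt`` are single bases
    kept so a round-trip through VCF is lossless.
    """

    ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    dosage: np.ndarray
    accessions: list[str]
    ref: np.ndarray | None = None
    alt: np.ndarray | None = None
    ploidy: int = 2

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.accessions), len(self.ids)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.accessions)} accessions x {len(self.ids)} markers"
            )
        if self.ref is None:
            self.ref = np.full(len(self.ids), "A")
        if self.alt is None:
            self.alt = np.full(len(self.ids), "T")

    @property
    def n_accessions(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per marker from non-missing calls."""
        d = self.dosage
        called = d != MISSING
        an = self.ploidy * called.sum(axis=0)
        ac = np.where(called, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            p = np.where(an > 0, ac / np.maximum(an, 1), np.nan)
        return np.minimum(p, 1 - p)

    def missingness(self) -> np.ndarray:
        return (self.dosage == MISSING).mean(axis=0)

    def take_markers(self, idx: np.ndarray) -> "SnpMatrix":
        return SnpMatrix(
            ids=self.ids[idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            dosage=self.dosage[:, idx],
            accessions=list(self.accessions),
            ref=self.ref[idx],
            alt=self.alt[idx],
            ploidy=self.ploidy,
        )


#: columns of the PavSet record table; flank/sequence columns may hold None
PAV_RECORD_COLUMNS = [
    "id", "chrom", "start", "end", "type", "length",
    "sequence", "left_flank", "right_flank",
]


@dataclass
class PavSet:
    """SV/PAV records plus a binary carrier-genotype matrix.

    ``records`` is a DataFrame with :data:`PAV_RECORD_COLUMNS`; ``genotypes``
    is accessions x PAVs with entries in {0 reference, 1 alternate, -1
    missing}.  Insertions are points (start == end) carrying the inserted
    sequence; deletions/inversions span [start, end).
    """

    records: pd.DataFrame
    genotypes: np.ndarray
    accessions: list[str]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        missing_cols = set(PAV_RECORD_COLUMNS) - set(self.records.columns)
        if missing_cols:
            raise ValueError(f"PAV records missing columns: {sorted(missing_cols)}")
        if self.genotypes.shape != (len(self.accessions), len(self.records)):
            raise ValueError("genotype matrix shape does not match records/accessions")
        bad = self.records[~self.records["type"].isin(SV_TYPES)]
        if len(bad):
            raise ValueError(f"unknown SV types: {sorted(bad['type'].unique())}")
        if (self.records["length"] < 50).any():
            raise ValueError("PAV records must be >= 50 bp")

    @property
    def n_accessions(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_pavs(self) -> int:
        return self.genotypes.shape[1]

    def take(self, idx: np.ndarray) -> "PavSet":
        return PavSet(
            records=self.records.iloc[idx].reset_index(drop=True),
            genotypes=self.genotypes[:, np.asarray(idx)],
            accessions=list(self.accessions),
        )


def check_groups(groups: pd.Series, accessions: list[str]) -> pd.Series:
    """Validate and align a group-label Series against an accession list."""
    missing = [a for a in accessions if a not in groups.index]
    if missing:
        raise ValueError(f"accessions without group labels: {missing[:5]}...")
    g = groups.loc[list(accessions)]
    unknown = set(g.unique()) - set(GROUP_ORDER)
    if unknown:
        raise ValueError(f"unknown group labels: {sorted(unknown)}")
    return g


@dataclass
class PhenoTable:
    """Trait values per accession per environment, long format."""

    data: pd.DataFrame  # columns: accession, group, env, trait, value

    REQUIRED = ("accession", "group", "env", "trait", "value")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.data.columns)
        if missing:
            raise ValueError(f"phenotype table missing columns: {sorted(missing)}")

    def trait_vector(self, trait: str, env: str,
                     accessions: list[str]) -> np.ndarray:
        """One value per accession for a trait x environment dataset."""
        sub = self.data[(self.data["trait"] == trait) & (self.data["env"] == env)]
        s = sub.set_index("accession")["value"]
        return s.loc[list(accessions)].to_numpy(dtype=float)

    @property
    def traits(self) -> list[str]:
        return sorted(self.data["trait"].unique())

    @property
    def envs(self) -> list[str]:
        return sorted(self.data["env"].unique())


@dataclass
class TruthSet:
    """Ground truth of a synthetic dataset (see :mod:`panpav.synthdata`)."""

    family_category: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    selected_pavs: pd.DataFrame = field(default_factory=pd.DataFrame)
    causal_effects: pd.DataFrame = field(default_factory=pd.DataFrame)
    planted_tsds: pd.DataFrame = field(default_factory=pd.DataFrame)
    te_derived_pavs: list[str] = field(default_factory=list)
    te_intervals: pd.DataFrame = field(default_factory=pd.DataFrame)

    def validate_against(self, snps: SnpMatrix, pavs: PavSet,
                         presence: pd.DataFrame) -> None:
        """Truth closure: every labeled id must resolve in the dataset."""
        pav_ids = set(pavs.records["id"])
        marker_ids = pav_ids | set(snps.ids)
        if len(self.selected_pavs):
            dangling = set(self.selected_pavs["pav_id"]) - pav_ids
            if dangling:
                raise ValueError(f"selected PAV ids not in dataset: {sorted(dangling)[:5]}")
        if len(self.causal_effects):
            dangling = set(self.causal_effects["marker_id"]) - marker_ids
            if dangling:
                raise ValueError(f"causal marker ids not in dataset: {sorted(dangling)[:5]}")
        if len(self.planted_tsds):
            dangling = set(self.planted_tsds["pav_id"]) - pav_ids
            if dangling:
                raise ValueError(f"TSD PAV ids not in dataset: {sorted(dangling)[:5]}")
        if len(self.family_category):
            dangling = set(self.family_category.index) - set(presence.index)
            if dangling:
                raise ValueError(f"family ids not in presence matrix: {sorted(dangling)[:5]}")
        dangling = set(self.te_derived_pavs) - pav_ids
        if dangling:
            raise ValueError(f"TE-derived ids not in dataset: {sorted(dangling)[:5]}")
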