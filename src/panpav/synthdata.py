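"""Synthetic three-group populations with full ground truth.

Emulates the statistical structure the downstream analyses assume: a
wild / landrace / cultivar panel whose allele frequencies drift apart
under a Balding–Nichols model, a planted set of "selected" PAVs whose
carrier frequencies change monotonically across the three groups, gene
and TE annotations with planted target-site duplications, a gene-family
presence matrix with designed occupancy categories, and additive
multi-environment phenotypes with known marker effects.

The generator is the definition of the study conditions for the test
suite: all defaults are chosen once (see docs/methods.md) and every
output is a deterministic function of :class:`SimConfig`, including the
seed.  Independent named RNG sub-streams are derived from the seed so
that, e.g., changing the number of SNPs does not perturb phenotypes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import (
    GROUP_ORDER, MISSING, PavSet, PhenoTable, SnpMatrix, TruthSet,
)

_BASES = np.array(list("ACGT"))

# fixed stream ids: adding a component must not renumber existing ones
_STREAMS = {
    "snp": 1, "pav": 2, "family": 3, "annotation": 4,
    "phenotype": 5, "missing": 6,
}

#: (contrast, direction) classes planted in round-robin order
SELECTED_CLASSES = (
    ("domestication", "gain"),
    ("domestication", "loss"),
    ("improvement", "gain"),
    ("improvement", "loss"),
)


@dataclass
class SimConfig:
    """Parameters of one synthetic study.

    The default panel mirrors a 35/40/35 wild/landrace/cultivar design;
    ``large_panel()`` returns a panel sized for association/prediction
    experiments.  ``f_drift`` is the Balding–Nichols differentiation
    parameter per group (maps to the expected F_ST-like divergence from
    the ancestral pool).  ``delta_f`` is the planted frequency shift of
    selected PAVs in their labeled contrast.
    """

    n_wild: int = 35
    n_landrace: int = 40
    n_cultivar: int = 35
    n_snp: int = 2000
    n_pav: int = 1000
    n_family: int = 5000
    f_drift: float = 0.05
    n_selected_pav: int = 60
    delta_f: float = 0.5
    n_causal: int = 20
    h2: float = 0.6
    n_env: int = 2
    n_traits: int = 1
    env_offset: float = 1.0
    genome: dict[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000})
    te_fraction: float = 0.605
    tsd_len_range: tuple[int, int] = (4, 10)
    tsd_fraction: float = 0.5
    te_derived_fraction: float = 0.15
    missing_rate: float = 0.02
    family_shares: tuple[float, float, float, float] = (0.25, 0.40, 0.30, 0.05)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_wild", "n_landrace", "n_cultivar", "n_snp", "n_pav",
                     "n_family", "n_selected_pav", "n_causal", "n_env",
                     "n_traits"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.f_drift < 1:
            raise ValueError("f_drift must be in [0, 1)")
        if not 0 <= self.h2 <= 1:
            raise ValueError("h2 must be in [0, 1]")
        if not 0 < self.delta_f <= 1:
            raise ValueError("delta_f must be in (0, 1]")
        if not 0 <= self.te_fraction <= 1:
            raise ValueError("te_fraction must be in [0, 1]")
        if self.n_selected_pav > self.n_pav:
            raise ValueError("n_selected_pav cannot exceed n_pav")
        if abs(sum(self.family_shares) - 1.0) > 1e-9:
            raise ValueError("family_shares must sum to 1")
        capacity = sum(self.genome.values())
        if self.n_snp + self.n_pav > capacity // 100:
            raise ValueError(
                f"{self.n_snp + self.n_pav} markers exceed the capacity of a "
                f"{capacity} bp genome (need >=100 bp per marker)")

    @property
    def n_accessions(self) -> int:
        return self.n_wild + self.n_landrace + self.n_cultivar

    @property
    def group_sizes(self) -> dict[str, int]:
        return {"wild": self.n_wild, "landrace": self.n_landrace,
                "cultivar": self.n_cultivar}

    def rng(self, stream: str) -> np.random.Generator:
        """Named deterministic sub-stream of the config seed."""
        return np.random.default_rng(
            np.random.SeedSequence((int(self.seed), _STREAMS[stream])))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tsd_len_range"] = list(self.tsd_len_range)
        d["family_shares"] = list(self.family_shares)
        return d

    @classmethod
    def large_panel(cls, **overrides) -> "SimConfig":
        """A panel sized for GWAS / genomic-selection experiments."""
        defaults = dict(n_wild=100, n_landrace=250, n_cultivar=250,
                        n_snp=3000, n_pav=800, n_family=1000)
        defaults.update(overrides)
        return cls(**defaults)


def accession_names(config: SimConfig) -> tuple[list[str], pd.Series]:
    names, labels = [], []
    for group, n in config.group_sizes.items():
        for i in range(n):
            names.append(f"{group[0].upper()}{i + 1:03d}")
            labels.append(group)
    return names, pd.Series(labels, index=names, name="group")


def _balding_nichols(rng: np.random.Generator, ancestral: np.ndarray,
                     f_drift: float, n_groups: int) -> np.ndarray:
    """Per-group frequencies: Beta reparameterized by ancestral p and F.

    F = 0 degenerates to the ancestral frequency exactly.
    """
    if f_drift == 0:
        return np.tile(ancestral, (n_groups, 1))
    scale = (1 - f_drift) / f_drift
    a = ancestral * scale
    b = (1 - ancestral) * scale
    return rng.beta(a, b, size=(n_groups, len(ancestral)))


def _positions(rng: np.random.Generator, genome: dict[str, int],
               n: int) -> tuple[np.ndarray, np.ndarray]:
    """n unique sorted positions allocated across chromosomes by length."""
    lengths = np.array(list(genome.values()), dtype=float)
    chroms = list(genome)
    counts = rng.multinomial(n, lengths / lengths.sum())
    out_chrom, out_pos = [], []
    for chrom, L, k in zip(chroms, lengths, counts):
        # oversample, deduplicate, keep first k; margin avoids pos 0 / chrom end
        pos = np.unique(rng.integers(100, int(L) - 100, size=max(4 * k, 16)))
        while len(pos) < k:  # pragma: no cover - only for absurdly dense configs
            pos = np.unique(np.concatenate(
                [pos, rng.integers(100, int(L) - 100, size=4 * k)]))
        pos = np.sort(rng.choice(pos, size=k, replace=False))
        out_chrom.append(np.full(k, chrom))
        out_pos.append(pos)
    return np.concatenate(out_chrom), np.concatenate(out_pos)


def _apply_missing(rng: np.random.Generator, matrix: np.ndarray,
                   rate: float) -> np.ndarray:
    if rate > 0:
        mask = rng.random(matrix.shape) < rate
        matrix = np.where(mask, MISSING, matrix).astype(np.int8)
    return matrix


def _planted_frequencies(rng: np.random.Generator, config: SimConfig
                         ) -> tuple[np.ndarray, pd.DataFrame]:
    """Group carrier frequencies of the planted selected PAVs.

    The labeled contrast gets the full ``delta_f`` shift; the remaining
    leg continues in the same direction with a 0.25 margin (clipped to
    [0, 1]) so that the realized ordering is resolvable at the default
    group sizes.  Returns an (n_selected, 3) frequency array in
    GROUP_ORDER plus the truth table.
    """
    margin = 0.25
    n = config.n_selected_pav
    lo = 0.01
    hi = max(lo + 0.001, 0.99 - config.delta_f)
    freqs = np.zeros((n, 3))
    rows = []
    for i in range(n):
        contrast, direction = SELECTED_CLASSES[i % len(SELECTED_CLASSES)]
        base = rng.uniform(lo, min(hi, 0.2))
        if contrast == "domestication":
            if direction == "gain":
                fw = base
                fl = fw + config.delta_f
                fc = min(fl + margin, 1.0)
            else:
                fw = 1 - base
                fl = fw - config.delta_f
                fc = max(fl - margin, 0.0)
        else:  # improvement: shift between landrace and cultivar
            if direction == "gain":
                fl = base
                fc = fl + config.delta_f
                fw = max(fl - margin, 0.0)
            else:
                fl = 1 - base
                fc = fl - config.delta_f
                fw = min(fl + margin, 1.0)
        freqs[i] = (fw, fl, fc)
        rows.append({"contrast": contrast, "direction": direction,
                     "f_wild": fw, "f_landrace": fl, "f_cultivar": fc})
    return np.clip(freqs, 0.0, 1.0), pd.DataFrame(rows)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def simulate_genotypes(config: SimConfig
                       ) -> tuple[SnpMatrix, PavSet, pd.Series, pd.DataFrame]:
    """Draw SNP dosages and PAV carrier genotypes for the three groups.

    Ancestral frequencies ~ U(0.05, 0.95); per-group frequencies by the
    Balding–Nichols construction; SNP dosages Binomial(2, f_group), PAV
    carriers Bernoulli(f_group).  The last ``n_selected_pav`` PAV columns
    are overwritten with the planted monotone frequencies.

    Returns (snps, pavs, groups, selected_pav_truth).
    """
    accessions, groups = accession_names(config)
    group_idx = [np.flatnonzero((groups == g).to_numpy()) for g in GROUP_ORDER]

    # --- SNPs ---
    rng = config.rng("snp")
    anc = rng.uniform(0.05, 0.95, size=config.n_snp)
    gfreq = _balding_nichols(rng, anc, config.f_drift, 3)
    dosage = np.zeros((config.n_accessions, config.n_snp), dtype=np.int8)
    for gi, idx in enumerate(group_idx):
        dosage[idx] = rng.binomial(2, gfreq[gi], size=(len(idx), config.n_snp))
    chrom, pos = _positions(rng, config.genome, config.n_snp)
    ref_i = rng.integers(0, 4, size=config.n_snp)
    alt_i = (ref_i + rng.integers(1, 4, size=config.n_snp)) % 4
    snps = SnpMatrix(
        ids=np.array([f"snp{i + 1}" for i in range(config.n_snp)]),
        chrom=chrom, pos=pos, dosage=dosage, accessions=accessions,
        ref=_BASES[ref_i], alt=_BASES[alt_i])

    # --- PAVs ---
    rng = config.rng("pav")
    anc_p = rng.uniform(0.05, 0.95, size=config.n_pav)
    pfreq = _balding_nichols(rng, anc_p, config.f_drift, 3)
    planted, truth = _planted_frequencies(rng, config)
    sel_idx = np.arange(config.n_pav - config.n_selected_pav, config.n_pav)
    pfreq[:, sel_idx] = planted.T
    carriers = np.zeros((config.n_accessions, config.n_pav), dtype=np.int8)
    for gi, idx in enumerate(group_idx):
        carriers[idx] = rng.binomial(1, pfreq[gi], size=(len(idx), config.n_pav))

    pchrom, ppos = _positions(rng, config.genome, config.n_pav)
    types = rng.choice(["INS", "DEL", "INV"], size=config.n_pav,
                       p=[0.55, 0.40, 0.05])
    lengths = (50 + np.rint(rng.lognormal(5.0, 1.0, size=config.n_pav))
               ).astype(int)
    lengths = np.minimum(lengths, 50_000)
    records = []
    for i in range(config.n_pav):
        start = int(ppos[i])
        if types[i] == "INS":
            end = start
            seq = _random_seq(rng, int(lengths[i])) if lengths[i] <= 2000 else None
        else:
            end = min(start + int(lengths[i]), config.genome[pchrom[i]])
            lengths[i] = end - start
            if lengths[i] < 50:  # clipped at chromosome end; re-anchor
                start = end - 50
                lengths[i] = 50
            seq = None
        records.append({"id": f"pav{i + 1}", "chrom": pchrom[i],
                        "start": start, "end": end, "type": types[i],
                        "length": int(lengths[i]), "sequence": seq,
                        "left_flank": None, "right_flank": None})
    rec_df = pd.DataFrame(records)
    truth.insert(0, "pav_id", rec_df["id"].iloc[sel_idx].to_numpy())

    miss_rng = config.rng("missing")
    snps.dosage = _apply_missing(miss_rng, snps.dosage, config.missing_rate)
    carriers = _apply_missing(miss_rng, carriers, config.missing_rate)
    pavs = PavSet(records=rec_df, genotypes=carriers, accessions=accessions)
    return snps, pavs, groups, truth


# ---------------------------------------------------------------------------
# gene families

def _category_bounds(N: int) -> dict[str, tuple[int, int]]:
    soft_min = math.ceil(0.9 * N)
    return {"core": (N, N), "softcore": (soft_min, N - 1),
            "dispensable": (2, soft_min - 1), "private": (1, 1)}


def simulate_families(config: SimConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Presence matrix with designed category shares.

    Occupancy counts are drawn uniformly inside each category's count
    range, so the classifier must recover the designed labels exactly.
    Returns (presence DataFrame families x accessions, truth Series).
    """
    if config.n_family < 4:
        raise ValueError("need at least 4 families (one per category)")
    rng = config.rng("family")
    accessions, _ = accession_names(config)
    N = len(accessions)
    bounds = _category_bounds(N)

    counts = [int(round(s * config.n_family)) for s in config.family_shares]
    counts[2] += config.n_family - sum(counts)  # residual to dispensable
    categories = np.repeat(list(bounds), counts)
    occupancy = np.empty(config.n_family, dtype=int)
    for cat, (lo, hi) in bounds.items():
        m = categories == cat
        occupancy[m] = rng.integers(lo, hi + 1, size=m.sum())

    matrix = np.zeros((config.n_family, N), dtype=bool)
    for i, c in enumerate(occupancy):
        matrix[i, rng.choice(N, size=c, replace=False)] = True
    fam_ids = pd.Index([f"fam{i + 1}" for i in range(config.n_family)],
                       name="family")
    presence = pd.DataFrame(matrix, index=fam_ids, columns=accessions)
    truth = pd.Series(categories, index=fam_ids, name="category")
    return presence, truth


# ---------------------------------------------------------------------------
# annotations

_FLANK_LEN = 30


def _clean_flanks(rng: np.random.Generator, k_range: tuple[int, int]
                  ) -> tuple[str, str]:
    """Flank pair guaranteed to contain no breakpoint-anchored duplication."""
    kmin, kmax = k_range
    while True:
        left = _random_seq(rng, _FLANK_LEN)
        right = _random_seq(rng, _FLANK_LEN)
        if not any(left[-k:] == right[:k] for k in range(kmin, kmax + 1)):
            return left, right


def _tsd_flanks(rng: np.random.Generator, tsd: str) -> tuple[str, str]:
    k = len(tsd)
    return (_random_seq(rng, _FLANK_LEN - k) + tsd,
            tsd + _random_seq(rng, _FLANK_LEN - k))


def simulate_annotations(config: SimConfig, pavs: PavSet
                         ) -> tuple[pd.DataFrame, pd.DataFrame, PavSet, TruthSet]:
    """Gene and TE intervals plus planted TSDs and TE-derived PAVs.

    Genes are non-overlapping intervals; TE intervals cover ~te_fraction
    of the genome (alternating exponential TE/gap walk).  A configured
    fraction of insertion PAVs receives planted TSD flanks; a subset of
    those is relocated to span exactly one intact TE (the planted
    TE-derived class).  All other PAVs get rejection-sampled
    duplication-free flanks, so TSD ground truth is exact.

    Returns (genes, tes, pavs-with-flanks, partial TruthSet).
    """
    rng = config.rng("annotation")

    genes = []
    gi = 0
    for chrom, L in config.genome.items():
        pos = 0
        while True:
            pos += int(rng.exponential(8000)) + 200
            glen = int(rng.integers(1000, 6001))
            if pos + glen >= L:
                break
            gi += 1
            genes.append({"chrom": chrom, "start": pos, "end": pos + glen,
                          "strand": rng.choice(["+", "-"]),
                          "gene_id": f"gene{gi}"})
            pos += glen
    genes_df = pd.DataFrame(genes)

    tes = []
    ti = 0
    mean_te = 1600.0  # exponential(1500) + 100 bp minimum
    if config.te_fraction > 0:
        mean_gap = mean_te * (1 - config.te_fraction) / config.te_fraction
        for chrom, L in config.genome.items():
            pos = 0
            while True:
                pos += int(rng.exponential(mean_gap)) if mean_gap > 0 else 0
                tlen = int(rng.exponential(mean_te - 100.0)) + 100
                if pos >= L:
                    break
                end = min(pos + tlen, L)
                ti += 1
                tes.append({"chrom": chrom, "start": pos, "end": end,
                            "intact": bool(rng.random() < 0.7),
                            "te_id": f"te{ti}"})
                pos = end
    tes_df = pd.DataFrame(tes, columns=["chrom", "start", "end", "intact", "te_id"])

    records = pavs.records.copy()
    kmin, kmax = config.tsd_len_range
    ins_idx = records.index[records["type"] == "INS"].to_numpy()
    n_tsd = int(round(config.tsd_fraction * len(ins_idx)))
    tsd_idx = rng.choice(ins_idx, size=n_tsd, replace=False) if n_tsd else np.array([], int)
    tsd_set = set(tsd_idx.tolist())

    tsd_rows = []
    for i in records.index:
        if i in tsd_set:
            k = int(rng.integers(kmin, kmax + 1))
            tsd = _random_seq(rng, k)
            while True:  # the duplication must not extend by accident
                left, right = _tsd_flanks(rng, tsd)
                if not any(left[-kk:] == right[:kk]
                           for kk in range(k + 1, kmax + 1)):
                    break
            records.at[i, "left_flank"] = left
            records.at[i, "right_flank"] = right
            tsd_rows.append({"pav_id": records.at[i, "id"],
                             "tsd": tsd, "length": k})
        else:
            left, right = _clean_flanks(rng, (kmin, kmax))
            records.at[i, "left_flank"] = left
            records.at[i, "right_flank"] = right

    # plant TE-derived PAVs: relocate TSD-bearing insertions onto intact TEs
    te_derived: list[str] = []
    intact = tes_df[tes_df["intact"]] if len(tes_df) else tes_df
    n_te_derived = min(int(round(config.te_derived_fraction * len(tsd_idx))),
                       len(tsd_idx), len(intact))
    if n_te_derived:
        chosen_pav = rng.choice(tsd_idx, size=n_te_derived, replace=False)
        chosen_te = rng.choice(intact.index.to_numpy(), size=n_te_derived,
                               replace=False)
        for pi, tei in zip(chosen_pav, chosen_te):
            records.at[pi, "chrom"] = tes_df.at[tei, "chrom"]
            records.at[pi, "start"] = int(tes_df.at[tei, "start"])
            records.at[pi, "end"] = int(tes_df.at[tei, "end"])
            records.at[pi, "type"] = "DEL"  # spans the TE body
            records.at[pi, "length"] = max(
                int(tes_df.at[tei, "end"] - tes_df.at[tei, "start"]), 50)
            records.at[pi, "sequence"] = None
            te_derived.append(records.at[pi, "id"])

    new_pavs = PavSet(records=records, genotypes=pavs.genotypes,
                      accessions=list(pavs.accessions))
    truth = TruthSet(
        planted_tsds=pd.DataFrame(tsd_rows, columns=["pav_id", "tsd", "length"]),
        te_derived_pavs=te_derived,
        te_intervals=tes_df,
    )
    return genes_df, tes_df, new_pavs, truth


# ---------------------------------------------------------------------------
# phenotypes

def _impute_dosage(dosage: np.ndarray) -> np.ndarray:
    d = dosage.astype(float)
    d[dosage == MISSING] = np.nan
    mean = np.nanmean(d, axis=0)
    mean = np.where(np.isnan(mean), 0.0, mean)
    idx = np.where(np.isnan(d))
    d[idx] = mean[idx[1]]
    return d


def simulate_phenotypes(snps: SnpMatrix, pavs: PavSet, groups: pd.Series,
                        config: SimConfig
                        ) -> tuple[PhenoTable, pd.DataFrame]:
    """Additive multi-environment phenotypes with known marker effects.

    trait = sum(effect * dosage) + environment offset + Gaussian noise,
    noise variance scaled so the genic variance fraction is h2.  h2 = 0
    produces pure environmental noise (no genetic term); h2 = 1 with no
    causal markers is a configuration error.

    Returns (phenotypes, causal-effect truth table).
    """
    if config.h2 == 1 and config.n_causal == 0:
        raise ValueError("h2 = 1 requires at least one causal marker")
    rng = config.rng("phenotype")
    marker_ids = np.concatenate([snps.ids, pavs.records["id"].to_numpy()])
    dosage = np.hstack([_impute_dosage(snps.dosage),
                        _impute_dosage(pavs.genotypes)])
    n = dosage.shape[0]
    accessions = list(snps.accessions)

    rows, effect_rows = [], []
    for t in range(config.n_traits):
        trait = f"trait{t + 1}"
        if config.n_causal and config.h2 > 0:
            causal = rng.choice(len(marker_ids), size=config.n_causal,
                                replace=False)
            effects = rng.normal(0, 1, size=config.n_causal)
            g = dosage[:, causal] @ effects
            for mid, eff in zip(marker_ids[causal], effects):
                effect_rows.append({"trait": trait, "marker_id": mid,
                                    "effect": eff})
            var_g = g.var()
            if config.h2 >= 1:
                sigma_e = 0.0
            else:
                sigma_e = math.sqrt(var_g * (1 - config.h2) / config.h2) \
                    if var_g > 0 else 1.0
        else:
            g = np.zeros(n)
            sigma_e = 1.0
        for e in range(config.n_env):
            env = f"env{e + 1}"
            noise = rng.normal(0, sigma_e, size=n) if sigma_e > 0 else np.zeros(n)
            values = g + e * config.env_offset + noise
            for acc, val in zip(accessions, values):
                rows.append({"accession": acc, "group": groups[acc],
                             "env": env, "trait": trait, "value": val})
    pheno = PhenoTable(pd.DataFrame(rows))
    effects_df = pd.DataFrame(effect_rows,
                              columns=["trait", "marker_id", "effect"])
    return pheno, effects_df


# ---------------------------------------------------------------------------
# full dataset

@dataclass
class SimDataset:
    """Everything one synthetic study produces, with ground truth."""

    config: SimConfig
    snps: SnpMatrix
    pavs: PavSet
    groups: pd.Series
    presence: pd.DataFrame
    genes: pd.DataFrame
    tes: pd.DataFrame
    phenotypes: PhenoTable
    truth: TruthSet


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Run every generator stage and assemble the consolidated TruthSet."""
    snps, pavs, groups, selected = simulate_genotypes(config)
    presence, categories = simulate_families(config)
    genes, tes, pavs, ann_truth = simulate_annotations(config, pavs)
    phenotypes, effects = simulate_phenotypes(snps, pavs, groups, config)
    truth = TruthSet(
        family_category=categories,
        selected_pavs=selected,
        causal_effects=effects,
        planted_tsds=ann_truth.planted_tsds,
        te_derived_pavs=ann_truth.te_derived_pavs,
        te_intervals=ann_truth.te_intervals,
    )
    truth.validate_against(snps, pavs, presence)
    return SimDataset(config=config, snps=snps, pavs=pavs, groups=groups,
                      presence=presence, genes=genes, tes=tes,
                      phenotypes=phenotypes, truth=truth)
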