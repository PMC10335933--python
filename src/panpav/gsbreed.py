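"""Marker-panel genomic prediction and breeding-potential enumeration.

Marker importance comes from a gradient-boosted decision-tree model:
feature gain (FG) is the total split gain attributed to a marker, and
the reduction-of-feature-gain statistic ROF_i = 1 - FG_i / FG_max
selects "highly effective" markers (ROF <= 0.99 keeps markers with at
least 1% of the maximum gain).  Six panels combine the
importance-selected (cg) sets with GWAS-significant sets for SNPs, SVs
and both.  Prediction precision is the Pearson correlation between
observed phenotypes and predicted GEBVs over repeated random
training/validation splits.  Breeding potential enumerates all 2^k
allele assignments of the top-k markers on the best accession's
background and reports the relative GEBV improvement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lightgbm import LGBMRegressor
from sklearn.linear_model import Ridge

from .containers import MISSING
from .gwasloci import _impute

PANEL_NAMES = ("SNP_cg", "SNP_cg_gwas", "SV_cg", "SV_cg_gwas",
               "SNPSV_cg", "SNPSV_cg_gwas")

_GBM_DEFAULTS = dict(
    n_estimators=200, learning_rate=0.05, num_leaves=15,
    min_child_samples=10, n_jobs=1, deterministic=True,
    force_col_wise=True, verbose=-1,
)


def make_predictor(model: str = "gbm", seed: int = 0, **params):
    """Predictor behind the shared model contract: 'gbm' or 'linear'.

    The linear predictor is a ridge regression (GBLUP-flavoured additive
    cross-check); both expose sklearn fit/predict.
    """
    if model == "gbm":
        kwargs = {**_GBM_DEFAULTS, **params, "random_state": seed}
        return LGBMRegressor(**kwargs)
    if model == "linear":
        return Ridge(alpha=params.get("alpha", 1.0))
    raise ValueError(f"unknown model {model!r}; use 'gbm' or 'linear'")


# ---------------------------------------------------------------------------
# feature gain and ROF selection

@dataclass
class MarkerImportance:
    """Per-marker feature gain and ROF (0 for the max-gain marker)."""

    table: pd.DataFrame  # marker_id, fg, rof

    @property
    def fg_max(self) -> float:
        return float(self.table["fg"].max()) if len(self.table) else 0.0

    def top(self, k: int) -> pd.DataFrame:
        return self.table.nlargest(k, "fg", keep="first")


def feature_gain(dosage: np.ndarray, phenotype: np.ndarray,
                 marker_ids: np.ndarray | None = None, seed: int = 0,
                 **gbm_params) -> MarkerImportance:
    """Gradient-boosting feature gain per marker.

    Markers never used in a split (including constant markers) get
    FG = 0.  A constant phenotype is a configuration error.
    """
    y = np.asarray(phenotype, float)
    if np.std(y) == 0:
        raise ValueError("constant phenotype: feature gain undefined")
    X = _impute(dosage)
    if marker_ids is None:
        marker_ids = np.array([f"m{i}" for i in range(X.shape[1])])
    model = make_predictor("gbm", seed=seed, **gbm_params)
    model.fit(X, y)
    fg = model.booster_.feature_importance(importance_type="gain")
    fg = np.asarray(fg, dtype=float)
    fg_max = fg.max() if len(fg) else 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        rof = np.where(fg_max > 0, 1.0 - fg / fg_max, np.nan)
    table = pd.DataFrame({"marker_id": marker_ids, "fg": fg, "rof": rof})
    return MarkerImportance(table=table)


def rof_select(importance: MarkerImportance, rof_max: float = 0.99
               ) -> list[str]:
    """Markers with ROF <= rof_max, i.e. FG >= (1 - rof_max) * FG_max.

    Scale-invariant in FG.  If every FG is zero the selection is empty
    (with a warning).
    """
    t = importance.table
    if importance.fg_max <= 0:
        warnings.warn("all feature gains are zero; empty selection",
                      stacklevel=2)
        return []
    sel = t.loc[t["rof"] <= rof_max, "marker_id"]
    return list(sel)


# ---------------------------------------------------------------------------
# panels

@dataclass
class MarkerPanel:
    name: str
    markers: list[str]
    provenance: dict[str, str] = field(default_factory=dict)  # id -> cg/gwas/both

    def __len__(self) -> int:
        return len(self.markers)


def _union_panel(name: str, cg: set, gwas: set) -> MarkerPanel:
    markers = sorted(cg | gwas)
    prov = {m: ("both" if m in cg and m in gwas else
                "cg" if m in cg else "gwas") for m in markers}
    return MarkerPanel(name=name, markers=markers, provenance=prov)


def build_panels(cg_snp, cg_sv, gwas_snp, gwas_sv) -> dict[str, MarkerPanel]:
    """The six marker panels from cg (importance) and GWAS sets.

    *_cg panels are the importance-selected sets; *_cg_gwas panels union
    in the GWAS-significant markers; SNPSV panels combine both marker
    types.  All inputs may be empty.
    """
    cg_snp, cg_sv = set(cg_snp), set(cg_sv)
    gwas_snp, gwas_sv = set(gwas_snp), set(gwas_sv)
    return {
        "SNP_cg": _union_panel("SNP_cg", cg_snp, set()),
        "SNP_cg_gwas": _union_panel("SNP_cg_gwas", cg_snp, gwas_snp),
        "SV_cg": _union_panel("SV_cg", cg_sv, set()),
        "SV_cg_gwas": _union_panel("SV_cg_gwas", cg_sv, gwas_sv),
        "SNPSV_cg": _union_panel("SNPSV_cg", cg_snp | cg_sv, set()),
        "SNPSV_cg_gwas": _union_panel("SNPSV_cg_gwas", cg_snp | cg_sv,
                                      gwas_snp | gwas_sv),
    }


# ---------------------------------------------------------------------------
# cross-validated prediction precision

@dataclass
class PredictionReport:
    """Per-replicate held-out Pearson precision of one panel."""

    precisions: np.ndarray
    n_train: int
    n_test: int
    n_excluded: int
    model: str

    @property
    def mean(self) -> float:
        return float(np.mean(self.precisions)) if len(self.precisions) else np.nan

    @property
    def sd(self) -> float:
        return float(np.std(self.precisions)) if len(self.precisions) else np.nan

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "model": self.model, "n_train": self.n_train,
            "n_test": self.n_test, "replicates": len(self.precisions),
            "excluded": self.n_excluded,
            "precision_mean": self.mean, "precision_sd": self.sd,
        }])


def _split_sizes(n: int, n_train: int | None, n_test: int | None
                 ) -> tuple[int, int]:
    """Default split: the reference 580/100 design at n = 680, otherwise
    a proportional 85%/15% split."""
    if n_train is not None and n_test is not None:
        if n_train + n_test > n:
            raise ValueError("n_train + n_test exceeds panel size")
        return n_train, n_test
    if n == 680:
        return 580, 100
    n_test = max(1, int(round(0.15 * n)))
    return n - n_test, n_test


def cross_validate(dosage: np.ndarray, phenotype: np.ndarray,
                   n_train: int | None = None, n_test: int | None = None,
                   reps: int = 100, seed: int = 0, model: str = "gbm",
                   **params) -> PredictionReport:
    """Repeated random-split prediction precision.

    Each replicate fits on a random training set and records the Pearson
    correlation between held-out phenotypes and predictions.  Replicates
    whose held-out truth or prediction is constant are excluded and
    counted.
    """
    y = np.asarray(phenotype, float)
    X = _impute(dosage)
    n = len(y)
    tr, te = _split_sizes(n, n_train, n_test)
    rng = np.random.default_rng(seed)
    rs, excluded = [], 0
    for _ in range(reps):
        perm = rng.permutation(n)
        train, test = perm[:tr], perm[tr:tr + te]
        pred = make_predictor(model, seed=seed, **params) \
            .fit(X[train], y[train]).predict(X[test])
        if np.std(y[test]) == 0 or np.std(pred) == 0:
            excluded += 1
            continue
        rs.append(np.corrcoef(y[test], pred)[0, 1])
    return PredictionReport(precisions=np.array(rs), n_train=tr, n_test=te,
                            n_excluded=excluded, model=model)


# ---------------------------------------------------------------------------
# breeding potential

@dataclass
class BreedingReport:
    gebv_max_cultivated: float
    gebv_max_haplotype: float
    n_combinations: int
    improvement_pct: float | None
    top_marker_ids: list[str]
    best_assignment: np.ndarray

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "gebv_max_cultivated": self.gebv_max_cultivated,
            "gebv_max_haplotype": self.gebv_max_haplotype,
            "n_combinations": self.n_combinations,
            "improvement_pct": self.improvement_pct,
        }])


def enumerate_breeding(model, dosage: np.ndarray, top_marker_cols: np.ndarray,
                       marker_ids: np.ndarray | None = None,
                       accession_mask: np.ndarray | None = None,
                       cap: int = 20) -> BreedingReport:
    """Exhaustive haplotype enumeration over the top-k markers.

    The background is the genotype of the highest-GEBV accession (within
    ``accession_mask`` if given, e.g. the cultivated group).  Every
    2^k assignment of the k markers to {absent, homozygous carrier}
    (0 or the marker's maximum observed dosage) is predicted; the report
    carries GEBV_max_haplotype, GEBV_max_cultivated and the improvement
    percentage 100 * (hap - cult) / cult.

    k above ``cap`` is refused: the enumeration is 2^k and the default
    cap of 20 already produces 1,048,576 combinations.
    """
    k = len(top_marker_cols)
    if k > cap:
        raise ValueError(
            f"top_k={k} would enumerate 2^{k} combinations; the cap is "
            f"{cap} (2^{cap}). Raise `cap` explicitly if you mean it.")
    X = _impute(dosage)
    gebv = model.predict(X)
    pool = np.flatnonzero(accession_mask) if accession_mask is not None \
        else np.arange(len(gebv))
    best_acc = pool[np.argmax(gebv[pool])]
    gebv_cult = float(gebv[best_acc])

    n_comb = 2 ** k
    bits = ((np.arange(n_comb)[:, None] >> np.arange(k)) & 1).astype(float)
    hi = X[:, top_marker_cols].max(axis=0)
    variants = np.tile(X[best_acc], (n_comb, 1))
    variants[:, top_marker_cols] = bits * hi
    pred = model.predict(variants)
    best = int(np.argmax(pred))
    gebv_hap = float(pred[best])

    improvement = None
    if gebv_cult != 0:
        improvement = 100.0 * (gebv_hap - gebv_cult) / gebv_cult
    ids = (marker_ids[top_marker_cols] if marker_ids is not None
           else np.array([f"m{c}" for c in top_marker_cols]))
    return BreedingReport(
        gebv_max_cultivated=gebv_cult, gebv_max_haplotype=gebv_hap,
        n_combinations=n_comb, improvement_pct=improvement,
        top_marker_ids=list(ids), best_assignment=bits[best] * hi)


# ---------------------------------------------------------------------------
# model object

@dataclass
class GenomicPredictionResults:
    importance: MarkerImportance
    selected: list[str]
    report: PredictionReport
    model: object
    marker_ids: np.ndarray
    dosage: np.ndarray = field(repr=False, default=None)

    def summary(self) -> pd.DataFrame:
        s = self.report.summary()
        s.insert(0, "n_selected_markers", len(self.selected))
        return s

    def breeding_potential(self, top_k: int = 20, cap: int = 20,
                           accession_mask: np.ndarray | None = None
                           ) -> BreedingReport:
        top = self.importance.top(top_k)
        cols = [int(np.flatnonzero(self.marker_ids == m)[0])
                for m in top["marker_id"]]
        return enumerate_breeding(self.model, self.dosage, np.array(cols),
                                  marker_ids=self.marker_ids,
                                  accession_mask=accession_mask, cap=cap)


class GenomicPrediction:
    """Genomic selection on one marker panel and one phenotype dataset.

    ``fit()`` estimates marker importance, applies the ROF cut, fits the
    full-data prediction model, and cross-validates precision.
    """

    def __init__(self, dosage: np.ndarray, phenotype: np.ndarray,
                 marker_ids: np.ndarray | None = None, model: str = "gbm",
                 rof_max: float = 0.99, reps: int = 100, seed: int = 0,
                 n_train: int | None = None, n_test: int | None = None,
                 **params) -> None:
        self.dosage = dosage
        self.phenotype = np.asarray(phenotype, float)
        self.marker_ids = (marker_ids if marker_ids is not None
                           else np.array([f"m{i}" for i in
                                          range(dosage.shape[1])]))
        self.model_kind = model
        self.rof_max = rof_max
        self.reps = reps
        self.seed = seed
        self.n_train = n_train
        self.n_test = n_test
        self.params = params

    def fit(self) -> GenomicPredictionResults:
        imp = feature_gain(self.dosage, self.phenotype,
                           marker_ids=self.marker_ids, seed=self.seed)
        selected = rof_select(imp, self.rof_max)
        report = cross_validate(self.dosage, self.phenotype,
                                n_train=self.n_train, n_test=self.n_test,
                                reps=self.reps, seed=self.seed,
                                model=self.model_kind, **self.params)
        full = make_predictor(self.model_kind, seed=self.seed, **self.params)
        full.fit(_impute(self.dosage), self.phenotype)
        return GenomicPredictionResults(
            importance=imp, selected=selected, report=report, model=full,
            marker_ids=self.marker_ids, dosage=self.dosage)
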