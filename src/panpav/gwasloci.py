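"""Mixed-model association with SV-aware locus clustering.

The association model follows the EMMAX convention: a single random
polygenic effect with VanRaden kinship K, variance components estimated
once on the null model through the eigendecomposition of K, then a
per-marker generalized least squares test in the rotated space.
Principal components of the genotype matrix enter as fixed covariates.
Significant markers are greedily clustered into loci around their
smallest-p leads (<= 50 kb and LD R^2 >= 0.3 by default), and SV-vs-SNP
complementarity is quantified as the fraction of SVs not tagged by any
flanking SNP.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import MISSING

#: default genome-wide significance threshold (0.05 / reported M_eff of the
#: reference panel); both alpha levels are emitted by significance_thresholds
DEFAULT_P_MAX = 7.81e-8


def _impute(dosage: np.ndarray) -> np.ndarray:
    """Column-mean imputation of missing dosage entries (float output)."""
    d = np.asarray(dosage, dtype=float).copy()
    d[dosage == MISSING] = np.nan
    mean = np.nanmean(d, axis=0)
    mean = np.where(np.isnan(mean), 0.0, mean)
    ii, jj = np.where(np.isnan(d))
    d[ii, jj] = mean[jj]
    return d


def filter_markers(dosage: np.ndarray, maf_min: float = 0.05,
                   miss_max: float = 0.1, ploidy: int = 2) -> np.ndarray:
    """Indices of markers passing MAF >= maf_min and missingness < miss_max."""
    d = np.asarray(dosage)
    called = d != MISSING
    miss = 1 - called.mean(axis=0)
    an = ploidy * called.sum(axis=0)
    ac = np.where(called, d, 0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(an > 0, ac / np.maximum(an, 1), 0.0)
    maf = np.minimum(p, 1 - p)
    return np.flatnonzero((maf >= maf_min) & (miss < miss_max))


def kinship(dosage: np.ndarray, ploidy: int = 2) -> np.ndarray:
    """VanRaden centered cross-product kinship.

    K = W W' / (ploidy * sum p (1-p)) with W the column-centered dosage
    matrix.  Zero-variance markers are excluded.  The diagonal mean is
    ~1 for a panel in Hardy-Weinberg proportions.
    """
    d = _impute(dosage)
    p = d.mean(axis=0) / ploidy
    keep = d.std(axis=0) > 0  # zero-variance markers carry no information
    if not keep.any():
        # e.g. a panel of identical accessions: no relatedness signal
        return np.zeros((d.shape[0], d.shape[0]))
    W = d[:, keep] - ploidy * p[keep]
    denom = ploidy * np.sum(p[keep] * (1 - p[keep]))
    return (W @ W.T) / denom


def genotype_pcs(dosage: np.ndarray, n_pc: int) -> np.ndarray:
    """Top principal components of the standardized genotype matrix."""
    if n_pc == 0:
        return np.empty((dosage.shape[0], 0))
    d = _impute(dosage)
    d -= d.mean(axis=0)
    sd = d.std(axis=0)
    sd[sd == 0] = 1.0
    d /= sd
    u, s, _ = np.linalg.svd(d, full_matrices=False)
    return u[:, :n_pc] * s[:n_pc]


def _ml_delta(eigenvalues: np.ndarray, y_rot: np.ndarray,
              x_rot: np.ndarray) -> float:
    """Profile the variance ratio delta = sigma_e^2 / sigma_g^2 by ML.

    Operates in the eigenbasis of K; y and covariates are already
    rotated.  Returns the maximizing delta on a log grid refined by
    bounded scalar optimization.
    """
    n = len(y_rot)

    def neg_loglik(log_delta: float) -> float:
        delta = math.exp(log_delta)
        w = 1.0 / (eigenvalues + delta)
        xw = x_rot * w[:, None]
        xtx = x_rot.T @ xw
        beta = np.linalg.solve(xtx, xw.T @ y_rot)
        resid = y_rot - x_rot @ beta
        rss = float(np.sum(resid ** 2 * w))
        return 0.5 * (n * math.log(rss / n) - np.sum(np.log(w)))

    grid = np.linspace(-10, 10, 21)
    best = min(grid, key=neg_loglik)
    res = optimize.minimize_scalar(neg_loglik,
                                   bounds=(best - 1.5, best + 1.5),
                                   method="bounded")
    return float(math.exp(res.x))


@dataclass
class LMMResults:
    """Per-marker association results plus the fitted null model."""

    table: pd.DataFrame
    delta: float
    h2: float
    n: int
    n_pc: int

    def significant(self, p_max: float = DEFAULT_P_MAX) -> pd.DataFrame:
        return self.table[self.table["p"] <= p_max]

    def summary(self) -> pd.DataFrame:
        lam = genomic_inflation(self.table["p"].to_numpy())
        return pd.DataFrame([{
            "n_markers": len(self.table), "n_accessions": self.n,
            "pseudo_h2": self.h2, "delta": self.delta,
            "lambda_gc": lam,
            "min_p": float(self.table["p"].min()) if len(self.table) else np.nan,
        }])


def genomic_inflation(p: np.ndarray) -> float:
    """Genomic-control lambda: median chi2(1) vs expected median."""
    chi = stats.chi2.isf(np.clip(p, 1e-300, 1), df=1)
    return float(np.median(chi) / stats.chi2.isf(0.5, df=1))


def lmm_assoc(dosage: np.ndarray, phenotype: np.ndarray,
              K: np.ndarray | None = None, n_pc: int = 10,
              marker_ids: np.ndarray | None = None,
              chrom: np.ndarray | None = None,
              pos: np.ndarray | None = None,
              marker_type: np.ndarray | None = None,
              ploidy: int = 2) -> LMMResults:
    """Single-trait mixed-model scan (EMMAX convention).

    Variance components are estimated once on the null model (intercept
    + PCs) via the eigendecomposition of K; each marker is then tested
    by OLS in the rotated, whitened space with per-marker residual
    variance (a Wald t-test).  With K = identity and n_pc = 0 this is
    exactly ordinary least squares.
    """
    y = np.asarray(phenotype, dtype=float)
    n, m = dosage.shape
    if len(y) != n:
        raise ValueError("phenotype length does not match accessions")
    if np.std(y) == 0:
        raise ValueError("constant phenotype")

    d = _impute(dosage)
    if K is None:
        K = kinship(dosage, ploidy=ploidy)
    pcs = genotype_pcs(dosage, n_pc)
    X0 = np.column_stack([np.ones(n), pcs])
    rank = np.linalg.matrix_rank(X0)
    if rank < X0.shape[1]:
        raise ValueError("singular covariate matrix: intercept/PC columns "
                         f"have rank {rank} < {X0.shape[1]}")

    eigval, eigvec = np.linalg.eigh(K)
    eigval = np.maximum(eigval, 0.0)
    y_rot = eigvec.T @ y
    x0_rot = eigvec.T @ X0
    delta = _ml_delta(eigval, y_rot, x0_rot)
    h2 = 1.0 / (1.0 + delta)

    w = 1.0 / np.sqrt(eigval + delta)  # whitening weights
    ys = y_rot * w
    X0s = x0_rot * w[:, None]
    G = (eigvec.T @ d) * w[:, None]

    # residualize on the null design
    q0, _ = np.linalg.qr(X0s)
    y_perp = ys - q0 @ (q0.T @ ys)
    g_perp = G - q0 @ (q0.T @ G)

    gtg = np.sum(g_perp ** 2, axis=0)
    ok = gtg > 1e-12
    beta = np.zeros(m)
    se = np.full(m, np.nan)
    pvals = np.ones(m)
    dof = n - X0.shape[1] - 1
    beta[ok] = (g_perp[:, ok] * y_perp[:, None]).sum(axis=0) / gtg[ok]
    rss = np.sum(y_perp ** 2) - beta[ok] ** 2 * gtg[ok]
    sigma2 = np.maximum(rss, 0.0) / dof
    se[ok] = np.sqrt(sigma2 / gtg[ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[ok] / se[ok]
    pvals[ok] = 2 * stats.t.sf(np.abs(t), dof)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)

    table = pd.DataFrame({
        "marker_id": marker_ids if marker_ids is not None
        else np.array([f"m{i}" for i in range(m)]),
        "type": marker_type if marker_type is not None else "SNP",
        "chrom": chrom if chrom is not None else "chr0",
        "pos": pos if pos is not None else np.arange(m),
        "maf": _maf_from_imputed(d, ploidy),
        "beta": beta, "se": se, "p": pvals,
    })
    return LMMResults(table=table, delta=delta, h2=h2, n=n, n_pc=n_pc)


def _maf_from_imputed(d: np.ndarray, ploidy: int) -> np.ndarray:
    p = d.mean(axis=0) / ploidy
    return np.minimum(p, 1 - p)


class MixedLMM:
    """Model object for one phenotype dataset.

    Wraps marker matrices (SNPs and/or SVs), computes kinship and PCs,
    and runs the per-marker scan on ``fit()``.
    """

    def __init__(self, phenotype: np.ndarray, dosage: np.ndarray,
                 marker_ids: np.ndarray | None = None,
                 chrom: np.ndarray | None = None,
                 pos: np.ndarray | None = None,
                 marker_type: np.ndarray | None = None,
                 K: np.ndarray | None = None, n_pc: int = 10,
                 maf_min: float = 0.05, miss_max: float = 0.1) -> None:
        keep = filter_markers(dosage, maf_min, miss_max)
        self.keep = keep
        self.dosage = dosage[:, keep]
        self.phenotype = np.asarray(phenotype, float)

        def _sub(a):
            return a[keep] if a is not None else None
        self.marker_ids = _sub(marker_ids)
        self.chrom = _sub(chrom)
        self.pos = _sub(pos)
        self.marker_type = _sub(marker_type)
        self.K = K if K is not None else kinship(self.dosage)
        self.n_pc = n_pc

    def fit(self) -> LMMResults:
        return lmm_assoc(self.dosage, self.phenotype, K=self.K,
                         n_pc=self.n_pc, marker_ids=self.marker_ids,
                         chrom=self.chrom, pos=self.pos,
                         marker_type=self.marker_type)


# ---------------------------------------------------------------------------
# effective number of markers

def effective_marker_number(dosage: np.ndarray, block_size: int = 1000
                            ) -> tuple[float, dict[float, float]]:
    """Effective number of independent tests, blockwise eigenvalue style.

    Markers are split into consecutive non-overlapping blocks; each
    block contributes sum_i [1(lambda_i >= 1) + (lambda_i - floor(
    lambda_i))] over the eigenvalues of its marker correlation matrix.
    Mutually orthogonal markers give M_eff = M; duplicating every marker
    halves it.  Returns (M_eff, thresholds alpha / M_eff).
    """
    d = _impute(dosage)
    m = d.shape[1]
    total = 0.0
    for start in range(0, m, block_size):
        block = d[:, start:start + block_size]
        sd = block.std(axis=0)
        block = block[:, sd > 0]
        if block.shape[1] == 0:
            continue
        if block.shape[1] == 1:
            total += 1.0
            continue
        corr = np.corrcoef(block, rowvar=False)
        lam = np.linalg.eigvalsh(corr)
        lam = np.clip(lam, 0.0, None)
        total += float(np.sum((lam >= 1 - 1e-9).astype(float)
                              + (lam - np.floor(lam + 1e-9))))
    thresholds = {0.05: 0.05 / total, 0.01: 0.01 / total} if total > 0 else {}
    return total, thresholds


# ---------------------------------------------------------------------------
# LD and locus clustering

def _pairwise_complete_r2(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of x against each column of Y,
    computed over pairwise-complete (non-missing) accessions."""
    out = np.full(Y.shape[1], np.nan)
    x = np.asarray(x, float)
    xm = x != MISSING
    for j in range(Y.shape[1]):
        yj = np.asarray(Y[:, j], float)
        m = xm & (Y[:, j] != MISSING)
        if m.sum() < 3:
            continue
        xv, yv = x[m], yj[m]
        if xv.std() == 0 or yv.std() == 0:
            continue
        r = np.corrcoef(xv, yv)[0, 1]
        out[j] = r * r
    return out


@dataclass
class Locus:
    """One association locus: a lead marker and its clustered members."""

    lead_id: str
    chrom: str
    lead_pos: int
    lead_p: float
    member_ids: list[str] = field(default_factory=list)
    span: tuple[int, int] = (0, 0)
    detection: str = "SNP-only"


def cluster_loci(assoc: pd.DataFrame, dosage: np.ndarray,
                 p_max: float = DEFAULT_P_MAX, dist_max: int = 50_000,
                 r2_min: float = 0.3) -> list[Locus]:
    """Greedy lead-marker clustering of significant associations.

    Repeatedly takes the smallest-p unassigned significant marker as a
    lead (ties: smaller chromosome index, then position) and assigns
    every unassigned significant marker within ``dist_max`` of it on the
    same chromosome with genotype R^2 >= ``r2_min``.  The result is a
    partition of the significant markers.

    ``dosage`` columns must align with ``assoc`` rows.
    """
    sig = assoc[assoc["p"] <= p_max].copy()
    if len(sig) == 0:
        return []
    chrom_rank = {c: i for i, c in enumerate(pd.unique(assoc["chrom"]))}
    sig["_crank"] = sig["chrom"].map(chrom_rank)
    sig = sig.sort_values(["p", "_crank", "pos"], kind="stable")

    unassigned = dict.fromkeys(sig.index)  # insertion-ordered set
    loci: list[Locus] = []
    while unassigned:
        lead_idx = next(iter(unassigned))
        lead = sig.loc[lead_idx]
        del unassigned[lead_idx]
        members = [lead_idx]
        cand = [i for i in unassigned
                if sig.at[i, "chrom"] == lead["chrom"]
                and abs(sig.at[i, "pos"] - lead["pos"]) <= dist_max]
        if cand:
            pos_idx = assoc.index.get_indexer(cand)
            lead_col = assoc.index.get_loc(lead_idx)
            r2 = _pairwise_complete_r2(dosage[:, lead_col],
                                       dosage[:, pos_idx])
            for i, v in zip(cand, r2):
                if np.isfinite(v) and v >= r2_min:
                    members.append(i)
                    del unassigned[i]
        sub = sig.loc[members]
        types = set(sub["type"])
        detection = ("both" if {"SNP", "SV"} <= types
                     else "SV-only" if types == {"SV"} else "SNP-only")
        loci.append(Locus(
            lead_id=str(lead["marker_id"]), chrom=str(lead["chrom"]),
            lead_pos=int(lead["pos"]), lead_p=float(lead["p"]),
            member_ids=[str(x) for x in sub["marker_id"]],
            span=(int(sub["pos"].min()), int(sub["pos"].max())),
            detection=detection))
    return loci


def loci_to_frame(loci: list[Locus]) -> pd.DataFrame:
    return pd.DataFrame([{
        "lead_id": l.lead_id, "chrom": l.chrom, "lead_pos": l.lead_pos,
        "lead_p": l.lead_p, "n_members": len(l.member_ids),
        "span_start": l.span[0], "span_end": l.span[1],
        "detection": l.detection,
        "member_ids": ",".join(l.member_ids),
    } for l in loci])


def candidate_genes(loci: list[Locus], genes: pd.DataFrame,
                    window: int = 50_000) -> pd.DataFrame:
    """Genes intersecting [lead - window, lead + window] per locus."""
    rows = []
    for locus in loci:
        lo, hi = locus.lead_pos - window, locus.lead_pos + window
        sub = genes[(genes["chrom"] == locus.chrom)
                    & (genes["start"] <= hi) & (genes["end"] >= lo)]
        for _, g in sub.iterrows():
            rows.append({"lead_id": locus.lead_id, "gene_id": g["gene_id"],
                         "chrom": locus.chrom, "gene_start": g["start"],
                         "gene_end": g["end"]})
    return pd.DataFrame(rows,
                        columns=["lead_id", "gene_id", "chrom",
                                 "gene_start", "gene_end"])


# ---------------------------------------------------------------------------
# SV-SNP LD complementarity

@dataclass
class LdComplement:
    table: pd.DataFrame
    untagged_fraction: float
    n_monomorphic: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "n_svs": len(self.table),
            "untagged_fraction": self.untagged_fraction,
            "n_monomorphic_excluded": self.n_monomorphic,
        }])


def sv_snp_ld_complement(sv_geno: np.ndarray, sv_chrom: np.ndarray,
                         sv_start: np.ndarray, sv_end: np.ndarray,
                         snp_geno: np.ndarray, snp_chrom: np.ndarray,
                         snp_pos: np.ndarray, sv_ids: np.ndarray | None = None,
                         flank: int = 50_000, r2_cut: float = 0.5
                         ) -> LdComplement:
    """Maximum SV-vs-flanking-SNP R^2 and the untagged-SV fraction.

    An SV is untagged when no SNP within ``flank`` bp of its breakpoints
    reaches R^2 >= ``r2_cut`` (including the no-flanking-SNP case).
    Monomorphic SVs are excluded and counted.
    """
    n_sv = sv_geno.shape[1]
    if sv_ids is None:
        sv_ids = np.array([f"sv{i}" for i in range(n_sv)])
    rows = []
    n_mono = 0
    for j in range(n_sv):
        x = sv_geno[:, j]
        called = x != MISSING
        if called.sum() == 0 or np.std(x[called].astype(float)) == 0:
            n_mono += 1
            continue
        m = (snp_chrom == sv_chrom[j]) & \
            (snp_pos >= sv_start[j] - flank) & (snp_pos <= sv_end[j] + flank)
        if m.any():
            r2 = _pairwise_complete_r2(x, snp_geno[:, m])
            max_r2 = float(np.nanmax(r2)) if np.isfinite(r2).any() else np.nan
        else:
            max_r2 = np.nan
        tagged = bool(np.isfinite(max_r2) and max_r2 >= r2_cut)
        rows.append({"sv_id": sv_ids[j], "max_r2": max_r2,
                     "n_flanking_snps": int(m.sum()), "tagged": tagged})
    table = pd.DataFrame(rows, columns=["sv_id", "max_r2",
                                        "n_flanking_snps", "tagged"])
    frac = float((~table["tagged"]).mean()) if len(table) else np.nan
    return LdComplement(table=table, untagged_fraction=frac,
                        n_monomorphic=n_mono)
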