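"""Sliding-window nucleotide diversity, pi-ratio and F_ST selection scans.

Windows default to 20 kb with a 2 kb step.  Per-site diversity uses the
unbiased heterozygosity 2*p*q*n/(n-1) over non-missing allele counts,
summed over variant sites and divided by the full window span
(monomorphic sites contribute zero).  F_ST is the Weir & Cockerham
(1984) estimator; window values are ratio-of-sums of the per-site
variance components a / (a + b + c).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MISSING, SnpMatrix, check_groups


def make_windows(genome: dict[str, int], size: int = 20_000,
                 step: int = 2_000) -> pd.DataFrame:
    """Sliding windows tiling each chromosome: starts 0, step, 2*step, ...

    Every window is clipped to the chromosome end; generation continues
    while the start is inside the chromosome.
    """
    if size <= 0 or step <= 0:
        raise ValueError("window size and step must be positive")
    rows = []
    for chrom, length in genome.items():
        for start in range(0, length, step):
            rows.append({"chrom": chrom, "start": start,
                         "end": min(start + size, length)})
    return pd.DataFrame(rows)


def _group_rows(snps: SnpMatrix, groups: pd.Series, group: str) -> np.ndarray:
    g = check_groups(groups, snps.accessions)
    rows = np.flatnonzero((g == group).to_numpy())
    if len(rows) == 0:
        raise ValueError(f"no accessions in group {group!r}")
    return rows


def _allele_counts(dosage: np.ndarray, ploidy: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    """(alt allele count, called allele count) per site."""
    called = dosage != MISSING
    an = ploidy * called.sum(axis=0)
    ac = np.where(called, dosage, 0).sum(axis=0)
    return ac.astype(float), an.astype(float)


def _site_pi(ac: np.ndarray, an: np.ndarray) -> np.ndarray:
    """Unbiased per-site heterozygosity 2 p q n/(n-1); 0 where n < 2.

    Equals the mean number of pairwise allele differences per site.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        p = ac / an
        pi = 2.0 * p * (1.0 - p) * an / (an - 1.0)
    pi[an < 2] = 0.0
    return pi


def _window_sums(values: np.ndarray, pos: np.ndarray, chrom: np.ndarray,
                 windows: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Sum sorted per-site values into windows; also count sites."""
    sums = np.zeros(len(windows))
    counts = np.zeros(len(windows), dtype=int)
    for c in windows["chrom"].unique():
        site_m = chrom == c
        p = pos[site_m]
        order = np.argsort(p, kind="stable")
        p = p[order]
        v = values[site_m][order]
        cum = np.concatenate([[0.0], np.cumsum(v)])
        win_m = (windows["chrom"] == c).to_numpy()
        lo = np.searchsorted(p, windows.loc[win_m, "start"].to_numpy())
        hi = np.searchsorted(p, windows.loc[win_m, "end"].to_numpy())
        sums[win_m] = cum[hi] - cum[lo]
        counts[win_m] = hi - lo
    return sums, counts


def window_pi(snps: SnpMatrix, groups: pd.Series, group: str,
              windows: pd.DataFrame) -> pd.DataFrame:
    """Windowed nucleotide diversity for one group (per-bp units)."""
    rows = _group_rows(snps, groups, group)
    ac, an = _allele_counts(snps.dosage[rows], snps.ploidy)
    pi = _site_pi(ac, an)
    sums, counts = _window_sums(pi, snps.pos, snps.chrom, windows)
    span = (windows["end"] - windows["start"]).to_numpy(float)
    out = windows.copy()
    out["n_variants"] = counts
    out["pi"] = sums / span
    return out


def _wc_components(acA, anA, hetA, nA, acB, anB, hetB, nB):
    """Per-site Weir & Cockerham (1984) variance components a, b, c.

    Inputs are per-site alt-allele counts, called allele counts, observed
    heterozygote counts and called individual counts for two populations
    of diploids.  Sites with fewer than 2 called individuals in either
    population are masked (returned as NaN).
    """
    r = 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        pA, pB = acA / anA, acB / anB
        hA, hB = hetA / nA, hetB / nB
        nbar = (nA + nB) / r
        nc = (r * nbar - (nA ** 2 + nB ** 2) / (r * nbar)) / (r - 1.0)
        pbar = (nA * pA + nB * pB) / (r * nbar)
        s2 = (nA * (pA - pbar) ** 2 + nB * (pB - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (nA * hA + nB * hB) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                     - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2.0
    bad = (nA < 2) | (nB < 2)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def site_fst_components(snps: SnpMatrix, groups: pd.Series,
                        group_a: str, group_b: str):
    rows_a = _group_rows(snps, groups, group_a)
    rows_b = _group_rows(snps, groups, group_b)
    if set(rows_a) & set(rows_b):
        raise ValueError("groups must be disjoint")

    def stats(rows):
        d = snps.dosage[rows]
        called = d != MISSING
        n = called.sum(axis=0).astype(float)
        ac = np.where(called, d, 0).sum(axis=0).astype(float)
        het = (d == 1).sum(axis=0).astype(float)
        return ac, snps.ploidy * n, het, n

    return _wc_components(*stats(rows_a), *stats(rows_b))


def window_fst(snps: SnpMatrix, groups: pd.Series, group_a: str,
               group_b: str, windows: pd.DataFrame) -> pd.DataFrame:
    """Windowed Weir & Cockerham F_ST: sum(a) / sum(a + b + c).

    Monomorphic or uncallable windows (zero denominator) are NaN.
    """
    a, b, c = site_fst_components(snps, groups, group_a, group_b)
    ok = np.isfinite(a)
    num = np.where(ok, a, 0.0)
    den = np.where(ok, a + b + c, 0.0)
    num_s, _ = _window_sums(num, snps.pos, snps.chrom, windows)
    den_s, counts = _window_sums(den, snps.pos, snps.chrom, windows)
    out = windows.copy()
    out["n_variants"] = counts
    with np.errstate(divide="ignore", invalid="ignore"):
        out["fst"] = np.where(den_s != 0, num_s / den_s, np.nan)
    return out


@dataclass
class ScanThresholds:
    """Empirical cutoffs per statistic at a genome-wide tail quantile."""

    quantile: float
    cutoffs: dict[str, float]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame([{"statistic": k, "cutoff": v,
                              "quantile": self.quantile}
                             for k, v in self.cutoffs.items()])


def scan_candidates(stats: pd.DataFrame, statistics: list[str],
                    quantile: float = 0.01
                    ) -> tuple[pd.DataFrame, ScanThresholds]:
    """Flag windows in the upper ``quantile`` tail of each statistic.

    Cutoffs are the empirical (1 - quantile) quantiles over finite
    window values; ``flag_joint`` is the intersection of all statistics.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    out = stats.copy()
    cutoffs = {}
    joint = np.ones(len(stats), dtype=bool)
    for name in statistics:
        v = stats[name].to_numpy(float)
        finite = np.isfinite(v)
        if finite.sum() < 1 / quantile:
            import warnings
            warnings.warn(f"only {finite.sum()} finite windows for {name}; "
                          f"cutoff at quantile {quantile} is unstable",
                          stacklevel=2)
        cutoffs[name] = float(np.quantile(v[finite], 1 - quantile)) \
            if finite.any() else np.nan
        flag = finite & (v > cutoffs[name])
        out[f"flag_{name}"] = flag
        joint &= flag
    out["flag_joint"] = joint
    return out, ScanThresholds(quantile=quantile, cutoffs=cutoffs)


@dataclass
class DiversityScanResults:
    """Windowed pi for both groups, pi-ratio and F_ST, plus flags."""

    windows: pd.DataFrame
    thresholds: ScanThresholds | None = None

    def candidates(self, quantile: float = 0.01) -> "DiversityScanResults":
        flagged, thr = scan_candidates(self.windows, ["pi_ratio", "fst"],
                                       quantile)
        return DiversityScanResults(windows=flagged, thresholds=thr)

    def summary(self) -> pd.DataFrame:
        w = self.windows
        rows = [{"statistic": "pi_ratio",
                 "median": float(np.nanmedian(w["pi_ratio"].replace(
                     [np.inf, -np.inf], np.nan)))},
                {"statistic": "fst", "median": float(np.nanmedian(w["fst"]))}]
        return pd.DataFrame(rows)


class DiversityScan:
    """Model object: windowed pi-ratio and F_ST between two groups.

    The numerator group defaults to wild and the denominator to landrace
    (selection depresses diversity in the derived group, inflating the
    ratio).
    """

    def __init__(self, snps: SnpMatrix, groups: pd.Series,
                 pair: tuple[str, str] = ("wild", "landrace"),
                 window_size: int = 20_000, step: int = 2_000,
                 genome: dict[str, int] | None = None) -> None:
        self.snps = snps
        self.groups = groups
        self.pair = pair
        self.window_size = window_size
        self.step = step
        if genome is None:
            genome = {c: int(snps.pos[snps.chrom == c].max()) + 1
                      for c in pd.unique(snps.chrom)}
        self.genome = genome

    def fit(self) -> DiversityScanResults:
        windows = make_windows(self.genome, self.window_size, self.step)
        ga, gb = self.pair
        pa = window_pi(self.snps, self.groups, ga, windows)
        pb = window_pi(self.snps, self.groups, gb, windows)
        fst = window_fst(self.snps, self.groups, ga, gb, windows)
        out = windows.copy()
        out["n_variants"] = fst["n_variants"]
        out[f"pi_{ga}"] = pa["pi"]
        out[f"pi_{gb}"] = pb["pi"]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = pa["pi"].to_numpy() / pb["pi"].to_numpy()
        ratio[(pa["pi"].to_numpy() == 0) & (pb["pi"].to_numpy() == 0)] = np.nan
        out["pi_ratio"] = ratio
        out["fst"] = fst["fst"]
        return DiversityScanResults(windows=out)
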