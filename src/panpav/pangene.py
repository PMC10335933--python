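"""Pan-genome composition and growth curves.

A gene family's occupancy count c over N accessions determines its
category:

* core:        c = N
* soft core:   ceil(0.9 N) <= c <= N - 1   (present in >90% but not all)
* dispensable: 2 <= c < ceil(0.9 N)
* private:     c = 1

At N = 111 the soft-core band is exactly 100–110 occupancies.  Growth
curves add accessions in random order and track the cumulative union
(pan) and intersection (core) family counts; the "detrended" curve is
the increment series Δpan(n), and the closure verdict fits a power law
K·n^γ + C to the mean pan curve.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

CATEGORIES = ("core", "softcore", "dispensable", "private")


def softcore_threshold(n_accessions: int) -> int:
    """Smallest occupancy count classified soft core: ceil(0.9 N)."""
    return math.ceil(0.9 * n_accessions)


@dataclass
class PanComposition:
    """Per-family categories with counts and proportions."""

    categories: pd.Series
    n_accessions: int

    @property
    def counts(self) -> dict[str, int]:
        vc = self.categories.value_counts()
        return {c: int(vc.get(c, 0)) for c in CATEGORIES}

    @property
    def proportions(self) -> dict[str, float]:
        total = len(self.categories)
        return {c: n / total for c, n in self.counts.items()}

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "category": list(CATEGORIES),
            "count": [self.counts[c] for c in CATEGORIES],
            "proportion": [self.proportions[c] for c in CATEGORIES],
        })


def classify_families(presence: pd.DataFrame) -> PanComposition:
    """Assign each family a pan-genome category from its occupancy count.

    ``presence`` is families x accessions, boolean/0-1.  A family absent
    from every accession violates the input invariant and raises.
    """
    N = presence.shape[1]
    if N < 4:
        raise ValueError("need at least 4 accessions to classify")
    counts = presence.to_numpy(dtype=bool).sum(axis=1)
    if (counts == 0).any():
        bad = presence.index[counts == 0][:5].tolist()
        raise ValueError(f"families absent from all accessions: {bad}")
    soft_min = softcore_threshold(N)
    cats = np.where(
        counts == N, "core",
        np.where(counts >= soft_min, "softcore",
                 np.where(counts >= 2, "dispensable", "private")))
    return PanComposition(
        categories=pd.Series(cats, index=presence.index, name="category"),
        n_accessions=N)


@dataclass
class GrowthCurve:
    """Mean/sd pan and core family counts for n = 1..N accession subsets."""

    pan_mean: np.ndarray
    pan_sd: np.ndarray
    core_mean: np.ndarray
    core_sd: np.ndarray
    n_permutations: int
    pan_per_perm: np.ndarray = field(repr=False, default=None)

    @property
    def n_accessions(self) -> int:
        return len(self.pan_mean)

    @property
    def increments(self) -> np.ndarray:
        """Detrended curve: Δpan(n) = pan(n) − pan(n−1), Δpan(1) = pan(1)."""
        return np.diff(self.pan_mean, prepend=0.0)

    def to_frame(self) -> pd.DataFrame:
        n = np.arange(1, self.n_accessions + 1)
        return pd.DataFrame({
            "n": n, "pan_mean": self.pan_mean, "pan_sd": self.pan_sd,
            "core_mean": self.core_mean, "core_sd": self.core_sd,
            "pan_increment": self.increments,
        })


def growth_curves(presence: pd.DataFrame, n_permutations: int = 100,
                  seed: int = 0, exhaustive: bool = False) -> GrowthCurve:
    """Cumulative pan/core counts over random accession orderings.

    With ``exhaustive=True`` every ordering of the N accessions is used
    (N! orderings; only sensible for N <= 8), which makes the means an
    exact enumeration rather than a Monte-Carlo estimate.
    """
    mat = presence.to_numpy(dtype=bool).T  # accessions x families
    N = mat.shape[0]
    if exhaustive:
        orders = [np.array(p) for p in itertools.permutations(range(N))]
    else:
        if n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        rng = np.random.default_rng(seed)
        orders = [rng.permutation(N) for _ in range(n_permutations)]

    pan = np.empty((len(orders), N))
    core = np.empty((len(orders), N))
    for r, order in enumerate(orders):
        sub = mat[order]
        pan_r = np.logical_or.accumulate(sub, axis=0).sum(axis=1)
        core_r = np.logical_and.accumulate(sub, axis=0).sum(axis=1)
        if np.any(np.diff(pan_r) < 0) or np.any(np.diff(core_r) > 0):
            raise AssertionError("pan must be non-decreasing and core "
                                 "non-increasing within a permutation")
        pan[r], core[r] = pan_r, core_r
    return GrowthCurve(
        pan_mean=pan.mean(axis=0), pan_sd=pan.std(axis=0),
        core_mean=core.mean(axis=0), core_sd=core.std(axis=0),
        n_permutations=len(orders), pan_per_perm=pan)


@dataclass
class ClosureFit:
    """Power-law fit pan(n) ~ K n^gamma + C plus the closure verdict."""

    gamma: float
    scale: float
    offset: float
    closed: bool
    plateau_n: int | None
    final_increment: float
    epsilon: float
    tol: float

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "gamma": self.gamma, "scale": self.scale, "offset": self.offset,
            "verdict": "closed" if self.closed else "open",
            "plateau_n": self.plateau_n,
            "final_increment": self.final_increment,
        }])


def fit_closure(curve: GrowthCurve, tol: float = 0.05,
                epsilon: float = 1e-3) -> ClosureFit:
    """Closure verdict from the mean pan curve.

    "closed" iff the fitted exponent gamma < 1 − tol AND the final mean
    increment is below epsilon * pan(N).  The plateau point n* is the
    smallest n whose increment falls below that same bound.  A constant
    curve short-circuits to gamma = 0, closed.
    """
    if curve.n_accessions < 5:
        raise ValueError("need a curve over at least 5 accessions")
    y = curve.pan_mean
    n = np.arange(1, len(y) + 1, dtype=float)
    total = y[-1]
    inc = curve.increments
    final_inc = inc[-1]

    if np.allclose(y, y[0]):
        return ClosureFit(gamma=0.0, scale=0.0, offset=float(y[0]),
                          closed=True, plateau_n=1, final_increment=0.0,
                          epsilon=epsilon, tol=tol)

    def model(x, k, gamma, c):
        return k * np.power(x, gamma) + c

    p0 = (max(y[0], 1.0), 0.5, 0.0)
    params, _ = curve_fit(model, n, y, p0=p0, maxfev=20000,
                          bounds=([0, 0, -np.inf], [np.inf, 3, np.inf]))
    k, gamma, c = (float(v) for v in params)

    bound = epsilon * total
    below = np.flatnonzero(inc[1:] < bound) + 2  # increments meaningful from n=2
    plateau = int(below[0]) if len(below) else None
    closed = (gamma < 1 - tol) and (final_inc < bound)
    return ClosureFit(gamma=gamma, scale=k, offset=c, closed=closed,
                      plateau_n=plateau, final_increment=float(final_inc),
                      epsilon=epsilon, tol=tol)


def plot_growth_curve(curve: GrowthCurve, path: str) -> None:
    """Write a pan/core growth-curve figure (mean ± sd) to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = np.arange(1, curve.n_accessions + 1)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
    for mean, sd, label in ((curve.pan_mean, curve.pan_sd, "pan"),
                            (curve.core_mean, curve.core_sd, "core")):
        ax1.plot(n, mean, label=label)
        ax1.fill_between(n, mean - sd, mean + sd, alpha=0.3)
    ax1.set_xlabel("accessions"); ax1.set_ylabel("gene families"); ax1.legend()
    ax2.plot(n, curve.increments)
    ax2.set_xlabel("accessions"); ax2.set_ylabel("pan increment")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
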