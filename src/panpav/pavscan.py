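"""PAV frequency scans: domestication/improvement selection, favorable
PAVs, gene/promoter mapping, TE association and TSD-based TE-derived
classification.

The selection scan compares carrier frequencies between wild and
landrace accessions ("domestication" contrast) and between landrace and
cultivar accessions ("improvement" contrast) with a two-sided Fisher
exact test, Benjamini–Hochberg adjusted across all tested PAVs.  A PAV
is flagged when q <= q_max AND |Δf| >= min_delta; a flagged PAV is a
favorable PAV (favPAV) when its three group frequencies are monotone
across wild -> landrace -> cultivar, strictly so in the flagged
contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .containers import GROUP_ORDER, MISSING, PavSet, check_groups

CONTRASTS = {
    "domestication": ("wild", "landrace"),
    "improvement": ("landrace", "cultivar"),
}

#: SV types with well-defined carrier semantics; TRA is excluded from scans
SCANNABLE_TYPES = ("INS", "DEL", "INV")


# ---------------------------------------------------------------------------
# Fisher exact test

@lru_cache(maxsize=4096)
def _fisher_grid(n1: int, n2: int) -> np.ndarray:
    """Two-sided Fisher p for every 2x2 table with fixed column margins.

    Entry [k1, k2] is the p-value of the table [[k1, n1-k1], [k2, n2-k2]].
    The two-sided p sums hypergeometric probabilities <= the observed
    table's probability (with a relative tolerance for ties).
    """
    N = n1 + n2
    grid = np.ones((n1 + 1, n2 + 1))
    for K in range(N + 1):  # total carriers
        lo, hi = max(0, K - n2), min(K, n1)
        support = np.arange(lo, hi + 1)
        pmf = hypergeom.pmf(support, N, K, n1)
        for k1, p_obs in zip(support, pmf):
            p = pmf[pmf <= p_obs * (1 + 1e-9)].sum()
            grid[k1, K - k1] = min(p, 1.0)
    return grid


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration.

    ``table`` is [[a, b], [c, d]] with rows = groups and columns =
    carrier / non-carrier.  An empty margin returns p = 1 by convention.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    n1, n2 = a + b, c + d
    if n1 == 0 or n2 == 0 or (a + c) == 0 or (b + d) == 0:
        return 1.0
    return float(_fisher_grid(n1, n2)[a, c])


def fisher_exact_vector(k1: np.ndarray, n1: np.ndarray,
                        k2: np.ndarray, n2: np.ndarray) -> np.ndarray:
    """Vectorized two-sided Fisher p over per-PAV carrier counts.

    Groups tables by their (n1, n2) margins and looks the p-values up in
    cached per-margin grids; identical to :func:`fisher_exact` per entry.
    """
    k1, n1, k2, n2 = (np.asarray(a, dtype=int) for a in (k1, n1, k2, n2))
    p = np.ones(len(k1))
    ok = (n1 > 0) & (n2 > 0)
    for m1, m2 in set(zip(n1[ok].tolist(), n2[ok].tolist())):
        grid = _fisher_grid(m1, m2)
        sel = ok & (n1 == m1) & (n2 == m2)
        p[sel] = grid[k1[sel], k2[sel]]
    return p


# ---------------------------------------------------------------------------
# frequencies

@dataclass
class PavFrequencies:
    """Per-PAV carrier frequency and counts in each accession group."""

    table: pd.DataFrame  # pav_id, type, f_<g>, carriers_<g>, called_<g>

    def freq(self, group: str) -> np.ndarray:
        return self.table[f"f_{group}"].to_numpy()

    def counts(self, group: str) -> tuple[np.ndarray, np.ndarray]:
        return (self.table[f"carriers_{group}"].to_numpy(),
                self.table[f"called_{group}"].to_numpy())


def pav_frequencies(pavs: PavSet, groups: pd.Series) -> PavFrequencies:
    """Carrier frequency per group = carriers / non-missing calls.

    A group with zero non-missing calls at a PAV yields NaN frequency;
    contrasts touching that group mask the PAV.
    """
    g = check_groups(groups, pavs.accessions)
    data = {"pav_id": pavs.records["id"].to_numpy(),
            "type": pavs.records["type"].to_numpy()}
    gt = pavs.genotypes
    for group in GROUP_ORDER:
        rows = np.flatnonzero((g == group).to_numpy())
        sub = gt[rows]
        called = (sub != MISSING).sum(axis=0)
        carriers = (sub == 1).sum(axis=0)
        with np.errstate(invalid="ignore"):
            f = np.where(called > 0, carriers / np.maximum(called, 1), np.nan)
        data[f"f_{group}"] = f
        data[f"carriers_{group}"] = carriers
        data[f"called_{group}"] = called
    return PavFrequencies(pd.DataFrame(data))


# ---------------------------------------------------------------------------
# selection scan

def scan_selected(freqs: PavFrequencies, contrast: str,
                  q_max: float = 0.01, min_delta: float = 0.25
                  ) -> pd.DataFrame:
    """Fisher + BH selection scan for one contrast.

    Returns one row per PAV: p, BH-adjusted q, delta_f (second group
    minus first, i.e. the derived-state direction), and the flag
    q <= q_max AND |delta_f| >= min_delta.  TRA records and PAVs with an
    uncallable group are excluded from testing (flag NA).
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}")
    ga, gb = CONTRASTS[contrast]
    ka, na = freqs.counts(ga)
    kb, nb = freqs.counts(gb)
    testable = (na > 0) & (nb > 0) & \
        np.isin(freqs.table["type"].to_numpy(), SCANNABLE_TYPES)

    p = np.full(len(ka), np.nan)
    p[testable] = fisher_exact_vector(ka[testable], na[testable],
                                      kb[testable], nb[testable])
    q = np.full_like(p, np.nan)
    if testable.any():
        q[testable] = multipletests(p[testable], method="fdr_bh")[1]
    delta = freqs.freq(gb) - freqs.freq(ga)
    flagged = testable & (q <= q_max) & (np.abs(delta) >= min_delta)
    return pd.DataFrame({
        "pav_id": freqs.table["pav_id"], "contrast": contrast,
        "p": p, "q": q, "delta_f": delta,
        "tested": testable, "flagged": flagged,
    })


def classify_favpav(dom: pd.DataFrame, imp: pd.DataFrame,
                    freqs: PavFrequencies) -> pd.DataFrame:
    """Favorable PAVs: flagged PAVs with monotone group frequencies.

    Direction "gain" requires f_wild <= f_landrace <= f_cultivar with a
    strict inequality in every flagged contrast; "loss" is the reversed
    ordering.  A favPAV is necessarily a domPAV or an impPAV.
    """
    fw, fl, fc = (freqs.freq(g) for g in GROUP_ORDER)
    dom_f = dom["flagged"].to_numpy()
    imp_f = imp["flagged"].to_numpy()
    any_f = dom_f | imp_f

    gain_weak = (fw <= fl) & (fl <= fc)
    gain_strict = np.where(dom_f, fw < fl, True) & np.where(imp_f, fl < fc, True)
    loss_weak = (fw >= fl) & (fl >= fc)
    loss_strict = np.where(dom_f, fw > fl, True) & np.where(imp_f, fl > fc, True)

    gain = any_f & gain_weak & gain_strict
    loss = any_f & loss_weak & loss_strict
    direction = np.where(gain, "gain", np.where(loss, "loss", ""))
    return pd.DataFrame({
        "pav_id": freqs.table["pav_id"],
        "dompav": dom_f, "imppav": imp_f,
        "favpav": gain | loss, "direction": direction,
        "f_wild": fw, "f_landrace": fl, "f_cultivar": fc,
    })


@dataclass
class SelectionScanResults:
    """Fitted selection scan: frequencies, per-contrast calls, favPAVs."""

    frequencies: PavFrequencies
    domestication: pd.DataFrame
    improvement: pd.DataFrame
    favpav: pd.DataFrame
    q_max: float
    min_delta: float

    @property
    def n_dompav(self) -> int:
        return int(self.domestication["flagged"].sum())

    @property
    def n_imppav(self) -> int:
        return int(self.improvement["flagged"].sum())

    @property
    def n_favpav(self) -> int:
        return int(self.favpav["favpav"].sum())

    def summary(self) -> pd.DataFrame:
        fav = self.favpav
        return pd.DataFrame([
            {"class": "domPAV", "count": self.n_dompav},
            {"class": "impPAV", "count": self.n_imppav},
            {"class": "favPAV", "count": self.n_favpav},
            {"class": "favPAV_gain",
             "count": int((fav["favpav"] & (fav["direction"] == "gain")).sum())},
            {"class": "favPAV_loss",
             "count": int((fav["favpav"] & (fav["direction"] == "loss")).sum())},
        ])


class SelectionScan:
    """Model object for the domestication/improvement PAV scan.

    Parameters mirror the scan defaults: BH-FDR ``q_max`` 0.01 and
    minimum absolute frequency shift ``min_delta`` 0.25.
    """

    def __init__(self, pavs: PavSet, groups: pd.Series,
                 q_max: float = 0.01, min_delta: float = 0.25) -> None:
        self.pavs = pavs
        self.groups = groups
        self.q_max = q_max
        self.min_delta = min_delta

    def fit(self) -> SelectionScanResults:
        freqs = pav_frequencies(self.pavs, self.groups)
        dom = scan_selected(freqs, "domestication", self.q_max, self.min_delta)
        imp = scan_selected(freqs, "improvement", self.q_max, self.min_delta)
        fav = classify_favpav(dom, imp, freqs)
        return SelectionScanResults(freqs, dom, imp, fav,
                                    self.q_max, self.min_delta)


# ---------------------------------------------------------------------------
# gene / promoter mapping

#: distance-profile bin edges in bp (powers of two kb, then overflow)
DISTANCE_BINS = [0, 1, 1000, 2000, 4000, 8000, 16000, 32000, 64000, 128000]


def _pav_interval(rec: pd.Series) -> tuple[int, int]:
    s, e = int(rec["start"]), int(rec["end"])
    return (s, max(e, s + 1))  # insertions occupy their breakpoint


def map_pavs_to_genes(pavs: PavSet, genes: pd.DataFrame,
                      promoter_len: int = 2000
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Associate PAVs with genes and profile PAV-to-gene distances.

    A PAV is associated with a gene when it intersects the gene body or
    the ``promoter_len`` window upstream of the strand-aware
    transcription start.  Genes with unknown strand take the promoter on
    both sides and are flagged.  Returns (associations, distance_profile);
    associations has one row per (PAV, gene) pair with a region label in
    {gene_body, promoter}; the profile bins every PAV by distance to the
    nearest gene body.
    """
    assoc_rows = []
    dists = np.full(len(pavs.records), np.inf)
    for chrom, gsub in genes.groupby("chrom", sort=False):
        g_start = gsub["start"].to_numpy(int)
        g_end = gsub["end"].to_numpy(int)
        strand = gsub["strand"].to_numpy()
        mask = pavs.records["chrom"].to_numpy() == chrom
        for ridx in np.flatnonzero(mask):
            rec = pavs.records.iloc[ridx]
            ps, pe = _pav_interval(rec)
            d = np.maximum(0, np.maximum(g_start - pe, ps - g_end))
            dists[ridx] = min(dists[ridx], d.min()) if len(d) else np.inf
            for j in range(len(gsub)):
                body = g_start[j] < pe and ps < g_end[j]
                ambiguous = strand[j] not in ("+", "-")
                if strand[j] == "+" or ambiguous:
                    prom = (g_start[j] - promoter_len) < pe and ps < g_start[j]
                else:
                    prom = False
                if strand[j] == "-" or ambiguous:
                    prom = prom or (g_end[j] < pe and ps < (g_end[j] + promoter_len))
                if body or prom:
                    assoc_rows.append({
                        "pav_id": rec["id"],
                        "gene_id": gsub["gene_id"].iloc[j],
                        "region": "gene_body" if body else "promoter",
                        "strand_ambiguous": ambiguous,
                    })
    assoc = pd.DataFrame(
        assoc_rows,
        columns=["pav_id", "gene_id", "region", "strand_ambiguous"])

    edges = DISTANCE_BINS + [np.inf]
    labels = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if lo == 0 and hi == 1:
            labels.append("overlapping")
        elif np.isinf(hi):
            labels.append(f">{lo // 1000}kb")
        else:
            labels.append(f"{lo // 1000}-{hi // 1000}kb")
    finite = np.isfinite(dists)
    binned = pd.cut(dists[finite], bins=edges, labels=labels,
                    right=False, include_lowest=True)
    profile = (binned.value_counts().reindex(labels).fillna(0).astype(int)
               .rename_axis("distance_bin").reset_index(name="n_pavs"))
    return assoc, profile


def favorable_genes(favpav: pd.DataFrame, associations: pd.DataFrame
                    ) -> pd.DataFrame:
    """Genes carrying a favPAV in their body or promoter."""
    fav_ids = set(favpav.loc[favpav["favpav"], "pav_id"])
    hits = associations[associations["pav_id"].isin(fav_ids)]
    return (hits.groupby("gene_id")
            .agg(n_favpavs=("pav_id", "nunique"),
                 regions=("region", lambda r: ",".join(sorted(set(r)))))
            .reset_index())


# ---------------------------------------------------------------------------
# TE association

def _merge_intervals(starts: np.ndarray, ends: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [], []
    for s, e in zip(starts, ends):
        if out_e and s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.array(out_s, dtype=int), np.array(out_e, dtype=int)


def _overlaps_any(ps: np.ndarray, pe: np.ndarray,
                  ms: np.ndarray, me: np.ndarray) -> np.ndarray:
    """Which query intervals [ps, pe) hit any merged interval [ms, me)."""
    if len(ms) == 0:
        return np.zeros(len(ps), dtype=bool)
    idx = np.searchsorted(me, ps, side="right")
    ok = idx < len(ms)
    hit = np.zeros(len(ps), dtype=bool)
    hit[ok] = ms[idx[ok]] < pe[ok]
    return hit


@dataclass
class TeEnrichment:
    observed_fraction: float
    null_fractions: np.ndarray
    p_value: float
    n_pavs: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "te_overlap_fraction": self.observed_fraction,
            "null_mean": float(self.null_fractions.mean())
            if len(self.null_fractions) else np.nan,
            "p_value": self.p_value, "n_pavs": self.n_pavs,
        }])


def te_overlap_enrichment(pavs: PavSet, tes: pd.DataFrame,
                          genome: dict[str, int], n_perm: int = 999,
                          seed: int = 0) -> TeEnrichment:
    """Observed TE-overlap fraction vs a random-placement null.

    Each permutation replaces every PAV uniformly at random on its own
    chromosome (length preserved); the one-sided p-value is
    (1 + #{null >= observed}) / (1 + n_perm).  PAVs longer than their
    chromosome are skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    merged = {}
    for chrom, sub in tes.groupby("chrom", sort=False):
        merged[chrom] = _merge_intervals(sub["start"].to_numpy(int),
                                         sub["end"].to_numpy(int))

    rec = pavs.records
    spans = np.maximum(rec["end"].to_numpy(int) - rec["start"].to_numpy(int), 1)
    chrom_len = rec["chrom"].map(genome).to_numpy(int)
    usable = spans <= chrom_len
    if not usable.all():
        warnings.warn(f"skipping {(~usable).sum()} PAVs longer than their "
                      "chromosome", stacklevel=2)
    obs_hits = np.zeros(len(rec), dtype=bool)
    null_hits = np.zeros((n_perm, len(rec)), dtype=bool)
    for chrom in rec["chrom"].unique():
        ms, me = merged.get(chrom, (np.array([], int), np.array([], int)))
        m = (rec["chrom"].to_numpy() == chrom) & usable
        ps = rec["start"].to_numpy(int)[m]
        pe = np.maximum(rec["end"].to_numpy(int)[m], ps + 1)
        obs_hits[m] = _overlaps_any(ps, pe, ms, me)
        L = genome[chrom]
        sp = spans[m]
        for r in range(n_perm):
            rs = rng.integers(0, np.maximum(L - sp, 1) + 1)
            null_hits[r, m] = _overlaps_any(rs, rs + sp, ms, me)

    n_used = int(usable.sum())
    if n_used == 0:
        return TeEnrichment(np.nan, np.array([]), 1.0, 0)
    observed = obs_hits[usable].mean()
    null = null_hits[:, usable].mean(axis=1) if n_perm else np.array([])
    p = (1 + int((null >= observed).sum())) / (1 + n_perm) if n_perm else 1.0
    return TeEnrichment(float(observed), null, float(p), n_used)


# ---------------------------------------------------------------------------
# TSD detection and TE-derived classification

@dataclass(frozen=True)
class TsdCall:
    length: int
    sequence: str


def detect_tsd(left_flank: str | None, right_flank: str | None,
               k_range: tuple[int, int] = (4, 10)) -> TsdCall | None:
    """Longest exact duplicated k-mer across an insertion breakpoint.

    The candidate duplication ends at the left breakpoint (suffix of the
    left flank) and begins at the right breakpoint (prefix of the right
    flank); lengths are scanned from k_max down so the longest match
    wins.  Flanks missing or shorter than k_min return None.
    """
    kmin, kmax = k_range
    if not left_flank or not right_flank:
        return None
    if len(left_flank) < kmin or len(right_flank) < kmin:
        return None
    top = min(kmax, len(left_flank), len(right_flank))
    for k in range(top, kmin - 1, -1):
        if left_flank[-k:] == right_flank[:k]:
            return TsdCall(length=k, sequence=left_flank[-k:])
    return None


def classify_te_derived(pavs: PavSet, tes: pd.DataFrame,
                        min_reciprocal: float = 0.8,
                        k_range: tuple[int, int] = (4, 10)) -> pd.DataFrame:
    """High-confidence TE-derived PAVs.

    A PAV qualifies iff it (i) intersects exactly one intact TE,
    (ii) reciprocally overlaps it by >= ``min_reciprocal`` of both
    lengths, and (iii) carries a detectable TSD.  Breakpoint-to-junction
    distances are emitted for every PAV that passes the single-intact-TE
    test.
    """
    intact = tes[tes["intact"]] if "intact" in tes.columns else tes
    by_chrom = {c: s for c, s in intact.groupby("chrom", sort=False)}
    rows = []
    for _, rec in pavs.records.iterrows():
        ps, pe = _pav_interval(rec)
        sub = by_chrom.get(rec["chrom"])
        n_hit, recip, dist_l, dist_r = 0, 0.0, np.nan, np.nan
        if sub is not None:
            ts = sub["start"].to_numpy(int)
            te_ = sub["end"].to_numpy(int)
            hit = (ts < pe) & (ps < te_)
            n_hit = int(hit.sum())
            if n_hit == 1:
                j = int(np.flatnonzero(hit)[0])
                ov = min(pe, te_[j]) - max(ps, ts[j])
                recip = min(ov / max(pe - ps, 1), ov / max(te_[j] - ts[j], 1))
                dist_l = abs(ps - ts[j])
                dist_r = abs(pe - te_[j])
        tsd = detect_tsd(rec["left_flank"], rec["right_flank"], k_range)
        rows.append({
            "pav_id": rec["id"], "n_intact_te": n_hit,
            "reciprocal_overlap": recip,
            "tsd_length": tsd.length if tsd else 0,
            "tsd_sequence": tsd.sequence if tsd else "",
            "junction_dist_left": dist_l, "junction_dist_right": dist_r,
            "te_derived": bool(n_hit == 1 and recip >= min_reciprocal
                               and tsd is not None),
        })
    return pd.DataFrame(rows)
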