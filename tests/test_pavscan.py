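"""PAV frequency scan, Fisher test, favPAV rules, gene/TE association,
TSD detection and TE-derived classification."""

from math import comb

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from panpav.containers import MISSING, PavSet
from panpav.pavscan import (
    PavFrequencies, SelectionScan, classify_favpav, classify_te_derived,
    detect_tsd, fisher_exact, fisher_exact_vector, map_pavs_to_genes,
    pav_frequencies, scan_selected, te_overlap_enrichment,
)
from panpav.synthdata import SimConfig, simulate_genotypes


def _pavset(genotypes, chrom=None, start=None, end=None, types=None,
            left=None, right=None):
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n_pav = genotypes.shape[1]
    rec = pd.DataFrame({
        "id": [f"p{i}" for i in range(n_pav)],
        "chrom": chrom if chrom is not None else ["chr1"] * n_pav,
        "start": start if start is not None else np.arange(n_pav) * 1000 + 500,
        "end": end if end is not None else np.arange(n_pav) * 1000 + 600,
        "type": types if types is not None else ["DEL"] * n_pav,
        "length": 100,
        "sequence": None,
        "left_flank": left if left is not None else [None] * n_pav,
        "right_flank": right if right is not None else [None] * n_pav,
    })
    acc = [f"a{i}" for i in range(genotypes.shape[0])]
    return PavSet(records=rec, genotypes=genotypes, accessions=acc)


def _groups(n_w, n_l, n_c):
    labels = ["wild"] * n_w + ["landrace"] * n_l + ["cultivar"] * n_c
    return pd.Series(labels, index=[f"a{i}" for i in range(len(labels))])


class TestFrequencies:
    def test_hand_counts(self):
        # wild group: 2 carriers, 1 non-carrier, 1 missing -> f = 2/3
        gt = np.array([[1], [1], [0], [MISSING], [0], [1], [0], [1]])
        pavs = _pavset(gt)
        groups = _groups(4, 2, 2)
        f = pav_frequencies(pavs, groups)
        assert f.freq("wild")[0] == pytest.approx(2 / 3)
        assert f.freq("landrace")[0] == pytest.approx(0.5)
        assert f.freq("cultivar")[0] == pytest.approx(0.5)

    def test_all_carriers(self):
        f = pav_frequencies(_pavset(np.ones((6, 2))), _groups(2, 2, 2))
        assert np.all(f.freq("wild") == 1)

    def test_matches_naive_counting_oracle(self, rng):
        gt = rng.choice([0, 1, MISSING], size=(30, 25), p=[0.5, 0.4, 0.1])
        pavs = _pavset(gt)
        groups = _groups(10, 10, 10)
        f = pav_frequencies(pavs, groups)
        for gi, g in enumerate(["wild", "landrace", "cultivar"]):
            rows = range(gi * 10, gi * 10 + 10)
            for j in range(25):
                vals = [gt[i, j] for i in rows if gt[i, j] != MISSING]
                expected = (sum(v == 1 for v in vals) / len(vals)
                            if vals else np.nan)
                got = f.freq(g)[j]
                assert (np.isnan(expected) and np.isnan(got)) \
                    or got == pytest.approx(expected)

    def test_uncallable_group_masked(self):
        gt = np.array([[MISSING], [MISSING], [1], [0], [1], [1]])
        pavs = _pavset(gt)
        f = pav_frequencies(pavs, _groups(2, 2, 2))
        assert np.isnan(f.freq("wild")[0])
        call = scan_selected(f, "domestication")
        assert not call["tested"].iloc[0]


def _oracle_fisher(a, b, c, d):
    """Two-sided Fisher p by direct enumeration with exact binomials."""
    n1, n2, K = a + b, c + d, a + c
    N = n1 + n2
    denom = comb(N, K)
    probs = []
    for i in range(max(0, K - n2), min(K, n1) + 1):
        probs.append((i, comb(n1, i) * comb(n2, K - i) / denom))
    p_obs = dict(probs)[a]
    return sum(p for _, p in probs if p <= p_obs * (1 + 1e-9))


class TestFisher:
    def test_balanced_table(self):
        assert fisher_exact([[5, 5], [5, 5]]) == pytest.approx(1.0, abs=1e-12)

    def test_perfect_separation(self):
        # 2 / C(20,10)
        assert fisher_exact([[10, 0], [0, 10]]) == \
            pytest.approx(2 / comb(20, 10), rel=1e-12)

    def test_empty_margin(self):
        assert fisher_exact([[0, 0], [3, 4]]) == 1.0
        assert fisher_exact([[0, 3], [0, 4]]) == 1.0

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -1], [2, 3]])

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_scipy_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            t = rng.integers(0, 30, size=(2, 2))
            ours = fisher_exact(t.tolist())
            ref = scipy.stats.fisher_exact(t).pvalue
            assert ours == pytest.approx(ref, rel=1e-9, abs=1e-12)

    def test_matches_enumeration_small_margins(self):
        for n1 in range(0, 9):
            for n2 in range(0, 9):
                for a in range(n1 + 1):
                    for c in range(n2 + 1):
                        t = [[a, n1 - a], [c, n2 - c]]
                        if n1 == 0 or n2 == 0 or a + c == 0 \
                                or (n1 - a) + (n2 - c) == 0:
                            assert fisher_exact(t) == 1.0
                        else:
                            assert fisher_exact(t) == pytest.approx(
                                _oracle_fisher(a, n1 - a, c, n2 - c),
                                abs=1e-12)

    def test_vector_matches_scalar(self, rng):
        k1 = rng.integers(0, 20, 40)
        n1 = k1 + rng.integers(0, 20, 40)
        k2 = rng.integers(0, 25, 40)
        n2 = k2 + rng.integers(0, 25, 40)
        pv = fisher_exact_vector(k1, n1, k2, n2)
        for i in range(40):
            expected = fisher_exact([[k1[i], n1[i] - k1[i]],
                                     [k2[i], n2[i] - k2[i]]])
            assert pv[i] == pytest.approx(expected, abs=1e-12)


class TestScan:
    def test_identical_frequencies_never_flagged(self):
        gt = np.tile([[1], [0]], (15, 1))  # alternating everywhere
        pavs = _pavset(gt)
        calls = scan_selected(pav_frequencies(pavs, _groups(10, 10, 10)),
                              "domestication")
        assert not calls["flagged"].any()
        assert (calls.loc[calls["tested"], "p"] >= 1 - 1e-9).all()

    def test_strong_shift_flagged_at_defaults(self, rng):
        n_w, n_l = 35, 40
        gt = np.zeros((110, 1), dtype=np.int8)
        gt[:n_w, 0] = rng.random(n_w) < 0.05
        gt[n_w:n_w + n_l, 0] = rng.random(n_l) < 0.9
        calls = scan_selected(pav_frequencies(_pavset(gt),
                                              _groups(35, 40, 35)),
                              "domestication")
        assert calls["flagged"].iloc[0]
        assert calls["p"].iloc[0] < 1e-6

    def test_tra_excluded(self):
        gt = np.array([[1, 1], [0, 0]] * 6)
        pavs = _pavset(gt, types=["TRA", "DEL"])
        calls = scan_selected(pav_frequencies(pavs, _groups(4, 4, 4)),
                              "domestication")
        assert not calls["tested"].iloc[0]
        assert calls["tested"].iloc[1]


class TestFavPav:
    def _fake(self, fw, fl, fc, dom=True, imp=False):
        freqs = PavFrequencies(pd.DataFrame({
            "pav_id": ["p0"], "type": ["DEL"],
            "f_wild": [fw], "carriers_wild": [0], "called_wild": [10],
            "f_landrace": [fl], "carriers_landrace": [0],
            "called_landrace": [10],
            "f_cultivar": [fc], "carriers_cultivar": [0],
            "called_cultivar": [10],
        }))
        mk = lambda f: pd.DataFrame({"pav_id": ["p0"], "flagged": [f]})
        return classify_favpav(mk(dom), mk(imp), freqs)

    @pytest.mark.parametrize("fw,fl,fc,fav,direction", [
        (0.1, 0.8, 0.95, True, "gain"),
        (0.1, 0.8, 0.30, False, ""),     # non-monotone
        (0.9, 0.2, 0.05, True, "loss"),
        (0.1, 0.8, 0.80, True, "gain"),  # tie outside the flagged contrast
        (0.5, 0.5, 0.9, False, ""),      # tie inside the flagged contrast
    ])
    def test_monotonicity_rule(self, fw, fl, fc, fav, direction):
        out = self._fake(fw, fl, fc, dom=True)
        assert bool(out["favpav"].iloc[0]) is fav
        assert out["direction"].iloc[0] == direction

    def test_favpav_implies_dom_or_imp(self):
        out = self._fake(0.1, 0.8, 0.9, dom=False, imp=False)
        assert not out["favpav"].iloc[0]

    def test_recovery_on_synthetic_panel(self):
        cfg = SimConfig(seed=17)
        _, pavs, groups, truth = simulate_genotypes(cfg)
        res = SelectionScan(pavs, groups).fit()
        planted = set(truth["pav_id"])
        called = set(res.favpav.loc[res.favpav["favpav"], "pav_id"])
        sens = len(planted & called) / len(planted)
        prec = len(planted & called) / max(len(called), 1)
        assert sens >= 0.85 and prec >= 0.85

    def test_directions_match_truth(self):
        cfg = SimConfig(seed=17)
        _, pavs, groups, truth = simulate_genotypes(cfg)
        res = SelectionScan(pavs, groups).fit()
        fav = res.favpav.set_index("pav_id")
        tr = truth.set_index("pav_id")
        both = fav.index[fav["favpav"]].intersection(tr.index)
        assert (fav.loc[both, "direction"] == tr.loc[both, "direction"]).all()


class TestGeneMapping:
    def _genes(self):
        return pd.DataFrame({
            "chrom": ["chr1", "chr1"],
            "start": [10_000, 50_000], "end": [12_000, 53_000],
            "strand": ["+", "-"], "gene_id": ["g1", "g2"],
        })

    def _scan(self, start, end):
        pavs = _pavset(np.ones((4, 1)), chrom=["chr1"], start=[start],
                       end=[end])
        return map_pavs_to_genes(pavs, self._genes(), promoter_len=2000)

    def test_inside_gene_body(self):
        assoc, _ = self._scan(10_500, 10_700)
        assert assoc.iloc[0]["gene_id"] == "g1"
        assert assoc.iloc[0]["region"] == "gene_body"

    def test_promoter_upstream_plus_strand(self):
        assoc, _ = self._scan(8_400, 8_500)  # 1.5 kb upstream of g1 TSS
        assert assoc.iloc[0]["region"] == "promoter"

    def test_promoter_is_strand_aware(self):
        # g2 is minus-strand: promoter lies right of its end coordinate
        assoc, _ = self._scan(53_500, 53_600)
        assert assoc.iloc[0]["gene_id"] == "g2"
        assoc, _ = self._scan(47_500, 47_600)  # left of g2 start: nothing
        assert len(assoc) == 0

    def test_distant_pav_not_associated_and_binned(self):
        assoc, profile = self._scan(22_000, 22_100)  # 10 kb from g1
        assert len(assoc) == 0
        assert profile.set_index("distance_bin").at["8-16kb", "n_pavs"] == 1

    def test_unknown_strand_takes_both_sides(self):
        genes = self._genes()
        genes["strand"] = "."
        pavs = _pavset(np.ones((4, 1)), chrom=["chr1"], start=[12_500],
                       end=[12_600])  # downstream of g1 end
        assoc, _ = map_pavs_to_genes(pavs, genes, promoter_len=2000)
        assert assoc.iloc[0]["strand_ambiguous"]


class TestTeOverlap:
    def test_zero_coverage(self):
        pavs = _pavset(np.ones((4, 3)))
        tes = pd.DataFrame(columns=["chrom", "start", "end"])
        enr = te_overlap_enrichment(pavs, tes, {"chr1": 100_000}, n_perm=99)
        assert enr.observed_fraction == 0.0
        assert enr.p_value == 1.0

    def test_maximal_enrichment(self):
        n = 50
        starts = np.arange(n) * 2000 + 100
        pavs = _pavset(np.ones((4, n)), start=starts, end=starts + 50)
        # TEs exactly covering each PAV: genome-wide coverage 50 * 50bp tiny,
        # so random placement virtually never reaches the observed 1.0
        tes = pd.DataFrame({"chrom": "chr1", "start": starts,
                            "end": starts + 50})
        enr = te_overlap_enrichment(pavs, tes, {"chr1": 1_000_000},
                                    n_perm=999, seed=3)
        assert enr.observed_fraction == 1.0
        assert enr.p_value == pytest.approx(1 / 1000)

    def test_observed_fraction_matches_naive_oracle(self, rng):
        n = 40
        starts = rng.integers(0, 90_000, n)
        ends = starts + rng.integers(60, 4000, n)
        pavs = _pavset(np.ones((4, n)), start=starts, end=ends)
        tes = pd.DataFrame({
            "chrom": "chr1",
            "start": (s := rng.integers(0, 95_000, 25)),
            "end": s + rng.integers(100, 3000, 25)})
        enr = te_overlap_enrichment(pavs, tes, {"chr1": 100_000}, n_perm=0)
        naive = np.mean([
            any(ts < pe and ps < te for ts, te in
                zip(tes["start"], tes["end"]))
            for ps, pe in zip(starts, ends)])
        assert enr.observed_fraction == pytest.approx(naive, abs=1e-12)

    def test_observed_invariant_under_seed(self, rng):
        starts = rng.integers(0, 50_000, 20)
        pavs = _pavset(np.ones((4, 20)), start=starts, end=starts + 100)
        tes = pd.DataFrame({"chrom": "chr1", "start": [0], "end": [25_000]})
        a = te_overlap_enrichment(pavs, tes, {"chr1": 100_000}, 49, seed=1)
        b = te_overlap_enrichment(pavs, tes, {"chr1": 100_000}, 49, seed=2)
        assert a.observed_fraction == b.observed_fraction


class TestTsd:
    def test_planted_duplication_recovered(self):
        call = detect_tsd("TTTTTTTTTTACGTA", "ACGTATTTTTTTTTT")
        assert call is not None
        assert (call.length, call.sequence) == (5, "ACGTA")

    def test_no_duplication(self):
        assert detect_tsd("AAAAAAAAAA", "CCCCCCCCCC") is None

    def test_short_or_missing_flanks(self):
        assert detect_tsd("ACG", "ACGTACGT") is None
        assert detect_tsd(None, "ACGTACGT") is None

    def test_longest_match_wins(self):
        # both a 4-mer and a 6-mer duplication exist; report the 6-mer
        call = detect_tsd("GGGGGGTACGCA", "TACGCAGGGGGG")
        assert call.length == 6

    def test_false_positive_rate_matches_analytic(self):
        """i.i.d. uniform flanks: P(any k in 4..10 matches) ~ 5.2e-3."""
        rng = np.random.default_rng(5)
        bases = np.array(list("ACGT"))
        n = 20_000
        hits = sum(
            detect_tsd("".join(bases[rng.integers(0, 4, 20)]),
                       "".join(bases[rng.integers(0, 4, 20)])) is not None
            for _ in range(n))
        analytic = 1 - np.prod([1 - 0.25 ** k for k in range(4, 11)])
        sd = np.sqrt(analytic * (1 - analytic) / n)
        assert abs(hits / n - analytic) < 5 * sd


class TestTeDerived:
    def _setup(self, n_te_hits, tsd=True, recip_frac=1.0):
        left = "TTTTTTTTTTACGTA" if tsd else "TTTTTTTTTTTTTTT"
        right = "ACGTATTTTTTTTTT" if tsd else "GGGGGGGGGGGGGGG"
        span = int(1000 * recip_frac)
        pavs = _pavset(np.ones((4, 1)), start=[5000], end=[5000 + span],
                       left=[left], right=[right])
        tes = pd.DataFrame({
            "chrom": "chr1",
            "start": [5000, 6200][:n_te_hits],
            "end": [6000, 7000][:n_te_hits],
            "intact": True,
            "te_id": ["t1", "t2"][:n_te_hits]})
        if n_te_hits == 2:
            tes.loc[1, ["start", "end"]] = [5500, 7000]
        return classify_te_derived(pavs, tes)

    def test_single_te_with_tsd_is_derived(self):
        out = self._setup(1, tsd=True)
        assert out["te_derived"].iloc[0]
        assert out["junction_dist_left"].iloc[0] == 0

    def test_two_tes_not_high_confidence(self):
        assert not self._setup(2, tsd=True)["te_derived"].iloc[0]

    def test_no_tsd_not_high_confidence(self):
        assert not self._setup(1, tsd=False)["te_derived"].iloc[0]

    def test_low_reciprocal_overlap_rejected(self):
        out = self._setup(1, tsd=True, recip_frac=2.0)  # PAV twice TE length
        assert not out["te_derived"].iloc[0]

    def test_planted_te_derived_recovered(self, small_dataset):
        out = classify_te_derived(small_dataset.pavs, small_dataset.tes)
        called = set(out.loc[out["te_derived"], "pav_id"])
        assert set(small_dataset.truth.te_derived_pavs) <= called
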