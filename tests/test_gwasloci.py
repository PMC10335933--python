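"""Mixed-model association, M_eff, locus clustering and SV-SNP LD."""

import numpy as np
import pandas as pd
import pytest
import scipy.linalg
import scipy.stats
import statsmodels.api as sm

from panpav.containers import MISSING
from panpav.gwasloci import (
    MixedLMM, candidate_genes, cluster_loci, effective_marker_number,
    kinship, lmm_assoc, loci_to_frame, sv_snp_ld_complement,
)


class TestKinship:
    def test_identical_accessions_constant_matrix(self, rng):
        row = rng.integers(0, 3, 30).astype(np.int8)
        K = kinship(np.tile(row, (6, 1)))
        assert np.allclose(K, K[0, 0])

    def test_symmetric_psd_unit_diagonal(self, rng):
        d = rng.binomial(2, rng.uniform(0.1, 0.9, 200), size=(40, 200)
                         ).astype(np.int8)
        K = kinship(d)
        assert np.allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() >= -1e-8
        assert K.diagonal().mean() == pytest.approx(1.0, abs=0.3)

    def test_matches_naive_double_loop(self, rng):
        d = rng.integers(0, 3, size=(10, 20)).astype(np.int8)
        d[:, 0] = 1  # zero-variance marker must be excluded
        K = kinship(d)
        x = d.astype(float)
        p = x.mean(axis=0) / 2
        keep = x.std(axis=0) > 0
        W = x[:, keep] - 2 * p[keep]
        denom = 2 * np.sum(p[keep] * (1 - p[keep]))
        naive = np.zeros((10, 10))
        for i in range(10):
            for j in range(10):
                naive[i, j] = np.dot(W[i], W[j]) / denom
        np.testing.assert_allclose(K, naive, atol=1e-12)

    def test_all_constant_panel_has_no_relatedness_signal(self):
        assert np.all(kinship(np.ones((5, 4), dtype=np.int8)) == 0)


class TestLmm:
    def test_identity_kinship_equals_ols(self, rng):
        n, m = 120, 60
        X = rng.binomial(2, rng.uniform(0.1, 0.9, m), size=(n, m)
                         ).astype(np.int8)
        y = rng.normal(size=n)
        res = lmm_assoc(X, y, K=np.eye(n), n_pc=0)
        for j in range(0, m, 7):
            ols = sm.OLS(y, sm.add_constant(X[:, j].astype(float))).fit()
            assert res.table["p"][j] == pytest.approx(ols.pvalues[1],
                                                      abs=1e-8)
            assert res.table["beta"][j] == pytest.approx(ols.params[1],
                                                         abs=1e-8)

    def test_permuted_phenotype_uniform_p(self, rng):
        n, m = 150, 2000
        X = rng.binomial(2, rng.uniform(0.1, 0.9, m), size=(n, m)
                         ).astype(np.int8)
        y = rng.normal(size=n)
        res = lmm_assoc(X, rng.permutation(y), n_pc=0)
        ks = scipy.stats.kstest(res.table["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_structure_confounding_reduced_vs_ols(self):
        """Two drifted groups + group-shifted phenotype: LMM p-values are
        closer to uniform than naive OLS (KS statistic)."""
        stats_lmm, stats_ols = [], []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            n2, m = 80, 400
            anc = rng.uniform(0.1, 0.9, m)
            f = np.clip(anc + rng.normal(0, 0.15, (2, m)), 0.02, 0.98)
            X = np.vstack([rng.binomial(2, f[0], size=(n2, m)),
                           rng.binomial(2, f[1], size=(n2, m))]).astype(np.int8)
            y = np.r_[np.zeros(n2), np.ones(n2)] + rng.normal(0, 1, 2 * n2)
            res = lmm_assoc(X, y, n_pc=0)
            ols_p = []
            for j in range(m):
                ols = sm.OLS(y, sm.add_constant(X[:, j].astype(float))).fit()
                ols_p.append(ols.pvalues[1])
            stats_lmm.append(scipy.stats.kstest(res.table["p"], "uniform").statistic)
            stats_ols.append(scipy.stats.kstest(ols_p, "uniform").statistic)
        assert np.mean(stats_lmm) < np.mean(stats_ols)

    def test_planted_marker_detected(self, rng):
        n, m = 300, 300
        X = rng.binomial(2, rng.uniform(0.2, 0.8, m), size=(n, m)
                         ).astype(np.int8)
        g = X[:, 7].astype(float)
        g = (g - g.mean()) / g.std()
        y = np.sqrt(0.2) * g + np.sqrt(0.8) * rng.normal(size=n)
        res = lmm_assoc(X, y, n_pc=0)
        assert res.table["p"][7] < 0.05 / m

    def test_constant_phenotype_rejected(self, rng):
        X = rng.integers(0, 3, size=(20, 5)).astype(np.int8)
        with pytest.raises(ValueError, match="constant"):
            lmm_assoc(X, np.ones(20))

    def test_model_object_filters_markers(self, rng):
        n = 60
        X = rng.binomial(2, rng.uniform(0.2, 0.8, 50), size=(n, 50)
                         ).astype(np.int8)
        X[:, 0] = 0            # MAF 0
        X[: n // 2, 1] = MISSING  # 50% missing
        y = rng.normal(size=n)
        model = MixedLMM(y, X, n_pc=2)
        assert 0 not in model.keep and 1 not in model.keep
        res = model.fit()
        assert (res.table["maf"] >= 0.05).all()


class TestEffectiveMarkers:
    def _orthogonal(self, n):
        """Mean-zero orthonormal columns via the Helmert construction."""
        return scipy.linalg.helmert(n).T  # n x (n-1)

    def test_orthogonal_markers_give_m(self):
        H = self._orthogonal(12)  # 11 exactly uncorrelated columns
        meff, thr = effective_marker_number(H, block_size=100)
        assert meff == pytest.approx(11, abs=1e-8)
        assert thr[0.05] == pytest.approx(0.05 / 11, rel=1e-6)

    def test_duplicated_markers_halve_meff(self):
        H = self._orthogonal(12)
        dup = np.repeat(H, 2, axis=1)
        meff, _ = effective_marker_number(dup, block_size=100)
        assert meff == pytest.approx(11, abs=1e-8)  # 22 columns, M/2

    def test_order_invariance_within_block(self, rng):
        X = rng.integers(0, 3, size=(50, 40)).astype(np.int8)
        a, _ = effective_marker_number(X, block_size=40)
        b, _ = effective_marker_number(X[:, rng.permutation(40)],
                                       block_size=40)
        assert a == pytest.approx(b, abs=1e-9)

    def test_single_marker_block_contributes_one(self, rng):
        X = rng.integers(0, 3, size=(30, 3)).astype(np.int8)
        meff, _ = effective_marker_number(X, block_size=1)
        assert meff == pytest.approx(3, abs=1e-9)


def _assoc_frame(p, pos, types=None):
    m = len(p)
    return pd.DataFrame({
        "marker_id": [f"m{i}" for i in range(m)],
        "type": types if types is not None else ["SNP"] * m,
        "chrom": "chr1", "pos": pos, "maf": 0.3,
        "beta": 1.0, "se": 0.1, "p": p,
    })


class TestClusterLoci:
    def _genotypes(self, r2_high, n=100, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.binomial(2, 0.5, n).astype(np.int8)
        if r2_high:
            b = a.copy()  # R^2 = 1
        else:
            b = rng.binomial(2, 0.5, n).astype(np.int8)  # R^2 ~ 0
        return np.column_stack([a, b])

    def test_near_and_correlated_merged(self):
        assoc = _assoc_frame([1e-10, 1e-9], [100_000, 110_000])
        loci = cluster_loci(assoc, self._genotypes(True), p_max=1e-7)
        assert len(loci) == 1
        assert loci[0].lead_id == "m0"
        assert set(loci[0].member_ids) == {"m0", "m1"}

    def test_distance_violation_splits(self):
        assoc = _assoc_frame([1e-10, 1e-9], [100_000, 160_000])
        loci = cluster_loci(assoc, self._genotypes(True), p_max=1e-7)
        assert len(loci) == 2

    def test_ld_violation_splits(self):
        assoc = _assoc_frame([1e-10, 1e-9], [100_000, 110_000])
        loci = cluster_loci(assoc, self._genotypes(False, seed=3), p_max=1e-7)
        assert len(loci) == 2

    def test_partition_of_significant_markers(self, rng):
        m = 40
        p = 10.0 ** rng.uniform(-12, -3, m)
        pos = np.sort(rng.choice(1_000_000, m, replace=False))
        geno = rng.binomial(2, 0.5, size=(80, m)).astype(np.int8)
        assoc = _assoc_frame(p, pos)
        loci = cluster_loci(assoc, geno, p_max=1e-7)
        members = [mid for l in loci for mid in l.member_ids]
        sig_ids = set(assoc.loc[assoc["p"] <= 1e-7, "marker_id"])
        assert len(members) == len(set(members))
        assert set(members) == sig_ids
        for l in loci:
            assert l.lead_p == min(
                assoc.set_index("marker_id").loc[l.member_ids, "p"])

    def test_no_significant_markers(self):
        assoc = _assoc_frame([0.5, 0.2], [1000, 2000])
        assert cluster_loci(assoc, self._genotypes(True)) == []

    def test_detection_class(self):
        assoc = _assoc_frame([1e-10, 1e-9], [100_000, 110_000],
                             types=["SNP", "SV"])
        loci = cluster_loci(assoc, self._genotypes(True), p_max=1e-7)
        assert loci[0].detection == "both"
        assert loci_to_frame(loci)["detection"].iloc[0] == "both"


class TestCandidateGenes:
    def _loci(self, pos):
        from panpav.gwasloci import Locus
        return [Locus(lead_id="m0", chrom="chr1", lead_pos=pos, lead_p=1e-9)]

    def _genes(self):
        return pd.DataFrame({
            "chrom": ["chr1"] * 3,
            "start": [99_000, 149_000, 151_000],
            "end": [101_000, 150_500, 153_000],
            "strand": "+", "gene_id": ["at_lead", "near", "far"],
        })

    def test_window_rule(self):
        # lead at 100 kb, +-50 kb: gene at lead and gene ending 50.5 kb away
        out = candidate_genes(self._loci(100_000), self._genes(),
                              window=50_000)
        assert set(out["gene_id"]) == {"at_lead", "near"}

    def test_matches_bruteforce(self, rng):
        genes = pd.DataFrame({
            "chrom": "chr1",
            "start": (s := np.sort(rng.integers(0, 900_000, 60))),
            "end": s + rng.integers(500, 5000, 60),
            "strand": "+",
            "gene_id": [f"g{i}" for i in range(60)]})
        lead = 450_000
        out = candidate_genes(self._loci(lead), genes, window=50_000)
        brute = set(genes.loc[(genes["start"] <= lead + 50_000)
                              & (genes["end"] >= lead - 50_000), "gene_id"])
        assert set(out["gene_id"]) == brute


class TestLdComplement:
    def test_identical_sv_and_snp_tagged(self, rng):
        x = rng.binomial(2, 0.5, 50).astype(np.int8)
        sv = np.clip(x, 0, 1).reshape(-1, 1)
        snp = np.column_stack([np.clip(x, 0, 1)])
        res = sv_snp_ld_complement(
            sv, np.array(["chr1"]), np.array([5000]), np.array([5100]),
            snp, np.array(["chr1"]), np.array([10_000]))
        assert res.table["max_r2"].iloc[0] == pytest.approx(1.0)
        assert res.untagged_fraction == 0.0

    def test_no_flanking_snp_untagged(self, rng):
        sv = rng.integers(0, 2, size=(30, 1)).astype(np.int8)
        snp = rng.integers(0, 3, size=(30, 1)).astype(np.int8)
        res = sv_snp_ld_complement(
            sv, np.array(["chr1"]), np.array([5000]), np.array([5100]),
            snp, np.array(["chr1"]), np.array([500_000]))
        assert not res.table["tagged"].iloc[0]
        assert res.untagged_fraction == 1.0

    def test_monomorphic_sv_excluded(self, rng):
        sv = np.hstack([np.zeros((30, 1)), rng.integers(0, 2, (30, 1))]
                       ).astype(np.int8)
        snp = rng.integers(0, 3, size=(30, 2)).astype(np.int8)
        res = sv_snp_ld_complement(
            sv, np.array(["chr1"] * 2), np.array([1000, 2000]),
            np.array([1100, 2100]), snp, np.array(["chr1"] * 2),
            np.array([1500, 2500]))
        assert res.n_monomorphic == 1
        assert len(res.table) == 1

    def test_matches_bruteforce_r2(self, rng):
        n, n_sv, n_snp = 40, 6, 30
        sv = rng.integers(0, 2, size=(n, n_sv)).astype(np.int8)
        snp = rng.integers(0, 3, size=(n, n_snp)).astype(np.int8)
        sv_pos = rng.integers(0, 200_000, n_sv)
        snp_pos = rng.integers(0, 200_000, n_snp)
        res = sv_snp_ld_complement(
            sv, np.array(["chr1"] * n_sv), sv_pos, sv_pos + 100,
            snp, np.array(["chr1"] * n_snp), snp_pos, flank=50_000)
        for _, row in res.table.iterrows():
            j = int(row["sv_id"][2:])
            best = -np.inf
            for k in range(n_snp):
                if not (sv_pos[j] - 50_000 <= snp_pos[k]
                        <= sv_pos[j] + 100 + 50_000):
                    continue
                x, y = sv[:, j].astype(float), snp[:, k].astype(float)
                if x.std() == 0 or y.std() == 0:
                    continue
                best = max(best, np.corrcoef(x, y)[0, 1] ** 2)
            if np.isfinite(best):
                assert row["max_r2"] == pytest.approx(best, abs=1e-12)
            else:
                assert not row["tagged"]

    def test_untagged_fraction_monotonicity(self, rng):
        n, n_sv, n_snp = 50, 15, 60
        sv = rng.integers(0, 2, size=(n, n_sv)).astype(np.int8)
        snp = rng.integers(0, 3, size=(n, n_snp)).astype(np.int8)
        sv_pos = rng.integers(0, 300_000, n_sv)
        snp_pos = rng.integers(0, 300_000, n_snp)
        args = (sv, np.array(["chr1"] * n_sv), sv_pos, sv_pos + 100,
                snp, np.array(["chr1"] * n_snp), snp_pos)
        fr = [sv_snp_ld_complement(*args, flank=f, r2_cut=0.5
                                   ).untagged_fraction
              for f in (10_000, 50_000, 200_000)]
        assert fr[0] >= fr[1] >= fr[2]
        rc = [sv_snp_ld_complement(*args, flank=50_000, r2_cut=c
                                   ).untagged_fraction
              for c in (0.1, 0.5, 0.9)]
        assert rc[0] <= rc[1] <= rc[2]
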