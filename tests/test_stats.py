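import itertools
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix

from adenomet.data_model import SampleMetadata
from adenomet.stats import (
    bh_fdr,
    bonferroni_adjust,
    fisher_exact_rxc,
    fisher_r_to_z_compare,
    permanova,
    permutation_f_test,
    permutation_f_tests,
    spearman,
    spearman_matrix,
    storey_qvalue,
)


def meta_from(groups, sexes=None, ages=None):
    n = len(groups)
    return SampleMetadata(pd.DataFrame({
        "group": groups,
        "age_stratum": ages or ["50-59"] * n,
        "sex": sexes or ["female"] * n,
        "race": ["white"] * n,
        "smoking": ["smoker"] * n,
    }, index=[f"s{i}" for i in range(n)]))


def permanova_oracle_F(d2, labels):
    """One-way pseudo-F computed from within-group squared distances."""
    n = len(labels)
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for g in set(labels):
        idx = [i for i, l in enumerate(labels) if l == g]
        ss_within += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    ss_between = ss_total - ss_within
    a = len(set(labels))
    return (ss_between / (a - 1)) / (ss_within / (n - a))


class TestPermanova:
    def test_duplicated_points_exhaustive_p(self):
        # two groups of duplicated identical points: only the observed split
        # (and its mirror) reaches the maximal F, so the exact p is 2/6
        X = np.array([[0.0, 0.0], [0.0, 0.0], [3.0, 4.0], [3.0, 4.0]])
        d = DistanceMatrix(squareform(pdist(X)), ids=[f"s{i}" for i in range(4)])
        meta = meta_from(["control", "control", "adenoma", "adenoma"])
        res = permanova(d, meta, ["group"], "marginal", n_perm=9999, seed=0)[0]
        assert res.var_explained_pct == pytest.approx(100.0, abs=1e-6)
        assert res.p == pytest.approx(1 / 3, abs=0.02)

    def test_pseudo_F_matches_within_group_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 4))
        labels = ["control"] * 6 + ["adenoma"] * 6
        d = DistanceMatrix(squareform(pdist(X)), ids=[f"s{i}" for i in range(12)])
        res = permanova(d, meta_from(labels), ["group"], "marginal",
                        n_perm=99, seed=1)[0]
        F_oracle = permanova_oracle_F(d.data ** 2, labels)
        assert res.pseudo_F == pytest.approx(F_oracle, rel=1e-10)

    def test_matches_vegan_adonis2(self, tmp_path):
        """Sums of squares and pseudo-F agree with vegan's adonis2 (margin
        and sequential decompositions) on a small random dataset."""
        rng = np.random.default_rng(7)
        n = 30
        Y = rng.normal(size=(n, 5))
        grp = rng.choice(["control", "adenoma"], n)
        sex = rng.choice(["female", "male"], n)
        age = rng.choice(["50-59", "60-69", ">=70"], n)
        np.savetxt(tmp_path / "Y.txt", Y)
        pd.DataFrame({"grp": grp, "sex": sex, "age": age}).to_csv(
            tmp_path / "meta.csv", index=False)
        rout = subprocess.run(
            ["Rscript", "-e", f'''
suppressMessages(library(vegan))
Y <- as.matrix(read.table("{tmp_path}/Y.txt"))
meta <- read.csv("{tmp_path}/meta.csv")
m <- adonis2(dist(Y) ~ grp + age + sex, data=meta, by="margin", permutations=9)
s <- adonis2(dist(Y) ~ grp + age + sex, data=meta, by="terms", permutations=9)
cat(m$SumOfSqs[1:3], m$F[1:3], s$SumOfSqs[1:3], s$F[1:3], sep="\\n")
'''],
            capture_output=True, text=True, timeout=120)
        assert rout.returncode == 0, rout.stderr
        ref = np.array([float(x) for x in rout.stdout.split()])
        meta = meta_from(list(grp), list(sex), list(age))
        d = DistanceMatrix(squareform(pdist(Y)), ids=meta.sample_ids)
        adj = permanova(d, meta, ["group", "age_stratum", "sex"], "adjusted",
                        n_perm=99, seed=0)
        seq = permanova(d, meta, ["group", "age_stratum", "sex"], "sequential",
                        n_perm=99, seed=0)
        np.testing.assert_allclose([r.ss for r in adj], ref[0:3], rtol=1e-6)
        np.testing.assert_allclose([r.pseudo_F for r in adj], ref[3:6], rtol=1e-6)
        np.testing.assert_allclose([r.ss for r in seq], ref[6:9], rtol=1e-6)
        np.testing.assert_allclose([r.pseudo_F for r in seq], ref[9:12], rtol=1e-6)

    def test_adjusted_ss_order_invariant(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(24, 3))
        grp = list(rng.choice(["control", "adenoma"], 24))
        sex = list(rng.choice(["female", "male"], 24))
        meta = meta_from(grp, sex)
        d = DistanceMatrix(squareform(pdist(X)), ids=meta.sample_ids)
        a = permanova(d, meta, ["group", "sex"], "adjusted", 99, 0)
        b = permanova(d, meta, ["sex", "group"], "adjusted", 99, 0)
        ss_a = {r.factor: r.ss for r in a}
        ss_b = {r.factor: r.ss for r in b}
        for f in ss_a:
            assert ss_a[f] == pytest.approx(ss_b[f], rel=1e-10)

    def test_sequential_ss_sums_to_total(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 3))
        grp = list(rng.choice(["control", "adenoma"], 20))
        sex = list(rng.choice(["female", "male"], 20))
        meta = meta_from(grp, sex)
        d = DistanceMatrix(squareform(pdist(X)), ids=meta.sample_ids)
        res = permanova(d, meta, ["group", "sex"], "sequential", 99, 0)
        from adenomet.stats import gower_center
        ss_total = np.trace(gower_center(d.data))
        r2_sum = sum(r.var_explained_pct for r in res)
        # residual share completes the decomposition
        assert r2_sum < 100
        ss_terms = sum(r.ss for r in res)
        assert ss_terms <= ss_total + 1e-9

    def test_single_level_factor_rejected(self):
        X = np.eye(4)
        meta = meta_from(["control"] * 4)
        d = DistanceMatrix(squareform(pdist(X)), ids=meta.sample_ids)
        with pytest.raises(ValueError, match="fewer than two"):
            permanova(d, meta, ["group"], "marginal", 99, 0)

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(16, 3))
        meta = meta_from(list(rng.choice(["control", "adenoma"], 16)))
        d = DistanceMatrix(squareform(pdist(X)), ids=meta.sample_ids)
        p1 = permanova(d, meta, ["group"], "marginal", 199, 42)[0].p
        p2 = permanova(d, meta, ["group"], "marginal", 199, 42)[0].p
        assert p1 == p2


class TestPermutationFTest:
    def test_equals_two_sample_permutation_t_test(self):
        """With no covariates and raw-label permutation, the partial F is t^2
        and the p-value matches a hand-rolled permutation t-test sharing the
        same permutation stream."""
        rng = np.random.default_rng(5)
        n = 16
        y = rng.normal(size=n) + np.r_[np.zeros(8), 0.8 * np.ones(8)]
        groups = ["control"] * 8 + ["adenoma"] * 8
        B, seed = 499, 9
        res = permutation_f_test(y, meta_from(groups), "group", [],
                                 n_perm=B, seed=seed, scheme="raw_label")

        def t2(yv):
            a, b = yv[:8], yv[8:]
            sp = ((a.var(ddof=1) * 7 + b.var(ddof=1) * 7) / 14)
            return (a.mean() - b.mean()) ** 2 / (sp * (1 / 8 + 1 / 8))

        t2_obs = t2(y)
        assert res.F_obs == pytest.approx(t2_obs, rel=1e-10)
        rng2 = np.random.default_rng(seed)
        exceed = sum(t2(y[rng2.permutation(n)]) >= t2_obs - 1e-12
                     for _ in range(B))
        assert res.p == pytest.approx((1 + exceed) / (1 + B))

    def test_perfect_separation_minimum_p(self):
        n, B = 20, 499
        y = np.r_[np.linspace(0, 0.1, 10), np.linspace(5, 5.1, 10)]
        groups = ["control"] * 10 + ["adenoma"] * 10
        res = permutation_f_test(y, meta_from(groups), "group", [],
                                 n_perm=B, seed=3)
        assert res.p == pytest.approx(1 / (1 + B))

    def test_type_I_error_near_nominal(self):
        """Null simulation: rejection rate at alpha=0.05 stays within a wide
        binomial interval (the full-scale calibration lives in the
        acceptance suite)."""
        rng = np.random.default_rng(6)
        n, B, sims = 30, 199, 200
        groups = list(rng.choice(["control", "adenoma"], n))
        sexes = list(rng.choice(["female", "male"], n))
        meta = meta_from(groups, sexes)
        Y = rng.normal(size=(n, sims))
        res = permutation_f_tests(Y, meta, "group", ["sex"], n_perm=B, seed=7)
        rate = np.mean([r.p <= 0.05 for r in res])
        lo, hi = sps.binom.ppf([0.005, 0.995], sims, 0.05) / sims
        assert lo - 1e-9 <= rate <= hi + 1e-9

    def test_direction_tracks_group_difference(self):
        rng = np.random.default_rng(8)
        n = 40
        groups = ["control"] * 20 + ["adenoma"] * 20
        up = rng.normal(size=n) + np.r_[np.zeros(20), np.ones(20)]
        down = rng.normal(size=n) - np.r_[np.zeros(20), np.ones(20)]
        res = permutation_f_tests(np.column_stack([up, down]),
                                  meta_from(groups), "group", [],
                                  n_perm=99, seed=0)
        assert res[0].direction == 1 and res[1].direction == -1
        assert res[0].group_means["adenoma"] > res[0].group_means["control"]

    def test_collinear_design_rejected(self):
        # race aliased with group in this layout
        meta = SampleMetadata(pd.DataFrame({
            "group": ["control"] * 4 + ["adenoma"] * 4,
            "age_stratum": ["50-59"] * 8,
            "sex": ["female", "male"] * 4,
            "race": ["white"] * 4 + ["black"] * 4,
            "smoking": ["smoker"] * 8,
        }, index=[f"s{i}" for i in range(8)]))
        y = np.arange(8.0)
        with pytest.raises(ValueError, match="collinear"):
            permutation_f_test(y, meta, "group", ["race"], n_perm=99, seed=0)

    def test_schemes_agree_under_exchangeability(self):
        rng = np.random.default_rng(10)
        n = 30
        groups = list(rng.choice(["control", "adenoma"], n))
        sexes = list(rng.choice(["female", "male"], n))
        meta = meta_from(groups, sexes)
        y = rng.normal(size=n)
        p_fl = permutation_f_test(y, meta, "group", ["sex"], 999, 1,
                                  "freedman_lane").p
        p_raw = permutation_f_test(y, meta, "group", ["sex"], 999, 1,
                                   "raw_label").p
        assert abs(p_fl - p_raw) < 0.12


class TestMultipleTesting:
    def test_all_p_one(self):
        res = storey_qvalue(np.ones(50))
        assert res.pi0 == 1.0
        np.testing.assert_allclose(res.q, 1.0)

    def test_storey_with_pi0_one_equals_bh(self):
        rng = np.random.default_rng(11)
        p = rng.random(200)
        res = storey_qvalue(p, pi0=1.0)
        from statsmodels.stats.multitest import multipletests
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(res.q, q_ref, atol=1e-12)

    def test_pi0_estimate_on_mixture(self):
        rng = np.random.default_rng(12)
        m = 2000
        null = rng.random(int(m * 0.8))
        alt = rng.beta(0.1, 1.0, m - len(null))
        res = storey_qvalue(np.r_[null, alt])
        assert res.pi0 == pytest.approx(0.8, abs=0.1)

    def test_small_m_falls_back_to_pi0_one(self):
        with pytest.warns(UserWarning, match="fewer than 10"):
            res = storey_qvalue(np.array([0.1, 0.5, 0.9]))
        assert res.pi0 == 1.0

    def test_bh_examples_and_monotonicity(self):
        res = bh_fdr(np.array([0.01, 0.02, 0.03]))
        np.testing.assert_allclose(res.q, [0.03, 0.03, 0.03])
        single = bh_fdr(np.array([0.37]))
        assert single.q[0] == pytest.approx(0.37)
        rng = np.random.default_rng(13)
        p = rng.random(100)
        q = bh_fdr(p).q
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_bonferroni(self):
        res = bonferroni_adjust(np.array([0.001]), m=100)
        assert res.q[0] == pytest.approx(0.1)
        res = bonferroni_adjust(np.array([0.5]), m=3)
        assert res.q[0] == 1.0
        big = bonferroni_adjust(np.full(10, 1e-6), m=31878)
        np.testing.assert_allclose(big.q, 31878e-6)

    def test_storey_q_below_bonferroni_q(self):
        rng = np.random.default_rng(14)
        p = rng.random(80)
        qs = storey_qvalue(p).q
        qb = bonferroni_adjust(p).q
        assert (qs <= qb + 1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            storey_qvalue(np.array([0.5, 1.5] + [0.2] * 10))


class TestFisherExact:
    def test_two_by_two_diagonal(self):
        res = fisher_exact_rxc(np.array([[2, 0], [0, 2]]))
        assert res.p == pytest.approx(1 / 3, abs=1e-12)
        assert not res.monte_carlo

    def test_equal_rows_p_one(self):
        res = fisher_exact_rxc(np.array([[5, 3, 2], [5, 3, 2]]))
        assert res.p == pytest.approx(1.0)

    def test_matches_scipy_on_random_2x2(self):
        rng = np.random.default_rng(15)
        for _ in range(100):
            t = rng.integers(1, 12, size=(2, 2))
            mine = fisher_exact_rxc(t).p
            ref = sps.fisher_exact(t)[1]
            assert mine == pytest.approx(ref, rel=1e-9, abs=1e-12)

    def test_monte_carlo_fallback(self):
        t = np.array([[8, 3, 5], [2, 9, 4], [6, 2, 7]])
        exact = fisher_exact_rxc(t)
        mc = fisher_exact_rxc(t, max_tables=10, n_mc=40000, seed=1)
        assert mc.monte_carlo and not exact.monte_carlo
        assert mc.p == pytest.approx(exact.p, abs=0.02)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margins"):
            fisher_exact_rxc(np.array([[0, 0], [1, 2]]))


class TestCorrelations:
    def test_spearman_signs(self):
        assert spearman([1, 2, 3], [3, 2, 1]).rho == pytest.approx(-1.0)
        assert spearman([1, 2, 3, 4], [1, 8, 27, 64]).rho == pytest.approx(1.0)

    def test_exact_permutation_matches_enumeration(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 3.0])
        res = spearman(x, y, exact=True)
        rho_obs = abs(sps.spearmanr(x, y)[0])
        hits = sum(
            abs(sps.spearmanr(x, y[list(p)])[0]) >= rho_obs - 1e-12
            for p in itertools.permutations(range(4)))
        assert res.p == pytest.approx(hits / 24)

    def test_zero_variance_flagged(self):
        res = spearman([1, 1, 1], [1, 2, 3])
        assert np.isnan(res.rho)

    def test_spearman_matrix_matches_pairwise(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(20, 3))
        Y = rng.normal(size=(20, 4))
        rho, p = spearman_matrix(X, Y)
        for i in range(3):
            for j in range(4):
                r_ref, p_ref = sps.spearmanr(X[:, i], Y[:, j])
                assert rho[i, j] == pytest.approx(r_ref, abs=1e-12)
                assert p[i, j] == pytest.approx(p_ref, rel=1e-9)

    def test_fisher_r_to_z(self):
        res = fisher_r_to_z_compare(0.5, 50, 0.5, 500)
        assert res.z == 0 and res.p == pytest.approx(1.0)
        a = fisher_r_to_z_compare(0.7, 40, 0.2, 60)
        b = fisher_r_to_z_compare(0.2, 60, 0.7, 40)
        assert a.z == pytest.approx(-b.z)
        assert a.p == pytest.approx(b.p)
        with pytest.raises(ValueError):
            fisher_r_to_z_compare(1.0, 50, 0.5, 50)
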