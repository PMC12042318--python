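import math
import subprocess
import tempfile

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from omicweaver.io_core import ExpressionMatrix, SampleTable, ValidationError
from omicweaver.diffexpr import (
    DesignSpec, bh_adjust, fit_fdist, fit_moderated_linear_model,
    median_ratio_size_factors, nb_wald_test, rna_protein_concordance, rrho_map,
)


def bh_bruteforce(p):
    """Independent oracle: fdr_i = min_{j >= rank(i)} m * p_(j) / j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    out = np.empty(m)
    for rank0, i in enumerate(order):
        candidates = [m * p[order[j]] / (j + 1) for j in range(rank0, m)]
        out[i] = min(1.0, min(candidates))
    return out


class TestBHAdjust:
    def test_hand_stepped_example(self):
        # ranks 1..4 give 0.04, 0.04, 0.04, 0.04 after monotonicity
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])),
            [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.3]))[0] == pytest.approx(0.3)

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(2, 50))
            np.testing.assert_allclose(bh_adjust(p), bh_bruteforce(p), atol=1e-10)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=30),
           st.randoms(use_true_random=False))
    def test_permutation_invariant(self, ps, rnd):
        p = np.array(ps)
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        direct = bh_adjust(p)
        permuted = bh_adjust(p[perm])
        back = np.empty_like(permuted)
        back[perm] = permuted
        np.testing.assert_allclose(direct, back, atol=1e-12)

    def test_missing_propagate(self):
        out = bh_adjust(np.array([0.01, np.nan, 0.5]))
        assert np.isnan(out[1]) and np.isfinite(out[0])


class TestSizeFactors:
    def _counts(self, vals):
        vals = np.asarray(vals, float)
        return ExpressionMatrix([f"g{i}" for i in range(vals.shape[0])],
                                [f"s{j}" for j in range(vals.shape[1])],
                                vals, "rna_counts")

    def test_hand_evaluated_two_sample_doubling(self):
        # col2 = 2 x col1 for every feature: geomean_g = K_g1 * sqrt(2),
        # ratios (1/sqrt2, sqrt2) for all features -> factors exactly those
        m = self._counts([[10, 20], [4, 8], [7, 14]])
        s = median_ratio_size_factors(m)
        np.testing.assert_allclose(s, [1 / math.sqrt(2), math.sqrt(2)], rtol=1e-12)
        assert s[1] / s[0] == pytest.approx(2.0)

    def test_identical_columns_give_unit_factors(self):
        m = self._counts([[5, 5, 5], [9, 9, 9]])
        np.testing.assert_allclose(median_ratio_size_factors(m), [1, 1, 1])

    def test_scaling_one_column_scales_its_factor(self):
        base = np.array([[10.0, 12, 9], [100, 90, 110], [5, 6, 7]])
        s0 = median_ratio_size_factors(self._counts(base))
        scaled = base.copy()
        scaled[:, 1] *= 10
        s1 = median_ratio_size_factors(self._counts(scaled))
        assert s1[1] / s0[1] == pytest.approx(10.0 * (s1[0] / s0[0]))

    def test_no_allpositive_feature_errors(self):
        with pytest.raises(ValidationError):
            median_ratio_size_factors(self._counts([[0, 5], [5, 0]]))


def _protein_fixture(G=80, n=16, seed=0, effect=0.0):
    rng = np.random.default_rng(seed)
    Y = rng.normal(7, 1, (G, n)) * rng.uniform(0.6, 1.4, G)[:, None]
    dx = np.array(["CON"] * (n // 2) + ["PTSD"] * (n // 2))
    Y[:, dx == "PTSD"] += effect
    s = SampleTable(pd.DataFrame(dict(
        sample_id=[f"S{j}" for j in range(n)], donor_id=[f"D{j}" for j in range(n)],
        dx=dx, region="DLPFC", sex=rng.choice(["M", "F"], n),
        age=rng.uniform(30, 70, n).round(1), ancestry="EUR",
        pmi=rng.uniform(10, 30, n), rin=rng.uniform(6, 9, n))))
    m = ExpressionMatrix([f"P{i}" for i in range(G)], s.sample_ids, Y,
                         "protein_log_intensity")
    return m, s


class TestModeratedLinearModel:
    def test_d0_zero_recovers_ordinary_ols_t(self):
        m, s = _protein_fixture()
        spec = DesignSpec(case="PTSD", covariates=("age", "sex"))
        tab, _ = fit_moderated_linear_model(m, s, spec, d0_override=0.0)
        # independent OLS per feature
        X, names = spec.build(s)
        j = names.index("dx")
        XtXi = np.linalg.inv(X.T @ X)
        for g in [0, 5, 33]:
            b = XtXi @ X.T @ m.values[g]
            r = m.values[g] - X @ b
            s2 = (r @ r) / (len(r) - X.shape[1])
            t_ols = b[j] / np.sqrt(s2 * XtXi[j, j])
            assert tab["statistic"][g] == pytest.approx(t_ols, abs=1e-10)

    def test_d0_infinite_shrinks_all_variances_to_prior(self):
        m, s = _protein_fixture()
        spec = DesignSpec(case="PTSD", covariates=("age", "sex"))
        tab, prior = fit_moderated_linear_model(m, s, spec, d0_override=np.inf)
        X, names = spec.build(s)
        j = names.index("dx")
        XtXi = np.linalg.inv(X.T @ X)
        # statistic must equal beta / (s0 * sqrt(v)) exactly
        b = np.linalg.lstsq(X, m.values.T, rcond=None)[0][j]
        expected = b / (np.sqrt(prior.s0_sq * XtXi[j, j]))
        np.testing.assert_allclose(tab["statistic"], expected, atol=1e-6)

    def test_matches_limma_on_shared_fixture(self, tmp_path):
        """Independent oracle: Bioconductor limma on the identical design."""
        m, s = _protein_fixture(G=60, n=16, seed=42)
        spec = DesignSpec(case="PTSD", covariates=("age", "sex"))
        tab, prior = fit_moderated_linear_model(m, s, spec)
        ydf = m.to_frame()
        ydf.to_csv(tmp_path / "y.csv")
        df = s.frame
        pd.DataFrame(dict(dx=(df["dx"] == "PTSD").astype(int), age=df["age"],
                          sex=(df["sex"] == "M").astype(int))
                     ).to_csv(tmp_path / "design.csv", index=False)
        script = f'''
suppressMessages(library(limma))
y <- as.matrix(read.csv("{tmp_path}/y.csv", row.names=1))
des <- read.csv("{tmp_path}/design.csv")
X <- model.matrix(~ dx + age + sex, des)
fit <- eBayes(lmFit(y, X))
write.csv(data.frame(t=fit$t[,"dx"], p=fit$p.value[,"dx"],
                     d0=fit$df.prior, s02=fit$s2.prior),
          "{tmp_path}/limma.csv")
'''
        res = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
        assert res.returncode == 0, res.stderr
        lim = pd.read_csv(tmp_path / "limma.csv", index_col=0)
        assert prior.d0 == pytest.approx(lim["d0"].iloc[0], rel=1e-6)
        assert prior.s0_sq == pytest.approx(lim["s02"].iloc[0], rel=1e-6)
        np.testing.assert_allclose(tab["statistic"], lim["t"], atol=1e-8)
        np.testing.assert_allclose(tab["p"], lim["p"], atol=1e-10)

    def test_log2fc_equals_group_mean_difference_on_balanced_design(self):
        # covariates orthogonal to dx: log2FC = log2(10) * (mean_case - mean_con)
        rng = np.random.default_rng(3)
        n = 20
        dx = np.array(["CON"] * 10 + ["PTSD"] * 10)
        age = np.tile(rng.uniform(30, 70, 10), 2)  # identical across groups
        Y = rng.normal(7, 1, (30, n))
        s = SampleTable(pd.DataFrame(dict(
            sample_id=[f"S{j}" for j in range(n)], donor_id=[f"D{j}" for j in range(n)],
            dx=dx, region="DLPFC", sex="M", age=age, ancestry="EUR",
            pmi=20.0, rin=7.0)))
        m = ExpressionMatrix([f"P{i}" for i in range(30)], s.sample_ids, Y,
                             "protein_log_intensity")
        tab, _ = fit_moderated_linear_model(m, s, DesignSpec("PTSD", ("age",)))
        diff = (Y[:, 10:].mean(axis=1) - Y[:, :10].mean(axis=1)) * np.log2(10)
        np.testing.assert_allclose(tab["log2fc"], diff, atol=1e-9)

    def test_rank_deficient_design_names_columns(self):
        m, s = _protein_fixture(G=5)
        s.frame["pmi"] = s.frame["age"] * 2.0
        with pytest.raises(ValidationError, match="collinear"):
            fit_moderated_linear_model(m, s, DesignSpec("PTSD", ("age", "pmi")))

    def test_features_with_too_few_complete_cases_flagged_untested(self):
        m, s = _protein_fixture(G=10)
        m.values[0, :-2] = np.nan
        m.missing_mask = np.isnan(m.values)
        tab, _ = fit_moderated_linear_model(m, s, DesignSpec("PTSD", ("age",)))
        assert not tab["tested"][0]
        assert np.isnan(tab["p"][0])
        assert tab["tested"][1:].all()


class TestFitFdist:
    def test_recovers_prior_from_scaled_inv_chisq(self):
        # s2_g ~ s0^2 * d0 / chi2_d0 truth, observed through chi2_dg sampling
        rng = np.random.default_rng(1)
        d0, s0_sq, dg, G = 4.0, 2.0, 25, 3000
        d0_hat, s0_hat = [], []
        for rep in range(8):
            sigma2 = s0_sq * d0 / rng.chisquare(d0, G)
            s2 = sigma2 * rng.chisquare(dg, G) / dg
            prior = fit_fdist(s2, np.full(G, float(dg)))
            d0_hat.append(prior.d0)
            s0_hat.append(prior.s0_sq)
        assert abs(np.median(d0_hat) - d0) / d0 < 0.25
        assert abs(np.median(s0_hat) - s0_sq) / s0_sq < 0.10

    def test_homoscedastic_variances_give_infinite_d0(self):
        # spread narrower than chi2 sampling alone -> d0 = inf branch
        s2 = np.full(200, 1.7)
        prior = fit_fdist(s2, np.full(200, 10.0))
        assert np.isinf(prior.d0)


class TestNBWald:
    def test_poisson_limit_matches_poisson_glm(self):
        """At alpha -> 0 and large mu the NB Wald z agrees with a Poisson GLM."""
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        n = 40
        dx = np.array(["CON"] * 20 + ["PTSD"] * 20)
        Y = rng.poisson(1000, (30, n)).astype(float)
        s = SampleTable(pd.DataFrame(dict(
            sample_id=[f"S{j}" for j in range(n)], donor_id=[f"D{j}" for j in range(n)],
            dx=dx, region="DLPFC", sex="M", age=50.0, ancestry="EUR",
            pmi=20.0, rin=7.0)))
        m = ExpressionMatrix([f"g{i}" for i in range(30)], s.sample_ids, Y, "rna_counts")
        tab = nb_wald_test(m, s, DesignSpec("PTSD", ()), size_factors=np.ones(n),
                           dispersion=1e-8)
        X = np.column_stack([np.ones(n), (dx == "PTSD").astype(float)])
        for g in [0, 7, 19]:
            fit = sm.GLM(Y[g], X, family=sm.families.Poisson()).fit()
            z_pois = fit.params[1] / fit.bse[1]
            assert tab["statistic"][g] == pytest.approx(z_pois, rel=0.02)

    def test_planted_fold_change_recovered_with_power(self):
        rng = np.random.default_rng(5)
        G, n = 400, 40
        dx = np.array(["CON"] * 20 + ["PTSD"] * 20)
        mu = np.full((G, n), 100.0)
        mu[:, 20:] *= 2.0  # log2fc = 1
        size = 1 / 0.1
        Y = rng.negative_binomial(size, size / (size + mu)).astype(float)
        s = SampleTable(pd.DataFrame(dict(
            sample_id=[f"S{j}" for j in range(n)], donor_id=[f"D{j}" for j in range(n)],
            dx=dx, region="DLPFC", sex="M", age=50.0, ancestry="EUR",
            pmi=20.0, rin=7.0)))
        m = ExpressionMatrix([f"g{i}" for i in range(G)], s.sample_ids, Y, "rna_counts")
        tab = nb_wald_test(m, s, DesignSpec("PTSD", ()), size_factors=np.ones(n))
        assert np.mean(tab["p"] < 0.05) >= 0.8
        assert np.median(tab["log2fc"]) == pytest.approx(1.0, abs=0.15)

    def test_non_count_modality_rejected(self):
        m, s = _protein_fixture(G=5)
        with pytest.raises(ValidationError):
            nb_wald_test(m, s, DesignSpec("PTSD", ()))


def hypergeom_tail_bruteforce(k, N, K, n):
    """P(X >= k) for overlap of a fixed n-set with a K-set in universe N."""
    total = math.comb(N, n)
    acc = 0
    for x in range(k, min(K, n) + 1):
        acc += math.comb(K, x) * math.comb(N - K, n - x)
    return acc / total


def _de_table(features, scores, seed=0):
    """DE table whose signed rank score -log10(p)*sign(lfc) equals `scores`."""
    scores = np.asarray(scores, float)
    p = 10.0 ** (-np.abs(scores))
    lfc = np.sign(scores) + 0.0
    lfc[lfc == 0] = 1e-9
    return pd.DataFrame(dict(feature_id=features, log2fc=lfc, p=p))


class TestRRHO:
    def test_self_comparison_peaks_on_concordant_quadrants(self):
        rng = np.random.default_rng(6)
        feats = [f"f{i}" for i in range(200)]
        scores = rng.normal(0, 2, 200)
        a = _de_table(feats, scores)
        rmap = rrho_map(a, a, step=10)
        uu = rmap.grid[rmap.quadrants["uu"]]
        ud = rmap.grid[rmap.quadrants["ud"]]
        assert uu.max() > 10
        assert np.all(ud <= 0)  # discordant quadrants carry the negative sign

    def test_tail_probability_matches_enumeration(self):
        # the map's hypergeometric upper tail equals combinatorial enumeration
        N = 18
        rng = np.random.default_rng(7)
        feats = [f"f{i}" for i in range(N)]
        a = _de_table(feats, rng.normal(0, 2, N))
        b = _de_table(feats, rng.normal(0, 2, N))
        rmap = rrho_map(a, b, step=3)
        sa = rmap.score_a
        sb = rmap.score_b
        for ii, i in enumerate(rmap.steps_a):
            top_a = set(sa.index[:i])
            for jj, j in enumerate(rmap.steps_b):
                top_b = set(sb.index[:j])
                k = len(top_a & top_b)
                expect = hypergeom_tail_bruteforce(k, N, i, j)
                got = 10 ** (-abs(rmap.grid[ii, jj]))
                assert got == pytest.approx(expect, abs=1e-10)

    def test_transpose_symmetry(self):
        rng = np.random.default_rng(8)
        feats = [f"f{i}" for i in range(60)]
        a = _de_table(feats, rng.normal(0, 2, 60))
        b = _de_table(feats, rng.normal(0, 2, 60))
        ab = rrho_map(a, b, step=6)
        ba = rrho_map(b, a, step=6)
        np.testing.assert_allclose(np.abs(ab.grid), np.abs(ba.grid.T), atol=1e-10)

    def test_independent_permutations_score_below_self(self):
        rng = np.random.default_rng(9)
        feats = [f"f{i}" for i in range(300)]
        scores = rng.normal(0, 2, 300)
        self_max = rrho_map(_de_table(feats, scores), _de_table(feats, scores)).grid.max()
        below = 0
        for s in range(10):
            r2 = np.random.default_rng(100 + s).permutation(scores)
            m = rrho_map(_de_table(feats, scores), _de_table(feats, r2))
            below += m.grid.max() < self_max
        assert below >= 9

    def test_too_few_common_features_errors(self):
        a = _de_table(["x", "y"], [1, -1])
        with pytest.raises(ValidationError):
            rrho_map(a, a)


class TestConcordance:
    def _tab(self, ids, lfc, p):
        return pd.DataFrame(dict(feature_id=ids, log2fc=lfc, p=p))

    def test_identical_tables_full_concordance(self):
        ids = [f"g{i}" for i in range(10)]
        pids = [f"p{i}" for i in range(10)]
        lfc = np.linspace(-2, 2, 10)
        lfc[lfc == 0] = 0.1
        rna = self._tab(ids, lfc, [0.01] * 10)
        prot = self._tab(pids, lfc, [0.01] * 10)
        table, summ = rna_protein_concordance(rna, prot, dict(zip(ids, pids)))
        assert summ["concordance"] == 1.0
        assert summ["slope"] == pytest.approx(1.0)
        assert summ["r"] == pytest.approx(1.0)

    def test_sign_flip_gives_zero_concordance(self):
        ids = [f"g{i}" for i in range(10)]
        pids = [f"p{i}" for i in range(10)]
        lfc = np.linspace(-2, 2, 10)
        lfc[np.abs(lfc) < 1e-9] = 0.1
        rna = self._tab(ids, lfc, [0.01] * 10)
        prot = self._tab(pids, -lfc, [0.01] * 10)
        _, summ = rna_protein_concordance(rna, prot, dict(zip(ids, pids)))
        assert summ["concordance"] == 0.0
        assert summ["r"] == pytest.approx(-1.0)

    def test_no_pairs_flagged_undefined(self):
        rna = self._tab(["g1"], [1.0], [0.9])
        prot = self._tab(["p1"], [1.0], [0.9])
        table, summ = rna_protein_concordance(rna, prot, {"g1": "p1"})
        assert len(table) == 0 and not summ["defined"]
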