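import numpy as np
import pandas as pd
import pytest
from scipy import stats

from irisquant.genetics import (
    CovariateTable,
    GenotypeMatrix,
    PredictionModelSpec,
    ancestry_informativeness,
    combined_association,
    cross_validated_r2,
    fit_prediction_model,
    hwe_exact_test,
    interaction_scan,
    interaction_test,
    ld_r2,
    snp_association,
    snp_summary,
)

from conftest import hwe_enumeration_oracle


def random_cov(n, seed=0, k_pop=3):
    rng = np.random.default_rng(seed)
    return CovariateTable(
        age=rng.uniform(65, 85, n),
        sex=rng.binomial(1, 0.5, n).astype(float),
        population=np.asarray([f"pop{i}" for i in rng.integers(0, k_pop, n)], dtype=object),
    )


class TestHWE:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(40, 0, 0) == 1.0
        assert hwe_exact_test(0, 0, 25) == 1.0

    def test_matches_enumeration_oracle_small_totals(self):
        for n in (5, 12, 23, 37, 50):
            for n_aa in range(0, n + 1, max(1, n // 5)):
                for n_het in range(0, n - n_aa + 1, max(1, n // 5)):
                    n_AA = n - n_aa - n_het
                    got = hwe_exact_test(n_AA, n_het, n_aa)
                    want = hwe_enumeration_oracle(n_AA, n_het, n_aa)
                    assert got == pytest.approx(want, abs=1e-12), (n_AA, n_het, n_aa)

    def test_perfect_hwe_attains_max_p(self):
        # with 100 of each allele, (25, 50, 25) is the perfect-HWE configuration;
        # no other heterozygote count attains a larger exact p
        p_obs = hwe_exact_test(25, 50, 25)
        for h in range(0, 101, 2):
            a = (100 - h) // 2
            assert hwe_exact_test(100 - h - a, h, a) <= p_obs + 1e-12

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)


class TestLD:
    def test_identical_vectors(self):
        g = np.array([0, 1, 2, 1, 0, 2, 1], dtype=float)
        assert ld_r2(g, g) == pytest.approx(1.0)

    def test_perfect_negative_dosage(self):
        g = np.array([0, 1, 2, 1, 0], dtype=float)
        assert ld_r2(g, 2 - g) == pytest.approx(1.0)

    def test_independent_snps_near_zero(self):
        rng = np.random.default_rng(11)
        a = rng.binomial(2, 0.3, 10_000).astype(float)
        b = rng.binomial(2, 0.3, 10_000).astype(float)
        assert ld_r2(a, b) < 0.01

    def test_constant_vector_undefined(self):
        with pytest.warns(UserWarning):
            assert np.isnan(ld_r2(np.zeros(10), np.arange(10.0)))


class TestAncestryInformativeness:
    def test_identical_frequencies_zero(self):
        g = np.array([0, 1, 2, 0, 1, 2], dtype=float)
        pop = np.asarray(["a", "a", "a", "b", "b", "b"], dtype=object)
        assert ancestry_informativeness(g, pop) == pytest.approx(0.0, abs=1e-12)

    def test_fixed_alternate_alleles_ln2(self):
        g = np.array([0, 0, 0, 2, 2, 2], dtype=float)
        pop = np.asarray(["a"] * 3 + ["b"] * 3, dtype=object)
        assert ancestry_informativeness(g, pop) == pytest.approx(np.log(2), abs=1e-12)

    def test_matches_formula_oracle_three_pops(self):
        rng = np.random.default_rng(4)
        pops = np.asarray([f"p{i}" for i in rng.integers(0, 3, 600)], dtype=object)
        freqs = {"p0": 0.1, "p1": 0.5, "p2": 0.8}
        g = np.array([rng.binomial(2, freqs[p]) for p in pops], dtype=float)
        # brute-force evaluation of the informativeness formula
        emp = [g[pops == f"p{i}"].mean() / 2 for i in range(3)]
        want = 0.0
        for pv in (np.array(emp), 1 - np.array(emp)):
            pbar = pv.mean()
            want += -(pbar * np.log(pbar)) + np.mean(pv * np.log(pv))
        assert ancestry_informativeness(g, pops) == pytest.approx(want, abs=1e-12)

    def test_single_population_rejected(self):
        with pytest.raises(ValueError):
            ancestry_informativeness(np.array([0.0, 1, 2]), np.asarray(["a"] * 3, dtype=object))


class TestSNPAssociation:
    def test_identity_association(self):
        rng = np.random.default_rng(0)
        g = rng.binomial(2, 0.4, 200).astype(float)
        res = snp_association(g, g.copy(), cov=None)
        assert res.r2 == pytest.approx(100.0)
        assert res.p <= np.finfo(float).tiny * 10

    def test_null_r2_small_and_p_uniform(self):
        pvals = []
        for seed in range(300):
            rng = np.random.default_rng(seed)
            g = rng.binomial(2, 0.3, 500).astype(float)
            y = rng.normal(size=500)
            res = snp_association(g, y, cov=None)
            pvals.append(res.p)
            assert res.r2 < 5.0
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_planned_variance_recovered(self):
        rng = np.random.default_rng(5)
        n = 3000
        cov = random_cov(n, seed=1005)  # distinct stream from the genotype draws
        g = rng.binomial(2, 0.3, n).astype(float)
        beta = 1.0
        var_g = beta**2 * g.var()
        noise = np.sqrt(var_g)  # 50% genetic variance after covariates
        y = beta * g + 0.02 * cov.age + 0.2 * cov.sex + noise * rng.standard_normal(n)
        res = snp_association(g, y, cov, snp_id="g")
        assert res.r2 == pytest.approx(50.0, abs=3.0)
        assert res.beta == pytest.approx(beta, abs=0.1)

    def test_partial_r2_matches_regression_t_statistic(self):
        """Squared partial correlation equals t^2/(t^2+df) from the full
        regression containing the same covariates (direct-fit oracle)."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 400
            cov = random_cov(n, seed=seed)
            g = rng.binomial(2, 0.35, n).astype(float)
            y = 0.3 * g + 0.01 * cov.age + rng.standard_normal(n)
            res = snp_association(g, y, cov, snp_id="g")
            Z, _ = cov.design()
            X = np.column_stack([np.ones(n), Z, g])
            beta, res_ss, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            dof = n - X.shape[1]
            sigma2 = resid @ resid / dof
            se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[-1, -1])
            t = beta[-1] / se
            partial_r2 = t**2 / (t**2 + dof)
            assert res.r2 / 100 == pytest.approx(partial_r2, abs=1e-10)

    def test_collinear_covariates_rejected(self):
        n = 100
        cov = CovariateTable(
            age=np.full(n, 70.0),  # constant age collinear with intercept... not quite
            sex=np.ones(n),        # constant sex IS collinear with intercept
            population=np.asarray(["a"] * n, dtype=object),
        )
        g = np.random.default_rng(0).binomial(2, 0.5, n).astype(float)
        with pytest.raises(ValueError, match="rank deficient"):
            snp_association(g, g + 1.0, cov)


class TestCombinedAssociation:
    def test_single_snp_matches_marginal(self):
        rng = np.random.default_rng(2)
        n = 500
        cov = random_cov(n, seed=2)
        g = rng.binomial(2, 0.3, n).astype(float)
        y = 0.5 * g + rng.standard_normal(n)
        G = GenotypeMatrix(g[:, None], ("snp1",))
        df, adj = combined_association(G, y, cov)
        single = snp_association(g, y, cov, snp_id="snp1")
        assert df.iloc[0]["beta"] == pytest.approx(single.beta, abs=1e-10)
        assert df.iloc[0]["t_p"] == pytest.approx(single.p, rel=1e-6)

    def test_two_causal_snps_additive_r2(self):
        rng = np.random.default_rng(3)
        n = 4000
        g1 = rng.binomial(2, 0.3, n).astype(float)
        g2 = rng.binomial(2, 0.4, n).astype(float)
        # each SNP plans 10% of total variance
        b1 = 1.0
        b2 = b1 * g1.std() / g2.std()
        var_g = (b1 * g1).var() + (b2 * g2).var()
        noise_sd = np.sqrt(var_g * 0.8 / 0.2)
        y = b1 * g1 + b2 * g2 + noise_sd * rng.standard_normal(n)
        G = GenotypeMatrix(np.column_stack([g1, g2]), ("a", "b"))
        _, adj = combined_association(G, y, cov=None)
        assert adj == pytest.approx(20.0, abs=3.0)

    def test_duplicate_column_dropped_with_warning(self):
        rng = np.random.default_rng(4)
        g = rng.binomial(2, 0.3, 300).astype(float)
        G = GenotypeMatrix(np.column_stack([g, g]), ("a", "a_dup"))
        y = g + rng.standard_normal(300)
        with pytest.warns(UserWarning, match="a_dup"):
            df, _ = combined_association(G, y, cov=None)
        assert list(df["snp_id"]) == ["a"]


class TestInteraction:
    def test_planted_interaction_detected(self):
        rng = np.random.default_rng(6)
        n = 3000
        a = rng.binomial(2, 0.4, n).astype(float)
        b = rng.binomial(2, 0.4, n).astype(float)
        y = 0.3 * a + 0.3 * b + 0.4 * a * b + rng.standard_normal(n)
        res = interaction_test(a, b, y, cov=None)
        assert res.p < 1e-6
        assert res.beta3 == pytest.approx(0.4, abs=0.15)

    def test_type_i_error_calibrated_small(self):
        rejections = 0
        n_sim = 400
        for seed in range(n_sim):
            rng = np.random.default_rng(seed)
            a = rng.binomial(2, 0.3, 500).astype(float)
            b = rng.binomial(2, 0.3, 500).astype(float)
            y = 0.5 * a + 0.5 * b + rng.standard_normal(500)
            if interaction_test(a, b, y).p < 0.05:
                rejections += 1
        lo, hi = stats.binom.interval(0.999, n_sim, 0.05)
        assert lo <= rejections <= hi

    def test_identical_snps_untestable(self):
        rng = np.random.default_rng(7)
        a = rng.binomial(2, 0.4, 200).astype(float)
        res = interaction_test(a, a.copy(), a + rng.standard_normal(200))
        # product term a*a is collinear-prone; at minimum the test must not
        # produce a spurious near-zero p from a degenerate design
        assert res.untestable or res.p > 1e-10

    def test_single_heterozygote_flagged(self):
        a = np.array([0.0] * 99 + [1.0])
        b = np.zeros(100)
        res = interaction_test(a, b, np.random.default_rng(1).normal(size=100))
        assert res.untestable


class TestInteractionScan:
    @staticmethod
    def _cohort(seed=0, n=800):
        rng = np.random.default_rng(seed)
        G = GenotypeMatrix(
            rng.binomial(2, 0.4, (n, 4)).astype(float), tuple("abcd")
        )
        y1 = rng.normal(size=n)
        y2 = 0.5 * G.values[:, 0] * G.values[:, 1] + rng.normal(size=n)
        return G, pd.DataFrame({"y1": y1, "y2": y2})

    def test_pair_count(self):
        G, Y = self._cohort()
        res = interaction_scan(G, Y)
        assert len(res) == 12  # 6 pairs x 2 phenotypes

    def test_high_ld_pair_excluded(self):
        rng = np.random.default_rng(1)
        g = rng.binomial(2, 0.4, 500).astype(float)
        g_dup = g.copy()
        flip = rng.random(500) < 0.01
        g_dup[flip] = 2 - g_dup[flip]
        other = rng.binomial(2, 0.4, 500).astype(float)
        G = GenotypeMatrix(np.column_stack([g, g_dup, other]), ("a", "a_ld", "c"))
        Y = pd.DataFrame({"y": rng.normal(size=500)})
        with pytest.warns(UserWarning, match="a_ld"):
            res = interaction_scan(G, Y, ld_exclusion_threshold=0.8)
        pairs = {(r.snp_a, r.snp_b) for r in res}
        assert ("a", "a_ld") not in pairs

    def test_planted_pair_tops_scan(self):
        hits = 0
        for seed in range(20):
            G, Y = self._cohort(seed=seed)
            res = interaction_scan(G, Y[["y2"]])
            if (res[0].snp_a, res[0].snp_b) == ("a", "b"):
                hits += 1
        assert hits >= 19

    def test_family_size_too_small_rejected(self):
        G, Y = self._cohort()
        with pytest.raises(ValueError):
            interaction_scan(G, Y, family_size=2)


class TestPrediction:
    def test_noiseless_exact_recovery(self):
        rng = np.random.default_rng(8)
        n = 300
        cov = random_cov(n, seed=8)
        g = rng.binomial(2, 0.4, n).astype(float)
        y = 2.0 * g + 1.0 * cov.age
        G = GenotypeMatrix(g[:, None], ("x1",))
        spec = PredictionModelSpec("y", ("x1",), use_sex=False, use_population=False)
        fit = fit_prediction_model(spec, G, y, cov)
        assert fit.coefficients["x1"] == pytest.approx(2.0, abs=1e-8)
        assert fit.coefficients["age"] == pytest.approx(1.0, abs=1e-8)
        assert fit.adjusted_r2 == pytest.approx(100.0, abs=1e-6)

    def test_pure_noise_adjusted_r2_near_zero(self):
        rng = np.random.default_rng(9)
        n = 1000
        G = GenotypeMatrix(rng.binomial(2, 0.3, (n, 12)).astype(float),
                           tuple(f"s{i}" for i in range(12)))
        y = rng.normal(size=n)
        spec = PredictionModelSpec("y", G.snp_ids)
        fit = fit_prediction_model(spec, G, y, cov=None)
        assert abs(fit.adjusted_r2) < 2.0

    def test_null_interaction_changes_little(self):
        rng = np.random.default_rng(10)
        n = 3000
        G = GenotypeMatrix(rng.binomial(2, 0.4, (n, 3)).astype(float), ("a", "b", "c"))
        y = G.values[:, 0] + rng.standard_normal(n)
        base = fit_prediction_model(PredictionModelSpec("y", G.snp_ids), G, y)
        withx = fit_prediction_model(
            PredictionModelSpec("y", G.snp_ids, interactions=(("a", "b"),)), G, y
        )
        assert abs(withx.adjusted_r2 - base.adjusted_r2) < 0.5

    def test_nested_models_monotone_on_noiseless_data(self):
        """A 6-SNP sub-model never out-predicts the 12-SNP model in training
        fit on noiseless synthetic data."""
        rng = np.random.default_rng(11)
        n = 500
        G = GenotypeMatrix(rng.binomial(2, 0.35, (n, 12)).astype(float),
                           tuple(f"s{i}" for i in range(12)))
        betas = rng.uniform(0.1, 1.0, 12)
        y = G.values @ betas
        full = fit_prediction_model(PredictionModelSpec("y", G.snp_ids), G, y)
        sub = fit_prediction_model(PredictionModelSpec("y", G.snp_ids[:6]), G, y)
        assert full.adjusted_r2 >= sub.adjusted_r2 - 1e-9

    def test_deterministic_cv(self):
        rng = np.random.default_rng(12)
        n = 600
        G = GenotypeMatrix(rng.binomial(2, 0.3, (n, 4)).astype(float), tuple("abcd"))
        y = G.values[:, 0] + rng.standard_normal(n)
        spec = PredictionModelSpec("y", G.snp_ids)
        r1 = cross_validated_r2(spec, G, y, n_rep=20, seed=42)
        r2 = cross_validated_r2(spec, G, y, n_rep=20, seed=42)
        assert r1.per_repeat_r2 == r2.per_repeat_r2
        assert r1.mean_r2 == r2.mean_r2

    def test_deterministic_y_every_repeat_100(self):
        rng = np.random.default_rng(13)
        n = 300
        G = GenotypeMatrix(rng.binomial(2, 0.4, (n, 2)).astype(float), ("a", "b"))
        y = 1.5 * G.values[:, 0] - 0.5 * G.values[:, 1]
        res = cross_validated_r2(PredictionModelSpec("y", ("a", "b")), G, y, n_rep=10, seed=0)
        assert all(abs(r - 100.0) < 1e-8 for r in res.per_repeat_r2)

    def test_interaction_not_in_snp_set_rejected(self):
        with pytest.raises(ValueError):
            PredictionModelSpec("y", ("a", "b"), interactions=(("a", "z"),))


def test_snp_summary_shape_and_ranges():
    rng = np.random.default_rng(14)
    n = 400
    cov = random_cov(n, seed=14)
    G = GenotypeMatrix(rng.binomial(2, 0.25, (n, 5)).astype(float),
                       tuple(f"s{i}" for i in range(5)))
    summ = snp_summary(G, cov)
    assert len(summ) == 5
    assert ((summ.maf >= 0) & (summ.maf <= 0.5)).all()
    assert ((summ.p_hwe > 0) & (summ.p_hwe <= 1)).all()
    assert (summ.in_ancestry >= 0).all()
    assert (summ.call_rate == 1.0).all()
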