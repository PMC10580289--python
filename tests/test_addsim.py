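import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from autozyg import addsim as ad
from autozyg.exceptions import ConfigError


class TestArchitecture:
    def test_frequency_range_contract(self):
        arch = ad.build_additive_architecture(1000, seed=3)
        assert arch.n_loci == 1000
        assert np.all((arch.freq > 0) & (arch.freq <= 0.5))

    def test_largest_effect_gets_smallest_frequency(self):
        arch = ad.build_additive_architecture(500, seed=1)
        assert np.argmax(np.abs(arch.beta)) == np.argmin(arch.freq)
        # rank order of 1/|beta| is preserved by the min-max rescale
        assert np.array_equal(
            np.argsort(1 / np.abs(arch.beta)), np.argsort(arch.freq, kind="stable")
        )

    def test_deterministic_under_seed(self):
        a = ad.build_additive_architecture(100, seed=7)
        b = ad.build_additive_architecture(100, seed=7)
        assert np.array_equal(a.beta, b.beta)
        assert np.array_equal(a.freq, b.freq)

    def test_too_few_loci(self):
        with pytest.raises(ConfigError):
            ad.build_additive_architecture(1)


class TestDiseaseProbability:
    def test_d_zero_gives_half_everywhere(self, rng):
        g = rng.normal(size=100)
        assert np.allclose(ad.disease_probability(g, 0.0), 0.5)

    def test_half_at_density_crossing(self):
        for d in (0.5, 1.0, 1.5):
            assert ad.disease_probability(np.array([d / 2]), d)[0] == pytest.approx(0.5)

    def test_symmetry(self, rng):
        d = 1.2
        g = rng.normal(size=50)
        lhs = ad.disease_probability(g, d)
        rhs = 1.0 - ad.disease_probability(d - g, d)
        assert np.allclose(lhs, rhs)


class TestAdditiveCohort:
    def test_variance_scales_with_one_plus_f(self):
        arch = ad.build_additive_architecture(1000, seed=0)
        n = 20_000
        v0 = ad.simulate_additive_cohort(
            arch, np.zeros(n), 1.0, seed=10, compute_h2=False
        ).raw_score.var()
        for F in (0.25, 1.0):
            v = ad.simulate_additive_cohort(
                arch, np.full(n, F), 1.0, seed=11, compute_h2=False
            ).raw_score.var()
            assert v / v0 == pytest.approx(1 + F, rel=0.06)

    def test_score_standardized_and_disease_binary(self):
        arch = ad.build_additive_architecture(300, seed=2)
        coh = ad.simulate_additive_cohort(
            arch, np.random.default_rng(0).uniform(0, 1, 2000), 1.0, seed=3
        )
        assert coh.score.mean() == pytest.approx(0.0, abs=1e-9)
        assert coh.score.std() == pytest.approx(1.0, abs=1e-9)
        assert set(np.unique(coh.disease)) <= {0, 1}

    def test_d_zero_disease_independent_of_froh(self):
        arch = ad.build_additive_architecture(300, seed=4)
        froh = np.random.default_rng(1).uniform(0, 1, 4000)
        coh = ad.simulate_additive_cohort(arch, froh, 0.0, seed=5, compute_h2=False)
        assert abs(np.corrcoef(froh, coh.disease)[0, 1]) < 0.05


class TestNagelkerke:
    def test_independent_score_near_zero(self, rng):
        y = rng.binomial(1, 0.4, 5000)
        s = rng.normal(size=5000)
        assert ad.nagelkerke_r2(y, s) < 0.01

    def test_separating_score_approaches_one(self):
        y = np.repeat([0, 1], 50)
        s = np.concatenate([np.linspace(-3, -1, 50), np.linspace(1, 3, 50)])
        assert ad.nagelkerke_r2(y, s) > 0.95

    def test_small_fixture_matches_direct_likelihood(self):
        """Oracle: likelihoods evaluated via an independent logistic fit."""
        rng = np.random.default_rng(6)
        s = rng.normal(size=20)
        y = (rng.uniform(size=20) < 1 / (1 + np.exp(-1.5 * s))).astype(float)
        lr = LogisticRegression(C=1e10, tol=1e-10).fit(s[:, None], y)
        p1 = lr.predict_proba(s[:, None])[:, 1]
        ll1 = float(np.sum(y * np.log(p1) + (1 - y) * np.log(1 - p1)))
        pbar = y.mean()
        ll0 = float(len(y) * (pbar * np.log(pbar) + (1 - pbar) * np.log(1 - pbar)))
        n = len(y)
        expected = (1 - np.exp(2 * (ll0 - ll1) / n)) / (1 - np.exp(2 * ll0 / n))
        assert ad.nagelkerke_r2(y, s) == pytest.approx(expected, abs=1e-6)

    def test_constant_outcome_rejected(self):
        with pytest.raises(ConfigError):
            ad.nagelkerke_r2(np.ones(10), np.arange(10))


class TestFrohPowerAdditive:
    def test_nested_alphas_and_reproducible(self):
        arch = ad.build_additive_architecture(200, seed=1)
        cfg = ad.FrohPowerConfig(
            d_grid=(1.5,), alphas=(0.05, 0.05 / 61), n_sims=30, n_individuals=1500,
            froh_sampler=lambda n, rng: rng.uniform(0, 1, n),
        )
        t1 = ad.froh_power_additive(cfg, arch, seed=3)
        t2 = ad.froh_power_additive(cfg, arch, seed=3)
        assert t1.equals(t2)
        strict = t1[t1["alpha"] < 0.05]["power"].iloc[0]
        nominal = t1[t1["alpha"] == 0.05]["power"].iloc[0]
        assert strict <= nominal

    def test_uniform_froh_variance_inflation_induces_association(self):
        """With F_ROH spanning [0,1], the (1+F) variance inflation alone
        induces a positive F_ROH-disease association at large n, with no
        non-additive gene action anywhere in the simulation."""
        import statsmodels.api as sm

        arch = ad.build_additive_architecture(300, seed=5)
        rng = np.random.default_rng(5)
        froh = rng.uniform(0, 1, 80_000)
        coh = ad.simulate_additive_cohort(arch, froh, 3.0, seed=15, compute_h2=False)
        fit = sm.Logit(coh.disease, sm.add_constant(froh)).fit(disp=False)
        assert fit.params[1] > 0
        assert fit.pvalues[1] < 0.001


class TestGenericPower:
    def test_logistic_null_or_gives_alpha(self):
        power, mc_se = ad.power_logistic_lognormal_covariate(
            1.0, 0.2, 500, alpha=0.05, n_sims=300, seed=1
        )
        assert abs(power - 0.05) < 3 * max(mc_se, 0.013)

    def test_logistic_power_monotone_in_n(self):
        powers = [
            ad.power_logistic_lognormal_covariate(
                2.5, 0.2, n, alpha=0.05, n_sims=150, seed=2
            )[0]
            for n in (200, 4000)
        ]
        assert powers[1] > powers[0]

    def test_linear_power_limits_and_monotonicity(self):
        assert ad.power_linear_model_r2(1e-9, 3, 100) == pytest.approx(0.05, abs=0.01)
        a = ad.power_linear_model_r2(0.01, 5, 500)
        b = ad.power_linear_model_r2(0.01, 5, 2000)
        c = ad.power_linear_model_r2(0.05, 5, 500)
        assert a < b and a < c

    def test_linear_power_matches_monte_carlo(self, rng):
        """Closed-form noncentral-F power vs simulated Gaussian regressions."""
        r2, k, n, alpha = 0.01, 11, 5000, 0.05
        analytic = ad.power_linear_model_r2(r2, k, n, alpha)
        from scipy import stats as st

        hits = 0
        n_sims = 300
        for _ in range(n_sims):
            X = rng.normal(size=(n, k))
            beta = np.zeros(k)
            beta[0] = np.sqrt(r2 / (1 - r2))
            y = X @ beta + rng.normal(size=n)
            # overall F-test via R^2
            Xc = np.column_stack([np.ones(n), X])
            coef, *_ = np.linalg.lstsq(Xc, y, rcond=None)
            resid = y - Xc @ coef
            ssr = ((y - y.mean()) ** 2).sum() - (resid**2).sum()
            f = (ssr / k) / ((resid**2).sum() / (n - k - 1))
            hits += f > st.f.isf(alpha, k, n - k - 1)
        mc = hits / n_sims
        assert analytic == pytest.approx(mc, abs=0.05)

    def test_invalid_inputs(self):
        with pytest.raises(ConfigError):
            ad.power_linear_model_r2(0.5, 3, 4)
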