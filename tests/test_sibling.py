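import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from _oracles import enumerate_replication_power
from autozyg import sibling as sib
from autozyg import synthdata as sd
from autozyg.exceptions import ConfigError, PipelineError


def make_pairs(f1, f2, y1, y2):
    n = len(f1)
    return pd.DataFrame(
        {
            "family_id": np.repeat([f"f{i}" for i in range(n)], 2),
            "froh": np.column_stack((f1, f2)).ravel(),
            "phenotype": np.column_stack((y1, y2)).ravel().astype(float),
        }
    )


class TestFitWithinFamily:
    def test_all_concordant_families_error(self, rng):
        f1 = rng.uniform(0, 0.1, 50)
        df = make_pairs(f1, f1 + 0.001, np.ones(50), np.ones(50))
        with pytest.raises(PipelineError, match="0 informative"):
            sib.fit_within_family(df, family="binomial")

    def test_zero_within_variation_inestimable(self, rng):
        f1 = rng.uniform(0, 0.1, 50)
        y1, y2 = np.ones(50), np.zeros(50)
        df = make_pairs(f1, f1, y1, y2)  # identical froh within pairs
        with pytest.raises(ConfigError, match="inestimable"):
            sib.fit_within_family(df, family="binomial")

    def test_binary_recovery_large_pairs(self):
        """Conditional-logistic estimate covers a strong simulated effect."""
        rng = np.random.default_rng(5)
        n = 4000
        beta = np.log(1.96) / 0.0625
        f1 = sd.truncated_normal_sampler(0.05, 0.02)(n, rng)
        f2 = np.maximum(f1 + rng.normal(0, 0.01, n), 0)
        p1 = 1 / (1 + np.exp(-(-1.0 + beta * f1)))
        p2 = 1 / (1 + np.exp(-(-1.0 + beta * f2)))
        y1 = rng.uniform(size=n) < p1
        y2 = rng.uniform(size=n) < p2
        df = make_pairs(f1, f2, y1, y2)
        res = sib.fit_within_family(df, family="binomial")
        assert res.beta - 1.96 * res.se < beta < res.beta + 1.96 * res.se

    def test_family_constant_covariate_dropped(self, rng):
        n = 100
        f1 = rng.uniform(0, 0.1, n)
        f2 = f1 + rng.normal(0, 0.01, n)
        y1, y2 = rng.binomial(1, 0.5, n), rng.binomial(1, 0.5, n)
        df = make_pairs(f1, f2, y1, y2)
        df["region"] = np.repeat(rng.normal(size=n), 2)  # family-constant
        res = sib.fit_within_family(df, family="binomial", covariates=["region"])
        assert res.dropped_covariates == ["region"]

    def test_gaussian_recovery(self):
        rng = np.random.default_rng(17)
        n = 3000
        beta = -0.93 / 0.0625
        f1 = sd.truncated_normal_sampler(0.05, 0.02)(n, rng)
        f2 = np.maximum(f1 + rng.normal(0, 0.01, n), 0)
        y1 = beta * f1 + rng.normal(0, 2.0, n)
        y2 = beta * f2 + rng.normal(0, 2.0, n)
        res = sib.fit_within_family(make_pairs(f1, f2, y1, y2), family="gaussian")
        assert res.beta == pytest.approx(beta, abs=3 * res.se)

    def test_family_level_confounding_immunity(self):
        """A family-level shift biases the pooled estimator but not the
        within-family one (the design's core property)."""
        rng = np.random.default_rng(23)
        n = 3000
        f_fam = rng.uniform(0, 0.1, n)  # family mean F_ROH
        f1 = f_fam + rng.normal(0, 0.005, n)
        f2 = f_fam + rng.normal(0, 0.005, n)
        u = 20.0 * f_fam  # family confounder tracking family F_ROH
        y1 = u + rng.normal(0, 1, n)  # NO direct froh effect
        y2 = u + rng.normal(0, 1, n)
        df = make_pairs(f1, f2, y1, y2)
        pooled = np.polyfit(df["froh"], df["phenotype"], 1)[0]
        assert pooled > 5.0  # heavily biased away from 0
        res = sib.fit_within_family(df, family="gaussian")
        assert abs(res.beta) < 3 * res.se  # unbiased

    def test_conditional_logit_agrees_with_statsmodels_on_pairs(self):
        """Dual route: the fast pair-difference Newton solver vs the
        general conditional likelihood."""
        rng = np.random.default_rng(3)
        n = 800
        d = rng.normal(0, 0.01, n)
        y1 = rng.uniform(size=n) < 1 / (1 + np.exp(-5.0 * d))
        beta, se, p = sib._fit_pair_conditional(d, y1.astype(float))
        f1 = np.abs(rng.uniform(0.02, 0.1, n))
        df = make_pairs(f1, f1 - d, y1, ~y1)
        res = sib.fit_within_family(df, family="binomial")
        # optimizer tolerances differ slightly between the two routes
        assert res.beta == pytest.approx(beta, rel=5e-3)
        assert res.se == pytest.approx(se, rel=1e-2)


class TestDiscordantPairs:
    @pytest.mark.parametrize(
        "avg,cases,expected", [(2.0, 100, 100), (2.05, 100, 105), (1.0, 7, 0)]
    )
    def test_forced_arithmetic(self, avg, cases, expected):
        assert sib.estimate_discordant_pairs(avg, cases) == expected

    def test_negative_rejected(self):
        with pytest.raises(ConfigError):
            sib.estimate_discordant_pairs(0.5, 10)


class TestBinaryPower:
    def test_null_or_gives_alpha(self):
        cfg = sib.PowerConfig(
            or_at_0625=1.0, prevalence=0.1, n_pairs=300, n_sims=200, alpha=0.05
        )
        est = sib.simulate_replication_power_binary(cfg, seed=2)
        assert abs(est.power - 0.05) < 3 * max(est.mc_se, 0.016)

    def test_power_monotone_in_pairs(self):
        powers = []
        for n_pairs in (200, 3000):
            cfg = sib.PowerConfig(
                or_at_0625=3.0,
                prevalence=0.2,
                n_pairs=n_pairs,
                n_sims=120,
                alpha=0.05,
                within_sd=0.01,
                index_froh_sampler=sd.truncated_normal_sampler(0.05, 0.02),
            )
            powers.append(
                sib.simulate_replication_power_binary(cfg, seed=4).power
            )
        assert powers[1] > powers[0]

    def test_infeasible_prevalence(self):
        cfg = sib.PowerConfig(
            or_at_0625=1.5, prevalence=1.5, n_pairs=10, n_sims=1
        )
        with pytest.raises(Exception):
            sib.simulate_replication_power_binary(cfg, seed=0)


class TestQuantitativePower:
    def test_null_beta_gives_alpha(self):
        cfg = sib.PowerConfig(beta=0.0, n_cliques=500, n_sims=300, alpha=0.05)
        est = sib.simulate_replication_power_quantitative(cfg, seed=1)
        assert abs(est.power - 0.05) < 3 * max(est.mc_se, 0.013)

    def test_vanishing_noise_gives_full_power(self):
        cfg = sib.PowerConfig(
            beta=-0.93 / 0.0625, n_cliques=200, n_sims=50, alpha=0.05,
            residual_sd=1e-6,
        )
        est = sib.simulate_replication_power_quantitative(cfg, seed=2)
        assert est.power == 1.0


class TestCombinePowers:
    def test_closed_forms(self):
        assert sib.combine_powers([0.5, 0.5]) == pytest.approx(0.75)
        assert sib.combine_powers([0.5, 0.5], "at_least_two") == pytest.approx(0.25)
        assert sib.combine_powers([1.0, 0.0]) == pytest.approx(1.0)
        assert sib.combine_powers([1.0, 0.0], "at_least_two") == pytest.approx(0.0)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=10))
    def test_matches_exhaustive_enumeration(self, powers):
        assert sib.combine_powers(powers) == pytest.approx(
            enumerate_replication_power(powers, 1), abs=1e-9
        )
        assert sib.combine_powers(powers, "at_least_two") == pytest.approx(
            enumerate_replication_power(powers, 2), abs=1e-9
        )

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=7))
    def test_ordering_properties(self, powers):
        one = sib.combine_powers(powers)
        two = sib.combine_powers(powers, "at_least_two")
        assert one >= max(powers) - 1e-12
        assert two <= one + 1e-12

    def test_empty_rejected(self):
        with pytest.raises(ConfigError, match="empty"):
            sib.combine_powers([])
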