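"""Strictly additive liability simulations and power calculators.

Autozygosity inflates the additive genetic variance of a trait by a factor
of (1 + F) without any non-additive gene action, because autozygous loci
contribute 2*Bernoulli(p) genotypes (variance 4p(1-p)) instead of
Binomial(2, p) (variance 2p(1-p)).  Under a liability-threshold-like model
this alone induces a positive F_ROH-disease association.  This module
simulates that null — effect sizes from N(0,1) at independent causal loci,
allele frequencies tied to effect magnitude, disease assigned by a
two-component density ratio — and measures how often a logistic scan of
disease on F_ROH would (falsely, with respect to non-additive biology)
reject, alongside generic Monte-Carlo and closed-form power calculators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import ConfigError, NumericalError
from .synthdata import truncated_lognormal_sampler

__all__ = [
    "AdditiveArchitecture",
    "AdditiveCohort",
    "FrohPowerConfig",
    "build_additive_architecture",
    "disease_probability",
    "simulate_additive_cohort",
    "nagelkerke_r2",
    "froh_power_additive",
    "power_logistic_lognormal_covariate",
    "power_linear_model_r2",
]


@dataclass(frozen=True)
class AdditiveArchitecture:
    """Effect sizes and allele frequencies of independent causal loci.

    Frequencies derive from effect magnitudes: 1/|beta| min-max rescaled
    into (eps, 0.5], so the largest effects get the rarest alleles (the
    magnitude-frequency coupling is a convention; the (1+F) variance law
    does not depend on it).
    """

    beta: np.ndarray
    freq: np.ndarray

    def __post_init__(self) -> None:
        if len(self.beta) != len(self.freq):
            raise ConfigError("beta and freq must have equal length")
        if np.any((self.freq <= 0) | (self.freq > 0.5)):
            raise ConfigError("frequencies must lie in (0, 0.5]")

    @property
    def n_loci(self) -> int:
        return len(self.beta)


def build_additive_architecture(
    n_loci: int = 1000, seed: int | None = None, eps: float = 1e-3
) -> AdditiveArchitecture:
    """Draw beta_j ~ N(0,1) and map 1/|beta_j| onto (eps, 0.5]."""
    if n_loci < 2:
        raise ConfigError("n_loci must be >= 2")
    rng = np.random.default_rng(seed)
    beta = rng.normal(0.0, 1.0, n_loci)
    inv = 1.0 / np.abs(beta)
    lo, hi = inv.min(), inv.max()
    freq = eps + (0.5 - eps) * (inv - lo) / (hi - lo)
    return AdditiveArchitecture(beta=beta, freq=freq)


def disease_probability(g: np.ndarray, d: float) -> np.ndarray:
    """Pr(disease | G) = N(G; d, 1) / (N(G; 0, 1) + N(G; d, 1)).

    Symmetric around G = d/2 (where both densities are equal and the
    probability is 1/2); identical to logistic(d*G - d^2/2).
    """
    if not np.isfinite(d):
        raise ConfigError("d must be finite")
    num = stats.norm.pdf(g, loc=d, scale=1.0)
    den = stats.norm.pdf(g, loc=0.0, scale=1.0) + num
    return num / den


@dataclass
class AdditiveCohort:
    froh: np.ndarray
    genotypes: np.ndarray
    score: np.ndarray  # standardized genetic score G
    raw_score: np.ndarray  # pre-standardization, for variance checks
    disease: np.ndarray
    d: float
    h2: float = field(default=np.nan)


def simulate_additive_cohort(
    arch: AdditiveArchitecture,
    froh: np.ndarray,
    d: float,
    seed: int | None = None,
    compute_h2: bool = True,
) -> AdditiveCohort:
    """Simulate genotypes, additive scores, and disease for given F_ROH.

    Per individual, round(n_loci * F_ROH) randomly chosen loci are
    autozygous (genotype 2*Bernoulli(p)); the remainder draw Binomial(2, p).
    G is the effect-weighted genotype sum standardized over the cohort;
    disease ~ Bernoulli(Pr(disease | G)).
    """
    froh = np.asarray(froh, dtype=float)
    if np.any((froh < 0) | (froh > 1)):
        raise ConfigError("froh must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n, m = len(froh), arch.n_loci
    n_auto = np.rint(m * froh).astype(int)
    G = np.empty((n, m), dtype=np.int8)
    chunk = max(1, 4_000_000 // m)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        c = hi - lo
        outbred = rng.binomial(2, arch.freq, size=(c, m)).astype(np.int8)
        autoz = (2 * rng.binomial(1, arch.freq, size=(c, m))).astype(np.int8)
        # per-row random subset of exactly n_auto loci is autozygous
        ranks = rng.random((c, m)).argsort(axis=1)
        mask = ranks < n_auto[lo:hi, None]
        G[lo:hi] = np.where(mask, autoz, outbred)
    raw = G @ arch.beta
    sd = raw.std()
    if sd == 0:
        raise NumericalError("degenerate genetic score (zero variance)")
    score = (raw - raw.mean()) / sd
    pdis = disease_probability(score, d)
    disease = (rng.uniform(size=n) < pdis).astype(np.int8)
    h2 = np.nan
    if compute_h2 and 0 < disease.sum() < n:
        h2 = nagelkerke_r2(disease, score)
    return AdditiveCohort(
        froh=froh, genotypes=G, score=score, raw_score=raw,
        disease=disease, d=d, h2=h2,
    )


def nagelkerke_r2(y, score) -> float:
    """Nagelkerke pseudo-R^2 of a logistic regression of ``y`` on
    ``score``: (1 - (L0/L1)^(2/n)) / (1 - L0^(2/n))."""
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise ConfigError("outcome is constant")
    X = sm.add_constant(np.asarray(score, dtype=float))
    fit = sm.Logit(y, X).fit(disp=False)
    n = len(y)
    ll1, ll0 = fit.llf, fit.llnull
    cox_snell = 1.0 - np.exp(2.0 * (ll0 - ll1) / n)
    max_cs = 1.0 - np.exp(2.0 * ll0 / n)
    return float(cox_snell / max_cs)


@dataclass
class FrohPowerConfig:
    """Grid configuration for the additive-null F_ROH power scan.

    ``froh_sampler`` defaults to lognormal(mu=-2.5, sigma=0.5) truncated to
    [0.02, 0.18], mimicking the F_ROH spread among first-cousin offspring;
    ``d_grid`` is the case mean-shift grid; power counts simulations with a
    positive F_ROH effect significant at each alpha.
    """

    d_grid: tuple = tuple(np.round(np.arange(0.5, 1.51, 0.1), 1))
    alphas: tuple = (0.05, 0.05 / 61)
    n_sims: int = 100
    n_individuals: int = 6000
    froh_sampler: object = None

    def __post_init__(self) -> None:
        if len(self.d_grid) == 0:
            raise ConfigError("empty d grid")
        if self.froh_sampler is None:
            self.froh_sampler = truncated_lognormal_sampler(-2.5, 0.5, 0.02, 0.18)


def froh_power_additive(
    cfg: FrohPowerConfig, arch: AdditiveArchitecture, seed: int | None = None
) -> pd.DataFrame:
    """Power table over (d, alpha): fraction of simulated additive cohorts
    in which logistic disease ~ F_ROH yields a positive, significant
    coefficient; also reports mean Nagelkerke h2 per d."""
    rng = np.random.default_rng(seed)
    rows = []
    for d in cfg.d_grid:
        hits = {a: 0 for a in cfg.alphas}
        h2s = []
        for _ in range(cfg.n_sims):
            froh = np.asarray(cfg.froh_sampler(cfg.n_individuals, rng))
            cohort = simulate_additive_cohort(
                arch, froh, d, seed=int(rng.integers(2**31))
            )
            if cohort.disease.min() == cohort.disease.max():
                continue
            X = sm.add_constant(froh)
            fit = sm.Logit(cohort.disease, X).fit(disp=False)
            beta, p = fit.params[1], fit.pvalues[1]
            for a in cfg.alphas:
                hits[a] += (beta > 0) and (p < a)
            if np.isfinite(cohort.h2):
                h2s.append(cohort.h2)
        for a in cfg.alphas:
            power = hits[a] / cfg.n_sims
            rows.append(
                {
                    "d": d,
                    "alpha": a,
                    "power": power,
                    "mc_se": float(np.sqrt(power * (1 - power) / cfg.n_sims)),
                    "mean_h2": float(np.mean(h2s)) if h2s else np.nan,
                }
            )
    return pd.DataFrame(rows)


def power_logistic_lognormal_covariate(
    or_at_0625: float,
    base_rate: float,
    n: int,
    alpha: float = 0.05,
    froh_sampler=None,
    n_sims: int = 500,
    seed: int | None = None,
) -> tuple[float, float]:
    """Monte-Carlo power of the Wald test for the F_ROH coefficient in a
    logistic regression at sample size ``n``.

    F_ROH is drawn from the truncated lognormal consanguineous-cohort
    distribution by default; the intercept is solved so the mean phenotype
    rate equals ``base_rate``.  Returns (power, MC SE).
    """
    if min(or_at_0625, base_rate, n, alpha) <= 0:
        raise ConfigError("all inputs must be positive")
    if froh_sampler is None:
        froh_sampler = truncated_lognormal_sampler(-2.5, 0.5, 0.02, 0.18)
    from scipy import optimize

    rng = np.random.default_rng(seed)
    slope = float(np.log(or_at_0625) / 0.0625)
    ref = np.asarray(froh_sampler(200_000, rng))

    def gap(b0):
        return float(np.mean(1 / (1 + np.exp(-(b0 + slope * ref))))) - base_rate

    try:
        b0 = optimize.brentq(gap, -40, 40)
    except ValueError as exc:
        raise NumericalError(f"infeasible base_rate {base_rate}") from exc
    hits = 0
    for _ in range(n_sims):
        f = np.asarray(froh_sampler(n, rng))
        pr = 1 / (1 + np.exp(-(b0 + slope * f)))
        y = (rng.uniform(size=n) < pr).astype(float)
        if y.min() == y.max():
            continue
        fit = sm.Logit(y, sm.add_constant(f)).fit(disp=False)
        hits += fit.pvalues[1] < alpha
    power = hits / n_sims
    return power, float(np.sqrt(power * (1 - power) / n_sims))


def power_linear_model_r2(r2: float, k: int, n: int, alpha: float = 0.05) -> float:
    """Closed-form power of the overall F-test of a linear model with
    ``k`` predictors explaining ``r2`` at sample size ``n``, via the
    noncentral F distribution with noncentrality n*r2/(1-r2)."""
    if not 0 < r2 < 1:
        raise ConfigError("r2 must be in (0, 1)")
    if k < 1:
        raise ConfigError("k must be >= 1")
    if n <= k + 1:
        raise ConfigError("n must exceed k + 1")
    df2 = n - k - 1
    nc = n * r2 / (1.0 - r2)
    f_crit = stats.f.isf(alpha, k, df2)
    return float(stats.ncf.sf(f_crit, k, df2, nc))
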