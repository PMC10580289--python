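"""Within-family (sibling) association and replication power simulation.

Within-family designs regress phenotype differences between siblings on
their F_ROH differences, eliminating every family-constant confounder —
population structure included — because siblings differ in F_ROH only
through stochastic recombination and Mendelian segregation.

Binary phenotypes use conditional logistic regression (exact conditioning
on per-family case counts), which for discordant pairs reduces to a
no-intercept logistic fit on within-pair differences and avoids the
incidental-parameter bias of unconditional family dummies at clique size 2.
Quantitative phenotypes use the within-family demeaning (fixed-effect)
estimator with family-count-corrected degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats, optimize

from .exceptions import ConfigError, NumericalError, PipelineError
from .synthdata import truncated_normal_sampler

__all__ = [
    "WithinFamilyResult",
    "PowerConfig",
    "fit_within_family",
    "estimate_discordant_pairs",
    "simulate_replication_power_binary",
    "simulate_replication_power_quantitative",
    "combine_powers",
]

_Z975 = 1.959963984540054


@dataclass
class WithinFamilyResult:
    beta: float
    se: float
    p: float
    n_informative_families: int
    dropped_covariates: list[str] = field(default_factory=list)


def _within_demean(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    g = df.groupby("family_id")[cols]
    return df[cols] - g.transform("mean")


def fit_within_family(
    cliques: pd.DataFrame,
    family: str = "binomial",
    covariates: list[str] | None = None,
    phenotype_col: str = "phenotype",
    froh_col: str = "froh",
) -> WithinFamilyResult:
    """Family-fixed-effect association of phenotype with F_ROH.

    ``cliques`` holds one row per sibling with ``family_id``, F_ROH,
    phenotype, and optional covariate columns.  Families with fewer than
    two phenotyped members are dropped; covariates constant within every
    family are absorbed by the family effect and reported as dropped.
    """
    covariates = list(covariates or [])
    df = cliques.dropna(subset=[phenotype_col, froh_col]).copy()
    sizes = df.groupby("family_id")[phenotype_col].transform("size")
    df = df[sizes >= 2]
    if family not in ("binomial", "gaussian"):
        raise ConfigError(f"unknown family {family!r}")

    xcols = [froh_col] + covariates
    demeaned = _within_demean(df, xcols) if len(df) else df[xcols]
    kept, dropped = [], []
    for c in xcols:
        (kept if len(df) and np.ptp(demeaned[c].to_numpy()) > 0 else dropped).append(c)
    if froh_col in dropped:
        raise ConfigError(
            "F_ROH has no within-family variation; coefficient inestimable"
        )

    if family == "binomial":
        case_counts = df.groupby("family_id")[phenotype_col].agg(["sum", "size"])
        informative = case_counts[
            (case_counts["sum"] > 0) & (case_counts["sum"] < case_counts["size"])
        ].index
        if len(informative) == 0:
            raise PipelineError(
                "0 informative (phenotype-discordant) families; "
                "concordant families contribute nothing to the conditional likelihood"
            )
        sub = df[df["family_id"].isin(informative)]
        from statsmodels.discrete.conditional_models import ConditionalLogit

        res = ConditionalLogit(
            sub[phenotype_col].to_numpy(dtype=float),
            sub[kept].to_numpy(dtype=float),
            groups=sub["family_id"].to_numpy(),
        ).fit(disp=False)
        j = kept.index(froh_col)
        return WithinFamilyResult(
            beta=float(res.params[j]),
            se=float(res.bse[j]),
            p=float(res.pvalues[j]),
            n_informative_families=len(informative),
            dropped_covariates=dropped,
        )

    # gaussian: within-family demeaning with corrected residual dof
    if df.empty:
        raise PipelineError("0 informative families (need >=2 phenotyped members)")
    yd = _within_demean(df, [phenotype_col])[phenotype_col].to_numpy()
    Xd = _within_demean(df, kept).to_numpy(dtype=float)
    n, k = Xd.shape
    n_fam = df["family_id"].nunique()
    dof = n - n_fam - k
    if dof <= 0:
        raise ConfigError("not enough within-family observations for inference")
    xtx = Xd.T @ Xd
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError:
        raise ConfigError("rank-deficient within-family design") from None
    beta = xtx_inv @ (Xd.T @ yd)
    resid = yd - Xd @ beta
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    j = kept.index(froh_col)
    t = beta[j] / se[j]
    return WithinFamilyResult(
        beta=float(beta[j]),
        se=float(se[j]),
        p=float(2 * stats.t.sf(abs(t), dof)),
        n_informative_families=n_fam,
        dropped_covariates=dropped,
    )


def estimate_discordant_pairs(avg_clique_size: float, n_cases_discordant: int) -> int:
    """N_p = round((average clique size - 1) * cases in discordant cliques),
    rounding half to even."""
    if avg_clique_size < 1 or n_cases_discordant < 0:
        raise ConfigError("avg_clique_size >= 1 and n_cases_discordant >= 0 required")
    return int(round((avg_clique_size - 1.0) * n_cases_discordant))


@dataclass
class PowerConfig:
    """Configuration for within-sibling replication power simulation.

    ``or_at_0625`` parameterizes the binary effect (odds ratio at
    F_ROH = 0.0625); ``beta`` the quantitative effect per unit F_ROH.
    ``residual_sd`` defaults to 9.4, the residual SD used for height.
    """

    or_at_0625: float | None = None
    beta: float | None = None
    prevalence: float | None = None
    n_pairs: int | None = None
    n_cliques: int | None = None
    n_sims: int = 1000
    alpha: float = 0.05
    within_sd: float = 0.002
    residual_sd: float = 9.4
    index_froh_sampler: object = None

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise ConfigError("n_sims must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.index_froh_sampler is None:
            self.index_froh_sampler = truncated_normal_sampler(0.0037, 0.0050)


@dataclass
class PowerEstimate:
    power: float
    mc_se: float
    n_sims: int


def _solve_intercept(slope: float, froh: np.ndarray, prevalence: float) -> float:
    """Intercept making mean disease probability equal the target prevalence."""

    def gap(b0):
        return float(np.mean(1.0 / (1.0 + np.exp(-(b0 + slope * froh))))) - prevalence

    try:
        return optimize.brentq(gap, -40.0, 40.0)
    except ValueError as exc:
        raise NumericalError(
            f"cannot achieve prevalence {prevalence} with slope {slope}"
        ) from exc


def _fit_pair_conditional(d_froh: np.ndarray, y_first: np.ndarray):
    """Newton fit of the discordant-pair conditional likelihood:
    P(sib1 is the case) = logistic(beta * (froh1 - froh2))."""
    beta = 0.0
    for _ in range(50):
        p = 1.0 / (1.0 + np.exp(-beta * d_froh))
        grad = float(((y_first - p) * d_froh).sum())
        info = float((p * (1 - p) * d_froh**2).sum())
        if info <= 0:
            raise NumericalError("no information in within-pair F_ROH differences")
        step = grad / info
        beta += step
        if abs(step) < 1e-10:
            break
    se = info**-0.5
    z = beta / se
    return beta, se, float(2 * stats.norm.sf(abs(z)))


def simulate_replication_power_binary(
    cfg: PowerConfig, seed: int | None = None
) -> PowerEstimate:
    """Monte-Carlo power of the within-sibling conditional logistic test.

    Each replicate draws index-sibling F_ROH values, co-sibling values from
    Normal(index, within_sd), assigns disease by a logistic model with the
    configured odds ratio and prevalence, keeps ``n_pairs`` discordant
    pairs, and tests the F_ROH coefficient at ``alpha``.
    """
    if cfg.or_at_0625 is None or cfg.prevalence is None or cfg.n_pairs is None:
        raise ConfigError("binary power needs or_at_0625, prevalence, n_pairs")
    rng = np.random.default_rng(seed)
    slope = float(np.log(cfg.or_at_0625) / 0.0625)
    ref = np.asarray(cfg.index_froh_sampler(200_000, rng))
    b0 = _solve_intercept(slope, ref, cfg.prevalence)
    p_disc_approx = 2 * cfg.prevalence * (1 - cfg.prevalence)
    hits = 0
    for _ in range(cfg.n_sims):
        d1 = np.empty(0)
        y1 = np.empty(0, dtype=bool)
        while d1.size < cfg.n_pairs:
            m = int((cfg.n_pairs - d1.size) / max(p_disc_approx, 1e-3) * 1.2) + 100
            f1 = np.asarray(cfg.index_froh_sampler(m, rng))
            f2 = np.maximum(f1 + rng.normal(0, cfg.within_sd, m), 0.0)
            pr1 = 1.0 / (1.0 + np.exp(-(b0 + slope * f1)))
            pr2 = 1.0 / (1.0 + np.exp(-(b0 + slope * f2)))
            case1 = rng.uniform(size=m) < pr1
            case2 = rng.uniform(size=m) < pr2
            disc = case1 != case2
            d1 = np.concatenate((d1, (f1 - f2)[disc]))
            y1 = np.concatenate((y1, case1[disc]))
        d1, y1 = d1[: cfg.n_pairs], y1[: cfg.n_pairs]
        _, _, p = _fit_pair_conditional(d1, y1.astype(float))
        hits += p < cfg.alpha
    power = hits / cfg.n_sims
    return PowerEstimate(power, float(np.sqrt(power * (1 - power) / cfg.n_sims)), cfg.n_sims)


def simulate_replication_power_quantitative(
    cfg: PowerConfig, seed: int | None = None
) -> PowerEstimate:
    """Monte-Carlo power of the within-sibling fixed-effect linear test for
    a quantitative trait (e.g. height: beta in trait units per unit F_ROH,
    residual SD 9.4)."""
    if cfg.beta is None or cfg.n_cliques is None:
        raise ConfigError("quantitative power needs beta and n_cliques")
    rng = np.random.default_rng(seed)
    hits = 0
    n = cfg.n_cliques
    for _ in range(cfg.n_sims):
        f1 = np.asarray(cfg.index_froh_sampler(n, rng))
        f2 = np.maximum(f1 + rng.normal(0, cfg.within_sd, n), 0.0)
        y1 = cfg.beta * f1 + rng.normal(0, cfg.residual_sd, n)
        y2 = cfg.beta * f2 + rng.normal(0, cfg.residual_sd, n)
        dx, dy = f1 - f2, y1 - y2
        sxx = float(dx @ dx)
        if sxx == 0:
            continue
        b = float(dx @ dy) / sxx
        resid = dy - b * dx
        dof = n - 1
        se = np.sqrt(float(resid @ resid) / dof / sxx)
        p = 2 * stats.t.sf(abs(b / se), dof)
        hits += p < cfg.alpha
    power = hits / cfg.n_sims
    return PowerEstimate(power, float(np.sqrt(power * (1 - power) / cfg.n_sims)), cfg.n_sims)


def combine_powers(powers, mode: str = "at_least_one") -> float:
    """Probability of replicating at least one (or at least two) of a set
    of independent associations given their per-phenotype powers.

    at_least_one = 1 - prod(1 - p_i);
    at_least_two subtracts the exactly-one term
    sum_i p_i * prod_{j != i} (1 - p_j).
    """
    p = np.asarray(powers, dtype=float)
    if p.size == 0:
        raise ConfigError("empty power vector")
    if np.any((p < 0) | (p > 1)):
        raise ConfigError("powers must lie in [0, 1]")
    none = float(np.prod(1.0 - p))
    if mode == "at_least_one":
        return 1.0 - none
    if mode == "at_least_two":
        exactly_one = 0.0
        for i in range(p.size):
            rest = np.delete(p, i)
            exactly_one += p[i] * float(np.prod(1.0 - rest))
        return 1.0 - none - exactly_one
    raise ConfigError(f"unknown mode {mode!r}")
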