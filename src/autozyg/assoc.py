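"""F_ROH-phenotype association models, IVW meta-analysis, multiplicity
adjustment, quintile-trend sensitivity analysis, and relative pruning.

Effect sizes are reported both per unit F_ROH (beta) and as the odds ratio
at F_ROH = 0.0625, the expectation for offspring of first cousins, which
puts estimates from cohorts with different consanguinity spectra on a
common, interpretable scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import ConfigError, PipelineError, StructuralError

__all__ = [
    "AssociationResult",
    "MetaResult",
    "TrendResult",
    "fit_glm_association",
    "ivw_meta",
    "adjust_multiplicity",
    "froh_quintile_trend",
    "prune_relatives",
]

FIRST_COUSIN_FROH = 0.0625


@dataclass
class AssociationResult:
    """Per-cohort GLM effect of F_ROH on one phenotype."""

    phenotype: str
    cohort: str
    beta: float
    se: float
    p: float
    n: int
    n_cases: int | None = None
    family: str = "binomial"

    @property
    def or_at_0625(self) -> float:
        return float(np.exp(FIRST_COUSIN_FROH * self.beta))

    @property
    def or_ci95(self) -> tuple[float, float]:
        lo = self.beta - 1.959963984540054 * self.se
        hi = self.beta + 1.959963984540054 * self.se
        return (
            float(np.exp(FIRST_COUSIN_FROH * lo)),
            float(np.exp(FIRST_COUSIN_FROH * hi)),
        )


def _design(froh, covariates) -> tuple[pd.DataFrame, list[str]]:
    X = pd.DataFrame({"froh": np.asarray(froh, dtype=float)})
    dropped = []
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        for c in cov.columns:
            col = cov[c].to_numpy(dtype=float)
            if np.ptp(col) == 0:
                dropped.append(str(c))
            else:
                X[str(c)] = col
    X.insert(0, "const", 1.0)
    return X, dropped


def _check_rank(X: pd.DataFrame) -> None:
    M = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(M)
    if rank < M.shape[1]:
        # name a minimal offending column by leave-one-out rank
        for j, name in enumerate(X.columns):
            sub = np.delete(M, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                raise ConfigError(f"collinear design column: {name!r}")
        raise ConfigError("rank-deficient design matrix")


def fit_glm_association(
    y,
    froh,
    covariates: pd.DataFrame | None = None,
    family: str = "binomial",
    phenotype: str = "phenotype",
    cohort: str = "cohort",
) -> AssociationResult:
    """Fit phenotype ~ F_ROH + covariates by maximum likelihood (IRLS for
    binomial, least squares for gaussian); Wald inference on the F_ROH
    coefficient."""
    y = np.asarray(y, dtype=float)
    froh = np.asarray(froh, dtype=float)
    if np.any(~np.isfinite(froh)):
        raise ConfigError("missing/non-finite froh values")
    if family not in ("binomial", "gaussian"):
        raise ConfigError(f"unknown family {family!r}")
    X, _ = _design(froh, covariates)
    _check_rank(X)
    fam = sm.families.Binomial() if family == "binomial" else sm.families.Gaussian()
    model = sm.GLM(y, X, family=fam)
    res = model.fit(maxiter=100)
    if family == "binomial" and not res.converged:
        raise PipelineError(
            "binomial GLM did not converge (possible separation); "
            f"deviance trace tail: {getattr(res, 'fit_history', {}).get('deviance', [])[-5:]}"
        )
    return AssociationResult(
        phenotype=phenotype,
        cohort=cohort,
        beta=float(res.params["froh"]),
        se=float(res.bse["froh"]),
        p=float(res.pvalues["froh"]),
        n=len(y),
        n_cases=int(y.sum()) if family == "binomial" else None,
        family=family,
    )


@dataclass
class MetaResult:
    """Inverse-variance-weighted fixed-effect pooled estimate."""

    beta: float
    se: float
    p: float
    cochran_q: float
    df: int
    p_het: float
    inputs: list[tuple[float, float]] = field(default_factory=list)

    @property
    def or_at_0625(self) -> float:
        return float(np.exp(FIRST_COUSIN_FROH * self.beta))


def ivw_meta(results) -> MetaResult:
    """Fixed-effect IVW pooling of (beta, se) pairs with Cochran's Q
    heterogeneity test.

    Accepts ``AssociationResult`` objects or plain (beta, se) tuples.
    """
    pairs = [
        (r.beta, r.se) if hasattr(r, "beta") else (float(r[0]), float(r[1]))
        for r in results
    ]
    if len(pairs) < 2:
        raise ConfigError("meta-analysis needs at least 2 studies")
    betas = np.array([b for b, _ in pairs])
    ses = np.array([s for _, s in pairs])
    if np.any(ses <= 0):
        raise ConfigError("all standard errors must be > 0")
    w = 1.0 / ses**2
    beta = float((w * betas).sum() / w.sum())
    se = float(w.sum() ** -0.5)
    z = beta / se
    q = float(((betas - beta) ** 2 * w).sum())
    df = len(pairs) - 1
    return MetaResult(
        beta=beta,
        se=se,
        p=float(2 * stats.norm.sf(abs(z))),
        cochran_q=q,
        df=df,
        p_het=float(stats.chi2.sf(q, df)),
        inputs=pairs,
    )


def adjust_multiplicity(
    pvals, m: int | None = None, fdr_q: float = 0.05, alpha: float = 0.05
) -> pd.DataFrame:
    """Benjamini-Hochberg (step-up at ``fdr_q`` over ``m`` tests) and
    Bonferroni (``alpha``/``m``) significance flags.

    ``m`` defaults to ``len(pvals)`` and may exceed it (tests run but not
    reported); it may not be smaller.
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ConfigError("p-values must be in (0, 1]")
    if m is None:
        m = len(p)
    if m < len(p):
        raise ConfigError(f"m={m} smaller than number of p-values ({len(p)})")
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    thresh = fdr_q * np.arange(1, len(p) + 1) / m
    passing = np.flatnonzero(ranked <= thresh)
    bh = np.zeros(len(p), dtype=bool)
    if passing.size:
        bh[order[: passing[-1] + 1]] = True
    return pd.DataFrame(
        {
            "p": p,
            "significant_fdr": bh,
            "significant_bonferroni": p < alpha / m,
        }
    )


@dataclass
class TrendResult:
    """Quintile log(OR) trend over residualized F_ROH bins."""

    log_or: np.ndarray  # per bin, reference bin fixed at 0
    se: np.ndarray
    bin_index: np.ndarray
    slope: float
    slope_se: float
    slope_p: float


def residualize(froh, covariates: pd.DataFrame | None) -> np.ndarray:
    """Least-squares residuals of F_ROH on covariates (plus intercept)."""
    froh = np.asarray(froh, dtype=float)
    X, _ = _design(np.zeros(len(froh)), covariates)
    X = X.drop(columns="froh")
    beta, *_ = np.linalg.lstsq(X.to_numpy(), froh, rcond=None)
    return froh - X.to_numpy() @ beta


def froh_quintile_trend(
    y,
    froh,
    covariates: pd.DataFrame | None = None,
    bin_edges: np.ndarray | None = None,
) -> TrendResult:
    """Residualize F_ROH, bin it (quintiles by default, or explicit
    reference-cohort edges), fit a logistic model with bin indicators
    (lowest bin = reference), and IVW-regress log(OR) on bin index.

    ``bin_edges`` lets edges defined on one reference cohort be applied to
    all cohorts.
    """
    y = np.asarray(y, dtype=float)
    resid = residualize(froh, covariates)
    explicit_edges = bin_edges is not None
    if bin_edges is None:
        bin_edges = np.quantile(resid, [0.2, 0.4, 0.6, 0.8])
    bins = np.searchsorted(np.asarray(bin_edges, dtype=float), resid, side="right")
    occupied = np.unique(bins)
    if occupied.size < 2:
        raise PipelineError("fewer than 2 occupied F_ROH bins")
    if explicit_edges and occupied[0] != 0:
        raise PipelineError("empty reference (lowest) bin under the given edges")
    ref = occupied[0]
    X = pd.DataFrame({"const": np.ones(len(y))})
    if covariates is not None:
        for c in pd.DataFrame(covariates).columns:
            col = pd.DataFrame(covariates)[c].to_numpy(dtype=float)
            if np.ptp(col) != 0:
                X[str(c)] = col
    for b in occupied[1:]:
        X[f"bin{b}"] = (bins == b).astype(float)
    res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
    log_or = np.array([0.0] + [res.params[f"bin{b}"] for b in occupied[1:]])
    se = np.array([0.0] + [res.bse[f"bin{b}"] for b in occupied[1:]])
    # IVW linear regression of log(OR) on bin index using per-bin SEs;
    # reference bin has no sampling error term and is anchored at 0.
    w = 1.0 / np.where(se > 0, se, se[se > 0].min() if np.any(se > 0) else 1.0) ** 2
    A = np.column_stack((np.ones(len(occupied)), occupied.astype(float)))
    WA = A * w[:, None]
    cov = np.linalg.inv(A.T @ WA)
    coef = cov @ (WA.T @ log_or)
    slope, slope_se = float(coef[1]), float(np.sqrt(cov[1, 1]))
    return TrendResult(
        log_or=log_or,
        se=se,
        bin_index=occupied,
        slope=slope,
        slope_se=slope_se,
        slope_p=float(2 * stats.norm.sf(abs(slope / slope_se))),
    )


def prune_relatives(edges, samples=None) -> set:
    """Greedy relatedness pruning: repeatedly drop the sample with the most
    remaining relatives (ties by sample-id order) until no related pair
    remains; returns the retained sample set.
    """
    adj: dict = {}
    for a, b in edges:
        if a == b:
            raise ConfigError(f"self-edge for sample {a!r}")
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    retained = set(adj)
    if samples is not None:
        unknown = set(adj) - set(samples)
        if unknown:
            raise ConfigError(f"edges reference unknown samples: {sorted(unknown)}")
        retained = set(samples)
    while True:
        degrees = {s: len(adj.get(s, set()) & retained) for s in retained}
        worst = max(degrees.values(), default=0)
        if worst == 0:
            return retained
        victim = min(s for s, d in degrees.items() if d == worst)
        retained.discard(victim)
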