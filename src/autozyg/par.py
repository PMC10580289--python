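"""Population-attributable risk (PAR) of autozygosity due to consanguinity.

Autozygosity is discretized into the pedigree expectations for offspring of
first cousins (F_ROH = 0.0625) and of second cousins / first cousins once
removed (F_ROH = 0.015625, printed as 0.01562).  Given the odds ratio per
unit F_ROH for a disease, the OR at each level is converted to a risk ratio
using the baseline disease prevalence among individuals with unrelated
parents, and the two Levin-form PAR terms are summed:

    PAR_l = 100 * ( P2*(RR_0.0156 - 1) / (P2*(RR_0.0156 - 1) + 1)
                  + P1*(RR_0.0625 - 1) / (P1*(RR_0.0625 - 1) + 1) )

Confidence intervals propagate the OR CI bounds through the monotone PAR
map; a parametric bootstrap on beta ~ Normal(beta, se) is available as an
alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigError
from .pedigree import expected_inbreeding

__all__ = [
    "ConsanguinityPrevalence",
    "RiskEstimate",
    "PARResult",
    "expected_froh",
    "or_to_rr",
    "single_class_par",
    "par_from_prevalence",
    "prs_par",
    "informative_genotype_count",
]

FIRST_COUSIN_FROH = 0.0625
SECOND_COUSIN_FROH = 0.015625


def expected_froh(union: str) -> float:
    """Expected F_ROH (pedigree inbreeding coefficient by path counting)
    for a union class: sibling 1/4, avuncular 1/8, first cousins 1/16,
    1C1R 1/32, second cousins 1/64, unrelated 0."""
    try:
        return expected_inbreeding(union)
    except KeyError as exc:
        raise ConfigError(str(exc)) from None


def or_to_rr(or_: float, pd: float) -> float:
    """Risk ratio from odds ratio: RR = OR / (1 - pd + pd*OR), where ``pd``
    is disease prevalence in unexposed (unrelated-parents) individuals."""
    if or_ <= 0:
        raise ConfigError("odds ratio must be > 0")
    if not 0 < pd < 1:
        raise ConfigError("pd must be in (0, 1)")
    return or_ / (1.0 - pd + pd * or_)


def single_class_par(prevalence: float, rr: float) -> float:
    """Levin PAR (%) for one exposure class: 100*P*(RR-1)/(P*(RR-1)+1)."""
    if prevalence < 0:
        raise ConfigError("prevalence must be >= 0")
    x = prevalence * (rr - 1.0)
    return 100.0 * x / (x + 1.0)


@dataclass(frozen=True)
class ConsanguinityPrevalence:
    """Fractions of a population with first-cousin (P1) and second-cousin /
    1C1R (P2) parents."""

    population: str
    p1: float
    p2: float

    def __post_init__(self) -> None:
        if self.p1 < 0 or self.p2 < 0 or self.p1 + self.p2 > 1:
            raise ConfigError("need P1, P2 >= 0 and P1 + P2 <= 1")


@dataclass(frozen=True)
class RiskEstimate:
    """Disease risk per unit F_ROH with baseline prevalence.

    ``beta`` is log-odds per unit F_ROH, so OR at F is exp(F * beta);
    ``beta_ci95`` its Wald interval; ``pd`` the disease prevalence in
    unexposed individuals.
    """

    beta: float
    beta_ci95: tuple[float, float]
    pd: float

    def __post_init__(self) -> None:
        if not 0 < self.pd < 1:
            raise ConfigError("pd must be in (0, 1)")

    @classmethod
    def from_or_at_0625(cls, or_: float, ci95: tuple[float, float], pd: float):
        b = np.log(or_) / FIRST_COUSIN_FROH
        lo = np.log(ci95[0]) / FIRST_COUSIN_FROH
        hi = np.log(ci95[1]) / FIRST_COUSIN_FROH
        return cls(float(b), (float(lo), float(hi)), pd)

    def or_at(self, froh: float) -> float:
        return float(np.exp(froh * self.beta))


@dataclass
class PARResult:
    population: str
    pd: float
    par_percent: float
    ci95: tuple[float, float]
    par_first_cousin: float
    par_second_cousin: float


def _combined_par(prev: ConsanguinityPrevalence, beta: float, pd: float) -> tuple[float, float, float]:
    rr1 = or_to_rr(float(np.exp(FIRST_COUSIN_FROH * beta)), pd)
    rr2 = or_to_rr(float(np.exp(SECOND_COUSIN_FROH * beta)), pd)
    par1 = single_class_par(prev.p1, rr1)
    par2 = single_class_par(prev.p2, rr2)
    return par1 + par2, par1, par2


def par_from_prevalence(
    prev: ConsanguinityPrevalence,
    risk: RiskEstimate,
    ci_method: str = "plugin",
    n_boot: int = 2000,
    seed: int | None = 0,
) -> PARResult:
    """Combined two-class PAR with CI.

    ``plugin`` propagates the beta CI bounds through the (monotone in beta)
    PAR map; ``bootstrap`` resamples beta ~ Normal(beta, se) with the SE
    implied by the Wald interval.
    """
    total, par1, par2 = _combined_par(prev, risk.beta, risk.pd)
    lo_b, hi_b = risk.beta_ci95
    if ci_method == "plugin":
        lo = _combined_par(prev, lo_b, risk.pd)[0]
        hi = _combined_par(prev, hi_b, risk.pd)[0]
    elif ci_method == "bootstrap":
        se = (hi_b - lo_b) / (2 * 1.959963984540054)
        rng = np.random.default_rng(seed)
        draws = rng.normal(risk.beta, se, n_boot)
        pars = np.array([_combined_par(prev, b, risk.pd)[0] for b in draws])
        lo, hi = np.percentile(pars, [2.5, 97.5])
    else:
        raise ConfigError(f"unknown ci_method {ci_method!r}")
    return PARResult(
        population=prev.population,
        pd=risk.pd,
        par_percent=total,
        ci95=(float(min(lo, hi)), float(max(lo, hi))),
        par_first_cousin=par1,
        par_second_cousin=par2,
    )


def prs_par(bin_or, pd: float, bin_prevalence: float = 0.01) -> np.ndarray:
    """Cumulative PAR over top polygenic-score percentile bins.

    ``bin_or``: odds ratios for disjoint top-percentile slices (top 1%,
    next 1%, ...); each slice holds ``bin_prevalence`` of the population.
    Returns the cumulative PAR curve over top-k% for k = 1..len(bin_or).
    """
    ors = np.asarray(bin_or, dtype=float)
    if ors.size == 0:
        raise ConfigError("empty OR vector")
    pars = np.array(
        [single_class_par(bin_prevalence, or_to_rr(o, pd)) for o in ors]
    )
    return np.cumsum(pars)


def informative_genotype_count(
    n: int, p: float, f: float, architecture: str = "recessive"
) -> float:
    """Expected number of informative genotypes at a locus of frequency
    ``p`` in a cohort of ``n`` with mean inbreeding ``f``.

    Recessive loci: n*((1-F)p^2 + F*p) alternate homozygotes (reduces to
    n*p^2 at F=0); additive loci: n*p carriers regardless of F.
    """
    if not 0 <= p <= 1:
        raise ConfigError("p must be in [0, 1]")
    if not 0 <= f <= 1:
        raise ConfigError("f must be in [0, 1]")
    if architecture == "additive":
        return n * p
    if architecture == "recessive":
        return n * ((1.0 - f) * p * p + f * p)
    raise ConfigError(f"unknown architecture {architecture!r}")
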