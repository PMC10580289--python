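"""Synthetic cohorts: founder haplotypes, gene-dropping, phenotypes.

The generator emulates the data structures the downstream autozygosity
analyses assume:

* founder haplotype panels with a configurable minor-allele-frequency
  spectrum (sites independent, i.e. no background LD);
* offspring of specified parental-relatedness union classes produced by
  recombination (Poisson crossovers, no interference, sex-averaged map) and
  Mendelian segregation, with the realized autozygous genome fraction
  tracked exactly through identity-by-descent mosaics;
* binary/quantitative phenotypes under a logistic/linear model in F_ROH
  with optional covariates and consanguinity-coupled confounders;
* sibling pairs whose F_ROH values differ by Normal(0, 0.002), the scale
  observed between real sibs.

All randomness flows from explicit ``numpy.random.Generator`` streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import CapacityError, ConfigError, NumericalError, StructuralError
from .genome import GeneticMap, default_genome
from .pedigree import UnionClass, get_union_class

__all__ = [
    "FounderPanel",
    "PhenotypeModel",
    "make_maf_sampler",
    "generate_founders",
    "drop_gamete",
    "simulate_union_offspring",
    "simulate_autozygosity",
    "simulate_phenotypes",
    "simulate_sibling_cohort",
    "truncated_normal_sampler",
    "truncated_lognormal_sampler",
]


# ---------------------------------------------------------------------------
# samplers

def make_maf_sampler(spec) -> Callable[[int, np.random.Generator], np.ndarray]:
    """Turn a MAF spec into ``f(n, rng) -> frequencies in (0, 1)``.

    Accepted specs: a float in (0,1); ``("uniform", lo, hi)``;
    ``("beta", a, b)`` (rescaled into [0.01, 0.5]); or a callable.
    """
    if callable(spec):
        return spec
    if isinstance(spec, (int, float)):
        p = float(spec)
        if not 0.0 < p < 1.0:
            raise ConfigError(f"fixed allele frequency must be in (0,1), got {p}")
        return lambda n, rng: np.full(n, p)
    if isinstance(spec, (tuple, list)) and len(spec) == 3:
        kind, a, b = spec
        a, b = float(a), float(b)
        if kind == "uniform":
            if not (0.0 < a <= b < 1.0):
                raise ConfigError(f"uniform MAF bounds invalid: ({a}, {b})")
            return lambda n, rng: rng.uniform(a, b, n)
        if kind == "beta":
            if a <= 0 or b <= 0:
                raise ConfigError(f"beta MAF parameters must be positive: ({a}, {b})")
            return lambda n, rng: 0.01 + 0.49 * rng.beta(a, b, n)
    raise ConfigError(f"unrecognized MAF sampler spec: {spec!r}")


def truncated_normal_sampler(mean: float, sd: float, low: float = 0.0):
    """Normal(mean, sd) truncated below at ``low`` (rejection-free via
    inverse CDF)."""
    from scipy import stats

    if sd < 0:
        raise ConfigError("sd must be >= 0")

    def sample(n: int, rng: np.random.Generator) -> np.ndarray:
        if sd == 0:
            return np.full(n, max(mean, low))
        a = (low - mean) / sd
        u = rng.uniform(stats.norm.cdf(a), 1.0, n)
        return mean + sd * stats.norm.ppf(u)

    return sample


def truncated_lognormal_sampler(mu: float, sigma: float, low: float, high: float):
    """Lognormal(mu, sigma) restricted to [low, high] via inverse CDF."""
    from scipy import stats

    if not 0 < low < high:
        raise ConfigError("truncation bounds must satisfy 0 < low < high")

    def sample(n: int, rng: np.random.Generator) -> np.ndarray:
        lo = stats.norm.cdf((np.log(low) - mu) / sigma)
        hi = stats.norm.cdf((np.log(high) - mu) / sigma)
        u = rng.uniform(lo, hi, n)
        return np.exp(mu + sigma * stats.norm.ppf(u))

    return sample


# ---------------------------------------------------------------------------
# founder panels

@dataclass
class FounderPanel:
    """Phased founder haplotypes over independent biallelic sites.

    ``haplotypes`` is (2H, S) in {0,1}; founder ``i`` owns rows
    ``2i`` and ``2i+1``.  ``sites`` has columns chrom, pos_bp, pos_cm, af.
    """

    haplotypes: np.ndarray
    sites: pd.DataFrame
    gmap: GeneticMap

    def __post_init__(self) -> None:
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[0] % 2:
            raise StructuralError("haplotype matrix must be (2H, S)")
        if self.haplotypes.shape[1] != len(self.sites):
            raise StructuralError("site table does not match haplotype matrix")

    @property
    def n_founders(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]


def generate_founders(
    n_founders: int,
    sites_per_chrom: int,
    n_chroms: int = 22,
    maf_sampler=("uniform", 0.05, 0.5),
    map_rate: float = 1.0,
    chrom_length_bp: int = 125_000_000,
    seed: int | None = None,
    gmap: GeneticMap | None = None,
) -> FounderPanel:
    """Simulate a phased founder panel with evenly spaced markers.

    Sites are spaced uniformly along each chromosome; per-site allele
    frequencies come from ``maf_sampler`` and haplotype alleles are drawn
    independently (no LD).  Deterministic given ``seed``.
    """
    if n_founders < 2:
        raise ConfigError("need at least 2 founders")
    if sites_per_chrom < 1:
        raise ConfigError("sites_per_chrom must be >= 1")
    sampler = make_maf_sampler(maf_sampler)
    rng = np.random.default_rng(seed)
    if gmap is None:
        gmap = GeneticMap.uniform(n_chroms, chrom_length_bp, map_rate)

    frames = []
    for chrom in gmap.chromosomes:
        length = gmap.length_bp(chrom)
        pos = np.linspace(1, length, sites_per_chrom, dtype=np.int64)
        pos = np.unique(pos)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos_bp": pos,
                    "pos_cm": gmap.bp_to_cm(chrom, pos),
                }
            )
        )
    sites = pd.concat(frames, ignore_index=True)
    sites["af"] = sampler(len(sites), rng)
    if np.any((sites["af"] <= 0) | (sites["af"] >= 1)):
        raise ConfigError("MAF sampler produced frequencies outside (0, 1)")
    haps = (
        rng.uniform(size=(2 * n_founders, len(sites))) < sites["af"].to_numpy()
    ).astype(np.uint8)
    return FounderPanel(haps, sites, gmap)


# ---------------------------------------------------------------------------
# recombination and gene dropping

def _sample_crossovers_bp(
    gmap: GeneticMap, chrom: str, rng: np.random.Generator
) -> np.ndarray:
    """Crossover positions (bp, sorted) on one chromosome: count is
    Poisson(length_cM / 100), positions uniform in genetic distance."""
    length_cm = gmap.length_cm(chrom)
    n_x = rng.poisson(length_cm / 100.0) if length_cm > 0 else 0
    if n_x == 0:
        return np.empty(0)
    cuts_cm = np.sort(rng.uniform(0.0, length_cm, n_x))
    return gmap.cm_to_bp(chrom, cuts_cm)


class _Mosaic:
    """Haploid chromosome as a founder-haplotype mosaic.

    ``ends`` are segment end positions in bp (last equals the chromosome
    end); segment i covers (ends[i-1], ends[i]] with source ``src[i]``.
    """

    __slots__ = ("ends", "src")

    def __init__(self, ends: np.ndarray, src: np.ndarray) -> None:
        self.ends = ends
        self.src = src

    @classmethod
    def uniform(cls, length_bp: float, hap_id: int) -> "_Mosaic":
        return cls(np.array([float(length_bp)]), np.array([hap_id]))

    def slice_sources(self, lo: float, hi: float):
        """Sub-mosaic over the interval (lo, hi]."""
        i0 = int(np.searchsorted(self.ends, lo, side="left"))
        if lo >= self.ends[i0]:
            i0 += 1
        i1 = int(np.searchsorted(self.ends, hi, side="left"))
        ends = self.ends[i0 : i1 + 1].copy()
        ends[-1] = hi
        return ends, self.src[i0 : i1 + 1]

    def lookup(self, pos: np.ndarray) -> np.ndarray:
        """Source haplotype id at each bp position."""
        idx = np.searchsorted(self.ends, pos, side="left")
        return self.src[idx]


def _recombine(
    m0: _Mosaic, m1: _Mosaic, cuts_bp: np.ndarray, start: int
) -> _Mosaic:
    """Splice two parental mosaics at the given crossover positions,
    starting from mosaic ``start``."""
    length = float(m0.ends[-1])
    if cuts_bp.size == 0:
        return (m0, m1)[start]
    bounds = np.concatenate(([0.0], cuts_bp, [length]))
    ends_parts, src_parts = [], []
    active = start
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if hi <= lo:
            active ^= 1
            continue
        e, s = (m0, m1)[active].slice_sources(lo, hi)
        ends_parts.append(e)
        src_parts.append(s)
        active ^= 1
    ends = np.concatenate(ends_parts)
    src = np.concatenate(src_parts)
    # merge adjacent segments with identical source
    keep = np.ones(len(src), dtype=bool)
    keep[:-1] = src[1:] != src[:-1]
    return _Mosaic(ends[keep], src[keep])


def _drop_gamete_mosaic(
    parent: dict[str, tuple[_Mosaic, _Mosaic]],
    gmap: GeneticMap,
    rng: np.random.Generator,
    chroms: list[str] | None = None,
    lens_cm: np.ndarray | None = None,
) -> dict[str, _Mosaic]:
    """One meiosis: per chromosome, recombine the parent's two homologs.

    Mosaics are immutable by convention, so chromosomes without crossovers
    pass a parental homolog through by reference.
    """
    if chroms is None:
        chroms = list(parent)
    if lens_cm is None:
        lens_cm = np.array([gmap.length_cm(c) for c in chroms])
    counts = rng.poisson(lens_cm / 100.0)
    starts = rng.integers(2, size=len(chroms))
    gamete = {}
    for k, chrom in enumerate(chroms):
        m0, m1 = parent[chrom]
        if counts[k] == 0:
            gamete[chrom] = (m0, m1)[starts[k]]
        else:
            cuts_cm = np.sort(rng.uniform(0.0, lens_cm[k], counts[k]))
            cuts = gmap.cm_to_bp(chrom, cuts_cm)
            gamete[chrom] = _recombine(m0, m1, cuts, int(starts[k]))
    return gamete


def drop_gamete(
    parent_haplotypes: np.ndarray,
    sites: pd.DataFrame,
    gmap: GeneticMap,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample one gamete from a (2, S) pair of parental haplotypes.

    Crossover counts are Poisson(cM length / 100) per chromosome with
    positions uniform in genetic distance (no interference); chromosomes
    assort independently.
    """
    parent_haplotypes = np.asarray(parent_haplotypes)
    if parent_haplotypes.shape != (2, len(sites)):
        raise StructuralError(
            "parent haplotypes must be (2, n_sites) over the given site table"
        )
    gamete = np.empty(len(sites), dtype=parent_haplotypes.dtype)
    for chrom, idx in sites.groupby("chrom", sort=False).indices.items():
        cuts = _sample_crossovers_bp(gmap, chrom, rng)
        start = int(rng.integers(2))
        pos = sites["pos_bp"].to_numpy()[idx]
        which = (start + np.searchsorted(cuts, pos)) % 2
        gamete[idx] = parent_haplotypes[which, idx]
    return gamete


def _gene_drop_focal(
    union: UnionClass,
    gmap: GeneticMap,
    founder_hap_ids: Sequence[int],
    rng: np.random.Generator,
    _founder_cache: dict | None = None,
) -> dict[str, tuple[_Mosaic, _Mosaic]]:
    """Drop genes through the union's pedigree; return the focal child's
    diploid mosaics keyed by chromosome."""
    ped = union.pedigree
    founders = ped.founders
    chroms = gmap.chromosomes
    lens_cm = np.array([gmap.length_cm(c) for c in chroms])
    cache = _founder_cache if _founder_cache is not None else {}

    def founder_hap(c: str, h: int) -> _Mosaic:
        key = (c, h)
        if key not in cache:
            cache[key] = _Mosaic.uniform(gmap.length_bp(c), h)
        return cache[key]

    hap_of = {f: (founder_hap_ids[2 * k], founder_hap_ids[2 * k + 1])
              for k, f in enumerate(founders)}
    diploid: list[dict[str, tuple[_Mosaic, _Mosaic]]] = []
    for i in range(ped.n_individuals):
        if ped.is_founder(i):
            h0, h1 = hap_of[i]
            diploid.append(
                {c: (founder_hap(c, h0), founder_hap(c, h1)) for c in chroms}
            )
        else:
            p, m = ped.parents[i]
            g_p = _drop_gamete_mosaic(diploid[p], gmap, rng, chroms, lens_cm)
            g_m = _drop_gamete_mosaic(diploid[m], gmap, rng, chroms, lens_cm)
            diploid.append({c: (g_p[c], g_m[c]) for c in chroms})
    g_f = _drop_gamete_mosaic(diploid[union.father], gmap, rng, chroms, lens_cm)
    g_m = _drop_gamete_mosaic(diploid[union.mother], gmap, rng, chroms, lens_cm)
    return {c: (g_f[c], g_m[c]) for c in chroms}


def _autozygous_fraction(focal: Mapping[str, tuple[_Mosaic, _Mosaic]]) -> float:
    """Fraction of the genome where the two homologs descend from the same
    founder haplotype (identity by descent)."""
    ibd = 0.0
    total = 0.0
    for m0, m1 in focal.values():
        if m0 is m1:
            ibd += float(m0.ends[-1])
            total += float(m0.ends[-1])
            continue
        ends = np.union1d(m0.ends, m1.ends)
        s0 = m0.lookup(ends)
        s1 = m1.lookup(ends)
        lengths = np.diff(np.concatenate(([0.0], ends)))
        ibd += float(lengths[s0 == s1].sum())
        total += float(ends[-1])
    return ibd / total


def _genotypes_at_sites(
    focal: Mapping[str, tuple[_Mosaic, _Mosaic]],
    panel: FounderPanel,
    site_idx_by_chrom: Mapping[str, np.ndarray],
) -> np.ndarray:
    geno = np.empty(panel.n_sites, dtype=np.int8)
    pos_all = panel.sites["pos_bp"].to_numpy()
    haps = panel.haplotypes
    for chrom, idx in site_idx_by_chrom.items():
        m0, m1 = focal[chrom]
        pos = pos_all[idx].astype(float)
        a0 = haps[m0.lookup(pos), idx]
        a1 = haps[m1.lookup(pos), idx]
        geno[idx] = a0 + a1
    return geno


def simulate_autozygosity(
    union: str | UnionClass,
    gmap: GeneticMap | None = None,
    n: int = 1000,
    seed: int | None = None,
) -> np.ndarray:
    """Realized autozygous genome fractions for ``n`` focal offspring of a
    union class (identity-by-descent bookkeeping only; no marker genotypes).

    The mean over replicates converges to the pedigree's path-counting
    inbreeding expectation.
    """
    if isinstance(union, str):
        union = get_union_class(union)
    if gmap is None:
        gmap = default_genome()
    rng = np.random.default_rng(seed)
    nf = union.n_founders
    hap_ids = np.arange(2 * nf)
    cache: dict = {}
    out = np.empty(n)
    for r in range(n):
        focal = _gene_drop_focal(union, gmap, hap_ids, rng, cache)
        out[r] = _autozygous_fraction(focal)
    return out


def simulate_union_offspring(
    panel: FounderPanel,
    union: str | UnionClass,
    n: int,
    seed: int | None = None,
    sample_prefix: str | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Gene-drop ``n`` focal offspring of a union class through the panel.

    Founders are drawn without replacement within each pedigree and with
    replacement across pedigrees.  Returns the (n, S) diploid genotype
    matrix (0/1/2 alternate-allele counts) and a truth table with the
    realized autozygous fraction per offspring.
    """
    if isinstance(union, str):
        union = get_union_class(union)
    if n < 1:
        raise ConfigError("n must be >= 1")
    nf = union.n_founders
    if panel.n_founders < nf:
        raise CapacityError(
            f"panel has {panel.n_founders} founders; union class "
            f"{union.label!r} needs {nf} per pedigree"
        )
    rng = np.random.default_rng(seed)
    gmap = panel.gmap
    site_idx = dict(panel.sites.groupby("chrom", sort=False).indices)
    prefix = sample_prefix or union.label
    genos = np.empty((n, panel.n_sites), dtype=np.int8)
    cache: dict = {}
    truth = []
    for r in range(n):
        founders = rng.choice(panel.n_founders, size=nf, replace=False)
        hap_ids = np.column_stack((2 * founders, 2 * founders + 1)).ravel()
        focal = _gene_drop_focal(union, gmap, hap_ids, rng, cache)
        genos[r] = _genotypes_at_sites(focal, panel, site_idx)
        truth.append(
            {
                "sample_id": f"{prefix}_{r}",
                "union_class": union.label,
                "realized_autozygous_fraction": _autozygous_fraction(focal),
            }
        )
    return genos, pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# phenotypes

@dataclass
class PhenotypeModel:
    """Phenotype-generating model: logistic (binary) or linear
    (quantitative) in F_ROH plus covariates.

    ``froh_coefficient`` is per unit F_ROH (log-odds for binary), so an
    odds ratio of R at F_ROH = 0.0625 corresponds to log(R)/0.0625.
    """

    kind: str = "binary"
    intercept: float = 0.0
    froh_coefficient: float = 0.0
    covariate_coefficients: dict[str, float] = field(default_factory=dict)
    residual_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "quantitative"):
            raise ConfigError(f"unknown phenotype kind {self.kind!r}")
        if self.kind == "quantitative" and self.residual_sd < 0:
            raise ConfigError("residual_sd must be >= 0")

    @classmethod
    def binary_from_or(
        cls, or_at_0625: float, intercept: float = 0.0, **kw
    ) -> "PhenotypeModel":
        """Binary model with the log-odds slope implied by an odds ratio at
        F_ROH = 0.0625."""
        return cls(
            kind="binary",
            intercept=intercept,
            froh_coefficient=float(np.log(or_at_0625) / 0.0625),
            **kw,
        )


def simulate_phenotypes(
    froh: np.ndarray,
    covariates: pd.DataFrame | None,
    model: PhenotypeModel,
    seed: int | None = None,
) -> np.ndarray:
    """Draw phenotypes given F_ROH and covariates under ``model``."""
    froh = np.asarray(froh, dtype=float)
    if np.any((froh < 0) | (froh > 1)):
        raise ConfigError("froh values must lie in [0, 1]")
    eta = model.intercept + model.froh_coefficient * froh
    if model.covariate_coefficients:
        if covariates is None:
            raise ConfigError("model references covariates but none supplied")
        if len(covariates) != len(froh):
            raise StructuralError("covariates not row-aligned with froh")
        for name, coef in model.covariate_coefficients.items():
            eta = eta + coef * covariates[name].to_numpy(dtype=float)
    bad = ~np.isfinite(eta)
    if np.any(bad):
        raise NumericalError(
            f"non-finite linear predictor at row {int(np.flatnonzero(bad)[0])}"
        )
    rng = np.random.default_rng(seed)
    if model.kind == "binary":
        p = 1.0 / (1.0 + np.exp(-eta))
        return (rng.uniform(size=len(eta)) < p).astype(np.int8)
    return eta + rng.normal(0.0, model.residual_sd, size=len(eta))


def simulate_sibling_cohort(
    n_pairs: int,
    index_froh_sampler=None,
    within_sd: float = 0.002,
    seed: int | None = None,
) -> pd.DataFrame:
    """Sibling-pair F_ROH table: sib 2's value is Normal(sib 1, within_sd)
    truncated at 0.

    The default index sampler is Normal(0.0037, 0.0050) truncated at 0,
    matching the F_ROH moments of a large outbred European-ancestry cohort.
    """
    if within_sd < 0:
        raise ConfigError("within_sd must be >= 0")
    if index_froh_sampler is None:
        index_froh_sampler = truncated_normal_sampler(0.0037, 0.0050)
    rng = np.random.default_rng(seed)
    f1 = np.asarray(index_froh_sampler(n_pairs, rng), dtype=float)
    f2 = np.maximum(f1 + rng.normal(0.0, within_sd, n_pairs), 0.0)
    fam = np.repeat(np.arange(n_pairs), 2)
    return pd.DataFrame(
        {
            "family_id": [f"fam{i}" for i in fam],
            "sample_id": [f"fam{i}_sib{s}" for i, s in zip(fam, [1, 2] * n_pairs)],
            "sib_index": np.tile([1, 2], n_pairs),
            "froh": np.column_stack((f1, f2)).ravel(),
        }
    )
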