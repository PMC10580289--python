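"""Runs of homozygosity: site QC, window-based calling, and F_ROH.

The caller reproduces the PLINK 1.9 ``--homozyg`` scanning semantics with
the parameter set used for SNP-array consanguinity work:
50-SNP sliding windows, a window "hit" allows at most 1 heterozygote and 5
missing calls, a SNP qualifies when at least 5% of its overlapping windows
are hits, and maximal runs of qualifying SNPs become segments subject to
minimum 50 SNPs, minimum 1,500 kb, a 1,000 kb gap split, and a maximum of
50 kb per SNP density.

F_ROH is the summed segment length divided by a genome-length denominator
(2.7e9 bp, the approximate autosomal genome, for real data; synthetic
mini-genomes pass their own total length).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigError, PipelineError, StructuralError
from .genome import GeneticMap

__all__ = [
    "ROHCallParams",
    "ROHSegment",
    "site_qc",
    "hwe_exact_p",
    "call_roh",
    "compute_froh",
    "froh_per_sample",
    "AUTOSOMAL_GENOME_BP",
]

AUTOSOMAL_GENOME_BP = 2_700_000_000


@dataclass(frozen=True)
class ROHCallParams:
    """PLINK 1.9 ``--homozyg`` parameters (defaults as used on array data)."""

    window_snp: int = 50
    min_snp: int = 50
    min_kb: float = 1500.0
    max_gap_kb: float = 1000.0
    density_kb_per_snp: float = 50.0
    window_missing: int = 5
    window_het: int = 1
    window_hit_threshold: float = 0.05

    def __post_init__(self) -> None:
        if min(self.window_snp, self.min_snp, self.window_missing, self.window_het) < 0:
            raise ConfigError("counts must be >= 0")
        if self.min_kb <= 0:
            raise ConfigError("min_kb must be > 0")
        if not 0 < self.window_hit_threshold <= 1:
            raise ConfigError("window_hit_threshold must be in (0, 1]")


@dataclass(frozen=True)
class ROHSegment:
    """One called homozygous segment (1-based inclusive coordinates)."""

    sample_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_snps: int
    length_cm: float = 0.0

    def __post_init__(self) -> None:
        if self.end_bp < self.start_bp:
            raise ConfigError("end_bp must be >= start_bp")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


# ---------------------------------------------------------------------------
# site QC

def hwe_exact_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value (biallelic site).

    Sums the probabilities of all heterozygote counts no more likely than
    the observed one, conditional on the allele counts (the standard exact
    formulation for SNP QC).
    """
    if min(n_het, n_hom1, n_hom2) < 0:
        raise ConfigError("genotype counts must be non-negative")
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    rare = 2 * min(n_hom1, n_hom2) + n_het
    # het counts share the parity of the rare-allele count
    het_values = np.arange(rare % 2, min(rare, 2 * n - rare) + 1, 2)
    # unnormalized probabilities via the symmetric recurrence
    # P(h+2)/P(h) = 4 * hom_r(h) * hom_c(h) / ((h+2) * (h+1))
    log_probs = np.zeros(len(het_values))
    for k in range(1, len(het_values)):
        h = het_values[k - 1]
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        log_probs[k] = log_probs[k - 1] + np.log(4.0 * hom_r * hom_c) - np.log(
            (h + 2.0) * (h + 1.0)
        )
    probs = np.exp(log_probs - log_probs.max())
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(het_values, n_het)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def site_qc(
    genotypes: np.ndarray,
    sites: pd.DataFrame,
    maf_min: float = 0.05,
    hwe_p_min: float | None = None,
    hwe_subset: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.DataFrame, pd.DataFrame]:
    """Remove low-MAF sites and (optionally) exact-HWE failures.

    ``genotypes`` is (n_samples, n_sites) with values {0,1,2} and negatives
    for missing.  ``hwe_subset`` restricts the HWE test to a sample subset
    (boolean mask or index array), mirroring QC computed within one
    ancestry group.  Returns (filtered genotypes, filtered sites, report).
    """
    G = np.asarray(genotypes)
    if G.ndim != 2 or G.shape[1] != len(sites):
        raise StructuralError("genotypes must be (n_samples, n_sites)")
    valid = G >= 0
    n_called = valid.sum(axis=0)
    alt = np.where(valid, G, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, alt / (2.0 * np.maximum(n_called, 1)), 0.0)
    maf = np.minimum(p, 1.0 - p)
    drop_maf = maf < maf_min

    reasons = np.where(drop_maf, "maf", "")
    if hwe_p_min is not None:
        H = G[hwe_subset] if hwe_subset is not None else G
        hwe_p = np.ones(G.shape[1])
        for j in range(G.shape[1]):
            col = H[:, j]
            col = col[col >= 0]
            hwe_p[j] = hwe_exact_p(
                int((col == 1).sum()), int((col == 0).sum()), int((col == 2).sum())
            )
        drop_hwe = hwe_p < hwe_p_min
        reasons = np.where(
            drop_maf & drop_hwe, "maf,hwe", np.where(drop_hwe, "hwe", reasons)
        )
    removed = reasons != ""
    report = sites.loc[removed, ["chrom", "pos_bp"]].copy()
    report["maf"] = maf[removed]
    report["reason"] = reasons[removed]
    if removed.all():
        raise PipelineError("all sites removed by QC")
    keep = ~removed
    return G[:, keep], sites.loc[keep].reset_index(drop=True), report.reset_index(drop=True)


# ---------------------------------------------------------------------------
# ROH calling

def _check_sorted(sites: pd.DataFrame) -> None:
    grp = sites.groupby("chrom", sort=False)
    for chrom, pos in grp["pos_bp"]:
        if np.any(np.diff(pos.to_numpy()) <= 0):
            raise StructuralError(f"sites not strictly sorted by position on {chrom!r}")


def _qualifying_snps(
    G: np.ndarray, params: ROHCallParams
) -> np.ndarray:
    """Boolean (n_samples, n_sites) matrix of SNPs passing the window-hit
    proportion rule on one chromosome."""
    n, s = G.shape
    w = params.window_snp
    if s < w:
        return np.zeros((n, s), dtype=bool)
    het = (G == 1).astype(np.int32)
    mis = (G < 0).astype(np.int32)
    chet = np.zeros((n, s + 1), dtype=np.int32)
    cmis = np.zeros((n, s + 1), dtype=np.int32)
    np.cumsum(het, axis=1, out=chet[:, 1:])
    np.cumsum(mis, axis=1, out=cmis[:, 1:])
    n_w = s - w + 1
    hets_w = chet[:, w:] - chet[:, :n_w]
    miss_w = cmis[:, w:] - cmis[:, :n_w]
    hit = (hets_w <= params.window_het) & (miss_w <= params.window_missing)
    chit = np.zeros((n, n_w + 1), dtype=np.int32)
    np.cumsum(hit.astype(np.int32), axis=1, out=chit[:, 1:])
    j = np.arange(s)
    lo = np.maximum(0, j - w + 1)
    hi = np.minimum(n_w - 1, j)
    n_windows = hi - lo + 1
    n_hits = chit[:, hi + 1] - chit[:, lo]
    return n_hits >= params.window_hit_threshold * n_windows


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, end] index pairs (inclusive) of True runs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1)
    if mask[0]:
        starts = np.concatenate(([0], starts))
    if mask[-1]:
        ends = np.concatenate((ends, [len(mask) - 1]))
    return list(zip(starts, ends))


def call_roh(
    genotypes: np.ndarray,
    sites: pd.DataFrame,
    gmap: GeneticMap | None = None,
    params: ROHCallParams = ROHCallParams(),
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Call ROH segments for every sample.

    Returns a DataFrame with columns sample_id, chrom, start_bp, end_bp,
    n_snps, length_bp, length_kb and (if ``gmap`` given) length_cm.
    """
    G = np.asarray(genotypes)
    if G.ndim == 1:
        G = G[None, :]
    if G.shape[1] != len(sites):
        raise StructuralError("genotypes do not match site table")
    _check_sorted(sites)
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(G.shape[0])]

    records = []
    for chrom, idx in sites.groupby("chrom", sort=False).indices.items():
        pos = sites["pos_bp"].to_numpy()[idx]
        qual = _qualifying_snps(G[:, idx], params)
        gap_break = np.diff(pos) > params.max_gap_kb * 1000.0
        for si in range(G.shape[0]):
            for a, b in _runs(qual[si]):
                # split candidate run at large inter-SNP gaps
                cut_points = [a] + [
                    k + 1 for k in range(a, b) if gap_break[k]
                ] + [b + 1]
                for lo, hi in zip(cut_points[:-1], cut_points[1:]):
                    hi -= 1
                    n_snps = hi - lo + 1
                    length_bp = int(pos[hi] - pos[lo]) + 1
                    length_kb = length_bp / 1000.0
                    if (
                        n_snps >= params.min_snp
                        and length_kb >= params.min_kb
                        and length_kb / n_snps <= params.density_kb_per_snp
                    ):
                        rec = {
                            "sample_id": sample_ids[si],
                            "chrom": chrom,
                            "start_bp": int(pos[lo]),
                            "end_bp": int(pos[hi]),
                            "n_snps": int(n_snps),
                            "length_bp": length_bp,
                            "length_kb": length_kb,
                        }
                        if gmap is not None:
                            cm = gmap.bp_to_cm(chrom, [pos[lo], pos[hi]])
                            rec["length_cm"] = float(cm[1] - cm[0])
                        records.append(rec)
    cols = ["sample_id", "chrom", "start_bp", "end_bp", "n_snps", "length_bp", "length_kb"]
    if gmap is not None:
        cols.append("length_cm")
    return pd.DataFrame(records, columns=cols)


# ---------------------------------------------------------------------------
# F_ROH

def _segment_lengths(segments) -> tuple[np.ndarray, pd.DataFrame | None]:
    if isinstance(segments, pd.DataFrame):
        return segments["length_bp"].to_numpy(dtype=float), segments
    lengths = np.array([s.length_bp for s in segments], dtype=float)
    return lengths, None


def compute_froh(segments, denominator_bp: int = AUTOSOMAL_GENOME_BP) -> float:
    """F_ROH = summed segment length (bp) / genome denominator for one
    sample; values above 1 are capped with a warning."""
    if denominator_bp <= 0:
        raise ConfigError("denominator_bp must be > 0")
    lengths, df = _segment_lengths(segments)
    if df is not None and len(df):
        if df["sample_id"].nunique() > 1:
            raise ConfigError("compute_froh expects segments of one sample")
        for _, sub in df.groupby("chrom", sort=False):
            s = sub.sort_values("start_bp")
            if np.any(s["start_bp"].to_numpy()[1:] <= s["end_bp"].to_numpy()[:-1]):
                raise ConfigError("overlapping ROH segments on one chromosome")
    froh = float(lengths.sum()) / denominator_bp
    if froh > 1.0:
        warnings.warn("F_ROH exceeds 1; capping (check denominator)", stacklevel=2)
        froh = 1.0
    return froh


def froh_per_sample(
    segments: pd.DataFrame,
    sample_ids: list[str] | None = None,
    denominator_bp: int = AUTOSOMAL_GENOME_BP,
) -> pd.Series:
    """F_ROH for each sample in a multi-sample segment table; samples with
    no segments get 0."""
    sums = segments.groupby("sample_id")["length_bp"].sum() / denominator_bp
    if sample_ids is not None:
        sums = sums.reindex(sample_ids, fill_value=0.0)
    return sums.clip(upper=1.0).rename("froh")
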