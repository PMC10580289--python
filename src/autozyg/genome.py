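"""Genetic map grids: physical (bp) <-> genetic (cM) coordinates.

A :class:`GeneticMap` holds, per chromosome, a grid of (position_bp,
position_cM) anchor points.  Interpolation between anchors is linear; maps
are sex-averaged.  The default synthetic genome is 22 autosomes with a
constant recombination rate of 1 cM/Mb.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GeneticMap", "default_genome"]


@dataclass
class GeneticMap:
    """Per-chromosome piecewise-linear bp <-> cM map.

    Parameters
    ----------
    grids
        Mapping chromosome -> (pos_bp, pos_cM) arrays.  Positions must be
        strictly increasing in bp and non-decreasing in cM, starting at
        (1, 0.0) or any anchored origin; the last anchor defines the
        chromosome length in both coordinate systems.
    """

    grids: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (bp, cm) in self.grids.items():
            bp = np.asarray(bp, dtype=np.int64)
            cm = np.asarray(cm, dtype=float)
            if bp.shape != cm.shape or bp.ndim != 1 or bp.size < 2:
                raise ValueError(f"map grid for {chrom!r} needs >=2 (bp, cM) anchors")
            if np.any(np.diff(bp) <= 0):
                raise ValueError(f"bp positions not strictly increasing on {chrom!r}")
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"cM positions decrease on {chrom!r}")
            clean[chrom] = (bp, cm)
        self.grids = clean

    @property
    def chromosomes(self) -> list[str]:
        return list(self.grids)

    def length_bp(self, chrom: str) -> int:
        bp, _ = self.grids[chrom]
        return int(bp[-1] - bp[0] + 1)

    def length_cm(self, chrom: str) -> float:
        _, cm = self.grids[chrom]
        return float(cm[-1] - cm[0])

    @property
    def total_bp(self) -> int:
        return sum(self.length_bp(c) for c in self.grids)

    @property
    def total_cm(self) -> float:
        return sum(self.length_cm(c) for c in self.grids)

    def bp_to_cm(self, chrom: str, pos_bp) -> np.ndarray:
        bp, cm = self.grids[chrom]
        pos = np.asarray(pos_bp, dtype=float)
        if np.any(pos < bp[0]) or np.any(pos > bp[-1]):
            raise ValueError(f"position outside map range on {chrom!r}")
        return np.interp(pos, bp.astype(float), cm)

    def cm_to_bp(self, chrom: str, pos_cm) -> np.ndarray:
        """Inverse interpolation; plateaus (0-recombination stretches) map to
        their left edge."""
        bp, cm = self.grids[chrom]
        pos = np.asarray(pos_cm, dtype=float)
        if np.any(pos < cm[0]) or np.any(pos > cm[-1]):
            raise ValueError(f"cM position outside map range on {chrom!r}")
        return np.interp(pos, cm, bp.astype(float))

    @classmethod
    def uniform(
        cls,
        n_chroms: int = 22,
        chrom_length_bp: int = 125_000_000,
        rate_cm_per_mb: float = 1.0,
    ) -> "GeneticMap":
        """Constant-rate map: ``n_chroms`` identical chromosomes."""
        if rate_cm_per_mb <= 0:
            raise ValueError("rate_cm_per_mb must be > 0")
        grids = {}
        cm_end = (chrom_length_bp - 1) / 1e6 * rate_cm_per_mb
        for i in range(1, n_chroms + 1):
            grids[str(i)] = (
                np.array([1, chrom_length_bp], dtype=np.int64),
                np.array([0.0, cm_end]),
            )
        return cls(grids)


def default_genome() -> GeneticMap:
    """22 x 125 Mb autosomes at 1 cM/Mb (2.75 Gb, ~2,750 cM total)."""
    return GeneticMap.uniform(22, 125_000_000, 1.0)
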