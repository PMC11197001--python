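"""Data-driven derivation of run-detection parameters.

The minimum number of consecutive matching SNPs that defines a run is set so
that the expected number of chance runs across the whole panel stays below a
false-positive rate alpha:

    n_snp = ceil( ln(alpha / (n_s * n_i)) / ln(1 - q) )

with n_s SNPs per individual, n_i individuals, and q the per-SNP probability
of the matching state by chance — the mean heterozygosity for homozygosity
runs (ROHom; chance homozygosity control) and the mean homozygosity for
heterozygosity-rich regions (ROHet). The budget of opposite (homozygous)
genotypes tolerated inside a ROHet is the ratio of the two thresholds,

    max_opp = round( n_snp_rohom / n_snp_rohet ),

rounded to the nearest integer (half away from zero). With the adopted
thresholds 50 and 18 this gives 3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .genotype_io import HET, HOM, MISSING, GenotypeMatrix


@dataclass(frozen=True)
class PanelStats:
    """Panel dimensions and mean heterozygosity entering the threshold formula."""

    n_s: int
    n_i: int
    mean_het: float

    def __post_init__(self) -> None:
        if self.n_s < 1 or self.n_i < 1:
            raise ValueError("panel dimensions must be positive")
        if not 0.0 < self.mean_het < 1.0:
            raise ValueError("mean heterozygosity must lie strictly in (0, 1)")

    @property
    def mean_hom(self) -> float:
        return 1.0 - self.mean_het

    @classmethod
    def from_matrix(cls, g: GenotypeMatrix) -> "PanelStats":
        return cls(n_s=g.n_snps, n_i=g.n_samples, mean_het=mean_heterozygosity(g))


@dataclass(frozen=True)
class DerivedParams:
    """Derived detection configuration for one panel."""

    alpha: float
    n_snp_rohom: int
    n_snp_rohet: int
    max_opp: int

    def __post_init__(self) -> None:
        if self.n_snp_rohom < 1 or self.n_snp_rohet < 1 or self.max_opp < 0:
            raise ValueError("derived counts out of range")


def mean_heterozygosity(g: GenotypeMatrix) -> float:
    """Proportion of heterozygous calls among all non-missing calls."""
    called = g.calls != MISSING
    n = int(called.sum())
    if n == 0:
        raise ValueError("no non-missing calls")
    return float((g.calls == 1).sum()) / n


def min_snp_threshold(stats: PanelStats, alpha: float, target: int) -> int:
    """Minimum matching-SNP count controlling chance runs at rate ``alpha``.

    ``target`` is HOM for ROHom (q = mean heterozygosity) or HET for ROHet
    (q = mean homozygosity). The ceiling guarantees the false-positive rate
    stays at or below alpha.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    q = stats.mean_het if target == HOM else stats.mean_hom
    if q <= 0.0 or q >= 1.0:
        raise ValueError("degenerate panel: interrupting-state frequency in {0,1}")
    value = math.log(alpha / (stats.n_s * stats.n_i)) / math.log1p(-q)
    return max(1, math.ceil(value - 1e-12))


def max_opposite(n_snp_rohom: int, n_snp_rohet: int) -> int:
    """Opposite-genotype budget inside a ROHet: nearest-integer ratio of the
    two minimum-SNP thresholds (half rounds away from zero)."""
    if n_snp_rohom < 1 or n_snp_rohet < 1:
        raise ValueError("minimum-SNP thresholds must be >= 1")
    ratio = n_snp_rohom / n_snp_rohet
    return int(math.floor(ratio + 0.5))


def derive_params(g: GenotypeMatrix, alpha: float = 0.05) -> DerivedParams:
    """All detection parameters from a post-QC panel."""
    stats = PanelStats.from_matrix(g)
    n_hom = min_snp_threshold(stats, alpha, HOM)
    n_het = min_snp_threshold(stats, alpha, HET)
    return DerivedParams(
        alpha=alpha,
        n_snp_rohom=n_hom,
        n_snp_rohet=n_het,
        max_opp=max_opposite(n_hom, n_het),
    )
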