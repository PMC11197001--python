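"""SNP and sample quality control for run detection.

Filters mirror common chip-genotype practice: autosomes only, individual and
SNP call rates > 95%, MAF > 0.01, and an exact Hardy-Weinberg equilibrium
test removing SNPs with P < 1e-6. Filter order follows PLINK's
mind -> geno -> maf -> hwe convention (samples before SNP-level filters).

The HWE test is the two-sided exact test of Wigginton, Cutler & Abecasis
(2005): conditioning on the observed allele counts, heterozygote counts of
matching parity follow a hypergeometric-type distribution, and the p-value
sums the probabilities of all outcomes no more likely than the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import CATTLE_AUTOSOMES, MISSING, GenotypeMatrix

# Tie guard for "probability <= observed": absorbs float rounding when two
# heterozygote counts have analytically equal probability.
_HWE_TIE_REL = 1e-9


class EmptyPanelError(ValueError):
    """Every SNP was removed by quality control."""


@dataclass(frozen=True)
class QcThresholds:
    """Quality-control thresholds (defaults: the cattle-chip protocol)."""

    hwe_p_min: float = 1e-6
    maf_min: float = 0.01
    snp_call_min: float = 0.95
    sample_call_min: float = 0.95
    autosomes: frozenset[str] = CATTLE_AUTOSOMES

    def __post_init__(self) -> None:
        for name in ("maf_min", "snp_call_min", "sample_call_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QcReport:
    """Removal counts per filter, in application order."""

    n_snps_in: int
    n_samples_in: int
    removed_non_autosomal: int = 0
    removed_samples_call_rate: int = 0
    removed_snps_call_rate: int = 0
    removed_snps_maf: int = 0
    removed_snps_hwe: int = 0
    n_snps_out: int = 0
    n_samples_out: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("input_snps", self.n_snps_in),
            ("input_samples", self.n_samples_in),
            ("removed_non_autosomal_snps", self.removed_non_autosomal),
            ("removed_samples_call_rate", self.removed_samples_call_rate),
            ("removed_snps_call_rate", self.removed_snps_call_rate),
            ("removed_snps_maf", self.removed_snps_maf),
            ("removed_snps_hwe", self.removed_snps_hwe),
            ("retained_snps", self.n_snps_out),
            ("retained_samples", self.n_samples_out),
        ]
        return pd.DataFrame(rows, columns=["step", "count"])


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value for one biallelic SNP.

    Probabilities over heterozygote counts (same parity as the rare-allele
    count) are built by the stable two-sided recurrence and normalised; the
    p-value is the summed mass of outcomes with probability <= the observed
    table's. Monomorphic SNPs return 1.0.
    """
    if n_AA < 0 or n_Aa < 0 or n_aa < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("total genotype count must be positive")
    n_A = 2 * n_AA + n_Aa
    rare = min(n_A, 2 * n - n_A)
    if rare == 0:
        return 1.0

    # heterozygote counts share the parity of the rare allele count
    hets = list(range(rare % 2, rare + 1, 2))
    probs = dict.fromkeys(hets, 0.0)

    # start near the distribution mode and recurse outward
    mid = int(rare * (2 * n - rare) / (2 * n))
    if mid % 2 != rare % 2:
        mid += 1
    if mid > rare:
        mid -= 2
    probs[mid] = 1.0
    # downward: P(h-2) = P(h) * h(h-1) / (4 (homr+1)(homc+1))
    homr = (rare - mid) // 2
    homc = n - mid - homr
    h, hr, hc = mid, homr, homc
    while h >= 2:
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (hr + 1) * (hc + 1))
        h, hr, hc = h - 2, hr + 1, hc + 1
    # upward: P(h+2) = P(h) * 4 homr homc / ((h+2)(h+1))
    h, hr, hc = mid, homr, homc
    while h <= rare - 2:
        probs[h + 2] = probs[h] * 4.0 * hr * hc / ((h + 2) * (h + 1))
        h, hr, hc = h + 2, hr - 1, hc - 1

    total = sum(probs.values())
    if n_Aa not in probs:  # impossible table given allele counts
        raise ValueError(
            f"heterozygote count {n_Aa} inconsistent with allele counts"
        )
    cutoff = probs[n_Aa] * (1.0 + _HWE_TIE_REL)
    p = sum(v for v in probs.values() if v <= cutoff) / total
    return min(1.0, p)


def maf(column: np.ndarray) -> float:
    """Minor allele frequency of one genotype column (missing excluded)."""
    column = np.asarray(column)
    ok = column != MISSING
    n = int(ok.sum())
    if n == 0:
        raise ValueError("MAF undefined: all calls missing")
    f = float(column[ok].sum()) / (2.0 * n)  # A2 frequency
    return min(f, 1.0 - f)


def _genotype_counts(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP (n_AA, n_Aa, n_aa) counts over non-missing calls."""
    n_AA = (calls == 0).sum(axis=0)
    n_Aa = (calls == 1).sum(axis=0)
    n_aa = (calls == 2).sum(axis=0)
    return n_AA, n_Aa, n_aa


def apply_qc(
    g: GenotypeMatrix, t: QcThresholds = QcThresholds()
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the full filter chain; raises :class:`EmptyPanelError` if nothing
    survives.

    Order: (1) non-autosomal SNPs, (2) sample call rate, (3) SNP call rate,
    (4) MAF, (5) exact HWE. Inequalities are strict per the protocol wording:
    call rates and MAF must *exceed* their thresholds to be retained; SNPs
    are removed when the HWE p-value is *below* ``hwe_p_min``.
    """
    if g.n_snps == 0 or g.n_samples == 0:
        raise ValueError("empty genotype matrix")
    report = QcReport(n_snps_in=g.n_snps, n_samples_in=g.n_samples)

    # 1. autosomes only
    keep_snp = np.fromiter(
        (c in t.autosomes for c in g.markers.chrom), dtype=bool, count=g.n_snps
    )
    report.removed_non_autosomal = int((~keep_snp).sum())
    g = g.subset(snp_idx=np.flatnonzero(keep_snp))
    if g.n_snps == 0:
        raise EmptyPanelError("no autosomal SNPs left after QC step 1")

    # 2. sample call rate
    call_rate = (g.calls != MISSING).mean(axis=1)
    keep_sample = call_rate > t.sample_call_min
    report.removed_samples_call_rate = int((~keep_sample).sum())
    g = g.subset(sample_idx=np.flatnonzero(keep_sample))
    if g.n_samples == 0:
        raise EmptyPanelError("no samples left after call-rate filter")

    # 3. SNP call rate
    snp_rate = (g.calls != MISSING).mean(axis=0)
    keep = snp_rate > t.snp_call_min
    report.removed_snps_call_rate = int((~keep).sum())
    g = g.subset(snp_idx=np.flatnonzero(keep))

    # 4. MAF
    if g.n_snps:
        n_AA, n_Aa, n_aa = _genotype_counts(g.calls)
        n_called = n_AA + n_Aa + n_aa
        with np.errstate(invalid="ignore", divide="ignore"):
            f = (2 * n_aa + n_Aa) / (2.0 * n_called)
        mafs = np.minimum(f, 1.0 - f)
        keep = (n_called > 0) & (mafs > t.maf_min)
        report.removed_snps_maf = int((~keep).sum())
        g = g.subset(snp_idx=np.flatnonzero(keep))

    # 5. exact HWE
    if g.n_snps:
        n_AA, n_Aa, n_aa = _genotype_counts(g.calls)
        keep = np.fromiter(
            (
                hwe_exact_p(int(a), int(b), int(c)) >= t.hwe_p_min
                for a, b, c in zip(n_AA, n_Aa, n_aa)
            ),
            dtype=bool,
            count=g.n_snps,
        )
        report.removed_snps_hwe = int((~keep).sum())
        g = g.subset(snp_idx=np.flatnonzero(keep))

    if g.n_snps == 0:
        raise EmptyPanelError("all SNPs removed by quality control")
    report.n_snps_out = g.n_snps
    report.n_samples_out = g.n_samples
    return g, report
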