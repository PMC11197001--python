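"""Independent brute-force oracles used by the test-suite.

These deliberately avoid the package's algorithmic shortcuts: run detection
is re-derived by enumerating every candidate window, the exact HWE p-value
by direct log-factorial enumeration over heterozygote counts, ANOVA by
textbook two-pass sums of squares, and the hypergeometric tail by explicit
summation. They are slow and simple on purpose.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

from rohetscan.genotype_io import MISS
from rohetscan.run_detection import RunParams


def enumerate_valid_windows(
    states: np.ndarray, pos: np.ndarray, p: RunParams
) -> list[tuple[int, int]]:
    """All (i, j) index windows satisfying every run constraint."""
    n = len(states)
    out = []
    for i in range(n):
        if states[i] != p.target:
            continue
        n_target = 0
        n_opp = 0
        n_miss = 0
        for j in range(i, n):
            if j > i and pos[j] - pos[j - 1] > p.max_gap_bp:
                break
            s = states[j]
            if s == p.target:
                n_target += 1
            elif s == MISS:
                n_miss += 1
            else:
                n_opp += 1
            if n_opp > p.max_opposite or n_miss > p.max_missing:
                break
            if (
                s == p.target
                and n_target >= p.min_snp
                and pos[j] - pos[i] >= p.min_length_bp
            ):
                out.append((i, j))
    return out


def brute_force_runs(
    states: np.ndarray, pos: np.ndarray, p: RunParams
) -> list[tuple[int, int, int, int, int, int]]:
    """Greedy leftmost-longest selection over the enumerated valid windows.

    Returns (start_bp, end_bp, n_total, n_target, n_opp, n_miss), matching
    the scanner's per-chromosome output format.
    """
    windows = enumerate_valid_windows(states, pos, p)
    chosen = []
    cursor = 0
    while True:
        candidates = [(i, j) for i, j in windows if i >= cursor]
        if not candidates:
            break
        i_min = min(i for i, _ in candidates)
        j_max = max(j for i, j in candidates if i == i_min)
        chosen.append((i_min, j_max))
        cursor = j_max + 1
    out = []
    for i, j in chosen:
        w = states[i : j + 1]
        n_target = int((w == p.target).sum())
        n_miss = int((w == MISS).sum())
        out.append(
            (
                int(pos[i]), int(pos[j]), j - i + 1, n_target,
                len(w) - n_target - n_miss, n_miss,
            )
        )
    return out


def hwe_enum_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided HWE p-value by direct enumeration with log-factorials."""
    n = n_AA + n_Aa + n_aa
    n_A = 2 * n_AA + n_Aa
    rare = min(n_A, 2 * n - n_A)
    if rare == 0:
        return 1.0
    hets = np.arange(rare % 2, rare + 1, 2)
    log_probs = _hwe_log_pmf(hets, n, n_A)
    probs = np.exp(log_probs - log_probs.max())
    probs /= probs.sum()
    obs = probs[hets == n_Aa][0]
    return float(min(1.0, probs[probs <= obs * (1.0 + 1e-9)].sum()))


def _hwe_log_pmf(hets: np.ndarray, n: int, n_A: int) -> np.ndarray:
    """Unnormalised log-probability of each heterozygote count given allele
    counts: multinomial genotype arrangements x 2^het."""
    n_AA = (n_A - hets) // 2
    n_aa = n - n_AA - hets
    return (
        gammaln(n + 1)
        - gammaln(n_AA + 1)
        - gammaln(hets + 1)
        - gammaln(n_aa + 1)
        + hets * math.log(2.0)
    )


def hwe_distributions_for(n: int, n_A: int) -> tuple[np.ndarray, np.ndarray]:
    """(het counts, normalised probabilities) for one (n, allele count) pair."""
    rare = min(n_A, 2 * n - n_A)
    hets = np.arange(rare % 2, rare + 1, 2)
    log_probs = _hwe_log_pmf(hets, n, n_A)
    probs = np.exp(log_probs - log_probs.max())
    return hets, probs / probs.sum()


def anova_two_pass(groups: dict[str, np.ndarray]) -> tuple[float, float]:
    """Textbook one-way fixed-effects ANOVA from explicit sums of squares."""
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    all_values = np.concatenate(arrays)
    grand = all_values.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b = len(arrays) - 1
    df_w = all_values.size - len(arrays)
    f = (ss_between / df_b) / (ss_within / df_w)
    return f, float(sps.f.sf(f, df_b, df_w))


def hypergeom_tail(k: int, M: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(M, K, n), by explicit log-factorial sum."""

    def log_c(a: int, b: int) -> float:
        return math.lgamma(a + 1) - math.lgamma(b + 1) - math.lgamma(a - b + 1)

    total = 0.0
    for x in range(k, min(K, n) + 1):
        if n - x > M - K:
            continue
        total += math.exp(log_c(K, x) + log_c(M - K, n - x) - log_c(M, n))
    return min(1.0, total)


def incidence_brute_force(runs, markers, n_animals_total):
    """Per-SNP incidence by an O(n_runs x n_snps) membership test."""
    counts = np.zeros(len(markers), dtype=int)
    animals = {r.animal for r in runs}
    for snp_i in range(len(markers)):
        c, p = markers.chrom[snp_i], markers.pos_bp[snp_i]
        n = 0
        for a in animals:
            if any(
                r.animal == a and r.chrom == c and r.start_bp <= p <= r.end_bp
                for r in runs
            ):
                n += 1
        counts[snp_i] = n
    return counts
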