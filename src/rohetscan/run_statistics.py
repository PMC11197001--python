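"""Per-animal and per-dataset run summaries, genomic coefficients,
cross-density comparisons and LD decay.

The genomic inbreeding coefficient F_ROHom (and its heterozygosity analogue,
the diversity coefficient D_ROHet) is the total run length of an animal
divided by the genome length covered by SNPs — the sum over autosomes of
(last SNP position - first SNP position).

Density groups are compared by classical one-way fixed-effects ANOVA with
Welch pairwise t-tests under Bonferroni correction, summarised as a compact
letter display. Linkage disequilibrium is measured as the squared Pearson
correlation of genotype dosages (0/1/2), binned by inter-marker distance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genotype_io import MISSING, GenotypeMatrix, MarkerMap
from .run_detection import LENGTH_CLASS_LABELS, Run, length_class


@dataclass(frozen=True)
class GenomeCoverage:
    """Genome length covered by SNPs, per autosome and total (bp)."""

    per_chrom: dict[str, int]
    total: int


def genome_length_covered(markers: MarkerMap) -> GenomeCoverage:
    """Covered span per chromosome (last - first SNP position).

    Chromosomes with fewer than two SNPs contribute zero.
    """
    if len(markers) == 0:
        raise ValueError("empty marker map")
    per: dict[str, int] = {}
    for chrom in markers.chromosomes:
        sl = markers.chrom_slice(chrom)
        pos = markers.pos_bp[sl]
        per[chrom] = int(pos[-1] - pos[0]) if len(pos) >= 2 else 0
    return GenomeCoverage(per_chrom=per, total=sum(per.values()))


def roh_coefficient(runs: list[Run], cov: GenomeCoverage) -> float:
    """F_ROHom / D_ROHet for one animal: total run length / covered genome."""
    if cov.total <= 0:
        raise ValueError("covered genome length must be positive")
    return sum(r.length_bp for r in runs) / cov.total


def per_animal_summary(
    runs: list[Run], cov: GenomeCoverage, animals: list[str]
) -> pd.DataFrame:
    """Per-animal table: run count, mean/total length, genomic coefficient.

    ``animals`` fixes the row set so animals with zero runs appear explicitly.
    """
    by_animal: dict[str, list[Run]] = {a: [] for a in animals}
    for r in runs:
        by_animal.setdefault(r.animal, []).append(r)
    rows = []
    for a in animals:
        rs = by_animal[a]
        lengths = [r.length_bp for r in rs]
        rows.append(
            {
                "animal": a,
                "n_runs": len(rs),
                "mean_length_bp": float(np.mean(lengths)) if lengths else 0.0,
                "total_length_bp": int(sum(lengths)),
                "coefficient": roh_coefficient(rs, cov),
            }
        )
    return pd.DataFrame(rows)


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    """Mean and sample SD (ddof=1; SD is NaN for < 2 values)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return 0.0, float("nan")
    sd = float(np.std(values, ddof=1)) if values.size > 1 else float("nan")
    return float(values.mean()), sd


def summarize_dataset(runs: list[Run], animals: list[str]) -> pd.DataFrame:
    """One-row dataset summary shaped like the per-density results table.

    Columns: total and unique run counts, animals with >= 1 run, per-animal
    count mean +/- SD (over animals with runs), overall run-length mean +/- SD
    (Mb), and per length class the run count and length mean +/- SD.
    """
    n_per_animal: dict[str, int] = {}
    for r in runs:
        n_per_animal[r.animal] = n_per_animal.get(r.animal, 0) + 1
    lengths_mb = np.array([r.length_bp for r in runs], dtype=float) / 1e6
    unique = len({(r.chrom, r.start_bp, r.end_bp) for r in runs})

    count_mean, count_sd = _mean_sd(np.array(list(n_per_animal.values())))
    len_mean, len_sd = _mean_sd(lengths_mb)
    row: dict[str, float | int] = {
        "n_total": len(runs),
        "n_unique": unique,
        "n_animals": len(n_per_animal),
        "runs_per_animal_mean": count_mean,
        "runs_per_animal_sd": count_sd,
        "length_mb_mean": len_mean,
        "length_mb_sd": len_sd,
    }
    classes = [length_class(r) for r in runs]
    for label in LENGTH_CLASS_LABELS:
        sub = lengths_mb[[c == label for c in classes]]
        m, s = _mean_sd(sub)
        key = label.replace(" Mb", "").replace(">", "gt").replace("-", "_")
        row[f"n_{key}"] = int(sub.size)
        row[f"len_{key}_mean"] = m
        row[f"len_{key}_sd"] = s
    return pd.DataFrame([row])


@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA with Bonferroni-corrected Welch pairwise letters."""

    f_statistic: float
    p_value: float
    group_means: dict[str, float]
    letters: dict[str, str]
    pairwise_p: dict[tuple[str, str], float]
    degenerate: bool = False


def one_way_anova(
    groups: dict[str, np.ndarray | list[float]], alpha: float = 0.001
) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA across named groups.

    Pairwise Welch t-tests with Bonferroni correction at ``alpha`` produce a
    compact letter display (groups sharing a letter are not significantly
    different). With zero within-group variance everywhere the F statistic is
    undefined and the result is flagged ``degenerate``.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least two values")
    means = {k: float(a.mean()) for k, a in zip(names, arrays)}

    within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    between_df = len(arrays) - 1
    grand = np.concatenate(arrays).mean()
    between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    if within == 0.0:
        if between == 0.0:
            # identical constant groups: no evidence of any difference
            return AnovaResult(0.0, 1.0, means, {k: "a" for k in names}, {},
                               degenerate=True)
        return AnovaResult(float("inf"), 0.0, means, {}, {}, degenerate=True)
    f_stat, p = sps.f_oneway(*arrays)

    pairs = list(itertools.combinations(names, 2))
    pairwise: dict[tuple[str, str], float] = {}
    differs: set[tuple[str, str]] = set()
    for a_name, b_name in pairs:
        a, b = groups[a_name], groups[b_name]
        pw = sps.ttest_ind(a, b, equal_var=False).pvalue
        pw_adj = min(1.0, float(pw) * len(pairs))
        pairwise[(a_name, b_name)] = pw_adj
        if pw_adj < alpha:
            differs.add((a_name, b_name))
            differs.add((b_name, a_name))

    letters = _compact_letter_display(names, means, differs)
    return AnovaResult(float(f_stat), float(p), means, letters, pairwise)


def _compact_letter_display(
    names: list[str], means: dict[str, float], differs: set[tuple[str, str]]
) -> dict[str, str]:
    """Insert-and-absorb letter assignment over groups sorted by mean."""
    ordered = sorted(names, key=lambda k: -means[k])
    letter_sets: list[set[str]] = []
    for name in ordered:
        placed = False
        for s in letter_sets:
            if all((name, other) not in differs for other in s):
                s.add(name)
                placed = True
        if not placed:
            letter_sets.append({name})
    # drop letter sets fully contained in another
    letter_sets = [
        s for i, s in enumerate(letter_sets)
        if not any(i != j and s < t for j, t in enumerate(letter_sets))
    ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {name: "" for name in names}
    for letter, s in zip(alphabet, letter_sets):
        for name in ordered:
            if name in s:
                out[name] += letter
    return out


def ld_decay(
    g: GenotypeMatrix,
    max_dist_bp: int = 1_000_000,
    bin_bp: int = 50_000,
) -> pd.DataFrame:
    """Binned mean r-squared versus inter-marker distance.

    Every intra-chromosomal SNP pair at distance <= ``max_dist_bp``
    contributes the squared Pearson correlation of its genotype dosages
    (pairwise-complete over non-missing animals); pairs where either SNP is
    monomorphic among the shared animals are skipped. Returns one row per
    distance bin with the mean r2 and the pair count.
    """
    if bin_bp <= 0 or max_dist_bp <= 0:
        raise ValueError("distances must be positive")
    n_bins = int(np.ceil(max_dist_bp / bin_bp))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)

    dosages = g.calls.astype(float)
    dosages[g.calls == MISSING] = np.nan
    for chrom in g.markers.chromosomes:
        sl = g.markers.chrom_slice(chrom)
        pos = g.markers.pos_bp[sl]
        X = dosages[:, sl]
        m = X.shape[1]
        for offset in range(1, m):
            d = pos[offset:] - pos[:-offset]
            keep = d <= max_dist_bp
            if not keep.any():
                break
            A, B = X[:, : m - offset][:, keep], X[:, offset:][:, keep]
            ok = ~np.isnan(A) & ~np.isnan(B)
            n = ok.sum(axis=0)
            A0, B0 = np.where(ok, A, 0.0), np.where(ok, B, 0.0)
            with np.errstate(invalid="ignore", divide="ignore"):
                ma, mb = A0.sum(0) / n, B0.sum(0) / n
                cov = (A0 * B0).sum(0) / n - ma * mb
                va = (A0 ** 2).sum(0) / n - ma ** 2
                vb = (B0 ** 2).sum(0) / n - mb ** 2
                r2 = cov ** 2 / (va * vb)
            good = (n >= 2) & (va > 0) & (vb > 0) & np.isfinite(r2)
            b = np.minimum((d[keep] - 1) // bin_bp, n_bins - 1)
            np.add.at(sums, b[good], r2[good])
            np.add.at(counts, b[good], 1)

    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "dist_bp_low": np.arange(n_bins) * bin_bp,
            "dist_bp_high": np.minimum((np.arange(n_bins) + 1) * bin_bp, max_dist_bp),
            "mean_r2": mean_r2,
            "n_pairs": counts,
        }
    )
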