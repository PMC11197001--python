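"""Population-level sharing of runs: repeated regions, per-SNP incidence,
islands, cross-density intersections, annotation and enrichment.

A *repeated region* is a run with identical start and end coordinates found
in more than one animal; regions in the top 0.1% of the sharing distribution
are flagged. The per-SNP *incidence* (SNP_ROHom / SNP_ROHet) counts the
animals in which that SNP lies inside a run; markers exceeding the 99th
percentile of the incidence distribution form *islands* — candidate
selection signatures — after merging near-contiguous members.

Percentiles use nearest-rank semantics over the within-dataset distribution
(zeros included) with strict exceedance, so thresholds are reproducible
integers. Gene/QTL annotation reports features within a +/- 250 kb flank;
over-representation per category uses a hypergeometric upper-tail test with
Bonferroni correction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genotype_io import MarkerMap
from .run_detection import Run


@dataclass(frozen=True)
class RepeatedRegion:
    chrom: str
    start_bp: int
    end_bp: int
    n_animals: int


@dataclass(frozen=True)
class Island:
    chrom: str
    start_bp: int
    end_bp: int
    snp_ids: tuple[str, ...]
    max_incidence: int


def nearest_rank_percentile(values: np.ndarray, pct: float) -> float:
    """Nearest-rank percentile: the ceil(pct/100 * N)-th smallest value."""
    values = np.sort(np.asarray(values))
    if values.size == 0:
        raise ValueError("empty distribution")
    rank = max(1, math.ceil(pct / 100.0 * values.size))
    return float(values[rank - 1])


def repeated_regions(
    runs: list[Run], top_fraction: float = 0.001
) -> tuple[list[RepeatedRegion], list[RepeatedRegion]]:
    """Runs shared with identical (chrom, start, end) by >= 2 animals.

    Returns (all repeated regions, top subset) where the top subset holds
    regions whose sharing count reaches the nearest-rank
    ``100*(1 - top_fraction)`` percentile of the sharing distribution
    (ties included). Sorted by descending sharing, then position.
    """
    groups: dict[tuple[str, int, int], set[str]] = {}
    for r in runs:
        groups.setdefault((r.chrom, r.start_bp, r.end_bp), set()).add(r.animal)
    repeated = [
        RepeatedRegion(c, s, e, len(animals))
        for (c, s, e), animals in groups.items()
        if len(animals) >= 2
    ]
    repeated.sort(key=lambda r: (-r.n_animals, r.chrom, r.start_bp))
    if not repeated:
        return [], []
    counts = np.array([r.n_animals for r in repeated])
    threshold = nearest_rank_percentile(counts, 100.0 * (1.0 - top_fraction))
    top = [r for r in repeated if r.n_animals >= threshold]
    return repeated, top


def snp_incidence(
    runs: list[Run], markers: MarkerMap, n_animals_total: int
) -> pd.DataFrame:
    """Per-SNP count (and %) of animals carrying that SNP inside a run."""
    counts = np.zeros(len(markers), dtype=np.int64)
    by_animal_chrom: dict[tuple[str, str], list[Run]] = {}
    for r in runs:
        by_animal_chrom.setdefault((r.animal, r.chrom), []).append(r)
    for (animal, chrom), rs in by_animal_chrom.items():
        sl = markers.chrom_slice(chrom)
        pos = markers.pos_bp[sl]
        covered = np.zeros(len(pos), dtype=bool)
        for r in rs:
            lo = np.searchsorted(pos, r.start_bp, side="left")
            hi = np.searchsorted(pos, r.end_bp, side="right")
            covered[lo:hi] = True
        counts[sl.start : sl.stop] += covered
    pct = 100.0 * counts / n_animals_total if n_animals_total else counts * 0.0
    return pd.DataFrame(
        {
            "snp_id": markers.snp_id,
            "chrom": markers.chrom,
            "pos_bp": markers.pos_bp,
            "n_animals_in_run": counts,
            "pct": pct,
        }
    )


def call_islands(
    track: pd.DataFrame, percentile: float = 99.0, merge_gap_bp: int = 1_000_000
) -> tuple[list[Island], float]:
    """Islands of SNPs strictly exceeding the incidence percentile.

    Consecutive above-threshold SNPs on one chromosome are merged into a
    single island while their positions are <= ``merge_gap_bp`` apart.
    Returns (islands, threshold). An all-equal track yields no island.
    """
    counts = track["n_animals_in_run"].to_numpy()
    threshold = nearest_rank_percentile(counts, percentile)
    above = track.loc[counts > threshold]
    if above.empty:
        warnings.warn(
            "no SNP strictly exceeds the incidence threshold; no islands called",
            stacklevel=2,
        )
        return [], threshold

    islands: list[Island] = []
    cur: list[tuple[str, int, str, int]] = []  # (snp_id, pos, chrom, count)
    for snp, chrom, pos, cnt in zip(
        above["snp_id"], above["chrom"], above["pos_bp"], above["n_animals_in_run"]
    ):
        if cur and (chrom != cur[-1][2] or pos - cur[-1][1] > merge_gap_bp):
            islands.append(_flush_island(cur))
            cur = []
        cur.append((snp, int(pos), chrom, int(cnt)))
    if cur:
        islands.append(_flush_island(cur))
    return islands, threshold


def _flush_island(members: list[tuple[str, int, str, int]]) -> Island:
    return Island(
        chrom=members[0][2],
        start_bp=members[0][1],
        end_bp=members[-1][1],
        snp_ids=tuple(m[0] for m in members),
        max_incidence=max(m[3] for m in members),
    )


def island_snp_ids(
    track: pd.DataFrame, percentile: float = 99.0
) -> set[str]:
    """SNP ids strictly exceeding the incidence percentile of one dataset."""
    counts = track["n_animals_in_run"].to_numpy()
    threshold = nearest_rank_percentile(counts, percentile)
    return set(track.loc[counts > threshold, "snp_id"])


def intersect_island_snps(
    tracks: dict[str, pd.DataFrame], percentile: float = 99.0
) -> set[str]:
    """SNP ids above the island threshold in *every* dataset."""
    if not tracks:
        return set()
    sets = [island_snp_ids(t, percentile) for t in tracks.values()]
    common = set.intersection(*sets)
    universe = set.intersection(*(set(t["snp_id"]) for t in tracks.values()))
    if not universe:
        warnings.warn("tracks share no SNP ids; intersection is empty", stacklevel=2)
    return common


def incidence_correlation(track_a: pd.DataFrame, track_b: pd.DataFrame) -> float:
    """Pearson correlation of per-SNP incidence counts on the shared SNPs."""
    merged = track_a.merge(track_b, on="snp_id", suffixes=("_a", "_b"))
    if merged.empty:
        raise ValueError("tracks share no SNPs")
    a = merged["n_animals_in_run_a"].to_numpy(dtype=float)
    b = merged["n_animals_in_run_b"].to_numpy(dtype=float)
    if a.std() == 0.0 or b.std() == 0.0:
        raise ValueError("incidence correlation undefined: zero variance track")
    return float(np.corrcoef(a, b)[0, 1])


def annotate_regions(
    regions: pd.DataFrame, features: pd.DataFrame, flank_bp: int = 250_000
) -> tuple[pd.DataFrame, int]:
    """Features intersecting each region extended by ``flank_bp`` on each side.

    ``regions`` needs (chrom, start_bp, end_bp); ``features`` needs
    (chrom, start, end, category, name), all 1-based inclusive. Malformed
    feature rows are skipped; their count is returned alongside the table.
    Overlap type is "inside" (feature within the region itself), "overlap"
    (intersects the region) or "flank" (only within the flanked interval).
    """
    n_bad = 0
    rows = []
    feats = []
    for rec in features.itertuples(index=False):
        try:
            feats.append(
                (str(rec.chrom), int(rec.start), int(rec.end),
                 str(rec.category), str(rec.name))
            )
            if feats[-1][1] > feats[-1][2]:
                feats.pop()
                n_bad += 1
        except (ValueError, TypeError, AttributeError):
            n_bad += 1
    for reg in regions.itertuples(index=False):
        r_chrom, r_start, r_end = str(reg.chrom), int(reg.start_bp), int(reg.end_bp)
        lo, hi = r_start - flank_bp, r_end + flank_bp
        for f_chrom, f_start, f_end, category, name in feats:
            if f_chrom != r_chrom or f_end < lo or f_start > hi:
                continue
            if f_start >= r_start and f_end <= r_end:
                kind = "inside"
            elif f_end >= r_start and f_start <= r_end:
                kind = "overlap"
            else:
                kind = "flank"
            rows.append(
                {
                    "chrom": r_chrom,
                    "region_start_bp": r_start,
                    "region_end_bp": r_end,
                    "feature": name,
                    "category": category,
                    "feature_start": f_start,
                    "feature_end": f_end,
                    "overlap_type": kind,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "region_start_bp", "region_end_bp", "feature", "category",
            "feature_start", "feature_end", "overlap_type",
        ],
    ), n_bad


def enrich_categories(
    region_hits: pd.DataFrame, all_features: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-category hypergeometric over-representation of region hits.

    For each category: drawing ``n`` hits from ``M`` background features of
    which ``K`` belong to the category, the upper-tail probability of seeing
    at least the observed ``k`` hits. Bonferroni-adjusted across the tested
    categories; significant iff adjusted p < ``alpha``.
    """
    if all_features.empty:
        raise ValueError("empty feature background")
    background = all_features.drop_duplicates(subset=["name", "category"])
    M = len(background)
    cat_totals = background.groupby("category").size()
    hits = region_hits.drop_duplicates(subset=["feature", "category"])
    n = len(hits)
    missing = set(hits["category"]) - set(cat_totals.index)
    if missing:
        raise ValueError(f"hit categories absent from background: {sorted(missing)}")
    cat_hits = hits.groupby("category").size()
    n_tested = len(cat_hits)
    rows = []
    for category, k in cat_hits.items():
        K = int(cat_totals[category])
        p = float(sps.hypergeom.sf(k - 1, M, K, n))
        p_adj = min(1.0, p * n_tested)
        rows.append(
            {
                "category": category,
                "hits": int(k),
                "background": K,
                "n_hits_total": n,
                "n_background_total": M,
                "p_value": p,
                "p_bonferroni": p_adj,
                "significant": p_adj < alpha,
            }
        )
    return pd.DataFrame(rows).sort_values("p_bonferroni", ignore_index=True)


def intervals_to_bed(df: pd.DataFrame) -> pd.DataFrame:
    """Convert 1-based inclusive (chrom, start_bp, end_bp) intervals to
    0-based half-open BED columns."""
    return pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start_bp"].astype(int) - 1,
            "end": df["end_bp"].astype(int),
        }
    )
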