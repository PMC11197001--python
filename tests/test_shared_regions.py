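import numpy as np
import pandas as pd
import pytest

from rohetscan.run_detection import Run
from rohetscan.shared_regions import (
    annotate_regions,
    call_islands,
    enrich_categories,
    incidence_correlation,
    intersect_island_snps,
    island_snp_ids,
    nearest_rank_percentile,
    repeated_regions,
    snp_incidence,
)

from oracles import hypergeom_tail, incidence_brute_force
from test_run_statistics import mk_map, mk_run


def track_from(counts, chrom=None, pos=None, n_total=100):
    n = len(counts)
    return pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(n)],
            "chrom": chrom or ["1"] * n,
            "pos_bp": pos if pos is not None else np.arange(n) * 10_000 + 1,
            "n_animals_in_run": counts,
            "pct": 100.0 * np.asarray(counts) / n_total,
        }
    )


class TestRepeatedRegions:
    def test_exact_sharing_grouped(self):
        runs = [mk_run(a, start=5_000_000, end=6_100_000) for a in "abc"]
        runs += [mk_run("d", start=7_000_000, end=8_100_000)]
        rep, top = repeated_regions(runs)
        assert len(rep) == 1
        assert rep[0].n_animals == 3
        assert top == rep

    def test_one_bp_difference_not_grouped(self):
        runs = [
            mk_run("a", start=5_000_000, end=6_100_000),
            mk_run("b", start=5_000_000, end=6_100_001),
        ]
        rep, _ = repeated_regions(runs)
        assert rep == []

    def test_same_animal_does_not_count_twice(self):
        runs = [mk_run("a"), mk_run("a", chrom="1")]
        rep, _ = repeated_regions(runs)
        assert rep == []

    def test_planted_shared_segment_tops_distribution(self, small_sim):
        """The identical planted segment dominates the sharing distribution
        (simulator bookkeeping as oracle)."""
        from rohetscan.run_detection import detect_runs, rohom_params

        cfg, g, truth = small_sim
        runs = detect_runs(g, rohom_params(min_snp=30))
        rep, top = repeated_regions(runs)
        assert rep, "no repeated regions found"
        best = rep[0]
        planted = truth.for_kind("ROHom")
        ident = planted[planted["segment_id"] == 0]
        n_carriers = ident["animal"].nunique()
        assert best.chrom == "1"
        assert best.n_animals == n_carriers
        # identical plants have sharp breakpoints: coordinates sit inside
        # the planted interval
        assert ident["start_bp"].iloc[0] <= best.start_bp
        assert best.end_bp <= ident["end_bp"].iloc[0]


class TestSnpIncidence:
    def test_no_runs_all_zero(self):
        markers = mk_map([("1", 100), ("1", 200)])
        track = snp_incidence([], markers, 10)
        assert (track["n_animals_in_run"] == 0).all()

    def test_single_run_covers_its_snps(self):
        markers = mk_map([("1", p) for p in range(100, 1100, 100)])
        runs = [mk_run("a", start=300, end=700)]
        track = snp_incidence(runs, markers, 5)
        assert track["n_animals_in_run"].tolist() == [0, 0, 1, 1, 1, 1, 1, 0, 0, 0]
        assert track["pct"].iloc[2] == 20.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(6)
        markers = mk_map([("1", p) for p in sorted(rng.choice(10**6, 60, False))]
                         + [("2", p) for p in sorted(rng.choice(10**6, 40, False))])
        runs = []
        for a in "abcdef":
            for chrom in ("1", "2"):
                s = int(rng.integers(1, 900_000))
                runs.append(mk_run(a, chrom, s, s + int(rng.integers(1, 300_000))))
        track = snp_incidence(runs, markers, 6)
        expected = incidence_brute_force(runs, markers, 6)
        assert track["n_animals_in_run"].tolist() == expected.tolist()


class TestIslands:
    def test_single_hot_snp(self):
        counts = np.zeros(1000, dtype=int)
        counts[500] = 50
        islands, threshold = call_islands(track_from(counts))
        assert len(islands) == 1
        assert islands[0].snp_ids == ("s500",)
        assert islands[0].max_incidence == 50

    def test_contiguous_members_merge_into_one_island(self):
        counts = np.zeros(10_000, dtype=int)
        counts[100:131] = 40  # 31 contiguous hot SNPs, well under 1% of panel
        islands, _ = call_islands(track_from(counts))
        assert len(islands) == 1
        assert len(islands[0].snp_ids) == 31
        assert islands[0].start_bp == 100 * 10_000 + 1
        assert islands[0].end_bp == 130 * 10_000 + 1

    def test_merge_gap_rule_splits_distant_members(self):
        counts = np.zeros(200, dtype=int)
        counts[[10, 150]] = 30  # 1.4 Mb apart at 10 kb spacing
        islands, _ = call_islands(track_from(counts), merge_gap_bp=1_000_000)
        assert len(islands) == 2

    def test_all_equal_track_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="no SNP"):
            islands, _ = call_islands(track_from(np.full(100, 3)))
        assert islands == []

    def test_islands_disjoint_sorted_above_threshold(self, small_sim):
        from rohetscan.run_detection import detect_runs, rohet_params

        _, g, _ = small_sim
        runs = detect_runs(g, rohet_params(min_snp=15, max_opposite=2))
        track = snp_incidence(runs, g.markers, g.n_samples)
        islands, threshold = call_islands(track)
        by_chrom: dict[str, int] = {}
        counts = dict(zip(track["snp_id"], track["n_animals_in_run"]))
        for isl in islands:
            assert isl.start_bp <= isl.end_bp
            assert all(counts[s] > threshold for s in isl.snp_ids)
            if isl.chrom in by_chrom:
                assert isl.start_bp > by_chrom[isl.chrom]
            by_chrom[isl.chrom] = isl.end_bp

    def test_raising_percentile_never_enlarges_islands(self):
        rng = np.random.default_rng(8)
        track = track_from(rng.poisson(3, 500))
        lo = island_snp_ids(track, 95.0)
        hi = island_snp_ids(track, 99.0)
        assert hi <= lo


class TestIntersections:
    def test_identical_tracks(self):
        counts = np.zeros(100, dtype=int)
        counts[10] = 9
        t = track_from(counts)
        assert intersect_island_snps({"a": t, "b": t}) == {"s10"}

    def test_disjoint_islands_empty(self):
        c1 = np.zeros(100, dtype=int)
        c2 = np.zeros(100, dtype=int)
        c1[10], c2[90] = 9, 9
        assert intersect_island_snps({"a": track_from(c1), "b": track_from(c2)}) \
            == set()

    def test_planted_rohet_found_at_multiple_densities(self, small_sim):
        """The shared planted ROHet region yields island SNPs at full and
        thinned density, and their intersection stays inside the plant."""
        from rohetscan.run_detection import detect_runs, rohet_params
        from rohetscan.synthetic_data import thin_density

        cfg, g, _ = small_sim
        p = rohet_params(min_snp=12, max_opposite=2)
        tracks = {}
        for label, frac in (("full", 1.0), ("thin", 0.4)):
            gt = thin_density(g, frac, seed=3)
            runs = detect_runs(gt, p)
            tracks[label] = snp_incidence(runs, gt.markers, gt.n_samples)
        common = intersect_island_snps(tracks)
        assert common
        pos = dict(zip(g.markers.snp_id, g.markers.pos_bp))
        chrom = dict(zip(g.markers.snp_id, g.markers.chrom))
        seg = cfg.planted[2]
        for s in common:
            assert chrom[s] == seg.chrom
            assert seg.start_bp <= pos[s] <= seg.end_bp


class TestIncidenceCorrelation:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(10)
        t = track_from(rng.poisson(2, 200))
        assert incidence_correlation(t, t) == pytest.approx(1.0)

    def test_anti_pattern_negative(self):
        c = np.arange(50)
        t1, t2 = track_from(c), track_from(c[::-1].copy())
        r = incidence_correlation(t1, t2)
        assert -1.0 <= r < 0.0

    def test_independent_tracks_near_zero(self):
        rng = np.random.default_rng(11)
        t1 = track_from(rng.poisson(3, 10_000))
        t2 = track_from(rng.poisson(3, 10_000))
        assert abs(incidence_correlation(t1, t2)) < 0.05

    def test_zero_variance_flagged(self):
        t1 = track_from(np.zeros(10, dtype=int))
        t2 = track_from(np.arange(10))
        with pytest.raises(ValueError, match="variance"):
            incidence_correlation(t1, t2)


def features_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "category", "name"])


class TestAnnotate:
    REGION = pd.DataFrame(
        [{"chrom": "1", "start_bp": 1_000_000, "end_bp": 2_000_000}]
    )

    def test_feature_within_flank_reported(self):
        feats = features_frame([("1", 850_000, 900_000, "gene", "G1")])
        hits, n_bad = annotate_regions(self.REGION, feats)
        assert len(hits) == 1
        assert hits["overlap_type"].iloc[0] == "flank"
        assert n_bad == 0

    def test_feature_beyond_flank_not_reported(self):
        feats = features_frame([("1", 600_000, 700_000, "gene", "G1")])
        hits, _ = annotate_regions(self.REGION, feats)
        assert hits.empty

    def test_feature_inside_region(self):
        feats = features_frame([("1", 1_200_000, 1_300_000, "gene", "G1")])
        hits, _ = annotate_regions(self.REGION, feats)
        assert hits["overlap_type"].iloc[0] == "inside"

    def test_malformed_rows_skipped_and_counted(self):
        feats = features_frame(
            [("1", 1_200_000, 1_100_000, "gene", "bad_interval"),
             ("1", 1_200_000, 1_300_000, "gene", "G1")]
        )
        hits, n_bad = annotate_regions(self.REGION, feats)
        assert n_bad == 1
        assert hits["feature"].tolist() == ["G1"]


class TestEnrichment:
    def test_extreme_enrichment_significant(self):
        bg = features_frame(
            [("1", i, i + 10, "rare" if i < 100 else "common", f"f{i}")
             for i in range(1, 10_001, 10)]
        )
        hits = bg[bg["category"] == "rare"].iloc[:8].rename(
            columns={"name": "feature"}
        )
        res = enrich_categories(hits, bg)
        assert res.loc[res["category"] == "rare", "significant"].iloc[0]

    def test_proportional_hits_not_significant(self):
        bg = features_frame(
            [("1", i, i + 1, "a" if i % 2 else "b", f"f{i}") for i in range(400)]
        )
        hits = bg.iloc[:100].rename(columns={"name": "feature"})
        res = enrich_categories(hits, bg)
        assert not res["significant"].any()
        assert (res["p_bonferroni"] >= res["p_value"]).all()

    def test_matches_hypergeometric_tail_oracle(self):
        bg = features_frame(
            [("1", i, i + 1, ["x", "y", "z"][i % 3], f"f{i}") for i in range(1000)]
        )
        rng = np.random.default_rng(12)
        hits = bg.iloc[rng.choice(1000, 20, replace=False)].rename(
            columns={"name": "feature"}
        )
        res = enrich_categories(hits, bg)
        for row in res.itertuples(index=False):
            expect = hypergeom_tail(
                row.hits, row.n_background_total, row.background, row.n_hits_total
            )
            assert row.p_value == pytest.approx(expect, rel=1e-9)
            assert 0.0 < row.p_value <= 1.0

    def test_unknown_hit_category_rejected(self):
        bg = features_frame([("1", 1, 2, "a", "f0")])
        hits = pd.DataFrame([{"feature": "g", "category": "zzz"}])
        with pytest.raises(ValueError, match="absent"):
            enrich_categories(hits, bg)


def test_nearest_rank_percentile_integer_semantics():
    values = np.arange(1, 101)
    assert nearest_rank_percentile(values, 99.0) == 99
    assert nearest_rank_percentile(values, 99.9) == 100
    assert nearest_rank_percentile(np.array([7]), 99.0) == 7
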