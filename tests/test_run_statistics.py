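import numpy as np
import pytest

from rohetscan.genotype_io import MISSING, MarkerMap
from rohetscan.run_detection import Run
from rohetscan.run_statistics import (
    GenomeCoverage,
    genome_length_covered,
    ld_decay,
    one_way_anova,
    per_animal_summary,
    roh_coefficient,
    summarize_dataset,
)

from conftest import make_matrix
from oracles import anova_two_pass


def mk_run(animal="a", chrom="1", start=1_000_000, end=2_500_000, n=30):
    return Run(animal, chrom, start, end, n, n, 0, 0)


def mk_map(chrom_pos):
    chrom = [c for c, _ in chrom_pos]
    pos = [p for _, p in chrom_pos]
    return MarkerMap(
        chrom=np.array(chrom, dtype=object),
        snp_id=np.array([f"s{i}" for i in range(len(pos))], dtype=object),
        pos_bp=np.array(pos),
    ).validate()


class TestGenomeCoverage:
    def test_span_is_last_minus_first(self):
        cov = genome_length_covered(mk_map([("1", 1_000_001), ("1", 3_000_001)]))
        assert cov.per_chrom["1"] == 2_000_000
        assert cov.total == 2_000_000

    def test_single_snp_chromosome_contributes_zero(self):
        cov = genome_length_covered(
            mk_map([("1", 100), ("1", 500), ("2", 1_000)])
        )
        assert cov.per_chrom["2"] == 0
        assert cov.total == 400

    def test_total_is_additive(self):
        cov = genome_length_covered(
            mk_map([("1", 100), ("1", 900), ("2", 50), ("2", 1_050)])
        )
        assert cov.total == 800 + 1_000

    def test_empty_map_errors(self):
        with pytest.raises(ValueError):
            genome_length_covered(
                MarkerMap(np.array([], dtype=object), np.array([], dtype=object),
                          np.array([], dtype=np.int64))
            )


class TestRohCoefficient:
    def test_no_runs_is_zero(self):
        assert roh_coefficient([], GenomeCoverage({"1": 10}, 10)) == 0.0

    def test_full_coverage_is_one(self):
        cov = GenomeCoverage({"1": 1_500_000}, 1_500_000)
        assert roh_coefficient([mk_run(start=1, end=1_500_001)], cov) == 1.0

    def test_planted_fraction_recovered(self, default_sim):
        """Mean F_ROHom over animals matches the planted autozygous fraction
        phi within 0.01 (simulator bookkeeping is the oracle)."""
        from rohetscan.quality_control import apply_qc
        from rohetscan.run_detection import detect_runs, rohom_params
        from rohetscan.run_params import derive_params

        cfg, g, _ = default_sim
        phi = cfg.planted_fraction("ROHom")
        g2, _ = apply_qc(g)
        d = derive_params(g2)
        runs = detect_runs(g2, rohom_params(min_snp=d.n_snp_rohom))
        cov = genome_length_covered(g2.markers)
        tbl = per_animal_summary(runs, cov, g2.samples)
        assert tbl["coefficient"].mean() == pytest.approx(phi, abs=0.01)


class TestSummarizeDataset:
    def test_single_animal_two_runs(self):
        runs = [
            mk_run(start=1_000_000, end=2_500_000),
            mk_run(chrom="2", start=1_000_000, end=3_500_000),
        ]
        tbl = summarize_dataset(runs, ["a", "b"])
        row = tbl.iloc[0]
        assert row["n_total"] == 2
        assert row["n_animals"] == 1
        assert row["runs_per_animal_mean"] == 2
        assert row["length_mb_mean"] == pytest.approx(2.0)
        assert row["n_1_2"] == 1 and row["n_2_4"] == 1

    def test_duplicate_interval_counted_once_in_unique(self):
        runs = [mk_run("a"), mk_run("b"), mk_run("b", chrom="2")]
        row = summarize_dataset(runs, ["a", "b"]).iloc[0]
        assert row["n_total"] == 3
        assert row["n_unique"] == 2

    def test_class_counts_sum_to_total(self, small_sim):
        from rohetscan.run_detection import detect_runs, rohom_params

        _, g, _ = small_sim
        runs = detect_runs(g, rohom_params(min_snp=30))
        row = summarize_dataset(runs, g.samples).iloc[0]
        class_sum = sum(
            row[f"n_{k}"] for k in ("1_2", "2_4", "4_8", "8_16", "gt16")
        )
        assert class_sum == row["n_total"] == len(runs)

    def test_empty_input(self):
        row = summarize_dataset([], ["a"]).iloc[0]
        assert row["n_total"] == 0 and row["n_animals"] == 0


class TestAnova:
    def test_identical_groups_give_f_zero(self):
        res = one_way_anova({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert res.f_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_clear_separation_is_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 50)
        res = one_way_anova({"a": a, "b": a + 10})
        assert res.p_value < 0.001
        assert res.letters["a"] != res.letters["b"]

    def test_matches_two_pass_oracle(self):
        """F and p agree with an independent sums-of-squares computation."""
        rng = np.random.default_rng(1)
        for _ in range(100):
            groups = {
                k: rng.normal(rng.uniform(-1, 1), 1.0, rng.integers(5, 30))
                for k in "abc"
            }
            res = one_way_anova(groups)
            f, p = anova_two_pass(groups)
            assert res.f_statistic == pytest.approx(f, abs=1e-10)
            assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_constant_groups_flagged_degenerate(self):
        res = one_way_anova({"a": [1.0, 1.0], "b": [1.0, 1.0]})
        assert res.degenerate

    def test_letters_share_letter_when_not_different(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 20)
        res = one_way_anova({"a": a, "b": a + 0.01, "c": a + 10})
        assert set(res.letters["a"]) & set(res.letters["b"])
        assert not set(res.letters["a"]) & set(res.letters["c"])


class TestLdDecay:
    def test_duplicated_column_gives_r2_one(self):
        rng = np.random.default_rng(3)
        col = rng.binomial(2, 0.5, 100).astype(np.int8)
        calls = np.column_stack([col, col])
        g = make_matrix(calls, pos=[1_000, 2_000])
        tbl = ld_decay(g, max_dist_bp=10_000, bin_bp=10_000)
        assert tbl["mean_r2"].iloc[0] == pytest.approx(1.0)
        assert tbl["n_pairs"].iloc[0] == 1

    def test_independent_snps_decay_to_noise_floor(self):
        """Independent loci: mean r2 stays near the 1/n sampling bias."""
        rng = np.random.default_rng(4)
        n = 200
        calls = rng.binomial(2, 0.5, size=(n, 120)).astype(np.int8)
        g = make_matrix(calls, pos=np.arange(120) * 10_000 + 1)
        tbl = ld_decay(g, max_dist_bp=500_000, bin_bp=100_000)
        assert (tbl["mean_r2"] < 3.0 / n).all()

    def test_missing_handled_pairwise_complete(self):
        rng = np.random.default_rng(5)
        col = rng.binomial(2, 0.5, 200).astype(np.int8)
        col2 = col.copy()
        col2[:20] = MISSING
        g = make_matrix(np.column_stack([col, col2]), pos=[1_000, 2_000])
        tbl = ld_decay(g, max_dist_bp=10_000, bin_bp=10_000)
        assert tbl["mean_r2"].iloc[0] == pytest.approx(1.0)

    def test_thinning_preserves_decay_curve(self, default_sim):
        """Marker thinning leaves the distance-binned r2 curve unchanged
        within sampling noise (curves overlap bin-wise)."""
        from rohetscan.synthetic_data import thin_density

        _, g, _ = default_sim
        sub = g.subset(snp_idx=np.arange(0, 4_000))  # one chromosome, fast
        full = ld_decay(sub, max_dist_bp=500_000, bin_bp=100_000)
        thin = ld_decay(thin_density(sub, 0.3, seed=1), max_dist_bp=500_000,
                        bin_bp=100_000)
        # background is unlinked, so both curves sit at the small-sample
        # noise floor; require bin-wise agreement well inside that scale
        assert np.allclose(full["mean_r2"], thin["mean_r2"], atol=0.01)
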