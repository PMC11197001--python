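"""End-to-end orchestration of the density-sensitivity experiment.

One call runs: simulate (or ingest) -> nested density tiers -> per-tier QC,
parameter derivation, ROHom and ROHet detection, dataset and per-animal
summaries, incidence tracks, islands and repeated regions -> cross-tier
ANOVA comparisons, island-SNP intersections, incidence correlations and LD
decay curves. Every output is a TSV/BED/JSON file under the output
directory, and a manifest records versions, seeds and all thresholds so a
rerun with the same config is byte-identical.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genotype_io import HET, HOM, GenotypeMatrix, read_bed, read_ped_map
from .quality_control import QcThresholds, apply_qc
from .run_detection import RunParams, detect_runs, runs_to_frame
from .run_params import derive_params
from .run_statistics import (
    genome_length_covered,
    ld_decay,
    one_way_anova,
    per_animal_summary,
    summarize_dataset,
)
from .shared_regions import (
    call_islands,
    incidence_correlation,
    intersect_island_snps,
    intervals_to_bed,
    repeated_regions,
    snp_incidence,
)
from .synthetic_data import SimConfig, nested_tiers, simulate, write_ground_truth

log = logging.getLogger("rohetscan")


class PipelineError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Pipeline configuration.

    Either ``sim`` (synthetic input) or ``ped``/``bed`` file paths must be
    given. ``tier_fractions`` defines the nested density tiers applied to
    the master panel.
    """

    out_dir: str = "rohetscan_out"
    seed: int = 0
    sim: SimConfig | None = None
    ped: str | None = None
    map: str | None = None
    bed: str | None = None
    bim: str | None = None
    fam: str | None = None
    qc: QcThresholds = field(default_factory=QcThresholds)
    alpha: float = 0.05
    tier_fractions: dict[str, float] = field(
        default_factory=lambda: {"HD": 1.0, "MD": 0.19, "LD": 0.075}
    )
    min_length_bp: int = 1_000_000
    max_gap_bp: int = 1_000_000
    island_percentile: float = 99.0
    repeated_top_fraction: float = 0.001
    anova_alpha: float = 0.001
    ld_max_dist_bp: int = 1_000_000
    ld_bin_bp: int = 50_000

    def validate(self) -> None:
        if self.sim is None:
            if self.ped is not None:
                paths = [self.ped, self.map]
            elif self.bed is not None:
                paths = [self.bed, self.bim, self.fam]
            else:
                raise ValueError("config needs either sim, ped/map or bed/bim/fam")
            for p in paths:
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"input file missing: {p}")
        if len(set(self.tier_fractions)) != len(self.tier_fractions):
            raise ValueError("tier labels must be unique")


def _load_master(cfg: PipelineConfig, out: Path) -> GenotypeMatrix:
    if cfg.sim is not None:
        g, truth = simulate(cfg.sim)
        write_ground_truth(truth, out / "ground_truth.tsv")
        return g
    if cfg.ped is not None:
        return read_ped_map(cfg.ped, cfg.map)
    return read_bed(cfg.bed, cfg.bim, cfg.fam)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full experiment; returns a result bundle of DataFrames.

    Raises :class:`PipelineError` naming the failing stage; outputs written
    before the failure are left on disk.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "load"
    try:
        master = _load_master(cfg, out)
        log.info("master panel: %d animals x %d SNPs", master.n_samples,
                 master.n_snps)

        stage = "thin"
        tiers = nested_tiers(master, cfg.tier_fractions, seed=cfg.seed + 1)

        bundle: dict = {"tiers": {}, "config": cfg}
        runs_frames: dict[tuple[str, str], pd.DataFrame] = {}
        tracks: dict[tuple[str, str], pd.DataFrame] = {}
        per_animal: dict[tuple[str, str], pd.DataFrame] = {}
        manifest: dict = {
            "rohetscan_version": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "seed": cfg.seed,
            "alpha": cfg.alpha,
            "qc": {
                "hwe_p_min": cfg.qc.hwe_p_min,
                "maf_min": cfg.qc.maf_min,
                "snp_call_min": cfg.qc.snp_call_min,
                "sample_call_min": cfg.qc.sample_call_min,
            },
            "island_percentile": cfg.island_percentile,
            "repeated_top_fraction": cfg.repeated_top_fraction,
            "anova_alpha": cfg.anova_alpha,
            "tiers": {},
        }

        for label in cfg.tier_fractions:
            tier_dir = out / label
            tier_dir.mkdir(exist_ok=True)
            g_raw = tiers[label]

            stage = f"{label}:qc"
            g, report = apply_qc(g_raw, cfg.qc)
            report.to_frame().to_csv(tier_dir / "qc_report.tsv", sep="\t",
                                     index=False)
            log.info("[%s] QC: %d -> %d SNPs, %d -> %d animals", label,
                     report.n_snps_in, report.n_snps_out,
                     report.n_samples_in, report.n_samples_out)

            stage = f"{label}:params"
            derived = derive_params(g, alpha=cfg.alpha)
            pd.DataFrame([asdict(derived)]).to_csv(
                tier_dir / "derived_params.tsv", sep="\t", index=False
            )
            params = {
                "ROHom": RunParams(
                    target=HOM, min_snp=derived.n_snp_rohom,
                    max_opposite=0, max_missing=0,
                    min_length_bp=cfg.min_length_bp, max_gap_bp=cfg.max_gap_bp,
                ),
                "ROHet": RunParams(
                    target=HET, min_snp=derived.n_snp_rohet,
                    max_opposite=derived.max_opp, max_missing=0,
                    min_length_bp=cfg.min_length_bp, max_gap_bp=cfg.max_gap_bp,
                ),
            }

            cov = genome_length_covered(g.markers)
            tier_bundle: dict = {
                "genotypes": g, "qc_report": report, "derived": derived,
                "coverage": cov,
            }
            manifest["tiers"][label] = {
                "n_snps": g.n_snps,
                "n_animals": g.n_samples,
                "covered_bp": cov.total,
                "n_snp_rohom": derived.n_snp_rohom,
                "n_snp_rohet": derived.n_snp_rohet,
                "max_opp": derived.max_opp,
            }

            for kind, p in params.items():
                stage = f"{label}:{kind}:detect"
                runs = detect_runs(g, p)
                rf = runs_to_frame(runs, group=label)
                rf.to_csv(tier_dir / f"runs_{kind}.tsv", sep="\t", index=False)
                runs_frames[(label, kind)] = rf
                log.info("[%s] %s: %d runs", label, kind, len(runs))

                stage = f"{label}:{kind}:summaries"
                summary = summarize_dataset(runs, g.samples)
                summary.to_csv(tier_dir / f"summary_{kind}.tsv", sep="\t",
                               index=False)
                animal_tbl = per_animal_summary(runs, cov, g.samples)
                animal_tbl.to_csv(tier_dir / f"per_animal_{kind}.tsv", sep="\t",
                                  index=False)
                per_animal[(label, kind)] = animal_tbl

                track = snp_incidence(runs, g.markers, g.n_samples)
                track.to_csv(tier_dir / f"incidence_{kind}.tsv", sep="\t",
                             index=False)
                tracks[(label, kind)] = track

                if not runs:
                    log.info("[%s] %s: no runs detected; islands and repeated "
                             "regions skipped", label, kind)
                    tier_bundle[kind] = {
                        "runs": rf, "summary": summary, "per_animal": animal_tbl,
                        "incidence": track, "islands": [], "repeated": [],
                        "repeated_top": [],
                    }
                    continue

                stage = f"{label}:{kind}:islands"
                islands, threshold = call_islands(
                    track, cfg.island_percentile, cfg.max_gap_bp
                )
                isl_df = pd.DataFrame(
                    [
                        {
                            "chrom": i.chrom, "start_bp": i.start_bp,
                            "end_bp": i.end_bp, "n_snps": len(i.snp_ids),
                            "max_incidence": i.max_incidence,
                        }
                        for i in islands
                    ]
                )
                isl_df.to_csv(tier_dir / f"islands_{kind}.tsv", sep="\t",
                              index=False)
                if not isl_df.empty:
                    intervals_to_bed(isl_df).to_csv(
                        tier_dir / f"islands_{kind}.bed", sep="\t",
                        index=False, header=False,
                    )

                stage = f"{label}:{kind}:repeated"
                rep, rep_top = repeated_regions(runs, cfg.repeated_top_fraction)
                rep_df = pd.DataFrame(
                    [
                        {
                            "chrom": r.chrom, "start_bp": r.start_bp,
                            "end_bp": r.end_bp, "n_animals": r.n_animals,
                            "top": r in rep_top,
                        }
                        for r in rep
                    ]
                )
                rep_df.to_csv(tier_dir / f"repeated_{kind}.tsv", sep="\t",
                              index=False)

                tier_bundle[kind] = {
                    "runs": rf, "summary": summary, "per_animal": animal_tbl,
                    "incidence": track, "islands": islands,
                    "islands_threshold": threshold, "repeated": rep,
                    "repeated_top": rep_top,
                }

            stage = f"{label}:ld"
            ld = ld_decay(g, cfg.ld_max_dist_bp, cfg.ld_bin_bp)
            ld.to_csv(tier_dir / "ld_decay.tsv", sep="\t", index=False)
            tier_bundle["ld_decay"] = ld
            bundle["tiers"][label] = tier_bundle

        stage = "cross-tier"
        bundle["comparisons"] = _cross_tier(
            cfg, out, runs_frames, tracks, per_animal
        )

        stage = "manifest"
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        bundle["manifest"] = manifest
        return bundle
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with stage name
        raise PipelineError(stage, exc) from exc


def _cross_tier(cfg, out, runs_frames, tracks, per_animal) -> dict:
    """ANOVA across tiers, island intersections and incidence correlations."""
    comparisons: dict = {}
    rows = []
    for kind in ("ROHom", "ROHet"):
        groups_n = {}
        groups_len = {}
        groups_coef = {}
        for label in cfg.tier_fractions:
            tbl = per_animal[(label, kind)]
            with_runs = tbl[tbl["n_runs"] > 0]
            if len(with_runs) >= 2:
                groups_n[label] = with_runs["n_runs"].to_numpy(dtype=float)
                groups_len[label] = (
                    with_runs["mean_length_bp"].to_numpy(dtype=float) / 1e6
                )
            groups_coef[label] = tbl["coefficient"].to_numpy(dtype=float)
        for name, groups in (
            ("n_runs", groups_n), ("mean_length_mb", groups_len),
            ("coefficient", groups_coef),
        ):
            if len(groups) < 2:
                continue
            res = one_way_anova(groups, alpha=cfg.anova_alpha)
            comparisons[(kind, name)] = res
            for label in groups:
                rows.append(
                    {
                        "kind": kind, "variable": name, "tier": label,
                        "mean": res.group_means[label],
                        "letters": res.letters.get(label, ""),
                        "F": res.f_statistic, "p": res.p_value,
                    }
                )
    pd.DataFrame(rows).to_csv(out / "anova_comparisons.tsv", sep="\t",
                              index=False)

    inter_rows = []
    for kind in ("ROHom", "ROHet"):
        kind_tracks = {
            label: tracks[(label, kind)]
            for label in cfg.tier_fractions
            if tracks[(label, kind)]["n_animals_in_run"].sum() > 0
        }
        if len(kind_tracks) >= 2:
            common = intersect_island_snps(kind_tracks, cfg.island_percentile)
            comparisons[(kind, "island_snps_common")] = common
            inter_rows += [{"kind": kind, "snp_id": s} for s in sorted(common)]
            labels = list(kind_tracks)
            for i in range(len(labels)):
                for j in range(i + 1, len(labels)):
                    try:
                        r = incidence_correlation(
                            kind_tracks[labels[i]], kind_tracks[labels[j]]
                        )
                    except ValueError:
                        continue
                    comparisons[(kind, f"corr_{labels[i]}_{labels[j]}")] = r
    pd.DataFrame(inter_rows, columns=["kind", "snp_id"]).to_csv(
        out / "island_snps_common.tsv", sep="\t", index=False
    )
    return comparisons
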