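"""Synthetic diploid SNP genotypes with planted runs and known ground truth.

The generator emulates the data structure of a multi-density cattle
genotyping study: a few hundred animals on several autosomes with bp
positions, Hardy-Weinberg background genotypes with Beta-distributed allele
frequencies, planted autozygous segments (long "recent" and short "ancient"
ROHom), planted heterozygosity-rich segments shared across animals,
configurable missingness, and nested density tiers (an HD master panel
thinned to MD and LD marker subsets, mirroring 800k/140k/50k arrays).

Autozygosity is planted by haplotype self-copying: carrier animals receive
both alleles from one sampled haplotype, creating true IBD-like homozygous
stretches without coalescent machinery. Segments planted with
``identical=True`` share a single haplotype across carriers and get sharp
breakpoints (the SNP flanking each side is forced heterozygous), producing
runs with identical coordinates across carriers — the raw material of
repeated-region and island statistics. Heterozygosity-rich plants are
per-SNP Bernoulli (default ``het_prob`` 0.9), since real heterozygosity-rich
regions are not perfectly heterozygous.

Ground truth records, per (segment, carrier), both the planted interval and
the realized first/last target-state SNP actually emitted inside it, so
detector recovery can be scored against what the genotypes truly contain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, MarkerMap


@dataclass(frozen=True)
class PlantedSegment:
    """One segment to plant: ``kind`` is "ROHom" or "ROHet"."""

    kind: str
    chrom: str
    start_bp: int
    end_bp: int
    carrier_fraction: float
    het_prob: float = 0.9  # ROHet only
    identical: bool = False  # ROHom only: shared haplotype + sharp breakpoints

    def __post_init__(self) -> None:
        if self.kind not in ("ROHom", "ROHet"):
            raise ValueError("segment kind must be 'ROHom' or 'ROHet'")
        if not 0.0 <= self.carrier_fraction <= 1.0:
            raise ValueError("carrier fraction outside [0, 1]")
        if self.start_bp >= self.end_bp:
            raise ValueError("segment start must precede end")


def _default_plants() -> list[PlantedSegment]:
    """Default planted-segment mix.

    ROHom: long recent (6-10 Mb) and short ancient (1.2-4.5 Mb) segments
    whose carrier-weighted expected length per animal is 10 Mb = 5% of the
    200 Mb default genome (planted autozygous fraction phi = 0.05). Carrier
    fractions stay at or below 0.25: a shared homozygous segment depresses
    heterozygosity locally, and larger sharing would make its SNPs fail the
    exact HWE filter — real shared ROH sit near ~10% sharing. Two segments
    are ``identical`` to seed repeated regions. ROHet: three shared
    heterozygosity-rich segments of 1.8-2.5 Mb.
    """
    H = PlantedSegment
    return [
        # kind, chrom, start, end, carrier fraction
        H("ROHom", "1", 30_000_000, 38_000_000, 0.20),
        H("ROHom", "2", 5_000_000, 15_000_000, 0.15),
        H("ROHom", "3", 10_000_000, 14_000_000, 0.25, identical=True),
        H("ROHom", "2", 25_000_000, 28_000_000, 0.25),
        H("ROHom", "4", 8_000_000, 9_500_000, 0.25, identical=True),
        H("ROHom", "5", 20_000_000, 21_500_000, 0.25),
        H("ROHom", "1", 10_000_000, 11_200_000, 0.25),
        H("ROHom", "4", 25_000_000, 31_000_000, 0.20),
        H("ROHom", "5", 5_000_000, 13_000_000, 0.15),
        H("ROHom", "3", 30_000_000, 34_000_000, 0.20),
        H("ROHom", "4", 15_000_000, 19_500_000, 0.20),
        H("ROHet", "5", 30_000_000, 32_500_000, 0.25),
        H("ROHet", "3", 25_000_000, 26_800_000, 0.20),
        H("ROHet", "1", 20_000_000, 22_000_000, 0.15),
    ]


@dataclass(frozen=True)
class SimConfig:
    """Simulation design. Defaults are the desk-scale study conditions:
    200 animals, 5 x 40 Mb autosomes, a 20k-SNP HD master (100 SNP/Mb),
    Beta(2,2) allele frequencies (mean heterozygosity 0.4), planted
    autozygous fraction 0.05, and nested HD/MD/LD tiers at 1/0.19/0.075."""

    n_animals: int = 200
    chrom_lengths_bp: tuple[int, ...] = (40_000_000,) * 5
    snp_density_per_mb: float = 100.0
    allele_freq_beta: tuple[float, float] = (2.0, 2.0)
    missing_rate: float = 0.0
    planted: tuple[PlantedSegment, ...] = field(
        default_factory=lambda: tuple(_default_plants())
    )
    thinning_fractions: dict[str, float] = field(
        default_factory=lambda: {"HD": 1.0, "MD": 0.19, "LD": 0.075}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate outside [0, 1]")
        lengths = dict(zip((str(i + 1) for i in range(len(self.chrom_lengths_bp))),
                           self.chrom_lengths_bp))
        for seg in self.planted:
            if seg.chrom not in lengths:
                raise ValueError(f"planted segment on unknown chromosome {seg.chrom}")
            if seg.end_bp > lengths[seg.chrom]:
                raise ValueError("planted segment exceeds chromosome length")

    @property
    def chromosomes(self) -> list[str]:
        return [str(i + 1) for i in range(len(self.chrom_lengths_bp))]

    def planted_fraction(self, kind: str = "ROHom") -> float:
        """Carrier-weighted expected planted fraction of the genome."""
        genome = sum(self.chrom_lengths_bp)
        return sum(
            (s.end_bp - s.start_bp) * s.carrier_fraction
            for s in self.planted
            if s.kind == kind
        ) / genome


@dataclass
class GroundTruth:
    """Per-(segment, carrier) record of what was actually planted."""

    table: pd.DataFrame  # columns: segment_id, kind, chrom, animal,
    #          start_bp, end_bp, realized_start_bp, realized_end_bp, n_informative

    def for_kind(self, kind: str) -> pd.DataFrame:
        return self.table[self.table["kind"] == kind].reset_index(drop=True)


def _check_segment_overlaps(cfg: SimConfig, carriers: dict[int, np.ndarray]) -> None:
    """Planted intervals of different kinds must not overlap for one animal."""
    by_animal: dict[int, list[tuple[str, str, int, int]]] = {}
    for seg_id, idx in carriers.items():
        seg = cfg.planted[seg_id]
        for a in idx:
            by_animal.setdefault(int(a), []).append(
                (seg.kind, seg.chrom, seg.start_bp, seg.end_bp)
            )
    for a, segs in by_animal.items():
        for i in range(len(segs)):
            for j in range(i + 1, len(segs)):
                k1, c1, s1, e1 = segs[i]
                k2, c2, s2, e2 = segs[j]
                if k1 != k2 and c1 == c2 and s1 < e2 and s2 < e1:
                    raise ValueError(
                        f"animal {a}: overlapping planted ROHom/ROHet segments "
                        f"on chromosome {c1}"
                    )


def simulate(cfg: SimConfig) -> tuple[GenotypeMatrix, GroundTruth]:
    """Generate the HD master panel and its ground truth (reproducible from
    ``cfg.seed``)."""
    rng = np.random.default_rng(cfg.seed)
    chroms = cfg.chromosomes

    # SNP positions: sorted uniform draws per chromosome at the HD density
    chrom_arr: list[str] = []
    pos_arr: list[np.ndarray] = []
    for c, length in zip(chroms, cfg.chrom_lengths_bp):
        n = int(round(length / 1e6 * cfg.snp_density_per_mb))
        pos = np.sort(rng.choice(np.int64(length), size=n, replace=False)) + 1
        chrom_arr += [c] * n
        pos_arr.append(pos)
    pos_all = np.concatenate(pos_arr)
    n_snps = pos_all.size
    markers = MarkerMap(
        chrom=np.array(chrom_arr, dtype=object),
        snp_id=np.array([f"snp_{c}_{p}" for c, p in zip(chrom_arr, pos_all)],
                        dtype=object),
        pos_bp=pos_all,
    ).validate()

    a, b = cfg.allele_freq_beta
    freqs = rng.beta(a, b, size=n_snps)
    calls = rng.binomial(2, freqs[None, :], size=(cfg.n_animals, n_snps)).astype(
        np.int8
    )

    # carrier assignment per segment
    carriers: dict[int, np.ndarray] = {}
    for seg_id, seg in enumerate(cfg.planted):
        n_carriers = int(round(seg.carrier_fraction * cfg.n_animals))
        carriers[seg_id] = np.sort(
            rng.choice(cfg.n_animals, size=n_carriers, replace=False)
        )
    _check_segment_overlaps(cfg, carriers)

    samples = [f"animal_{i:04d}" for i in range(cfg.n_animals)]
    gt_rows: list[dict] = []
    for seg_id, seg in enumerate(cfg.planted):
        sl = markers.chrom_slice(seg.chrom)
        pos = markers.pos_bp[sl]
        lo = sl.start + int(np.searchsorted(pos, seg.start_bp, side="left"))
        hi = sl.start + int(np.searchsorted(pos, seg.end_bp, side="right"))
        width = hi - lo
        if width == 0:
            continue
        shared_hap = rng.random(width) < freqs[lo:hi]  # one haplotype, if shared
        for animal_idx in carriers[seg_id]:
            if seg.kind == "ROHom":
                hap = (
                    shared_hap
                    if seg.identical
                    else rng.random(width) < freqs[lo:hi]
                )
                calls[animal_idx, lo:hi] = np.where(hap, 2, 0)
                if seg.identical:  # sharp IBD breakpoints
                    if lo > sl.start:
                        calls[animal_idx, lo - 1] = 1
                    if hi < sl.stop:
                        calls[animal_idx, hi] = 1
            else:
                het = rng.random(width) < seg.het_prob
                f = freqs[lo:hi]
                hom2 = rng.random(width) < f**2 / (f**2 + (1 - f) ** 2)
                calls[animal_idx, lo:hi] = np.where(het, 1, np.where(hom2, 2, 0))
            gt_rows.append(
                {
                    "segment_id": seg_id,
                    "kind": seg.kind,
                    "chrom": seg.chrom,
                    "animal": samples[animal_idx],
                    "start_bp": seg.start_bp,
                    "end_bp": seg.end_bp,
                    "_lo": lo,
                    "_hi": hi,
                }
            )

    if cfg.missing_rate > 0:
        mask = rng.random(calls.shape) < cfg.missing_rate
        calls[mask] = MISSING

    g = GenotypeMatrix(samples=samples, calls=calls, markers=markers)
    base = pd.DataFrame(
        gt_rows,
        columns=["segment_id", "kind", "chrom", "animal", "start_bp", "end_bp",
                 "_lo", "_hi"],
    ).drop(columns=["_lo", "_hi"])
    truth = GroundTruth(table=realize_on(g, base))
    return g, truth


def realize_on(g: GenotypeMatrix, table: pd.DataFrame) -> pd.DataFrame:
    """Realized anchors of each planted instance on a given panel.

    For every (segment, carrier) row, locate the first and last target-state
    SNP inside the planted interval *on this panel's map and genotypes* and
    count the informative (target-state) SNPs between them. Recomputable on
    any QC'd or thinned panel, so detector recovery is always scored against
    the markers that actually survive.
    """
    sample_idx = {s: i for i, s in enumerate(g.samples)}
    out = []
    for row in table.to_dict("records"):
        row = dict(row)
        sl = g.markers.chrom_slice(str(row["chrom"]))
        pos = g.markers.pos_bp[sl]
        lo = sl.start + int(np.searchsorted(pos, row["start_bp"], side="left"))
        hi = sl.start + int(np.searchsorted(pos, row["end_bp"], side="right"))
        i = sample_idx.get(row["animal"])
        if i is None or hi <= lo:
            row["realized_start_bp"] = row["realized_end_bp"] = -1
            row["n_informative"] = 0
            out.append(row)
            continue
        seg_calls = g.calls[i, lo:hi]
        target = (
            (seg_calls == 1)
            if row["kind"] == "ROHet"
            else np.isin(seg_calls, (0, 2))
        )
        idx = np.flatnonzero(target)
        if idx.size:
            row["realized_start_bp"] = int(g.markers.pos_bp[lo + idx[0]])
            row["realized_end_bp"] = int(g.markers.pos_bp[lo + idx[-1]])
        else:
            row["realized_start_bp"] = row["realized_end_bp"] = -1
        row["n_informative"] = int(idx.size)
        out.append(row)
    columns = [
        "segment_id", "kind", "chrom", "animal", "start_bp", "end_bp",
        "realized_start_bp", "realized_end_bp", "n_informative",
    ]
    return pd.DataFrame(out, columns=columns)


def thin_density(
    g: GenotypeMatrix, fraction: float, seed: int | np.random.Generator
) -> GenotypeMatrix:
    """Random marker subset of the given fraction, uniform per chromosome,
    order preserved; genotypes are kept exactly (never resampled)."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if fraction == 1.0:
        return g
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    keep: list[np.ndarray] = []
    for chrom in g.markers.chromosomes:
        sl = g.markers.chrom_slice(chrom)
        n = sl.stop - sl.start
        k = int(round(fraction * n))
        if k == 0:
            import warnings

            warnings.warn(
                f"thinning to {fraction} removes every SNP on chromosome {chrom}",
                stacklevel=2,
            )
            continue
        keep.append(
            np.sort(rng.choice(np.arange(sl.start, sl.stop), size=k, replace=False))
        )
    idx = np.concatenate(keep) if keep else np.empty(0, dtype=np.intp)
    return g.subset(snp_idx=idx)


def nested_tiers(
    g: GenotypeMatrix,
    fractions: dict[str, float],
    seed: int,
) -> dict[str, GenotypeMatrix]:
    """Nested density tiers: each sparser tier's markers are a subset of the
    denser tier's (LD within MD within HD), mimicking shared-SNP panels."""
    rng = np.random.default_rng(seed)
    ordered = sorted(fractions.items(), key=lambda kv: -kv[1])
    out: dict[str, GenotypeMatrix] = {}
    current = g
    current_fraction = 1.0
    for label, frac in ordered:
        current = thin_density(current, frac / current_fraction, rng)
        current_fraction = frac
        out[label] = current
    return out


def make_hwe_violator(n: int) -> np.ndarray:
    """An all-heterozygote genotype column: the maximal Hardy-Weinberg
    violation at MAF 0.5 (passes the MAF filter, fails only the HWE test)."""
    if n < 50:
        raise ValueError("need n >= 50 for the violation to reach P < 1e-6")
    return np.ones(n, dtype=np.int8)


def write_ground_truth(truth: GroundTruth, path) -> None:
    truth.table.to_csv(path, sep="\t", index=False)
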