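"""PLINK genotype input/output and run-state conversion.

Genotypes live in a :class:`GenotypeMatrix` — an animals x SNPs matrix of
codes ``0`` (homozygous A1A1), ``1`` (heterozygous), ``2`` (homozygous A2A2)
and ``-1`` (missing) — bound to a :class:`MarkerMap` of (chromosome, SNP id,
bp position) records sorted along the genome.

Run detection only ever looks at zygosity, so PED parsing assigns A1 to the
first allele encountered at each SNP; allele identity is otherwise ignored.
Both the text PED/MAP and the binary BED/BIM/FAM (v1.00, SNP-major) flavors
are supported with writer counterparts, and round-trip exactly.

Coordinates are 1-based inclusive base pairs throughout; BED-format *interval*
exports elsewhere in the package convert to 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Missing-genotype sentinel in :attr:`GenotypeMatrix.calls`.
MISSING: int = -1

#: Zygosity states used by the run scanner.
HOM: int = 0
HET: int = 1
MISS: int = 2

_STATE_NAMES = {HOM: "HOM", HET: "HET", MISS: "MISS"}

#: Cattle autosomes — the default autosome set for QC.
CATTLE_AUTOSOMES: frozenset[str] = frozenset(str(c) for c in range(1, 30))


class GenotypeFileError(ValueError):
    """Malformed or unsupported genotype file content."""


def _chrom_sort_key(label: str) -> tuple[int, int | str]:
    """Natural ordering: numeric chromosome labels first, then lexicographic."""
    try:
        return (0, int(label))
    except ValueError:
        return (1, label)


@dataclass(frozen=True)
class MarkerMap:
    """Ordered SNP records defining the coordinate context for all runs.

    Parameters
    ----------
    chrom, snp_id, pos_bp
        Equal-length arrays; positions are 1-based bp. Records must be
        sorted by (chrom, pos_bp) with strictly increasing positions within
        a chromosome and unique SNP ids — use :meth:`validate` after manual
        construction, or :meth:`from_frame` which sorts for you.
    """

    chrom: np.ndarray
    snp_id: np.ndarray
    pos_bp: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", np.asarray(self.chrom, dtype=object))
        object.__setattr__(self, "snp_id", np.asarray(self.snp_id, dtype=object))
        object.__setattr__(self, "pos_bp", np.asarray(self.pos_bp, dtype=np.int64))

    def __len__(self) -> int:
        return len(self.snp_id)

    def validate(self) -> "MarkerMap":
        if not (len(self.chrom) == len(self.snp_id) == len(self.pos_bp)):
            raise GenotypeFileError("marker map arrays have unequal lengths")
        if len(self) and self.pos_bp.min() < 1:
            raise GenotypeFileError("marker positions must be >= 1 (1-based bp)")
        ids = pd.Index(self.snp_id)
        if ids.has_duplicates:
            dup = ids[ids.duplicated()][0]
            raise GenotypeFileError(f"duplicate snp_id {dup!r}")
        for lo, hi in zip(*self._chrom_bounds()):
            pos = self.pos_bp[lo:hi]
            if np.any(np.diff(pos) <= 0):
                raise GenotypeFileError(
                    f"positions not strictly increasing on chromosome "
                    f"{self.chrom[lo]!r}"
                )
        return self

    def _chrom_bounds(self) -> tuple[list[int], list[int]]:
        """Start/stop index pairs of each chromosome block, in map order."""
        starts: list[int] = []
        stops: list[int] = []
        prev = None
        for i, c in enumerate(self.chrom):
            if c != prev:
                if prev is not None:
                    stops.append(i)
                starts.append(i)
                prev = c
        if prev is not None:
            stops.append(len(self.chrom))
        return starts, stops

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome labels in map order (each once)."""
        out: list[str] = []
        for c in self.chrom:
            if not out or out[-1] != c:
                out.append(c)
        return out

    def chrom_slice(self, chrom: str) -> slice:
        """Index slice of ``chrom``'s SNPs; empty slice if absent."""
        idx = np.flatnonzero(self.chrom == chrom)
        if idx.size == 0:
            return slice(0, 0)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "snp_id": self.snp_id, "pos_bp": self.pos_bp}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MarkerMap":
        """Build a sorted, validated map from a (chrom, snp_id, pos_bp) frame."""
        df = df.copy()
        df["_key"] = [_chrom_sort_key(str(c)) for c in df["chrom"]]
        df = df.sort_values(["_key", "pos_bp"], kind="stable")
        return cls(
            chrom=df["chrom"].astype(str).to_numpy(dtype=object),
            snp_id=df["snp_id"].astype(str).to_numpy(dtype=object),
            pos_bp=df["pos_bp"].to_numpy(dtype=np.int64),
        ).validate()

    def argsort_genome(self) -> np.ndarray:
        """Permutation sorting records by (chrom natural order, pos_bp)."""
        keys = [_chrom_sort_key(str(c)) for c in self.chrom]
        return np.array(
            sorted(range(len(self)), key=lambda i: (keys[i], self.pos_bp[i])),
            dtype=np.intp,
        )


@dataclass
class GenotypeMatrix:
    """Animals x SNPs genotype codes bound to a :class:`MarkerMap`.

    ``calls`` is an ``int8`` array with values in {0, 1, 2, MISSING}.
    """

    samples: list[str]
    calls: np.ndarray
    markers: MarkerMap

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise GenotypeFileError("calls must be a 2-D array")
        if self.calls.shape != (len(self.samples), len(self.markers)):
            raise GenotypeFileError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} SNPs"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise GenotypeFileError("genotype codes outside {0,1,2,MISSING}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.markers)

    def sample_index(self, animal: str) -> int:
        try:
            return self.samples.index(animal)
        except ValueError:
            raise KeyError(f"unknown animal {animal!r}") from None

    def subset(
        self,
        sample_idx: np.ndarray | Sequence[int] | None = None,
        snp_idx: np.ndarray | Sequence[int] | None = None,
    ) -> "GenotypeMatrix":
        """New matrix restricted to the given sample/SNP indices (order kept)."""
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        mi = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        markers = MarkerMap(
            chrom=self.markers.chrom[mi],
            snp_id=self.markers.snp_id[mi],
            pos_bp=self.markers.pos_bp[mi],
        )
        return GenotypeMatrix(
            samples=[self.samples[i] for i in si],
            calls=self.calls[np.ix_(si, mi)],
            markers=markers,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and np.array_equal(self.calls, other.calls)
            and np.array_equal(self.markers.chrom, other.markers.chrom)
            and np.array_equal(self.markers.snp_id, other.markers.snp_id)
            and np.array_equal(self.markers.pos_bp, other.markers.pos_bp)
        )


@dataclass(frozen=True)
class StateSequence:
    """Per-SNP zygosity states for one animal on one chromosome.

    ``states`` holds {HOM, HET, MISS}; ``target`` records which state counts
    as "matching" for the downstream scan; ``pos_bp`` is the aligned map slice.
    """

    animal: str
    chrom: str
    states: np.ndarray
    pos_bp: np.ndarray
    target: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", np.asarray(self.states, dtype=np.int8))
        object.__setattr__(self, "pos_bp", np.asarray(self.pos_bp, dtype=np.int64))
        if len(self.states) != len(self.pos_bp):
            raise ValueError("states and positions have different lengths")
        if self.target not in (HOM, HET):
            raise ValueError("target must be HOM or HET")


def calls_to_states(calls: np.ndarray) -> np.ndarray:
    """Map genotype codes {0,1,2,MISSING} onto zygosity states {HOM,HET,MISS}."""
    states = np.empty(calls.shape, dtype=np.int8)
    states[(calls == 0) | (calls == 2)] = HOM
    states[calls == 1] = HET
    states[calls == MISSING] = MISS
    return states


def to_states(g: GenotypeMatrix, animal: str, chrom: str, target: int) -> StateSequence:
    """State sequence for one animal on one chromosome.

    ``target`` (HOM or HET) only relabels which state is "matching" for the
    scanner; the state coding itself is symmetric in the allele labels.
    """
    i = g.sample_index(animal)
    sl = g.markers.chrom_slice(chrom)
    if sl.start == sl.stop:
        raise KeyError(f"unknown chromosome {chrom!r}")
    return StateSequence(
        animal=animal,
        chrom=chrom,
        states=calls_to_states(g.calls[i, sl]),
        pos_bp=g.markers.pos_bp[sl],
        target=target,
    )


def zygosity_equivalent(a: GenotypeMatrix, b: GenotypeMatrix) -> bool:
    """True when two matrices are identical up to per-column allele-label
    swaps (codes 0 and 2 exchanged on some columns).

    This is the natural equality for PED round trips: text PED files carry no
    allele-priority side channel, so a column whose first non-missing call is
    homozygous A2 necessarily reads back with swapped labels under
    first-allele coding. Zygosity — all that run detection uses — is
    preserved exactly.
    """
    if (
        a.samples != b.samples
        or not np.array_equal(a.markers.chrom, b.markers.chrom)
        or not np.array_equal(a.markers.snp_id, b.markers.snp_id)
        or not np.array_equal(a.markers.pos_bp, b.markers.pos_bp)
    ):
        return False
    same = (a.calls == b.calls).all(axis=0)
    swapped = np.where(a.calls == 0, 2, np.where(a.calls == 2, 0, a.calls))
    return bool((same | (swapped == b.calls).all(axis=0)).all())


# ---------------------------------------------------------------------------
# PED/MAP text format


def read_ped_map(ped_path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    """Read a PLINK text fileset.

    A1 at each SNP is the first non-missing allele encountered in file order
    (deterministic); ``0 0`` codes a missing genotype. The map is sorted by
    (chromosome, position) and genotype columns permuted to match.
    """
    map_df = pd.read_csv(
        map_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos_bp"],
        dtype={"chrom": str, "snp_id": str},
    )
    if map_df.shape[1] != 4:
        raise GenotypeFileError("MAP file must have 4 columns")
    n_snps = len(map_df)

    samples: list[str] = []
    rows: list[np.ndarray] = []
    a1: list[str | None] = [None] * n_snps
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_snps:
                raise GenotypeFileError(
                    f"PED line {lineno}: expected {6 + 2 * n_snps} fields "
                    f"for {n_snps} SNPs, got {len(fields)}"
                )
            samples.append(fields[1])
            alleles = fields[6:]
            row = np.empty(n_snps, dtype=np.int8)
            for j in range(n_snps):
                x, y = alleles[2 * j], alleles[2 * j + 1]
                if x == "0" or y == "0":
                    row[j] = MISSING
                    continue
                if a1[j] is None:
                    a1[j] = x
                row[j] = int(x != a1[j]) + int(y != a1[j])
            rows.append(row)
    calls = np.vstack(rows) if rows else np.empty((0, n_snps), dtype=np.int8)

    markers = MarkerMap(
        chrom=map_df["chrom"].to_numpy(dtype=object),
        snp_id=map_df["snp_id"].to_numpy(dtype=object),
        pos_bp=map_df["pos_bp"].to_numpy(dtype=np.int64),
    )
    order = markers.argsort_genome()
    markers = MarkerMap(
        chrom=markers.chrom[order], snp_id=markers.snp_id[order],
        pos_bp=markers.pos_bp[order],
    ).validate()
    return GenotypeMatrix(samples=samples, calls=calls[:, order], markers=markers)


def write_ped_map(
    g: GenotypeMatrix, ped_path: str | Path, map_path: str | Path
) -> None:
    """Write a PLINK text fileset (alleles coded A/B, missing as ``0 0``)."""
    with open(map_path, "w") as fh:
        for c, s, p in zip(g.markers.chrom, g.markers.snp_id, g.markers.pos_bp):
            fh.write(f"{c}\t{s}\t0\t{p}\n")
    pair = {0: "A A", 1: "A B", 2: "B B", MISSING: "0 0"}
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(g.samples):
            geno = " ".join(pair[int(v)] for v in g.calls[i])
            fh.write(f"{sid} {sid} 0 0 0 -9 {geno}\n")


# ---------------------------------------------------------------------------
# BED/BIM/FAM binary format (PLINK v1.00, SNP-major)

_BED_MAGIC = b"\x6c\x1b"
_SNP_MAJOR = b"\x01"

# 2-bit PLINK codes -> genotype codes: 00 hom A1, 01 missing, 10 het, 11 hom A2
_BED_DECODE = np.array([0, MISSING, 1, 2], dtype=np.int8)
_BED_ENCODE = {0: 0b00, MISSING: 0b01, 1: 0b10, 2: 0b11}


def read_bed(
    bed_path: str | Path, bim_path: str | Path, fam_path: str | Path
) -> GenotypeMatrix:
    """Read a PLINK binary fileset (v1.00, SNP-major)."""
    fam = pd.read_csv(fam_path, sep=r"\s+", header=None, dtype=str)
    samples = fam[1].tolist()
    bim = pd.read_csv(
        bim_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos_bp", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str},
    )
    n_samples, n_snps = len(samples), len(bim)

    raw = Path(bed_path).read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise GenotypeFileError("not a PLINK BED file (bad magic bytes)")
    if raw[2:3] != _SNP_MAJOR:
        raise GenotypeFileError(
            "unsupported BED mode: only SNP-major (0x01) v1.00 files are read"
        )
    bytes_per_snp = (n_samples + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_snp * n_snps:
        raise GenotypeFileError(
            f"BED payload is {body.size} bytes, expected {bytes_per_snp * n_snps}"
        )
    body = body.reshape(n_snps, bytes_per_snp)
    # unpack 2-bit fields, sample s lives in bits (2s % 8, +1) of byte s//4
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    two_bit = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    two_bit = two_bit.reshape(n_snps, bytes_per_snp * 4)[:, :n_samples]
    calls = _BED_DECODE[two_bit].T  # -> samples x snps

    markers = MarkerMap(
        chrom=bim["chrom"].to_numpy(dtype=object),
        snp_id=bim["snp_id"].to_numpy(dtype=object),
        pos_bp=bim["pos_bp"].to_numpy(dtype=np.int64),
    )
    order = markers.argsort_genome()
    markers = MarkerMap(
        chrom=markers.chrom[order], snp_id=markers.snp_id[order],
        pos_bp=markers.pos_bp[order],
    ).validate()
    return GenotypeMatrix(samples=samples, calls=calls[:, order], markers=markers)


def write_bed(
    g: GenotypeMatrix,
    bed_path: str | Path,
    bim_path: str | Path,
    fam_path: str | Path,
) -> None:
    """Write a PLINK binary fileset (v1.00, SNP-major; alleles coded A/B)."""
    with open(fam_path, "w") as fh:
        for sid in g.samples:
            fh.write(f"{sid} {sid} 0 0 0 -9\n")
    with open(bim_path, "w") as fh:
        for c, s, p in zip(g.markers.chrom, g.markers.snp_id, g.markers.pos_bp):
            fh.write(f"{c}\t{s}\t0\t{p}\tA\tB\n")

    n_samples, n_snps = g.n_samples, g.n_snps
    bytes_per_snp = (n_samples + 3) // 4
    codes = np.empty((n_snps, bytes_per_snp * 4), dtype=np.uint8)
    codes[:] = 0
    enc = np.zeros(4, dtype=np.uint8)
    for geno, code in _BED_ENCODE.items():
        enc[geno % 4] = code  # MISSING (-1) -> index 3
    codes[:, :n_samples] = enc[(g.calls.T % 4)]
    codes = codes.reshape(n_snps, bytes_per_snp, 4)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (codes << shifts[None, None, :]).sum(axis=2).astype(np.uint8)
    with open(bed_path, "wb") as fh:
        fh.write(_BED_MAGIC + _SNP_MAJOR)
        fh.write(packed.tobytes())
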