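"""Consecutive-scan detection of ROHom and ROHet.

A run is a maximal stretch of map-consecutive SNPs whose endpoints are in the
target state (homozygous for ROHom, heterozygous for ROHet) and which
satisfies, jointly:

* at least ``min_snp`` target-state SNPs,
* at most ``max_opposite`` opposite-state and ``max_missing`` missing SNPs
  strictly inside,
* no adjacent-SNP gap above ``max_gap_bp`` anywhere inside,
* a physical span (end - start) of at least ``min_length_bp``.

Detection is a left-to-right greedy scan per animal and chromosome emitting
non-overlapping, leftmost-longest windows: each emitted run starts at the
earliest feasible target-state SNP not covered by a previous run and extends
as far right as validity permits; scanning then resumes after the run. For a
fixed start, every violated constraint is monotone in the right endpoint, so
the longest valid window at that start is well defined; the implementation
exploits this with prefix counts and binary searches rather than rescanning,
but its output is checked against a brute-force window enumerator in the
test-suite.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import (
    HET,
    HOM,
    MISS,
    GenotypeMatrix,
    StateSequence,
    calls_to_states,
)

#: Run-length class edges in Mb: [1,2), [2,4), [4,8), [8,16), [16, inf).
LENGTH_CLASS_EDGES_MB = (1, 2, 4, 8, 16)
LENGTH_CLASS_LABELS = ("1-2 Mb", "2-4 Mb", "4-8 Mb", "8-16 Mb", ">16 Mb")


@dataclass(frozen=True)
class RunParams:
    """Detection configuration for one run kind."""

    target: int  # HOM or HET
    min_snp: int
    max_opposite: int = 0
    max_missing: int = 0
    min_length_bp: int = 1_000_000
    max_gap_bp: int = 1_000_000

    def __post_init__(self) -> None:
        if self.target not in (HOM, HET):
            raise ValueError("target must be HOM or HET")
        if self.min_snp < 1:
            raise ValueError("min_snp must be >= 1")
        if self.max_opposite < 0 or self.max_missing < 0:
            raise ValueError("budgets must be >= 0")
        if self.min_length_bp < 0 or self.max_gap_bp < 0:
            raise ValueError("lengths must be >= 0")

    @property
    def kind(self) -> str:
        return "ROHom" if self.target == HOM else "ROHet"


def rohom_params(min_snp: int = 50, max_opposite: int = 0, max_missing: int = 0,
                 **kw) -> RunParams:
    """The adopted homozygosity-run configuration: ``min_snp`` homozygous
    SNPs, no heterozygous or missing call allowed inside."""
    return RunParams(target=HOM, min_snp=min_snp, max_opposite=max_opposite,
                     max_missing=max_missing, **kw)


def rohet_params(min_snp: int = 18, max_opposite: int = 3, max_missing: int = 0,
                 **kw) -> RunParams:
    """The adopted heterozygosity-rich configuration: ``min_snp`` heterozygous
    SNPs, ``max_opposite`` homozygous calls tolerated, no missing."""
    return RunParams(target=HET, min_snp=min_snp, max_opposite=max_opposite,
                     max_missing=max_missing, **kw)


@dataclass(frozen=True)
class Run:
    """One detected run."""

    animal: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snp_total: int
    n_target: int
    n_opposite: int
    n_missing: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp

    def as_tuple(self) -> tuple:
        return (
            self.animal, self.chrom, self.start_bp, self.end_bp,
            self.n_snp_total, self.n_target, self.n_opposite, self.n_missing,
        )


def is_valid_window(
    states: np.ndarray, positions: np.ndarray, p: RunParams
) -> bool:
    """Declarative validity predicate for one candidate window."""
    states = np.asarray(states)
    positions = np.asarray(positions)
    if len(states) == 0:
        return False
    if states[0] != p.target or states[-1] != p.target:
        return False
    n_target = int((states == p.target).sum())
    n_miss = int((states == MISS).sum())
    n_opp = len(states) - n_target - n_miss
    if n_target < p.min_snp or n_opp > p.max_opposite or n_miss > p.max_missing:
        return False
    if len(positions) > 1 and int(np.diff(positions).max()) > p.max_gap_bp:
        return False
    return int(positions[-1] - positions[0]) >= p.min_length_bp


def _scan_chromosome(
    states: np.ndarray, pos: np.ndarray, p: RunParams
) -> list[tuple[int, int, int, int, int, int]]:
    """Greedy leftmost-longest scan of one chromosome.

    Returns (start_bp, end_bp, n_total, n_target, n_opp, n_miss) tuples.
    """
    t_idx = np.flatnonzero(states == p.target)
    m = t_idx.size
    if m == 0:
        return []
    pos = np.asarray(pos, dtype=np.int64)

    # cumulative interrupting-state counts up to and including each SNP
    opp_state_mask = (states != p.target) & (states != MISS)
    c_opp = np.concatenate(([0], np.cumsum(opp_state_mask)))
    c_miss = np.concatenate(([0], np.cumsum(states == MISS)))
    opp_t = c_opp[t_idx + 1]   # non-decreasing over target SNPs
    miss_t = c_miss[t_idx + 1]

    # gap blocks: a gap > max_gap_bp can never be inside a run
    block = np.concatenate(([0], np.cumsum(np.diff(pos) > p.max_gap_bp)))
    block_t = block[t_idx]
    pos_t = pos[t_idx]

    # for each start a (in target-index space), the largest end b allowed by
    # each monotone constraint
    b_opp = np.searchsorted(opp_t, opp_t + p.max_opposite, side="right") - 1
    b_miss = np.searchsorted(miss_t, miss_t + p.max_missing, side="right") - 1
    b_block = np.searchsorted(block_t, block_t, side="right") - 1
    b_max = np.minimum(np.minimum(b_opp, b_miss), b_block)

    # the smallest end b meeting the count and span requirements
    b_span = np.searchsorted(pos_t, pos_t + p.min_length_bp, side="left")
    b_need = np.maximum(np.arange(m) + p.min_snp - 1, b_span)

    valid_starts = np.flatnonzero(b_max >= b_need)
    out: list[tuple[int, int, int, int, int, int]] = []
    cursor = 0
    k = 0
    while k < valid_starts.size:
        a = int(valid_starts[k])
        if a < cursor:
            k = bisect_left(valid_starts, cursor, lo=k)  # type: ignore[arg-type]
            continue
        b = int(b_max[a])
        i, j = int(t_idx[a]), int(t_idx[b])
        out.append(
            (
                int(pos[i]),
                int(pos[j]),
                j - i + 1,
                b - a + 1,
                int(opp_t[b] - opp_t[a]),
                int(miss_t[b] - miss_t[a]),
            )
        )
        cursor = b + 1
        k += 1
    return out


def detect_runs_states(seq: StateSequence, p: RunParams) -> list[Run]:
    """Detect runs on a single pre-built state sequence."""
    if np.any(np.diff(seq.pos_bp) <= 0):
        raise ValueError("positions must be strictly increasing")
    return [
        Run(seq.animal, seq.chrom, *tup)
        for tup in _scan_chromosome(seq.states, seq.pos_bp, p)
    ]


def detect_runs(g: GenotypeMatrix, p: RunParams) -> list[Run]:
    """Detect runs for every animal and chromosome of a genotype matrix.

    Output is sorted by (animal, chrom, start_bp) with animals in sample
    order and chromosomes in map order.
    """
    states_all = calls_to_states(g.calls)
    runs: list[Run] = []
    for chrom in g.markers.chromosomes:
        sl = g.markers.chrom_slice(chrom)
        pos = g.markers.pos_bp[sl]
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"unsorted map on chromosome {chrom!r}")
        for i, animal in enumerate(g.samples):
            for tup in _scan_chromosome(states_all[i, sl], pos, p):
                runs.append(Run(animal, chrom, *tup))
    order = {a: i for i, a in enumerate(g.samples)}
    chrom_order = {c: i for i, c in enumerate(g.markers.chromosomes)}
    runs.sort(key=lambda r: (order[r.animal], chrom_order[r.chrom], r.start_bp))
    return runs


def length_class(length_bp: int | "Run") -> str:
    """Length-class label for a run (bins [1,2), [2,4), [4,8), [8,16), >=16 Mb)."""
    if isinstance(length_bp, Run):
        length_bp = length_bp.length_bp
    mb = length_bp / 1e6
    if mb < LENGTH_CLASS_EDGES_MB[0]:
        raise ValueError(f"run length {length_bp} bp below the 1 Mb class floor")
    for lo, hi, label in zip(
        LENGTH_CLASS_EDGES_MB[:-1], LENGTH_CLASS_EDGES_MB[1:], LENGTH_CLASS_LABELS
    ):
        if mb < hi:
            return label
    return LENGTH_CLASS_LABELS[-1]


def runs_to_frame(runs: list[Run], group: str = "all") -> pd.DataFrame:
    """Tabulate runs in detectRUNS-style columns plus budget counts."""
    return pd.DataFrame(
        {
            "group": group,
            "id": [r.animal for r in runs],
            "chrom": [r.chrom for r in runs],
            "nSNP": [r.n_snp_total for r in runs],
            "from": [r.start_bp for r in runs],
            "to": [r.end_bp for r in runs],
            "lengthBps": [r.length_bp for r in runs],
            "n_target": [r.n_target for r in runs],
            "n_opposite": [r.n_opposite for r in runs],
            "n_missing": [r.n_missing for r in runs],
        }
    )


def frame_to_runs(df: pd.DataFrame) -> list[Run]:
    """Rebuild :class:`Run` objects from a :func:`runs_to_frame` table."""
    cols = ["id", "chrom", "from", "to", "nSNP", "n_target", "n_opposite", "n_missing"]
    return [
        Run(
            animal=str(a), chrom=str(c), start_bp=int(s), end_bp=int(e),
            n_snp_total=int(n), n_target=int(t), n_opposite=int(o),
            n_missing=int(mi),
        )
        for a, c, s, e, n, t, o, mi in zip(*(df[col] for col in cols))
    ]
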