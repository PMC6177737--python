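"""Capture-design geometry: genomic intervals, target sets, and random
placement of simulated deletions over the target regions.

Coordinates are BED-style 0-based half-open everywhere inside the package;
conversion to or from 1-based systems happens only at I/O boundaries.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

DOWNSAMPLE = "downsample"
XREPLACE = "xreplace"
METHODS = (DOWNSAMPLE, XREPLACE)


class BedParseError(ValueError):
    """A BED line could not be parsed (strict mode)."""


class PlacementError(RuntimeError):
    """Deletion placement could not be completed within the attempt budget."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on one contig."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self!r}")
        if self.start >= self.end:
            raise ValueError(f"empty or inverted interval: {self.chrom}:{self.start}-{self.end}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval", reciprocal: float = 0.0) -> bool:
        """True if the two intervals share >= 1 bp, and — when ``reciprocal``
        is positive — the shared span covers at least that fraction of *both*
        intervals."""
        ov = self.overlap_len(other)
        if ov <= 0:
            return False
        if reciprocal > 0.0:
            return ov >= reciprocal * self.width and ov >= reciprocal * other.width
        return True

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


class TargetSet:
    """Ordered, merged collection of capture target regions.

    Intervals are sorted by (chrom, start); overlapping input intervals
    (sharing >= 1 bp) are merged on construction, so the stored intervals are
    pairwise disjoint within a contig. Book-ended intervals are kept separate:
    they are distinct capture targets.
    """

    def __init__(self, intervals: Iterable[GenomicInterval]):
        merged: list[GenomicInterval] = []
        for iv in sorted(intervals):
            if merged and merged[-1].chrom == iv.chrom and iv.start < merged[-1].end:
                prev = merged.pop()
                merged.append(GenomicInterval(prev.chrom, prev.start, max(prev.end, iv.end)))
            else:
                merged.append(iv)
        self._intervals: tuple[GenomicInterval, ...] = tuple(merged)
        # per-contig positional index over the merged (disjoint) intervals
        self._index: dict[str, tuple[int, np.ndarray, np.ndarray]] = {}
        pos = 0
        for chrom in dict.fromkeys(iv.chrom for iv in merged):
            ivs = [iv for iv in merged if iv.chrom == chrom]
            self._index[chrom] = (
                pos,
                np.array([iv.start for iv in ivs], dtype=np.int64),
                np.array([iv.end for iv in ivs], dtype=np.int64),
            )
            pos += len(ivs)

    @property
    def intervals(self) -> tuple[GenomicInterval, ...]:
        return self._intervals

    def __len__(self) -> int:
        return len(self._intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self._intervals[i]

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TargetSet) and self._intervals == other._intervals

    def contigs(self) -> list[str]:
        return list(self._index)

    def targeted_span(self) -> int:
        """Total targeted bases: the sum of interval widths."""
        return sum(iv.width for iv in self._intervals)

    def contig_indices(self, chrom: str) -> range:
        """Global indices of the targets on one contig (a contiguous block)."""
        if chrom not in self._index:
            return range(0)
        offset, starts, _ = self._index[chrom]
        return range(offset, offset + len(starts))

    def overlapping(self, interval: GenomicInterval) -> list[int]:
        """Global indices of targets sharing >= 1 bp with ``interval``."""
        if interval.chrom not in self._index:
            return []
        offset, starts, ends = self._index[interval.chrom]
        lo = int(np.searchsorted(ends, interval.start, side="right"))
        hi = int(np.searchsorted(starts, interval.end, side="left"))
        return list(range(offset + lo, offset + hi))

    def span_of(self, indices: Sequence[int]) -> GenomicInterval:
        """Interval from the first member target's start to the last's end."""
        ivs = [self._intervals[i] for i in indices]
        if len({iv.chrom for iv in ivs}) != 1:
            raise ValueError("target run crosses contigs")
        return GenomicInterval(ivs[0].chrom, ivs[0].start, ivs[-1].end)


@dataclass(frozen=True)
class SimulatedDeletion:
    """Truth record for one simulated single-copy deletion.

    ``target_indices`` is a run of consecutive indices into the TargetSet the
    deletion was placed on. ``targeted_interval`` spans from the first member
    target's start to the last member's end; ``expanded_interval`` (set by the
    X-replacement method only) additionally clears flanking read overlaps.
    """

    sample_id: str
    method: str
    target_indices: tuple[int, ...]
    targeted_interval: GenomicInterval
    targeted_bases: int
    seed: int
    expanded_interval: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if not self.target_indices:
            raise ValueError("deletion with no member targets")
        idx = self.target_indices
        if tuple(idx) != tuple(range(idx[0], idx[0] + len(idx))):
            raise ValueError("target indices must be consecutive")
        if self.expanded_interval is not None and not self.expanded_interval.contains(
            self.targeted_interval
        ):
            raise ValueError("expanded interval must contain the targeted interval")

    @property
    def n_targets(self) -> int:
        return len(self.target_indices)

    @property
    def region(self) -> GenomicInterval:
        """The region whose reads are depleted (expanded when available)."""
        return self.expanded_interval or self.targeted_interval

    @property
    def deletion_id(self) -> str:
        return f"{self.sample_id}:{self.targeted_interval}"


def read_targets(path: str | Path, strict: bool = True) -> TargetSet:
    """Read capture targets from a BED file (3+ tab-separated columns).

    Overlapping intervals are merged. Comment/track/browser lines are ignored.
    In strict mode a malformed line raises :class:`BedParseError` naming the
    line number; otherwise malformed lines are dropped and counted in the log.
    """
    intervals: list[GenomicInterval] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if len(fields) < 3:
                    raise ValueError("fewer than 3 columns")
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                intervals.append(GenomicInterval(chrom, start, end))
            except ValueError as exc:
                if strict:
                    raise BedParseError(f"{path}: malformed BED line {lineno}: {exc}") from exc
                dropped += 1
    if dropped:
        logger.warning("%s: dropped %d malformed BED line(s)", path, dropped)
    return TargetSet(intervals)


def write_targets_bed(targets: TargetSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in targets:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def select_deletion_targets(
    targets: TargetSet,
    samples: Sequence[str],
    n_range: tuple[int, int],
    size_range_targets: tuple[int, int],
    restrict_chrom: str | None = None,
    rng_seed: int = 0,
    method: str = DOWNSAMPLE,
    max_attempts: int = 1000,
    cross_sample_disjoint: bool = False,
) -> list[SimulatedDeletion]:
    """Randomly place simulated deletions over the capture targets.

    Each sample receives k deletions, k ~ Uniform(n_range); each deletion
    covers m consecutive target regions on one contig, m ~ Uniform(
    size_range_targets). Deletions within a sample are separated by at least
    one untouched target region so adjacent events cannot fuse into one
    larger apparent deletion. With ``cross_sample_disjoint`` the same applies
    across the whole cohort (for callers using a cohort reference).

    Placement is by rejection sampling with ``max_attempts`` tries per
    deletion; an infeasible request raises :class:`PlacementError` reporting
    how many deletions were placed.
    """
    if size_range_targets[0] < 1:
        raise ValueError("minimum deletion size is 1 target region")
    if n_range[0] < 0 or n_range[0] > n_range[1]:
        raise ValueError(f"invalid n_range {n_range}")
    if size_range_targets[0] > size_range_targets[1]:
        raise ValueError(f"invalid size_range_targets {size_range_targets}")

    if restrict_chrom is not None:
        eligible = list(targets.contig_indices(restrict_chrom))
        if not eligible:
            raise PlacementError(f"no target regions on contig {restrict_chrom!r}")
    else:
        eligible = list(range(len(targets)))

    rng = np.random.default_rng(rng_seed)
    truth: list[SimulatedDeletion] = []
    shared_occupied: set[int] = set()  # used only when cross_sample_disjoint
    placed = 0

    for sample_id in samples:
        k = int(rng.integers(n_range[0], n_range[1] + 1))
        occupied = shared_occupied if cross_sample_disjoint else set()
        for _ in range(k):
            deletion = None
            for _attempt in range(max_attempts):
                m = int(rng.integers(size_range_targets[0], size_range_targets[1] + 1))
                i = int(eligible[rng.integers(len(eligible))])
                run = list(range(i, i + m))
                chrom = targets[i].chrom
                block = targets.contig_indices(chrom)
                if run[-1] >= block.stop:  # run must stay on one contig
                    continue
                # require a >= 1-target untouched gap around the run
                if any(j in occupied for j in range(i - 1, i + m + 1)):
                    continue
                span = targets.span_of(run)
                deletion = SimulatedDeletion(
                    sample_id=sample_id,
                    method=method,
                    target_indices=tuple(run),
                    targeted_interval=span,
                    targeted_bases=sum(targets[j].width for j in run),
                    seed=int(rng.integers(2**31)),
                )
                break
            if deletion is None:
                raise PlacementError(
                    f"could not place deletion for sample {sample_id!r} after "
                    f"{max_attempts} attempts ({placed} deletions placed so far)"
                )
            occupied.update(deletion.target_indices)
            truth.append(deletion)
            placed += 1
    return truth


# ---------------------------------------------------------------------------
# Truth-set I/O: BED for genome-browser use, TSV with the full record.

_TRUTH_COLUMNS = (
    "sample_id",
    "method",
    "chrom",
    "start",
    "end",
    "target_indices",
    "n_targets",
    "targeted_bases",
    "expanded_start",
    "expanded_end",
    "seed",
)


def _truth_sorted(truth: Iterable[SimulatedDeletion]) -> list[SimulatedDeletion]:
    return sorted(truth, key=lambda d: (d.targeted_interval, d.sample_id))


def write_truth_bed(truth: Iterable[SimulatedDeletion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for d in _truth_sorted(truth):
            iv = d.targeted_interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{d.sample_id};{d.method};{d.n_targets}\n")


def write_truth_tsv(truth: Iterable[SimulatedDeletion], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TRUTH_COLUMNS) + "\n")
        for d in _truth_sorted(truth):
            iv = d.targeted_interval
            exp = d.expanded_interval
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        d.sample_id,
                        d.method,
                        iv.chrom,
                        iv.start,
                        iv.end,
                        ",".join(map(str, d.target_indices)),
                        d.n_targets,
                        d.targeted_bases,
                        exp.start if exp else ".",
                        exp.end if exp else ".",
                        d.seed,
                    )
                )
                + "\n"
            )


def read_truth_tsv(path: str | Path) -> list[SimulatedDeletion]:
    truth: list[SimulatedDeletion] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _TRUTH_COLUMNS:
            raise ValueError(f"{path}: unexpected truth TSV header {header}")
        for line in fh:
            f = dict(zip(_TRUTH_COLUMNS, line.rstrip("\n").split("\t")))
            iv = GenomicInterval(f["chrom"], int(f["start"]), int(f["end"]))
            exp = None
            if f["expanded_start"] != ".":
                exp = GenomicInterval(f["chrom"], int(f["expanded_start"]), int(f["expanded_end"]))
            truth.append(
                SimulatedDeletion(
                    sample_id=f["sample_id"],
                    method=f["method"],
                    target_indices=tuple(int(i) for i in f["target_indices"].split(",")),
                    targeted_interval=iv,
                    targeted_bases=int(f["targeted_bases"]),
                    seed=int(f["seed"]),
                    expanded_interval=exp,
                )
            )
    return truth


def with_expanded(deletion: SimulatedDeletion, expanded: GenomicInterval) -> SimulatedDeletion:
    return dataclasses.replace(deletion, expanded_interval=expanded)
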