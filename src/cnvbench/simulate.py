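"""Read-depth depletion in alignment files.

Two depletion methods produce the single-copy (heterozygous deletion) depth
level in selected capture targets:

* **downsampling** — every read pair with a mate overlapping the deletion
  target is removed with fixed probability (default 0.5), assuming read depth
  scales linearly with copy number;
* **X-replacement** — in a female sample, all reads over an X-chromosome
  region are replaced by a library-size-normalised set of reads from the same
  region of a male sample, exploiting the true one-copy state of the male X
  and thereby avoiding the linearity assumption.

Removal decisions are a deterministic keyed hash of the read name, so both
mates of a pair (and any secondary/supplementary records) always share one
fate and reruns with the same seed reproduce the same output bytes.
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import dataclass, field
from hashlib import blake2b
from pathlib import Path
from typing import Sequence

import pysam

from .regions import (
    DOWNSAMPLE,
    XREPLACE,
    GenomicInterval,
    SimulatedDeletion,
    TargetSet,
    select_deletion_targets,
    with_expanded,
    write_truth_bed,
    write_truth_tsv,
)

logger = logging.getLogger(__name__)

MALE = "male"
FEMALE = "female"

X_CONTIG_NAMES = ("chrX", "X")


class InputError(ValueError):
    """Alignment input does not meet requirements (missing index, empty)."""


class ConfigurationError(ValueError):
    """Simulation configuration cannot be satisfied by the cohort."""


class ExpansionError(RuntimeError):
    """No read-free flanking position found within the allowed expansion."""


def _is_usable(read: pysam.AlignedSegment) -> bool:
    """Primary, mapped, non-duplicate — the records that carry RD signal."""
    return not (
        read.is_unmapped
        or read.is_secondary
        or read.is_supplementary
        or read.is_duplicate
    )


@dataclass
class AlignmentSource:
    """A coordinate-sorted, indexed alignment file for one sample."""

    path: Path
    sample_id: str
    sex: str = FEMALE
    _library_size: int | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.path = Path(self.path)
        if self.sex not in (MALE, FEMALE):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")

    def open(self) -> pysam.AlignmentFile:
        af = pysam.AlignmentFile(str(self.path), "rb")
        if not af.has_index():
            af.close()
            raise InputError(f"{self.path}: coordinate-sorted, indexed BAM required")
        return af

    def library_size(self) -> int:
        """Count of primary, mapped, non-duplicate records; cached."""
        if self._library_size is None:
            with self.open() as af:
                n = sum(1 for r in af.fetch() if _is_usable(r))
            if n == 0:
                raise InputError(f"{self.path}: empty alignment file (library size 0)")
            self._library_size = n
        return self._library_size


def library_size(src: AlignmentSource) -> int:
    return src.library_size()


def _unit_hash(name: str, seed: int) -> float:
    """Deterministic uniform(0,1) variate keyed by read name and seed."""
    key = int(seed).to_bytes(8, "little", signed=False)
    h = blake2b(name.encode(), key=key, digest_size=8).digest()
    return int.from_bytes(h, "big") / 2.0**64


@dataclass
class DeletionEdit:
    """Edit set for one deletion: names to delete, records to add."""

    deletion: SimulatedDeletion
    removed_names: frozenset[str]
    inserted: list[pysam.AlignedSegment] = field(default_factory=list)
    reads_before: int = 0
    reads_removed: int = 0


def downsample_deletion(
    src: AlignmentSource,
    deletion: SimulatedDeletion,
    p_remove: float = 0.5,
    seed: int | None = None,
) -> DeletionEdit:
    """Decide, pair-atomically, which reads over the deletion target to drop.

    Every read pair with >= 1 mate overlapping ``deletion.targeted_interval``
    is removed with probability ``p_remove``; the decision is a keyed hash of
    the read name so mates always agree and the edit is reproducible.
    """
    if deletion.method != DOWNSAMPLE:
        raise ValueError(f"deletion method is {deletion.method!r}, not downsample")
    if not 0.0 <= p_remove <= 1.0:
        raise ValueError(f"p_remove must be in [0,1], got {p_remove}")
    use_seed = deletion.seed if seed is None else seed
    iv = deletion.targeted_interval
    removed: set[str] = set()
    before = 0
    removed_count = 0
    with src.open() as af:
        for read in af.fetch(iv.chrom, iv.start, iv.end):
            if not _is_usable(read):
                continue
            before += 1
            if _unit_hash(read.query_name, use_seed) < p_remove:
                removed.add(read.query_name)
                removed_count += 1
    return DeletionEdit(
        deletion=deletion,
        removed_names=frozenset(removed),
        reads_before=before,
        reads_removed=removed_count,
    )


def _straddled(af: pysam.AlignmentFile, chrom: str, pos: int) -> bool:
    """True if any read covers ``pos`` with an interior base (start < pos < end)."""
    if pos <= 0:
        return False
    for read in af.fetch(chrom, max(0, pos - 1), pos + 1):
        if read.is_unmapped:
            continue
        if read.reference_start < pos < (read.reference_end or read.reference_start):
            return True
    return False


def expand_to_read_free_boundaries(
    female: AlignmentSource,
    male: AlignmentSource,
    targeted: GenomicInterval,
    step: int = 100,
    max_expansion: int = 100_000,
) -> GenomicInterval:
    """Expand a targeted interval until neither boundary splits a read.

    Scans outward from each flank in ``step``-bp increments, in both the
    female and male alignments, until a coordinate is found that no read
    straddles. Raises :class:`ExpansionError` if no such coordinate exists
    within ``max_expansion`` bp of a flank.
    """
    with female.open() as fa, male.open() as ma:

        def find(start_pos: int, direction: int) -> int:
            pos = start_pos
            while abs(pos - start_pos) <= max_expansion:
                if pos <= 0:
                    return 0
                if not _straddled(fa, targeted.chrom, pos) and not _straddled(
                    ma, targeted.chrom, pos
                ):
                    return pos
                pos += direction * step
            raise ExpansionError(
                f"no read-free boundary within {max_expansion} bp of "
                f"{targeted.chrom}:{start_pos}"
            )

        left = find(targeted.start, -1)
        right = find(targeted.end, +1)
    return GenomicInterval(targeted.chrom, left, right)


def x_replacement_deletion(
    female: AlignmentSource,
    male: AlignmentSource,
    deletion: SimulatedDeletion,
    seed: int | None = None,
) -> DeletionEdit:
    """Swap female reads over the expanded region for male reads.

    All female reads overlapping ``deletion.expanded_interval`` are removed;
    male reads from the same region are inserted, each pair retained with
    probability ``f = min(1, library_size(female)/library_size(male))`` via
    the same name-keyed rule (downsampling here only compensates for library
    size differences). Inserted records get a collision-proof name prefix and
    the female sample's read group.
    """
    if deletion.method != XREPLACE:
        raise ValueError(f"deletion method is {deletion.method!r}, not xreplace")
    if female.sex != FEMALE or male.sex != MALE:
        raise ConfigurationError("x_replacement_deletion needs a female target and male donor")
    if deletion.targeted_interval.chrom not in X_CONTIG_NAMES:
        raise ConfigurationError(
            f"X-replacement requires an X-chromosome deletion, got "
            f"{deletion.targeted_interval.chrom!r}"
        )
    region = deletion.expanded_interval
    if region is None:
        raise ValueError("deletion.expanded_interval must be computed before X-replacement")
    use_seed = deletion.seed if seed is None else seed

    ratio = female.library_size() / male.library_size()
    if ratio > 1.0:
        logger.warning(
            "library-size ratio %.3f > 1 for %s; proceeding with retention 1.0",
            ratio,
            deletion.deletion_id,
        )
    f_keep = min(1.0, ratio)

    removed: set[str] = set()
    before = 0
    removed_count = 0
    with female.open() as fa:
        header = fa.header.to_dict()
        for read in fa.fetch(region.chrom, region.start, region.end):
            if read.is_unmapped:
                continue
            removed.add(read.query_name)
            if _is_usable(read):
                before += 1
                removed_count += 1

    prefix = f"XR{use_seed % 100_000_000}"
    new_header = pysam.AlignmentHeader.from_dict(header)
    inserted: list[pysam.AlignedSegment] = []
    with male.open() as ma:
        for read in ma.fetch(region.chrom, region.start, region.end):
            if not _is_usable(read):
                continue
            if _unit_hash(read.query_name, use_seed) >= f_keep:
                continue
            d = read.to_dict()
            d["name"] = f"{prefix}_{read.query_name}"
            tags = [t for t in d.get("tags", []) if not t.startswith("RG:")]
            tags.append(f"RG:Z:{female.sample_id}")
            d["tags"] = tags
            inserted.append(pysam.AlignedSegment.from_dict(d, new_header))

    return DeletionEdit(
        deletion=deletion,
        removed_names=frozenset(removed),
        inserted=inserted,
        reads_before=before,
        reads_removed=removed_count,
    )


def apply_edits(src: AlignmentSource, edits: Sequence[DeletionEdit], out_path: str | Path) -> None:
    """Write an edited copy of one sample's BAM, preserving coordinate sort.

    Records whose name is in any edit's removal set are dropped wherever they
    occur (pair atomicity). Inserted records, already position-sorted, are
    merged in during the single pass over the input, so the output is sorted
    without an external re-sort; the output is then indexed.
    """
    out_path = Path(out_path)
    removed: set[str] = set()
    inserted: list[pysam.AlignedSegment] = []
    for e in edits:
        removed.update(e.removed_names)
        inserted.extend(e.inserted)

    with src.open() as af:
        inserted.sort(key=lambda r: (r.reference_id, r.reference_start))
        pending = iter(inserted)
        nxt = next(pending, None)
        with pysam.AlignmentFile(str(out_path), "wb", header=af.header) as out:
            for read in af.fetch(until_eof=True):
                key = (read.reference_id, read.reference_start)
                while nxt is not None and (nxt.reference_id, nxt.reference_start) <= key:
                    out.write(nxt)
                    nxt = next(pending, None)
                if read.query_name in removed:
                    continue
                out.write(read)
            while nxt is not None:
                out.write(nxt)
                nxt = next(pending, None)
    pysam.index(str(out_path))


@dataclass
class SimulationConfig:
    """Parameters of one simulation run."""

    method: str = DOWNSAMPLE
    n_range: tuple[int, int] = (2, 10)
    size_range_targets: tuple[int, int] = (1, 5)
    seed: int = 0
    p_remove: float = 0.5
    x_contig: str | None = None  # auto-detected from the target set when None
    donor: str | None = None  # sample id of the male donor; highest library size when None
    cross_sample_disjoint: bool = False
    expansion_step: int = 100
    max_expansion: int = 100_000
    passthrough: str = "copy"  # or "symlink"

    def __post_init__(self) -> None:
        if self.method not in (DOWNSAMPLE, XREPLACE):
            raise ConfigurationError(f"unknown simulation method {self.method!r}")
        if self.passthrough not in ("copy", "symlink"):
            raise ConfigurationError(f"passthrough must be copy|symlink, got {self.passthrough!r}")


@dataclass
class SimulationResult:
    """Outputs of a simulation run: new BAMs, the truth set, read accounting."""

    sample_paths: dict[str, Path]
    truth: list[SimulatedDeletion]
    accounting: list[dict]
    truth_bed: Path
    truth_tsv: Path


def _detect_x_contig(targets: TargetSet) -> str:
    for name in X_CONTIG_NAMES:
        if name in targets.contigs():
            return name
    raise ConfigurationError(
        f"no X contig (one of {X_CONTIG_NAMES}) found among target contigs {targets.contigs()}"
    )


def count_region_reads(src: AlignmentSource, region: GenomicInterval) -> int:
    with src.open() as af:
        return sum(1 for r in af.fetch(region.chrom, region.start, region.end) if _is_usable(r))


def run_simulation(
    cohort: Sequence[AlignmentSource],
    targets: TargetSet,
    config: SimulationConfig,
    out_dir: str | Path,
) -> SimulationResult:
    """Select deletion sites, deplete reads, and write the simulated cohort.

    Downsampling may place deletions in any sample on any contig;
    X-replacement places deletions only on the X chromosome of female
    samples, with one male sample serving as the read donor. Each modified
    sample gets a new coordinate-sorted, indexed BAM; unmodified samples are
    copied (or symlinked) through. Partial outputs are removed on failure.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_id = {s.sample_id: s for s in cohort}
    if len(by_id) != len(cohort):
        raise ConfigurationError("duplicate sample ids in cohort")

    if config.method == XREPLACE:
        females = [s for s in cohort if s.sex == FEMALE]
        males = [s for s in cohort if s.sex == MALE]
        if not males:
            raise ConfigurationError("X-replacement requires at least one male donor sample")
        if not females:
            raise ConfigurationError("X-replacement requires at least one female sample")
        if config.donor is not None:
            donor = by_id[config.donor]
            if donor.sex != MALE:
                raise ConfigurationError(f"configured donor {config.donor!r} is not male")
        else:
            donor = max(males, key=lambda s: s.library_size())
        x_contig = config.x_contig or _detect_x_contig(targets)
        recipients = [s.sample_id for s in females]
        restrict = x_contig
    else:
        donor = None
        recipients = [s.sample_id for s in cohort]
        restrict = None

    truth = select_deletion_targets(
        targets,
        recipients,
        n_range=config.n_range,
        size_range_targets=config.size_range_targets,
        restrict_chrom=restrict,
        rng_seed=config.seed,
        method=config.method,
        cross_sample_disjoint=config.cross_sample_disjoint,
    )

    written: list[Path] = []
    try:
        sample_paths: dict[str, Path] = {}
        accounting: list[dict] = []
        final_truth: list[SimulatedDeletion] = []
        truth_by_sample: dict[str, list[SimulatedDeletion]] = {}
        for d in truth:
            truth_by_sample.setdefault(d.sample_id, []).append(d)

        for src in cohort:
            out_path = out_dir / f"{src.sample_id}.bam"
            sample_dels = truth_by_sample.get(src.sample_id, [])
            if not sample_dels:
                if config.passthrough == "symlink":
                    for suffix in ("", ".bai"):
                        link = Path(str(out_path) + suffix)
                        target = Path(str(src.path) + suffix)
                        if link.exists() or link.is_symlink():
                            link.unlink()
                        link.symlink_to(target.resolve())
                        written.append(link)
                else:
                    shutil.copyfile(src.path, out_path)
                    written.append(out_path)
                    bai = Path(str(src.path) + ".bai")
                    if bai.exists():
                        shutil.copyfile(bai, Path(str(out_path) + ".bai"))
                        written.append(Path(str(out_path) + ".bai"))
                    else:
                        pysam.index(str(out_path))
                sample_paths[src.sample_id] = out_path
                continue

            edits: list[DeletionEdit] = []
            for d in sample_dels:
                if config.method == DOWNSAMPLE:
                    edit = downsample_deletion(src, d, p_remove=config.p_remove)
                else:
                    assert donor is not None
                    expanded = expand_to_read_free_boundaries(
                        src,
                        donor,
                        d.targeted_interval,
                        step=config.expansion_step,
                        max_expansion=config.max_expansion,
                    )
                    d = with_expanded(d, expanded)
                    edit = x_replacement_deletion(src, donor, d)
                edits.append(edit)
                final_truth.append(edit.deletion)
                accounting.append(
                    {
                        "deletion_id": edit.deletion.deletion_id,
                        "sample_id": src.sample_id,
                        "method": config.method,
                        "region": str(edit.deletion.region),
                        "reads_before": edit.reads_before,
                        "reads_removed": edit.reads_removed,
                        "reads_added": len(edit.inserted),
                    }
                )
            apply_edits(src, edits, out_path)
            written.extend([out_path, Path(str(out_path) + ".bai")])
            sample_paths[src.sample_id] = out_path

        truth_bed = out_dir / "truth.bed"
        truth_tsv = out_dir / "truth.tsv"
        write_truth_bed(final_truth, truth_bed)
        write_truth_tsv(final_truth, truth_tsv)
        written.extend([truth_bed, truth_tsv])
        acc_path = out_dir / "accounting.json"
        with open(acc_path, "w") as fh:
            json.dump(sorted(accounting, key=lambda a: a["deletion_id"]), fh, indent=1)
        written.append(acc_path)
    except Exception:
        for p in written:
            try:
                p.unlink()
            except OSError:
                pass
        raise

    return SimulationResult(
        sample_paths=sample_paths,
        truth=final_truth,
        accounting=accounting,
        truth_bed=truth_bed,
        truth_tsv=truth_tsv,
    )


def mean_depth(src: AlignmentSource, region: GenomicInterval) -> float:
    """Mean per-base read depth over a region (primary, non-duplicate reads)."""
    with src.open() as af:
        total = 0
        for read in af.fetch(region.chrom, region.start, region.end):
            if not _is_usable(read):
                continue
            total += max(
                0, min(read.reference_end or 0, region.end) - max(read.reference_start, region.start)
            )
    return total / region.width
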