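"""Fully synthetic test cohorts with known copy-number truth.

Everything downstream — depletion, the toy caller, evaluation, QC — works
from coordinates and flags only, so reads are placed directly at valid
positions (constant base content and qualities) instead of being produced by
sequence simulation and alignment. Per-target read counts are Poisson with
mean proportional to ``mean_depth * copy/2``; male samples carry one copy of
the X chromosome, females two, which is exactly the ploidy difference the
X-replacement depletion method exploits.

Also provided: a synthetic caller-output generator with controllable
sensitivity, false-positive rate and score separation, and a minimal
read-depth caller (normalise per-target depth by library size, log-ratio
against the per-target cohort median, segment consecutive depleted targets)
so the whole simulate→call→evaluate loop can run with no external tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .calls import CnvCall
from .regions import GenomicInterval, SimulatedDeletion, TargetSet
from .simulate import FEMALE, MALE, X_CONTIG_NAMES, AlignmentSource

_BASE_QUAL = 30
_MAPQ = 60


@dataclass
class CohortSpec:
    """Recipe for one synthetic cohort."""

    samples: Sequence[tuple[str, str]]  # (sample_id, sex)
    contigs: Sequence[tuple[str, int]]  # (name, length)
    targets: TargetSet
    mean_depth: float = 60.0  # reads per base at copy number 2
    read_length: int = 100
    insert_mean: float = 300.0
    insert_sd: float = 50.0
    true_cnvs: Sequence[tuple[str, GenomicInterval, int]] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if self.read_length >= self.insert_mean:
            raise ValueError("read_length must be smaller than the mean insert size")
        sexes = {sex for _, sex in self.samples}
        if not sexes <= {MALE, FEMALE}:
            raise ValueError(f"sexes must be male/female, got {sexes}")
        lengths = dict(self.contigs)
        for iv in self.targets:
            if iv.chrom not in lengths:
                raise ValueError(f"target contig {iv.chrom!r} not declared in contigs")
            if iv.end > lengths[iv.chrom]:
                raise ValueError(f"target {iv} exceeds contig length {lengths[iv.chrom]}")
        for sample, iv, copy in self.true_cnvs:
            if sample not in {s for s, _ in self.samples}:
                raise ValueError(f"true CNV names unknown sample {sample!r}")
            if copy < 0:
                raise ValueError("copy number must be >= 0")

    def copy_number(self, sample_id: str, sex: str, target: GenomicInterval) -> int:
        copy = 1 if (sex == MALE and target.chrom in X_CONTIG_NAMES) else 2
        for s, iv, c in self.true_cnvs:
            if s == sample_id and iv.overlaps(target):
                copy = c
        return copy


@dataclass
class CohortManifest:
    sources: list[AlignmentSource]
    chrom_sizes: Path
    truth_cn: Path
    out_dir: Path

    @property
    def contig_lengths(self) -> dict[str, int]:
        out: dict[str, int] = {}
        with open(self.chrom_sizes) as fh:
            for line in fh:
                chrom, length = line.split("\t")
                out[chrom] = int(length)
        return out


def generate_cohort(spec: CohortSpec, out_dir: str | Path) -> CohortManifest:
    """Write one coordinate-sorted, indexed BAM per sample plus manifests.

    Per target of width w, a sample at copy number c receives
    ``Poisson(mean_depth * (c/2) * w / (2*read_length))`` proper FR read
    pairs with Gaussian insert sizes (truncated below at the read length) and
    fragment starts uniform over the target. Unique read names, read group ==
    sample id. Fixed seed gives byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    lengths = dict(spec.contigs)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": name, "LN": length} for name, length in spec.contigs],
        }
    )
    tid = {name: i for i, (name, _l) in enumerate(spec.contigs)}

    sources: list[AlignmentSource] = []
    for sample_id, sex in spec.samples:
        sample_header = pysam.AlignmentHeader.from_dict(
            {**header.to_dict(), "RG": [{"ID": sample_id, "SM": sample_id}]}
        )
        records: list[tuple[int, int, pysam.AlignedSegment]] = []
        serial = 0
        for target in spec.targets:
            copy = spec.copy_number(sample_id, sex, target)
            lam = spec.mean_depth * (copy / 2.0) * target.width / (2.0 * spec.read_length)
            n_pairs = int(rng.poisson(lam))
            if n_pairs == 0:
                continue
            starts = rng.integers(target.start, target.end, size=n_pairs)
            frags = np.maximum(
                spec.read_length,
                np.rint(rng.normal(spec.insert_mean, spec.insert_sd, size=n_pairs)).astype(int),
            )
            contig_len = lengths[target.chrom]
            for s, frag in zip(starts, frags):
                s = int(min(s, max(0, contig_len - frag)))
                frag = int(min(frag, contig_len - s))
                r2_start = max(s, s + frag - spec.read_length)
                name = f"{sample_id}.{serial}"
                serial += 1
                for is_first, pos, mate_pos, flag in (
                    (True, s, r2_start, 0x1 | 0x2 | 0x20 | 0x40),
                    (False, r2_start, s, 0x1 | 0x2 | 0x10 | 0x80),
                ):
                    r = pysam.AlignedSegment(sample_header)
                    r.query_name = name
                    r.flag = flag
                    r.reference_id = tid[target.chrom]
                    r.reference_start = pos
                    r.mapping_quality = _MAPQ
                    r.cigarstring = f"{spec.read_length}M"
                    r.next_reference_id = tid[target.chrom]
                    r.next_reference_start = mate_pos
                    r.template_length = frag if is_first else -frag
                    r.query_sequence = "A" * spec.read_length
                    r.query_qualities = pysam.qualitystring_to_array(
                        chr(33 + _BASE_QUAL) * spec.read_length
                    )
                    r.set_tag("RG", sample_id)
                    records.append((r.reference_id, pos, r))
        records.sort(key=lambda t: (t[0], t[1]))
        path = out_dir / f"{sample_id}.bam"
        with pysam.AlignmentFile(str(path), "wb", header=sample_header) as bam:
            for _tid, _pos, r in records:
                bam.write(r)
        pysam.index(str(path))
        sources.append(AlignmentSource(path=path, sample_id=sample_id, sex=sex))

    chrom_sizes = out_dir / "chrom.sizes"
    with open(chrom_sizes, "w") as fh:
        for name, length in spec.contigs:
            fh.write(f"{name}\t{length}\n")

    truth_cn = out_dir / "copy_number_truth.tsv"
    with open(truth_cn, "w") as fh:
        fh.write("sample_id\tchrom\tstart\tend\tcopy_number\n")
        for sample_id, sex in spec.samples:
            if sex == MALE:
                for name, length in spec.contigs:
                    if name in X_CONTIG_NAMES:
                        fh.write(f"{sample_id}\t{name}\t0\t{length}\t1\n")
        for sample, iv, copy in spec.true_cnvs:
            fh.write(f"{sample}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{copy}\n")

    return CohortManifest(
        sources=sources, chrom_sizes=chrom_sizes, truth_cn=truth_cn, out_dir=out_dir
    )


# ---------------------------------------------------------------------------
# Synthetic caller output


def generate_caller_output(
    truth: Sequence[SimulatedDeletion],
    targets: TargetSet,
    samples: Sequence[str],
    sensitivity: float = 1.0,
    fp_rate: float = 2.0,
    score_margin: float = 2.0,
    boundary_jitter: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Emit a synthetic call table with known accuracy characteristics.

    Each truth deletion is emitted with probability ``sensitivity`` (with
    boundaries jittered by up to ``boundary_jitter`` bp while preserving
    overlap); per sample, ``Poisson(fp_rate)`` false calls are placed on
    random target runs that avoid that sample's truth. TP scores are
    N(score_margin, 1) and FP scores N(0, 1), so ``score_margin`` controls
    how well scores separate true from false calls (0 = uninformative).

    Returns a 0-based half-open table with columns chrom/start/end/sample/
    score, the schema :func:`cnvbench.calls.read_calls` reads by default.
    """
    if not 0.0 <= sensitivity <= 1.0:
        raise ValueError("sensitivity must be in [0,1]")
    rng = np.random.default_rng(seed)
    truth_by_sample: dict[str, list[SimulatedDeletion]] = {}
    for d in truth:
        truth_by_sample.setdefault(d.sample_id, []).append(d)

    rows: list[dict] = []
    for d in truth:
        if rng.random() >= sensitivity:
            continue
        iv = d.targeted_interval
        js = int(rng.integers(-boundary_jitter, boundary_jitter + 1))
        je = int(rng.integers(-boundary_jitter, boundary_jitter + 1))
        start = max(0, min(iv.start + js, iv.end - 1))
        end = max(start + 1, max(iv.start + 1, iv.end + je))
        rows.append(
            {
                "chrom": iv.chrom,
                "start": start,
                "end": end,
                "sample": d.sample_id,
                "score": float(rng.normal(score_margin, 1.0)),
            }
        )
    for sample in samples:
        own_truth = truth_by_sample.get(sample, [])
        n_fp = int(rng.poisson(fp_rate))
        placed = 0
        attempts = 0
        while placed < n_fp and attempts < 100 * max(1, n_fp):
            attempts += 1
            i = int(rng.integers(len(targets)))
            m = int(rng.integers(1, 4))
            run = list(range(i, min(i + m, len(targets))))
            if len({targets[j].chrom for j in run}) != 1:
                run = [i]
            span = targets.span_of(run)
            if any(span.overlaps(d.targeted_interval) for d in own_truth):
                continue
            rows.append(
                {
                    "chrom": span.chrom,
                    "start": span.start,
                    "end": span.end,
                    "sample": sample,
                    "score": float(rng.normal(0.0, 1.0)),
                }
            )
            placed += 1
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "sample", "score"])
    return df.sort_values(["chrom", "start", "end", "sample"], kind="stable").reset_index(drop=True)


def calls_from_frame(df: pd.DataFrame, caller: str) -> list[CnvCall]:
    """Convert a 0-based call table (the synthetic schema) to CnvCall objects."""
    return [
        CnvCall(
            sample_id=str(r.sample),
            caller=caller,
            interval=GenomicInterval(str(r.chrom), int(r.start), int(r.end)),
            quality=float(r.score),
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Toy read-depth caller


class CohortTooSmallError(ValueError):
    """The toy caller needs >= 3 samples to form a cohort reference."""


def depth_matrix(
    sources: Sequence[AlignmentSource], targets: TargetSet
) -> tuple[np.ndarray, np.ndarray]:
    """(n_targets x n_samples) matrix of per-target read counts, plus the
    per-sample genome-wide library sizes."""
    depth = np.zeros((len(targets), len(sources)), dtype=float)
    for j, src in enumerate(sources):
        with src.open() as af:
            for t, iv in enumerate(targets):
                depth[t, j] = af.count(iv.chrom, iv.start, iv.end, read_callback="all")
    libsizes = np.array([src.library_size() for src in sources], dtype=float)
    return depth, libsizes


def calls_from_depth(
    depth: np.ndarray,
    libsizes: np.ndarray,
    targets: TargetSet,
    sample_ids: Sequence[str],
    z_threshold: float = 3.0,
    min_log2_ratio: float = -0.5,
    sd_floor: float = 0.05,
) -> pd.DataFrame:
    """Segment depleted targets into deletion calls from a depth matrix.

    Per-target counts are normalised by library size and expressed as a log2
    ratio against the per-target cohort median. A target is depleted for a
    sample when its z-score (robust, MAD-based, across samples) is below
    ``-z_threshold`` *and* the log-ratio is below ``min_log2_ratio`` (a
    magnitude guard against tiny-variance targets; the default -0.5 is half-way
    to the -1.0 expected for a heterozygous deletion). Consecutive depleted
    targets on one contig form one call; the call quality is the sum of the
    negative z-scores over the segment.
    """
    if depth.shape[1] < 3:
        raise CohortTooSmallError("need >= 3 samples for a cohort reference")
    norm = (depth + 0.5) / libsizes[np.newaxis, :]
    ref = np.median(norm, axis=1, keepdims=True)
    lr = np.log2(norm / ref)
    med_lr = np.median(lr, axis=1, keepdims=True)
    mad = np.median(np.abs(lr - med_lr), axis=1, keepdims=True)
    sd = np.maximum(1.4826 * mad, sd_floor)
    z = (lr - med_lr) / sd
    depleted = (z < -z_threshold) & (lr < min_log2_ratio)

    rows: list[dict] = []
    for j, sample in enumerate(sample_ids):
        t = 0
        while t < len(targets):
            if not depleted[t, j]:
                t += 1
                continue
            seg_start = t
            chrom = targets[t].chrom
            while (
                t + 1 < len(targets)
                and depleted[t + 1, j]
                and targets[t + 1].chrom == chrom
            ):
                t += 1
            span = targets.span_of(range(seg_start, t + 1))
            rows.append(
                {
                    "chrom": span.chrom,
                    "start": span.start,
                    "end": span.end,
                    "sample": sample,
                    "score": float(-z[seg_start : t + 1, j].sum()),
                }
            )
            t += 1
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "sample", "score"])
    return df.sort_values(["chrom", "start", "end", "sample"], kind="stable").reset_index(drop=True)


def toy_depth_caller(
    sources: Sequence[AlignmentSource],
    targets: TargetSet,
    z_threshold: float = 3.0,
) -> pd.DataFrame:
    """Run the minimal read-depth deletion caller on a cohort of BAMs."""
    depth, libsizes = depth_matrix(sources, targets)
    return calls_from_depth(
        depth, libsizes, targets, [s.sample_id for s in sources], z_threshold=z_threshold
    )
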