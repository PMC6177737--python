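"""Shared builders: hand-laid-out BAMs for exact-layout tests and
session-scoped synthetic cohorts for the depth/end-to-end suites."""

from __future__ import annotations

from pathlib import Path

import pysam
import pytest

from cnvbench.fixtures import CohortSpec, generate_cohort
from cnvbench.regions import GenomicInterval, TargetSet

READ_LEN = 50


def build_bam(
    path: Path,
    contigs: dict[str, int],
    reads: list[dict],
    sample_id: str = "S",
) -> Path:
    """Write an indexed BAM from explicit read descriptions.

    Each read dict: name, chrom, pos; optional: length (50), dup, secondary,
    unmapped_mate ignored. Reads are written as unpaired records unless
    ``mate_pos`` is given, in which case a proper FR pair is emitted.
    """
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": length} for c, length in contigs.items()],
            "RG": [{"ID": sample_id, "SM": sample_id}],
        }
    )
    tid = {c: i for i, c in enumerate(contigs)}
    records = []
    for spec in reads:
        length = spec.get("length", READ_LEN)
        mate_pos = spec.get("mate_pos")
        base_flag = 0
        if spec.get("dup"):
            base_flag |= 0x400
        if spec.get("secondary"):
            base_flag |= 0x100
        if mate_pos is None:
            r = pysam.AlignedSegment(header)
            r.query_name = spec["name"]
            r.flag = base_flag
            r.reference_id = tid[spec["chrom"]]
            r.reference_start = spec["pos"]
            r.mapping_quality = 60
            r.cigarstring = f"{length}M"
            r.query_sequence = "A" * length
            r.query_qualities = pysam.qualitystring_to_array("I" * length)
            records.append(r)
        else:
            for pos, other, flag in (
                (spec["pos"], mate_pos, 0x1 | 0x2 | 0x20 | 0x40),
                (mate_pos, spec["pos"], 0x1 | 0x2 | 0x10 | 0x80),
            ):
                r = pysam.AlignedSegment(header)
                r.query_name = spec["name"]
                r.flag = flag | base_flag
                r.reference_id = tid[spec["chrom"]]
                r.reference_start = pos
                r.mapping_quality = 60
                r.cigarstring = f"{length}M"
                r.next_reference_id = tid[spec["chrom"]]
                r.next_reference_start = other
                r.query_sequence = "A" * length
                r.query_qualities = pysam.qualitystring_to_array("I" * length)
                records.append(r)
    records.sort(key=lambda r: (r.reference_id, r.reference_start))
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for r in records:
            bam.write(r)
    pysam.index(str(path))
    return path


def uniform_targets(chrom: str, n: int, width: int = 150, gap: int = 350, start: int = 1000):
    """n equal-width targets separated by fixed gaps on one contig."""
    return [
        GenomicInterval(chrom, start + i * (width + gap), start + i * (width + gap) + width)
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def depth_cohort(tmp_path_factory):
    """10-sample (5F/5M) cohort with autosomal and X targets at depth 100.

    Shared by the depth-ratio suites; treat as read-only (simulation writes
    its outputs elsewhere).
    """
    targets = TargetSet(
        uniform_targets("chr1", 60, gap=450)
        + uniform_targets("chrX", 45, width=400, gap=450)
    )
    spec = CohortSpec(
        samples=[(f"F{i}", "female") for i in range(5)] + [(f"M{i}", "male") for i in range(5)],
        contigs=[("chr1", 40_000), ("chrX", 45_000)],
        targets=targets,
        mean_depth=100.0,
        read_length=100,
        insert_mean=250.0,
        insert_sd=30.0,
        seed=11,
    )
    manifest = generate_cohort(spec, tmp_path_factory.mktemp("depth_cohort"))
    return spec, manifest


@pytest.fixture(scope="session")
def e2e_cohort(tmp_path_factory):
    """20-sample single-contig cohort with 200 targets at depth 100."""
    targets = TargetSet(uniform_targets("chr1", 200))
    spec = CohortSpec(
        samples=[(f"S{i:02d}", "female") for i in range(20)],
        contigs=[("chr1", 110_000)],
        targets=targets,
        mean_depth=100.0,
        read_length=100,
        insert_mean=300.0,
        insert_sd=50.0,
        seed=7,
    )
    manifest = generate_cohort(spec, tmp_path_factory.mktemp("e2e_cohort"))
    return spec, manifest
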