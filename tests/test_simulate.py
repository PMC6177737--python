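"""Read-depth depletion: library size, downsampling, boundary expansion,
X-replacement, and whole-cohort simulation runs."""

from hashlib import blake2b

import pysam
import pytest
from scipy.stats import binom

from cnvbench.regions import (
    GenomicInterval,
    SimulatedDeletion,
    TargetSet,
    with_expanded,
)
from cnvbench.simulate import (
    AlignmentSource,
    ConfigurationError,
    InputError,
    SimulationConfig,
    count_region_reads,
    downsample_deletion,
    expand_to_read_free_boundaries,
    library_size,
    mean_depth,
    run_simulation,
    x_replacement_deletion,
)

from conftest import build_bam, uniform_targets

CONTIGS = {"chr1": 100_000, "chrX": 100_000}


def deletion(chrom="chr1", start=1000, end=1150, method="downsample", seed=42, idx=(0,)):
    return SimulatedDeletion(
        sample_id="S",
        method=method,
        target_indices=tuple(idx),
        targeted_interval=GenomicInterval(chrom, start, end),
        targeted_bases=end - start,
        seed=seed,
    )


class TestLibrarySize:
    def test_counts_primary_mapped_nonduplicate(self, tmp_path):
        reads = [{"name": f"r{i}", "chrom": "chr1", "pos": 100 + i} for i in range(100)]
        for i in range(10):
            reads[i] = {**reads[i], "dup": True}
        reads.append({"name": "sec", "chrom": "chr1", "pos": 500, "secondary": True})
        bam = build_bam(tmp_path / "a.bam", CONTIGS, reads)
        assert library_size(AlignmentSource(bam, "S")) == 90

    def test_known_record_count(self, tmp_path):
        n = 137
        bam = build_bam(
            tmp_path / "b.bam",
            CONTIGS,
            [{"name": f"r{i}", "chrom": "chr1", "pos": 10 * i} for i in range(n)],
        )
        # independent oracle: plain record iteration
        with pysam.AlignmentFile(str(bam)) as af:
            oracle = sum(1 for _ in af.fetch())
        assert library_size(AlignmentSource(bam, "S")) == oracle == n

    def test_empty_file_is_an_error(self, tmp_path):
        bam = build_bam(tmp_path / "e.bam", CONTIGS, [])
        with pytest.raises(InputError, match="library size"):
            library_size(AlignmentSource(bam, "S"))

    def test_cached(self, tmp_path):
        bam = build_bam(tmp_path / "c.bam", CONTIGS, [{"name": "r", "chrom": "chr1", "pos": 5}])
        src = AlignmentSource(bam, "S")
        assert src.library_size() == 1
        bam.unlink()  # a second call must not reopen the file
        assert src.library_size() == 1


def region_pairs(n, chrom="chr1", start=1000, end=1150):
    """n read pairs whose first mate overlaps [start, end)."""
    return [
        {"name": f"p{i}", "chrom": chrom, "pos": start + (i % (end - start - 10)),
         "mate_pos": start + (i % (end - start - 10)) + 200}
        for i in range(n)
    ]


class TestDownsample:
    def test_p_zero_removes_nothing(self, tmp_path):
        bam = build_bam(tmp_path / "a.bam", CONTIGS, region_pairs(50))
        edit = downsample_deletion(AlignmentSource(bam, "S"), deletion(), p_remove=0.0)
        assert edit.removed_names == frozenset()
        assert edit.reads_before > 0

    def test_p_one_removes_everything(self, tmp_path):
        bam = build_bam(tmp_path / "a.bam", CONTIGS, region_pairs(50))
        src = AlignmentSource(bam, "S")
        edit = downsample_deletion(src, deletion(), p_remove=1.0)
        assert len(edit.removed_names) == 50

    def test_retained_fraction_and_hash_oracle(self, tmp_path):
        """At p=0.5 the retained pair count sits in the exact binomial 99%
        interval, and the removed set equals an independent application of
        the keyed-hash rule to each read name."""
        n = 10_000
        bam = build_bam(tmp_path / "big.bam", CONTIGS, region_pairs(n))
        edit = downsample_deletion(AlignmentSource(bam, "S"), deletion(seed=123), p_remove=0.5)
        retained = n - len(edit.removed_names)
        lo, hi = binom.interval(0.99, n, 0.5)
        assert lo <= retained <= hi

        def oracle_removes(name: str) -> bool:
            key = (123).to_bytes(8, "little")
            h = blake2b(name.encode(), key=key, digest_size=8).digest()
            return int.from_bytes(h, "big") / 2.0**64 < 0.5

        expected = {f"p{i}" for i in range(n) if oracle_removes(f"p{i}")}
        assert edit.removed_names == expected

    def test_decision_covers_pairs_with_one_overlapping_mate(self, tmp_path):
        # mate starts before the region but overlaps it; pair is in scope
        bam = build_bam(
            tmp_path / "m.bam",
            CONTIGS,
            [{"name": "edge", "chrom": "chr1", "pos": 980, "mate_pos": 2000}],
        )
        edit = downsample_deletion(AlignmentSource(bam, "S"), deletion(), p_remove=1.0)
        assert edit.removed_names == {"edge"}


class TestExpansion:
    def test_clear_flanks_return_targeted(self, tmp_path):
        reads = [{"name": "far", "chrom": "chr1", "pos": 5000}]
        f = build_bam(tmp_path / "f.bam", CONTIGS, reads)
        m = build_bam(tmp_path / "m.bam", CONTIGS, reads)
        iv = GenomicInterval("chr1", 1000, 1150)
        out = expand_to_read_free_boundaries(
            AlignmentSource(f, "F"), AlignmentSource(m, "M", sex="male"), iv
        )
        assert out == iv

    def test_straddling_read_pushes_boundary(self, tmp_path):
        # read spans [990, 1040): boundary 1000 is straddled
        f = build_bam(tmp_path / "f.bam", CONTIGS, [{"name": "s", "chrom": "chr1", "pos": 990}])
        m = build_bam(tmp_path / "m.bam", CONTIGS, [])
        out = expand_to_read_free_boundaries(
            AlignmentSource(f, "F"), AlignmentSource(m, "M", sex="male"),
            GenomicInterval("chr1", 1000, 1150),
        )
        assert out.start <= 990
        assert out.end >= 1150

    def test_matches_per_base_oracle(self, tmp_path):
        """With step=1 the boundaries equal a brute-force per-base check."""
        import numpy as np

        rng = np.random.default_rng(4)
        reads = [
            {"name": f"r{i}", "chrom": "chr1", "pos": int(p)}
            for i, p in enumerate(rng.integers(500, 2000, size=120))
        ]
        f = build_bam(tmp_path / "f.bam", CONTIGS, reads[:60])
        m = build_bam(tmp_path / "m.bam", CONTIGS, reads[60:])
        iv = GenomicInterval("chr1", 1000, 1300)
        out = expand_to_read_free_boundaries(
            AlignmentSource(f, "F"), AlignmentSource(m, "M", sex="male"), iv, step=1
        )
        spans = [(r["pos"], r["pos"] + 50) for r in reads]

        def straddled(b):
            return any(s < b < e for s, e in spans)

        left = iv.start
        while straddled(left):
            left -= 1
        right = iv.end
        while straddled(right):
            right += 1
        assert (out.start, out.end) == (left, right)


class TestXReplacement:
    def _sources(self, tmp_path, female_reads, male_reads):
        f = build_bam(tmp_path / "f.bam", CONTIGS, female_reads, sample_id="F")
        m = build_bam(tmp_path / "m.bam", CONTIGS, male_reads, sample_id="M")
        return AlignmentSource(f, "F"), AlignmentSource(m, "M", sex="male")

    def test_equal_libraries_insert_everything(self, tmp_path):
        female = region_pairs(100, chrom="chrX")
        male = region_pairs(100, chrom="chrX")
        fsrc, msrc = self._sources(tmp_path, female, male)
        d = with_expanded(
            deletion(chrom="chrX", method="xreplace"), GenomicInterval("chrX", 500, 2000)
        )
        edit = x_replacement_deletion(fsrc, msrc, d)
        assert len(edit.inserted) == 200  # both mates of every male pair
        # every female record in the expanded region is removed
        assert len(edit.removed_names) == 100
        assert all(r.query_name.startswith("XR") for r in edit.inserted)
        assert all(r.get_tag("RG") == "F" for r in edit.inserted)

    def test_library_ratio_downsampling_within_binomial_interval(self, tmp_path):
        # female library half the male's: retention f = 0.5
        female = region_pairs(1000, chrom="chrX")
        male = region_pairs(2000, chrom="chrX")
        fsrc, msrc = self._sources(tmp_path, female, male)
        d = with_expanded(
            deletion(chrom="chrX", method="xreplace", seed=77),
            GenomicInterval("chrX", 500, 2500),
        )
        edit = x_replacement_deletion(fsrc, msrc, d)
        inserted_pairs = len({r.query_name for r in edit.inserted})
        lo, hi = binom.interval(0.99, 2000, 0.5)
        assert lo <= inserted_pairs <= hi

    def test_autosomal_deletion_rejected(self, tmp_path):
        fsrc, msrc = self._sources(
            tmp_path, region_pairs(5), region_pairs(5)
        )
        d = with_expanded(deletion(method="xreplace"), GenomicInterval("chr1", 500, 2000))
        with pytest.raises(ConfigurationError, match="X-chromosome"):
            x_replacement_deletion(fsrc, msrc, d)


def small_cohort(tmp_path, n_samples=3, n_targets=12):
    targets = TargetSet(uniform_targets("chr1", n_targets, width=100, gap=400))
    cohort = []
    for i in range(n_samples):
        reads = []
        for t, iv in enumerate(targets):
            for k in range(20):
                reads.append(
                    {
                        "name": f"s{i}t{t}k{k}",
                        "chrom": "chr1",
                        "pos": iv.start + (k * 7) % iv.width,
                        "mate_pos": iv.start + (k * 7) % iv.width + 150,
                    }
                )
        bam = build_bam(tmp_path / f"s{i}.bam", CONTIGS, reads, sample_id=f"s{i}")
        cohort.append(AlignmentSource(bam, f"s{i}"))
    return targets, cohort


class TestRunSimulation:
    def test_zero_deletions_passthrough_identical(self, tmp_path):
        targets, cohort = small_cohort(tmp_path)
        result = run_simulation(
            cohort, targets, SimulationConfig(method="downsample", n_range=(0, 0)), tmp_path / "o"
        )
        assert result.truth == []
        for src in cohort:
            out = result.sample_paths[src.sample_id]
            assert out.read_bytes() == src.path.read_bytes()

    def test_xreplace_without_male_is_config_error(self, tmp_path):
        targets, cohort = small_cohort(tmp_path)  # all female by default
        out = tmp_path / "o"
        with pytest.raises(ConfigurationError, match="male"):
            run_simulation(cohort, targets, SimulationConfig(method="xreplace"), out)
        assert not list(out.glob("*.bam")) if out.exists() else True

    def test_mate_consistency_and_locality(self, tmp_path):
        """After depletion no retained record has a removed mate, and pairs
        never touching a depleted region are carried through unchanged."""
        targets, cohort = small_cohort(tmp_path, n_samples=2)
        result = run_simulation(
            cohort,
            targets,
            SimulationConfig(method="downsample", n_range=(2, 2), size_range_targets=(1, 1), seed=5),
            tmp_path / "o",
        )
        regions = {d.sample_id: [] for d in result.truth}
        for d in result.truth:
            regions[d.sample_id].append(d.region)
        for src in cohort:
            with pysam.AlignmentFile(str(src.path)) as af:
                before = {}
                for r in af.fetch():
                    before.setdefault(r.query_name, []).append(r.to_string())
            with pysam.AlignmentFile(str(result.sample_paths[src.sample_id])) as af:
                after = {}
                for r in af.fetch():
                    after.setdefault(r.query_name, []).append(r.to_string())
            # pair atomicity: a name is fully kept or fully gone
            for name, recs in after.items():
                assert recs == before[name]
            # locality: pairs not touching any depleted region are retained
            for d in result.truth:
                if d.sample_id != src.sample_id:
                    continue
            touched = set()
            with pysam.AlignmentFile(str(src.path)) as af:
                for reg in regions.get(src.sample_id, []):
                    for r in af.fetch(reg.chrom, reg.start, reg.end):
                        touched.add(r.query_name)
            for name in before:
                if name not in touched:
                    assert name in after

    def test_xreplace_accounting(self, tmp_path):
        """Three X deletions in one female: truth has 3 rows, and each shows
        reads removed and added, consistent with independent region counts."""
        targets = TargetSet(uniform_targets("chrX", 15, width=100, gap=400))
        reads_f, reads_m = [], []
        for t, iv in enumerate(targets):
            for k in range(20):
                pos = iv.start + (k * 5) % iv.width
                reads_f.append({"name": f"f{t}k{k}", "chrom": "chrX", "pos": pos, "mate_pos": pos + 150})
                if k < 10:  # male X at half depth
                    reads_m.append({"name": f"m{t}k{k}", "chrom": "chrX", "pos": pos, "mate_pos": pos + 150})
        f = build_bam(tmp_path / "f.bam", CONTIGS, reads_f, sample_id="F")
        m = build_bam(tmp_path / "m.bam", CONTIGS, reads_m, sample_id="M")
        cohort = [AlignmentSource(f, "F"), AlignmentSource(m, "M", sex="male")]
        result = run_simulation(
            cohort,
            targets,
            SimulationConfig(method="xreplace", n_range=(3, 3), size_range_targets=(1, 1), seed=2),
            tmp_path / "o",
        )
        assert len(result.truth) == 3
        assert all(d.sample_id == "F" for d in result.truth)
        out_src = AlignmentSource(result.sample_paths["F"], "F")
        for row, d in zip(sorted(result.accounting, key=lambda a: a["deletion_id"]),
                          sorted(result.truth, key=lambda d: d.deletion_id)):
            assert row["reads_removed"] > 0
            assert row["reads_added"] > 0
            n_after = count_region_reads(out_src, d.region)
            assert n_after == row["reads_added"] + (
                count_region_reads(AlignmentSource(f, "F"), d.region) - row["reads_removed"]
            )

    def test_reproducible_output_bytes(self, tmp_path):
        targets, cohort = small_cohort(tmp_path, n_samples=2)
        cfg = SimulationConfig(method="downsample", n_range=(2, 3), size_range_targets=(1, 2), seed=8)
        r1 = run_simulation(cohort, targets, cfg, tmp_path / "o1")
        r2 = run_simulation(cohort, targets, cfg, tmp_path / "o2")
        for sid in r1.sample_paths:
            assert r1.sample_paths[sid].read_bytes() == r2.sample_paths[sid].read_bytes()
        assert r1.truth == r2.truth


def test_mean_depth_simple(tmp_path):
    # 10 reads of length 50 all inside a 100 bp window: depth 5
    reads = [{"name": f"r{i}", "chrom": "chr1", "pos": 1000 + i} for i in range(10)]
    bam = build_bam(tmp_path / "d.bam", CONTIGS, reads)
    d = mean_depth(AlignmentSource(bam, "S"), GenomicInterval("chr1", 1000, 1100))
    assert d == pytest.approx(sum(min(1000 + i + 50, 1100) - (1000 + i) for i in range(10)) / 100)
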