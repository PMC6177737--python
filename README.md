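# cnvbench

Benchmarking copy-number-variant (CNV) detection in whole-exome and targeted
panel sequencing, by simulating heterozygous deletions directly in a
cohort's aligned reads and scoring caller output against the known truth.

## The problem

Exome capture leaves CNV breakpoints unsequenced, so read depth (RD) is the
only signal exome CNV callers can use — and RD-based callers behave very
differently across datasets, capture designs, and parameter settings.
Before trusting a caller on a given dataset, an analyst needs to measure its
sensitivity and false-positive behaviour *on that dataset*. `cnvbench` does
this by planting synthetic single-copy deletions into the cohort's own BAM
files, so every confounder of the real data (capture efficiency, GC bias,
batch structure) is preserved, then quantifying how well any caller's output
recovers them.

## The method

**Deletion placement.** Random runs of adjacent capture targets are chosen
per sample (count per sample uniform in a configurable range, 2–10 by
default; size in target regions); truth is written as BED + TSV.

**Two depletion methods** reduce depth over a chosen region to the
single-copy level:

- *Downsampling* — each read pair with a mate overlapping the deletion
  target is removed with probability `p = 0.5`, assuming depth is linear in
  copy number. Removal decisions are a keyed hash of the read name, so mates
  share one fate and runs are byte-reproducible.
- *X-replacement* — on the X chromosome of a female sample, the region is
  first expanded until no read straddles either boundary; all female reads
  there are replaced by reads from the same region of a male sample,
  retained with probability `f = min(1, N_f / N_m)` where `N_f`, `N_m` are
  the samples' library sizes (primary, mapped, non-duplicate records). The
  male X truly has one copy, so no linearity assumption is needed and
  read-level features (inserts, SNV phasing) stay realistic.

**Evaluation.** A call is a true positive iff it overlaps a simulated
deletion of the same sample; anything else counts as a false positive
relative to the simulation (it may be a real CNV of the sample). Accuracy is
reported as a ranked, ROC-style curve in absolute counts — distinct
simulated deletions recovered (y) versus false-positive calls admitted (x)
as the quality threshold descends — plus sensitivity/precision summaries,
size-stratified subsets (by targeted bases or target count), quality-score
calibration (empirical precision in ~5 quantile score bins), and
multi-caller union/intersection combinations ranked by within-caller score
percentiles.

**QC.** Per-sample call-count distributions (with outlier flagging) and
genome-wide call density in 5 Mb bins expose sample-quality and
recurrent-artifact problems that raw accuracy numbers hide.

Everything is testable offline: a fixtures module generates synthetic
cohorts (sex-aware X ploidy, Poisson coverage) plus caller output with
controllable accuracy, and includes a minimal read-depth caller
(median-normalised log-ratio + segmentation) to close the loop.

## Worked example

Simulate deletions into a 6-sample synthetic cohort, call them back with the
built-in read-depth caller, and assemble the report:

```python
from cnvbench import CohortSpec, RunConfig, run_full
from cnvbench.fixtures import generate_cohort
from cnvbench.regions import GenomicInterval, TargetSet, write_targets_bed

targets = TargetSet(
    GenomicInterval("chr1", 1000 + i * 500, 1150 + i * 500) for i in range(40)
)
spec = CohortSpec(
    samples=[(f"s{i}", "female") for i in range(6)],
    contigs=[("chr1", 25_000)],
    targets=targets,
    mean_depth=80.0,
    seed=9,
)
manifest = generate_cohort(spec, "cohort")
write_targets_bed(targets, "targets.bed")

config = RunConfig.from_dict({
    "output_dir": "report",
    "targets": "targets.bed",
    "bams": {s.sample_id: str(s.path) for s in manifest.sources},
    "simulation": {"method": "downsample", "n_range": [2, 3],
                   "size_range_targets": [2, 3], "seed": 77},
    "toy_caller": {"enabled": True},
    "qc": {"chrom_sizes": str(manifest.chrom_sizes)},
})
run_full(config)
```

`report/index.md` then contains:

```
| call set | calls | TP | FP | sensitivity | precision |
|---|---|---|---|---|---|
| toy_rd | 14 | 14 | 0 | 0.929 | 1.000 |
```

14 deletions were simulated; the caller emitted 14 calls, all overlapping a
simulated deletion of the right sample (precision 1.000). They cover 13 of
the 14 distinct deletions — one deletion was hit by two calls, one was
missed — giving sensitivity 13/14 = 0.929. The report directory also holds
the ranked-accuracy curve (`roc_toy_rd.tsv`, `roc.png`), quality
calibration, per-sample call counts, genome-bin call density, and the
resolved configuration (`effective_config.yaml`), which reproduces the
identical report when re-run.

The same loop is available from the shell via the `cnvbench` command
(`simulate`, `evaluate`, `qc`, `merge`, `fixtures`, `run` subcommands); see
`cnvbench --help`.

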