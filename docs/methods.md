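# Methods

This note documents the models, numerical choices, and limitations behind
`cnvbench`. Coordinates are 0-based half-open (BED convention) throughout
the package; conversion happens only when reading tables declared 1-based.

## Deletion placement

Simulated deletions are runs of adjacent capture target regions. Per sample,
the deletion count k is drawn uniformly from `n_range` (default 2–10) and
each deletion's size m uniformly from `size_range_targets` (in target
regions, the unit RD callers operate on; a targeted-bases stratification is
available at evaluation time). Placement is rejection sampling with a cap of
1000 attempts per deletion; an infeasible request fails loudly, reporting
how many deletions were placed.

Two rules are deliberate design choices rather than externally mandated:

- **Gap rule.** Deletions within one sample must be separated by at least
  one untouched target region. Without it, two adjacent simulated events
  would be indistinguishable from a single larger one, corrupting both the
  truth count and the size stratification.
- **Cross-sample reuse.** By default the same genomic site may host
  deletions in several samples; `cross_sample_disjoint` forces cohort-wide
  disjointness for callers that build a cohort reference (a site deleted in
  many samples shifts a median reference toward the deleted level and hides
  the event). Both behaviours are supported because neither is obviously
  the "real" study design.

Each truth record carries its own sub-seed, drawn from the placement RNG, so
per-deletion read edits are reproducible independently of evaluation order.

## Downsampling depletion

Every read pair with at least one mate overlapping the targeted interval is
removed with probability `p_remove` (default 0.5, the linear
copy-number–depth assumption for a heterozygous deletion: 1 of 2 copies).
The removal decision is `blake2b(read_name, key=seed) < p`, i.e. a
deterministic keyed hash per read *name*:

- both mates (and any secondary/supplementary records of the pair) always
  share one fate — orphaned mates would create anomalous-pair signals that
  real deletions do not produce and that some tools treat as evidence;
- reruns with the same seed are byte-identical;
- the per-pair decisions are i.i.d. Bernoulli, so the retained count over n
  pairs is exactly Binomial(n, 1−p) — the property the test suite checks
  with exact binomial intervals.

The cost of pair atomicity is a slightly soft deletion edge: a removed pair
whose second mate lies outside the region also loses that mate. The
locality guarantee is therefore stated per pair: pairs that never touch a
depleted region are carried through byte-identical.

## X-replacement depletion

On the X chromosome of a female sample, the targeted interval is first
expanded outward (100 bp steps, 100 kb cap, both configurable) until neither
boundary coordinate is straddled by any read in either the female or the
male file; this guarantees the subsequent swap cannot split a read across
the boundary. All female reads overlapping the expanded region are removed
and male reads from the same region are inserted, each pair retained with
probability `f = min(1, N_f/N_m)` using the same keyed-hash rule, where N is
the genome-wide count of primary, mapped, non-duplicate records. Inserted
records keep their original coordinates and CIGAR (they are real
alignments; re-aligning would defeat the realism argument), get a
collision-proof name prefix, and are re-tagged to the female read group. The
output stays coordinate-sorted by merging the position-sorted insertions
during a single pass over the input, which keeps outputs byte-stable (no
re-sort step that could embed temporary paths in the header).

Choices worth noting:

- **Donor selection**: one male donor per run — configured explicitly or
  the male with the largest library. Mixing donors would average away
  donor-specific coverage structure that is part of the method's realism.
- **Normalisation scope**: genome-wide library sizes, which are robust to
  the depletion being simulated. When the design is X-heavy the female/male
  ratio exceeds 1 purely from ploidy; retention is then capped at 1 with a
  warning (one cannot upsample reads), which in a same-depth cohort is also
  the correct normalisation.
- A male pair with only one mate inside the expanded region contributes
  only that mate; flags are left as-is. At read-free boundaries this is
  rare, and RD-based tools do not inspect the missing mate.
- Expanded intervals of distinct deletions are assumed disjoint (the gap
  rule plus modest expansions make this hold in practice); overlapping
  expansions would double-insert donor reads in the overlap.

## Evaluation model

A call is **TP** iff it overlaps — ≥ 1 bp by default, optionally a
reciprocal fraction of both intervals — the targeted span of at least one
simulated deletion *of the same sample*; otherwise **FP**. FPs are relative
to the simulation: a real CNV of the sample counts as FP by construction,
which is inherent to the definition and not corrected for. Calls from
samples outside the simulated cohort (e.g. males in an X-replacement run)
are FP-eligible.

The ranked accuracy curve admits calls in descending quality order, one
point per distinct score with the whole tie group entering together
(threshold semantics are "at or above"). The y-axis counts *distinct*
deletions recovered, so the final point over |truth| is the overall
sensitivity; both coordinates are non-decreasing by construction and every
metric is invariant under strictly monotone transforms of any one caller's
scores.

Calibration bins are equal-count quantile bins (default 5) over the
observed score range; when there are no more distinct scores than requested
bins, each distinct score forms its own bin. Equal-count bins keep per-bin
precision estimates comparably stable, at the cost of unequal score widths.

Size stratification filters the truth by targeted bases or target count and
re-labels calls against the retained subset. A TP call whose every match
was excluded is dropped rather than relabelled FP: it is a correct
detection of an out-of-range event, not noise, and counting it as FP would
penalise callers for finding real (simulated) signal.

Cross-caller combinations (union/intersection of merged overlapping calls)
are ranked by within-caller rank percentiles — max over members for union,
min for intersection — because raw scores are incomparable across tools.

## QC summaries

Per-sample call counts are tabulated over the full declared cohort
(zero-filled), per caller; a sample is flagged when its count exceeds
median + 3·IQR of that caller's distribution. The rule is a conventional
robust-outlier cut chosen here; the underlying phenomenon (a few samples
hoarding most calls) is what matters, and the threshold is configurable.
Genome-wide call density uses fixed 5 Mb bins tiled from position 0 of each
contig; a boundary-spanning call increments every bin it overlaps.

## Synthetic cohorts

The generator emulates what RD-signal analysis actually consumes:
coordinate-sorted proper FR read pairs at Poisson per-target counts with
mean `mean_depth · copy/2 · width/(2·read_length)`, Gaussian insert sizes
truncated below at the read length, constant base content and qualities,
unique names, and read groups set to the sample id. Males carry one X copy,
females two; explicit per-sample copy-number overrides are supported.
Defaults (depth 60–120, 2×100 bp reads, ~300 bp inserts) sit in the range
of contemporary exome datasets.

What it does **not** model: sequence content, base errors, mappability and
GC bias, duplicates, off-target coverage, batch effects. Tests passing on
these cohorts therefore validate the *bookkeeping and statistics* of
depletion and evaluation — that depth really halves, that labels, curves
and bins are computed correctly — not any claim about caller performance on
real data, which is exactly the question the tool exists to let users
answer on their own cohorts.

The synthetic caller-output generator emits each truth deletion with a set
sensitivity (boundaries jittered while preserving overlap), Poisson
false calls per sample on non-truth target runs, and scores
N(margin, 1) vs N(0, 1) for TP vs FP, making score informativeness a dial
(margin 0 = useless scores).

The built-in toy read-depth caller normalises per-target counts by library
size, takes log2 ratios against the per-target cohort median, flags targets
with robust z < −3 *and* log-ratio < −0.5 (half-way to the −1.0 of a
heterozygous deletion; the magnitude guard suppresses tiny-variance
artifacts), segments consecutive flagged targets, and scores segments by
the summed negative z. It needs ≥ 3 samples for a median reference and is
a testing instrument, not a production caller: it has no GC/mappability
correction and a shared-median reference that mixed-sex cohorts would bias
on X.

## Problem sizes and reproducibility

The shipped test suite and `scripts/acceptance.py` use cohorts of 3–20
samples, 40–200 targets of 120–400 bp, and mean depth 30–100: large enough
that binomial/Poisson checks have power (≥ 10⁴ pairs for the retention
rate, ≥ 50 deletions for depth ratios, ≥ 60 truth deletions end-to-end),
small enough to synthesise in seconds. Every random choice flows from an
explicit seed (placement and per-deletion hashes from the truth RNG,
cohorts from the spec seed), and full runs write a resolved configuration
that reproduces the report byte-for-byte.

## Known limitations

- Deletions only; no duplications, homozygous or mosaic states (the
  evaluation side is state-agnostic, so externally simulated events can be
  scored by supplying a truth TSV).
- BAM only (no CRAM) in this version.
- No interactive report; outputs are static TSV/JSON/PNG/Markdown.
- The FP definition cannot distinguish a caller's noise from its genuine
  discoveries outside the simulation.
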