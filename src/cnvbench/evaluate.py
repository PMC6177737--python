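"""Scoring CNV calls against simulated truth.

A call is a true positive when it overlaps a simulated deletion of the same
sample; anything else is a false positive *relative to the simulation* — it
may well be a genuine CNV of the sample, which is inherent to this
definition and not corrected for. Accuracy is summarised as a ranked
(ROC-style) curve in absolute counts: distinct simulated deletions recovered
(y) versus false-positive calls admitted (x) as the quality threshold is
lowered, which compares the *ranking* induced by each caller's confidence
score rather than raw call counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .calls import CnvCall
from .regions import SimulatedDeletion

logger = logging.getLogger(__name__)

TP = "TP"
FP = "FP"


@dataclass(frozen=True)
class LabelledCall:
    call: CnvCall
    label: str
    matched_truth_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.label not in (TP, FP):
            raise ValueError(f"label must be TP|FP, got {self.label!r}")
        if (self.label == TP) != bool(self.matched_truth_ids):
            raise ValueError("label TP iff matched_truth_ids is non-empty")


@dataclass(frozen=True)
class RocPoint:
    """One point of the ranked accuracy curve at an inclusive quality cut."""

    threshold: float
    fp_count: int
    tp_truth_count: int


@dataclass(frozen=True)
class CalibrationBin:
    score_low: float
    score_high: float
    n_calls: int
    n_tp: int

    @property
    def precision(self) -> float:
        return self.n_tp / self.n_calls if self.n_calls else math.nan


class SampleMismatchError(ValueError):
    """A call names a sample absent from the simulated cohort (strict mode)."""


def classify_calls(
    calls: Sequence[CnvCall],
    truth: Sequence[SimulatedDeletion],
    overlap_frac: float = 0.0,
    known_samples: Iterable[str] | None = None,
    strict: bool = False,
) -> list[LabelledCall]:
    """Label each call TP or FP against the simulated truth.

    A call is TP iff it overlaps (>= 1 bp by default; reciprocal fraction
    ``overlap_frac`` of both intervals when > 0) the targeted interval of at
    least one truth deletion *of the same sample*; all matched truth ids are
    recorded. Calls from samples outside the simulated cohort are FP-eligible
    with a warning, or an error in strict mode.
    """
    truth_index: dict[tuple[str, str], list[SimulatedDeletion]] = {}
    for d in truth:
        truth_index.setdefault((d.sample_id, d.targeted_interval.chrom), []).append(d)

    known = set(known_samples) if known_samples is not None else None
    labelled: list[LabelledCall] = []
    for c in calls:
        if known is not None and c.sample_id not in known:
            msg = f"call sample {c.sample_id!r} not in the simulated cohort"
            if strict:
                raise SampleMismatchError(msg)
            logger.warning("%s; treating its calls as FP-eligible", msg)
        matches = tuple(
            d.deletion_id
            for d in truth_index.get((c.sample_id, c.interval.chrom), [])
            if c.interval.overlaps(d.targeted_interval, overlap_frac)
        )
        labelled.append(LabelledCall(call=c, label=TP if matches else FP, matched_truth_ids=matches))
    return labelled


def roc_curve(labelled: Sequence[LabelledCall], truth: Sequence[SimulatedDeletion]) -> list[RocPoint]:
    """Ranked accuracy curve for one caller (or one combined call set).

    Calls are admitted in descending quality order; one point per distinct
    quality value, the whole tie group entering together. ``tp_truth_count``
    counts *distinct* simulated deletions recovered (a deletion hit by three
    calls counts once), so the final point over |truth| is the overall
    sensitivity. An empty call set yields the single point (0, 0).
    """
    if not labelled:
        return [RocPoint(threshold=math.inf, fp_count=0, tp_truth_count=0)]
    ordered = sorted(labelled, key=lambda lc: -lc.call.quality)
    points: list[RocPoint] = []
    seen_truth: set[str] = set()
    fp = 0
    i = 0
    while i < len(ordered):
        q = ordered[i].call.quality
        while i < len(ordered) and ordered[i].call.quality == q:
            lc = ordered[i]
            if lc.label == FP:
                fp += 1
            else:
                seen_truth.update(lc.matched_truth_ids)
            i += 1
        points.append(RocPoint(threshold=q, fp_count=fp, tp_truth_count=len(seen_truth)))
    return points


@dataclass(frozen=True)
class AccuracySummary:
    n_truth: int
    n_calls: int
    n_tp_calls: int
    n_fp_calls: int
    truth_detected: int
    sensitivity: float | None  # None when the truth set is empty
    precision: float | None  # None when no calls pass the threshold
    threshold: float | None


def sensitivity_precision(
    labelled: Sequence[LabelledCall],
    truth: Sequence[SimulatedDeletion],
    threshold: float | None = None,
) -> AccuracySummary:
    """Sensitivity (distinct deletions recovered / |truth|) and precision
    (TP calls / all calls) at an inclusive quality threshold (default: all)."""
    kept = [lc for lc in labelled if threshold is None or lc.call.quality >= threshold]
    tp_calls = [lc for lc in kept if lc.label == TP]
    detected = {tid for lc in tp_calls for tid in lc.matched_truth_ids}
    n_truth = len({d.deletion_id for d in truth})
    return AccuracySummary(
        n_truth=n_truth,
        n_calls=len(kept),
        n_tp_calls=len(tp_calls),
        n_fp_calls=len(kept) - len(tp_calls),
        truth_detected=len(detected),
        sensitivity=(len(detected) / n_truth) if n_truth else None,
        precision=(len(tp_calls) / len(kept)) if kept else None,
        threshold=threshold,
    )


def calibration_bins(labelled: Sequence[LabelledCall], n_bins: int = 5) -> list[CalibrationBin]:
    """Quantile-bin the quality scores and compute per-bin empirical precision.

    Bins are equal-count quantile bins spanning the full observed score
    range; when there are no more distinct scores than bins, each distinct
    score gets its own bin. Bins are returned in ascending score order and
    partition the call set (counts sum to the total).
    """
    if not labelled:
        raise ValueError("calibration requires at least one call")
    scores = np.array([lc.call.quality for lc in labelled], dtype=float)
    is_tp = np.array([lc.label == TP for lc in labelled])
    distinct = np.unique(scores)
    if len(distinct) <= n_bins:
        bins = []
        for v in distinct:
            mask = scores == v
            bins.append(
                CalibrationBin(
                    score_low=float(v),
                    score_high=float(v),
                    n_calls=int(mask.sum()),
                    n_tp=int(is_tp[mask].sum()),
                )
            )
        return bins
    cats = pd.qcut(scores, q=n_bins, duplicates="drop")
    out: list[CalibrationBin] = []
    for interval in cats.categories:
        mask = np.asarray(cats == interval)
        out.append(
            CalibrationBin(
                score_low=float(interval.left),
                score_high=float(interval.right),
                n_calls=int(mask.sum()),
                n_tp=int(is_tp[mask].sum()),
            )
        )
    return out


def size_stratify(
    truth: Sequence[SimulatedDeletion],
    labelled: Sequence[LabelledCall],
    by: str = "targets",
    size_range: tuple[float, float] = (0, math.inf),
) -> tuple[list[SimulatedDeletion], list[LabelledCall]]:
    """Restrict truth and calls to deletions in a size range.

    ``by`` is "bases" (targeted bases: summed member-target widths) or
    "targets" (number of member target regions). Calls are re-labelled
    against the retained truth; a TP call whose every match was excluded is
    *dropped* — it is a correct detection of an out-of-range event, not
    noise — while FP calls are kept as FP.
    """
    if by not in ("bases", "targets"):
        raise ValueError(f"by must be bases|targets, got {by!r}")
    lo, hi = size_range
    if lo > hi:
        raise ValueError(f"invalid size range {size_range}")

    def size(d: SimulatedDeletion) -> int:
        return d.targeted_bases if by == "bases" else d.n_targets

    kept_truth = [d for d in truth if lo <= size(d) <= hi]
    kept_ids = {d.deletion_id for d in kept_truth}
    if not kept_truth:
        logger.warning("size stratum %s %s retains no truth deletions", by, size_range)

    out: list[LabelledCall] = []
    for lc in labelled:
        if lc.label == FP:
            out.append(lc)
            continue
        matches = tuple(t for t in lc.matched_truth_ids if t in kept_ids)
        if matches:
            out.append(LabelledCall(call=lc.call, label=TP, matched_truth_ids=matches))
        # else: correct detection of an excluded deletion — dropped
    return kept_truth, out


def roc_points_frame(points: Sequence[RocPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "threshold": [p.threshold for p in points],
            "fp_count": [p.fp_count for p in points],
            "tp_truth_count": [p.tp_truth_count for p in points],
        }
    )


def calibration_frame(bins: Sequence[CalibrationBin]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "score_low": [b.score_low for b in bins],
            "score_high": [b.score_high for b in bins],
            "n_calls": [b.n_calls for b in bins],
            "n_tp": [b.n_tp for b in bins],
            "precision": [b.precision for b in bins],
        }
    )
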