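"""Uniform CNV call model: reading heterogeneous caller tables, merging
overlapping calls, and union/intersection combinations of callers.

Raw quality scores are caller-specific and incomparable across tools, so
cross-caller combination ranks calls by their within-caller rank percentile,
which is invariant to any strictly monotone rescaling of one caller's scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .regions import GenomicInterval

logger = logging.getLogger(__name__)

DEL = "DEL"
DUP = "DUP"
ANY = "ANY"


class SchemaError(ValueError):
    """Call table lacks a mandatory column."""


@dataclass(frozen=True)
class CnvCall:
    """One caller detection with a higher-is-better confidence score."""

    sample_id: str
    caller: str
    interval: GenomicInterval
    quality: float
    cnv_type: str = DEL
    imputed_quality: bool = False

    def __post_init__(self) -> None:
        if self.cnv_type not in (DEL, DUP, ANY):
            raise ValueError(f"unknown cnv_type {self.cnv_type!r}")
        if not pd.notna(self.quality) or self.quality in (float("inf"), float("-inf")):
            raise ValueError(f"quality must be finite, got {self.quality!r}")


@dataclass(frozen=True)
class MergedCall:
    """Cluster of mutually (transitively) overlapping calls in one sample."""

    sample_id: str
    span: GenomicInterval
    members: tuple[CnvCall, ...]
    supporters: frozenset[str] = field(default=frozenset())

    @property
    def support_count(self) -> int:
        return len(self.supporters)


@dataclass(frozen=True)
class CallDialect:
    """How to read one caller's output table.

    ``coords`` is "0-based" (half-open, BED-like; used as is) or "1-based"
    (inclusive; start is decremented on load). ``higher_is_better`` declares
    the score orientation; lower-is-better scores are negated so stored
    qualities are uniformly higher-is-better.
    """

    coords: str = "0-based"
    higher_is_better: bool = True
    chrom_col: str = "chrom"
    start_col: str = "start"
    end_col: str = "end"
    sample_col: str = "sample"
    type_col: str | None = None

    def __post_init__(self) -> None:
        if self.coords not in ("0-based", "1-based"):
            raise ValueError(f"unknown coordinate dialect {self.coords!r}")


def read_calls(
    path: str | Path,
    caller: str,
    score_column: str,
    dialect: CallDialect = CallDialect(),
) -> list[CnvCall]:
    """Read one caller's tab-separated call table into the uniform model.

    Rows with a missing score get the caller's minimum observed score and are
    flagged (``imputed_quality``); if no row has a score, 0.0 is used.
    """
    df = pd.read_csv(path, sep="\t")
    required = [dialect.chrom_col, dialect.start_col, dialect.end_col, dialect.sample_col]
    missing = [c for c in required + [score_column] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")

    scores = pd.to_numeric(df[score_column], errors="coerce")
    if not dialect.higher_is_better:
        scores = -scores
    observed = scores.dropna()
    fill = float(observed.min()) if len(observed) else 0.0
    n_imputed = int(scores.isna().sum())
    if n_imputed:
        logger.warning("%s: %d call(s) lacked a score; imputed caller minimum %.4g", path, n_imputed, fill)

    out: list[CnvCall] = []
    for row, score in zip(df.itertuples(index=False), scores):
        start = int(getattr(row, dialect.start_col))
        end = int(getattr(row, dialect.end_col))
        if dialect.coords == "1-based":
            start -= 1
        cnv_type = DEL
        if dialect.type_col is not None:
            cnv_type = str(getattr(row, dialect.type_col)).upper()
        out.append(
            CnvCall(
                sample_id=str(getattr(row, dialect.sample_col)),
                caller=caller,
                interval=GenomicInterval(str(getattr(row, dialect.chrom_col)), start, end),
                quality=float(score) if pd.notna(score) else fill,
                cnv_type=cnv_type,
                imputed_quality=bool(pd.isna(score)),
            )
        )
    return out


def write_calls_tsv(calls: Iterable[CnvCall], path: str | Path) -> None:
    rows = [
        {
            "chrom": c.interval.chrom,
            "start": c.interval.start,
            "end": c.interval.end,
            "sample": c.sample_id,
            "caller": c.caller,
            "type": c.cnv_type,
            "quality": c.quality,
        }
        for c in sorted(calls, key=lambda c: (c.interval, c.sample_id, c.caller))
    ]
    pd.DataFrame(
        rows, columns=["chrom", "start", "end", "sample", "caller", "type", "quality"]
    ).to_csv(path, sep="\t", index=False)


def merge_calls(calls: Sequence[CnvCall], reciprocal: float = 0.0) -> list[MergedCall]:
    """Single-linkage clustering of overlapping calls within each sample.

    Two calls link when their intervals overlap by >= 1 bp (and, when
    ``reciprocal`` > 0, by that fraction of both intervals); clusters are the
    transitive closure. Calls from different samples never merge. Every input
    call belongs to exactly one cluster.
    """
    groups: dict[tuple[str, str], list[CnvCall]] = {}
    for c in calls:
        groups.setdefault((c.sample_id, c.interval.chrom), []).append(c)

    merged: list[MergedCall] = []
    for (sample_id, _chrom), group in groups.items():
        group = sorted(group, key=lambda c: (c.interval.start, c.interval.end))
        parent = list(range(len(group)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        # starts are sorted, so j can only overlap i while start_j < end_i;
        # links between later pairs are found at their own i
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                if group[j].interval.start >= group[i].interval.end:
                    break
                if group[i].interval.overlaps(group[j].interval, reciprocal):
                    parent[find(i)] = find(j)
        clusters: dict[int, list[CnvCall]] = {}
        for i, c in enumerate(group):
            clusters.setdefault(find(i), []).append(c)
        for members in clusters.values():
            span = GenomicInterval(
                members[0].interval.chrom,
                min(m.interval.start for m in members),
                max(m.interval.end for m in members),
            )
            merged.append(
                MergedCall(
                    sample_id=sample_id,
                    span=span,
                    members=tuple(members),
                    supporters=frozenset(m.caller for m in members),
                )
            )
    merged.sort(key=lambda m: (m.span, m.sample_id))
    return merged


def _rank_percentiles(calls: Sequence[CnvCall]) -> dict[int, float]:
    """Within-caller rank percentile of each call's quality (by identity)."""
    pct: dict[int, float] = {}
    by_caller: dict[str, list[CnvCall]] = {}
    for c in calls:
        by_caller.setdefault(c.caller, []).append(c)
    for group in by_caller.values():
        qualities = pd.Series([c.quality for c in group])
        ranks = qualities.rank(pct=True, method="average")
        for c, r in zip(group, ranks):
            pct[id(c)] = float(r)
    return pct


def combine_callers(
    calls_by_caller: Mapping[str, Sequence[CnvCall]],
    mode: str,
    min_support: int | None = None,
    reciprocal: float = 0.0,
) -> list[CnvCall]:
    """Union or intersection of several callers' results.

    All calls are merged; each cluster passing the support rule (union:
    >= 1 caller; intersection: >= ``min_support`` distinct callers, default
    all of them) is emitted as one synthetic call spanning the cluster. The
    synthetic quality is a within-caller rank-percentile aggregate — max over
    members for union, min for intersection — keeping combined results
    rankable on a common scale.
    """
    if mode not in ("union", "intersection"):
        raise ValueError(f"mode must be union|intersection, got {mode!r}")
    if not calls_by_caller:
        raise ValueError("at least one caller required")
    n_callers = len(calls_by_caller)
    if mode == "intersection":
        min_support = n_callers if min_support is None else min_support
        if min_support > n_callers:
            raise ValueError(f"min_support {min_support} exceeds number of callers {n_callers}")
    else:
        min_support = 1

    all_calls: list[CnvCall] = [c for group in calls_by_caller.values() for c in group]
    pct = _rank_percentiles(all_calls)
    agg = max if mode == "union" else min
    out: list[CnvCall] = []
    for mc in merge_calls(all_calls, reciprocal=reciprocal):
        if mc.support_count < min_support:
            continue
        quality = agg(pct[id(m)] for m in mc.members)
        out.append(
            CnvCall(
                sample_id=mc.sample_id,
                caller=mode,
                interval=mc.span,
                quality=quality,
                cnv_type=DEL,
            )
        )
    out.sort(key=lambda c: (c.interval, c.sample_id))
    return out
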