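"""Cohort-level QC summaries of CNV call sets.

Two views flag dataset problems before any accuracy interpretation: the
per-sample call-count distribution (samples hoarding a disproportionate
share of calls usually indicate sample-quality or normalisation trouble) and
the genome-wide call density in fixed 5 Mb bins (recurrently noisy regions
that may merit exclusion from the capture design used for calling).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .calls import CnvCall

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 5_000_000  # 5 Mb


def sample_counts(
    calls_by_caller: Mapping[str, Sequence[CnvCall]],
    samples: Iterable[str] | None = None,
    outlier_iqr: float = 3.0,
) -> pd.DataFrame:
    """Per-(sample, caller) call counts over the full cohort grid.

    The grid covers every declared sample crossed with every caller,
    zero-filled for samples a caller is silent on. A sample is flagged as an
    outlier for a caller when its count exceeds
    ``median + outlier_iqr * IQR`` of that caller's per-sample counts.
    """
    declared = list(samples) if samples is not None else sorted(
        {c.sample_id for group in calls_by_caller.values() for c in group}
    )
    rows = []
    for caller, group in calls_by_caller.items():
        counts = {s: 0 for s in declared}
        for c in group:
            if c.sample_id not in counts:
                counts[c.sample_id] = 0
            counts[c.sample_id] += 1
        values = np.array(list(counts.values()), dtype=float)
        med = float(np.median(values))
        q1, q3 = np.percentile(values, [25, 75])
        cut = med + outlier_iqr * (q3 - q1)
        for s, n in counts.items():
            rows.append(
                {
                    "sample_id": s,
                    "caller": caller,
                    "n_calls": n,
                    "outlier": bool(n > cut),
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "caller", "n_calls", "outlier"])


def genome_distribution(
    calls_by_caller: Mapping[str, Sequence[CnvCall]],
    contig_lengths: Mapping[str, int],
    bin_width: int = DEFAULT_BIN_WIDTH,
) -> pd.DataFrame:
    """Call density along the genome in fixed-width bins.

    Each contig is tiled from position 0 with ``bin_width``-wide bins (the
    last bin may be shorter). A call increments every bin it overlaps; calls
    on contigs absent from ``contig_lengths`` are skipped with a warning.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    bins: list[tuple[str, int, int]] = []
    for chrom, length in contig_lengths.items():
        for start in range(0, length, bin_width):
            bins.append((chrom, start, min(start + bin_width, length)))
    bin_index = {(chrom, start): i for i, (chrom, start, _end) in enumerate(bins)}

    rows = []
    for caller, group in calls_by_caller.items():
        counts = np.zeros(len(bins), dtype=int)
        skipped = 0
        for c in group:
            if c.interval.chrom not in contig_lengths:
                skipped += 1
                continue
            length = contig_lengths[c.interval.chrom]
            first = (c.interval.start // bin_width) * bin_width
            last = ((min(c.interval.end, length) - 1) // bin_width) * bin_width
            for start in range(first, last + 1, bin_width):
                counts[bin_index[(c.interval.chrom, start)]] += 1
        if skipped:
            logger.warning(
                "caller %s: skipped %d call(s) on contigs with unknown length", caller, skipped
            )
        for (chrom, start, end), n in zip(bins, counts):
            rows.append(
                {
                    "chrom": chrom,
                    "bin_start": start,
                    "bin_end": end,
                    "caller": caller,
                    "n_overlapping_calls": int(n),
                }
            )
    return pd.DataFrame(
        rows, columns=["chrom", "bin_start", "bin_end", "caller", "n_overlapping_calls"]
    )
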