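"""Expected-vs-observed significance bookkeeping.

For the class-level evaluation, each (measurement, movement class) cell has a
prior expectation -- is this measurement designed to capture that class's
characteristic movement?  Crossing the observed significance flags with that
expectation mask gives per-class counts: TP (significant and expected), FP
(significant but not expected), FN (expected but not significant); true
negatives are ignored.  Recall/precision/F1 per class (and pooled over all
classes) then summarize how well the measurement set captures the movements
it was designed for.
"""

from __future__ import annotations

import pandas as pd

from .classification import MetricsTable, metrics_from_counts

__all__ = ["expected_observed_metrics"]


def expected_observed_metrics(
    significant: pd.DataFrame, expected: pd.DataFrame
) -> MetricsTable:
    """Cross-tabulate significance flags against an expectation mask.

    Both frames are boolean with measurements as rows and class labels as
    columns (identical shape and labels).  Returns per-class TP/FP/FN with
    R/P/F1, plus an ``ALL`` row pooling the counts over classes.
    """
    if list(significant.index) != list(expected.index) or list(
        significant.columns
    ) != list(expected.columns):
        raise ValueError("significant and expected masks must share labels")
    sig = significant.astype(bool)
    exp = expected.astype(bool)
    tp = (sig & exp).sum(axis=0)
    fp = (sig & ~exp).sum(axis=0)
    fn = (~sig & exp).sum(axis=0)
    labels = list(significant.columns) + ["ALL"]
    return metrics_from_counts(
        list(tp) + [int(tp.sum())],
        list(fp) + [int(fp.sum())],
        list(fn) + [int(fn.sum())],
        labels,
    )
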