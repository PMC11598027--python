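"""LOOCV word classification by profile-matching and confusion-matrix metrics.

The classifier is deliberately simple: for one measurement stream and
derivative order, a held-out participant's word trace t is compared with the
cohort profile mean p of each candidate word by the mean squared pointwise
difference over the 1000 normalized-time samples,

    psi(m, w) = (1/1000) * sum_i (p_i - t_i)^2,

and the predicted word is the argmin of psi over the word set.  Ties break
deterministically in canonical word-list order.  Leave-one-out
cross-validation rebuilds the profiles from the remaining participants for
every held-out participant, yielding 20 x N observations per measurement in
a 20 x 20 confusion matrix.

Word-level matrices aggregate into 5 x 5 movement-similarity classes (with
"Papa" excluded, its row and column dropped before summing) and into 2 x 2
mandibular vs labial-facial groups (with "Papa" reincluded).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources as _importlib_resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "WORDS",
    "ConfusionMatrix",
    "AggregationMap",
    "MetricsTable",
    "default_aggregation_maps",
    "psi",
    "predict_word",
    "loocv_classify",
    "aggregate_confusion",
    "compute_metrics",
    "metrics_from_counts",
]


def _wordlist_resource() -> dict:
    text = _importlib_resources.files("facekin.resources").joinpath("wordlist.json").read_text()
    return json.loads(text)


WORDS: tuple[str, ...] = tuple(_wordlist_resource()["words"])


@dataclass(frozen=True)
class ConfusionMatrix:
    """Labeled counts; rows are true labels, columns predicted labels."""

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.shape != (len(self.labels), len(self.labels)):
            raise ValueError("counts must be a square labels x labels grid")
        if np.any(c < 0):
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))


@dataclass(frozen=True)
class AggregationMap:
    """Word -> coarser label mapping with optional excluded words."""

    mapping: Mapping[str, str]
    label_order: tuple[str, ...]
    excluded: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        mapped = set(self.mapping.values())
        if not mapped <= set(self.label_order):
            raise ValueError("mapping targets must appear in label_order")


def default_aggregation_maps() -> dict[str, AggregationMap]:
    """The shipped movement-similarity class map and the two-group map.

    The class map partitions 19 words into five movement classes ("Papa" is
    excluded -- its kinematic production resembles none of the others); the
    group map partitions all 20 words into mandibular vs labial-facial.
    """
    data = _wordlist_resource()
    class_map = {
        w: cls for cls, words in data["classes"].items() for w in words
    }
    classes = AggregationMap(
        mapping=class_map,
        label_order=tuple(sorted(data["classes"], key=int)),
        excluded=frozenset(data["excluded_at_class_level"]),
    )
    group_map = {w: g for g, words in data["groups"].items() for w in words}
    groups = AggregationMap(
        mapping=group_map,
        label_order=("mandibular", "labial_facial"),
        excluded=frozenset(),
    )
    return {"class": classes, "group": groups}


def psi(profile_mean: np.ndarray, test_trace: np.ndarray) -> float:
    """Mean squared pointwise difference between a profile mean and a trace."""
    p = np.asarray(profile_mean, dtype=float)
    t = np.asarray(test_trace, dtype=float)
    if p.shape != t.shape or p.ndim != 1:
        raise ValueError(f"profile and trace must be 1-D and equal length, got {p.shape} vs {t.shape}")
    return float(np.mean((p - t) ** 2))


def predict_word(
    test_traces: Mapping[str, np.ndarray],
    profiles: Mapping[str, np.ndarray],
    word_order: Sequence[str] = WORDS,
) -> dict[str, str]:
    """Predict each test word as the argmin-psi profile over the word set.

    Ties break toward the earliest word in ``word_order``.  Raises KeyError if
    any word in the order lacks a profile.
    """
    missing = [w for w in word_order if w not in profiles]
    if missing:
        raise KeyError(f"missing profile(s) for {missing}")
    out = {}
    for w, trace in test_traces.items():
        psis = [psi(profiles[cand], trace) for cand in word_order]
        out[w] = word_order[int(np.argmin(psis))]
    return out


def loocv_classify(
    traces: Mapping[str, Mapping[str, np.ndarray]],
    word_order: Sequence[str] = WORDS,
) -> ConfusionMatrix:
    """Leave-one-out cross-validated word classification for one measurement.

    ``traces`` maps participant id -> word -> 1000-point trace.  Each
    participant in turn is held out; profiles are rebuilt as the pointwise
    mean over the remaining participants' traces, and each of the held-out
    participant's word traces is classified by argmin psi.  A participant
    missing a word trace contributes no observation for that word (logged).
    """
    pids = sorted(traces)
    if len(pids) < 3:
        raise ValueError("LOOCV needs at least 3 participants")
    words = tuple(word_order)
    widx = {w: i for i, w in enumerate(words)}
    P, W = len(pids), len(words)
    n_pts = len(next(iter(next(iter(traces.values())).values())))
    arr = np.full((P, W, n_pts), np.nan)
    for i, p in enumerate(pids):
        for w, tr in traces[p].items():
            if w in widx:
                arr[i, widx[w]] = tr
    have = ~np.isnan(arr[:, :, 0])
    for i, p in enumerate(pids):
        for j, w in enumerate(words):
            if not have[i, j]:
                logger.warning("participant %s missing trace for word %s; skipped", p, w)

    counts = np.zeros((W, W), dtype=np.int64)
    sums = np.where(have[:, :, None], arr, 0.0).sum(axis=0)
    ns = have.sum(axis=0)
    for i in range(P):
        n_train = ns - have[i]
        if np.any(n_train == 0):
            bad = [words[j] for j in np.where(n_train == 0)[0]]
            raise KeyError(f"missing profile(s) for {bad} with participant {pids[i]} held out")
        prof = (sums - np.where(have[i][:, None], arr[i], 0.0)) / n_train[:, None]
        for j in range(W):
            if not have[i, j]:
                continue
            d = prof - arr[i, j][None, :]
            psis = np.mean(d * d, axis=1)
            counts[j, int(np.argmin(psis))] += 1
    return ConfusionMatrix(labels=words, counts=counts)


def aggregate_confusion(cm: ConfusionMatrix, agg: AggregationMap) -> ConfusionMatrix:
    """Sum confusion counts into coarser labels, dropping excluded words.

    Excluded words' rows *and* columns are removed before summing, so the
    total changes only by the observations involving excluded labels.
    """
    unmapped = [l for l in cm.labels if l not in agg.mapping and l not in agg.excluded]
    if unmapped:
        raise KeyError(f"labels {unmapped} neither mapped nor excluded")
    out_labels = agg.label_order
    oidx = {l: i for i, l in enumerate(out_labels)}
    counts = np.zeros((len(out_labels), len(out_labels)), dtype=np.int64)
    for i, li in enumerate(cm.labels):
        if li in agg.excluded:
            continue
        for j, lj in enumerate(cm.labels):
            if lj in agg.excluded:
                continue
            counts[oidx[agg.mapping[li]], oidx[agg.mapping[lj]]] += cm.counts[i, j]
    return ConfusionMatrix(labels=out_labels, counts=counts)


@dataclass(frozen=True)
class MetricsTable:
    """Per-label TP/FP/FN with recall, precision and F1, plus the average F1.

    ``average_f1`` is the unweighted mean of per-label F1 scores; the
    word-level reports print it x100.
    """

    table: pd.DataFrame

    @property
    def average_f1(self) -> float:
        return float(self.table["F1"].mean())

    def __getitem__(self, label: str) -> pd.Series:
        return self.table.loc[label]


def _rpf(tp: np.ndarray, fp: np.ndarray, fn: np.ndarray):
    tp, fp, fn = (np.asarray(x, dtype=float) for x in (tp, fp, fn))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        p = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        f1 = np.where(r + p > 0, 2 * r * p / (r + p), 0.0)
    return r, p, f1


def metrics_from_counts(
    tp: Sequence[float], fp: Sequence[float], fn: Sequence[float],
    labels: Sequence[str],
) -> MetricsTable:
    """Metrics from explicit TP/FP/FN counts (e.g. expected-vs-observed tallies)."""
    r, p, f1 = _rpf(tp, fp, fn)
    table = pd.DataFrame(
        {"TP": tp, "FP": fp, "FN": fn, "R": r, "P": p, "F1": f1},
        index=list(labels),
    )
    return MetricsTable(table)


def compute_metrics(cm: ConfusionMatrix) -> MetricsTable:
    """Per-label recall/precision/F1 from a confusion matrix.

    TP is the diagonal, FP the column sum minus TP, FN the row sum minus TP;
    R = TP/(TP+FN), P = TP/(TP+FP), F1 = 2RP/(R+P) with zero-division guards
    (a label with no TP scores 0).
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(cm.counts)
    fp = cm.counts.sum(axis=0) - tp
    fn = cm.counts.sum(axis=1) - tp
    return metrics_from_counts(tp, fp, fn, cm.labels)
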