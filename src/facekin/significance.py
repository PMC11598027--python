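"""Monte-Carlo F1 significance thresholds under a uniform-prediction null.

The null model asks: if a measurement carried no information at all, so each
observation's predicted label were drawn i.i.d. uniformly over the label set
(true-label counts fixed by the design -- N participants per word, or
words-per-class x participants per movement class), how large an F1 score
would arise by chance?  The significance threshold for each label is the
empirical (1 - alpha) quantile of that label's F1 across replicates; an
observed F1 strictly above the threshold is flagged significant.

Per-label thresholds differ when label membership is uneven (the five
movement classes contain 4/2/3/3/7 words), because a label that soaks up a
larger share of the true observations earns higher chance precision.

The simulation is vectorized (one multinomial draw per true label per
replicate) and chunked to bound memory; quantiles use the lower empirical
order statistic for cross-platform determinism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classification import MetricsTable

__all__ = [
    "NullModelSpec",
    "ThresholdTable",
    "mc_f1_threshold",
    "mc_f1_difference_threshold",
    "flag_significant",
    "simulate_null_f1",
]

_CHUNK = 50_000


@dataclass(frozen=True)
class NullModelSpec:
    """Design of the chance-classification null for one label set."""

    labels: tuple[str, ...]
    true_counts: tuple[int, ...]
    n_sim: int = 1_000_000
    alpha: float = 0.05
    seed: int | None = None

    def __post_init__(self):
        if len(self.labels) != len(self.true_counts):
            raise ValueError("one true count per label required")
        if any(c <= 0 for c in self.true_counts):
            raise ValueError("true counts must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def per_word(cls, words: Sequence[str], n_participants: int, **kw) -> "NullModelSpec":
        return cls(labels=tuple(words), true_counts=(n_participants,) * len(words), **kw)

    @classmethod
    def per_class(
        cls, class_sizes: Mapping[str, int], n_participants: int, **kw
    ) -> "NullModelSpec":
        """Class-level null: each class's true count = (words in class) x N."""
        labels = tuple(class_sizes)
        counts = tuple(int(class_sizes[l]) * n_participants for l in labels)
        return cls(labels=labels, true_counts=counts, **kw)


@dataclass(frozen=True)
class ThresholdTable:
    """Per-label F1 significance thresholds at a given alpha."""

    labels: tuple[str, ...]
    thresholds: np.ndarray
    alpha: float
    n_sim: int
    seed: int | None = None

    def __post_init__(self):
        t = np.asarray(self.thresholds, dtype=float)
        if np.any(t < 0) or np.any(t > 1):
            raise ValueError("F1 thresholds must lie in [0, 1]")
        object.__setattr__(self, "thresholds", t)

    def __getitem__(self, label: str) -> float:
        return float(self.thresholds[self.labels.index(label)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"label": list(self.labels), "alpha": self.alpha,
             "threshold": self.thresholds, "n_sim": self.n_sim, "seed": self.seed}
        )


def simulate_null_f1(
    true_counts: Sequence[int],
    n_sim: int,
    rng: np.random.Generator,
    chunk: int = _CHUNK,
) -> np.ndarray:
    """Simulate per-label F1 under i.i.d.-uniform predictions.

    Returns an (n_sim, K) array.  For each replicate and true label j, the
    predicted-label counts of that row are one multinomial draw of size
    true_counts[j] with uniform cell probabilities; F1 for label k is
    2*TP_k / (row_k + col_k) with the zero-denominator guard.
    """
    counts = np.asarray(true_counts, dtype=np.int64)
    K = len(counts)
    p = np.full(K, 1.0 / K)
    out = np.empty((n_sim, K))
    done = 0
    while done < n_sim:
        m = min(chunk, n_sim - done)
        M = np.stack([rng.multinomial(int(c), p, size=m) for c in counts], axis=1)
        tp = np.einsum("nkk->nk", M)
        col = M.sum(axis=1)
        denom = counts[None, :] + col
        f1 = np.where(denom > 0, 2 * tp / denom, 0.0)
        out[done:done + m] = f1
        done += m
    return out


def _quantile(samples: np.ndarray, q: float) -> np.ndarray:
    # lower empirical order statistic: deterministic across platforms
    return np.quantile(samples, q, axis=0, method="lower")


def mc_f1_threshold(spec: NullModelSpec, rng: np.random.Generator | None = None) -> ThresholdTable:
    """Estimate per-label F1 significance thresholds for a null design."""
    if spec.n_sim < 1000:
        warnings.warn("n_sim < 1000 gives an unstable tail quantile")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    f1 = simulate_null_f1(spec.true_counts, spec.n_sim, rng)
    thr = _quantile(f1, 1.0 - spec.alpha)
    return ThresholdTable(
        labels=spec.labels, thresholds=thr, alpha=spec.alpha,
        n_sim=spec.n_sim, seed=spec.seed,
    )


def mc_f1_difference_threshold(
    spec_a: NullModelSpec,
    spec_b: NullModelSpec,
    rng: np.random.Generator | None = None,
) -> ThresholdTable:
    """Threshold on |F1_A - F1_B| between two independent cohorts' nulls.

    Labels must match; the returned per-label thresholds are the (1 - alpha)
    quantiles of the absolute F1 difference under independent draws from each
    cohort's null.  Alpha and n_sim are taken from ``spec_a``.
    """
    if spec_a.labels != spec_b.labels:
        raise ValueError("cohort null specs must share the same labels")
    if spec_a.n_sim < 1000:
        warnings.warn("n_sim < 1000 gives an unstable tail quantile")
    if rng is None:
        rng = np.random.default_rng(spec_a.seed)
    fa = simulate_null_f1(spec_a.true_counts, spec_a.n_sim, rng)
    fb = simulate_null_f1(spec_b.true_counts, spec_a.n_sim, rng)
    thr = _quantile(np.abs(fa - fb), 1.0 - spec_a.alpha)
    return ThresholdTable(
        labels=spec_a.labels, thresholds=thr, alpha=spec_a.alpha,
        n_sim=spec_a.n_sim, seed=spec_a.seed,
    )


def flag_significant(metrics: MetricsTable, thresholds: ThresholdTable) -> pd.Series:
    """Boolean per label: F1 strictly greater than its null threshold.

    Equality is *not* significant (strict inequality, by contract).
    """
    labels = list(metrics.table.index)
    if set(labels) != set(thresholds.labels):
        raise KeyError(
            f"label mismatch: metrics {labels} vs thresholds {list(thresholds.labels)}"
        )
    thr = pd.Series(thresholds.thresholds, index=list(thresholds.labels))
    return metrics.table["F1"] > thr.reindex(labels)
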