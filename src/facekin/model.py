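"""Model-style front end: fit a cohort, get a results object.

:class:`SpeechKinematicClassifier` is constructed from a trace store (or
straight from landmark/timings CSVs); ``fit()`` runs the leave-one-out word
classification for every measurement stream and derivative order and returns
a :class:`ClassificationResults` carrying the confusion matrices, the
word/class/group metrics, and significance testing against Monte-Carlo null
thresholds.  ``summary()`` prints the word-level average-F1 table in the
standard x100 scale with significance marks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classification import (
    WORDS,
    AggregationMap,
    ConfusionMatrix,
    MetricsTable,
    aggregate_confusion,
    compute_metrics,
    default_aggregation_maps,
    loocv_classify,
)
from .pipeline import DERIVATIVE_ORDERS, TraceStore, extract_traces
from .significance import NullModelSpec, ThresholdTable, mc_f1_threshold

__all__ = ["SpeechKinematicClassifier", "ClassificationResults", "SignificanceReport"]

_ORDER_NAMES = {0: "Dis.", 1: "Vel.", 2: "Acc."}


class SpeechKinematicClassifier:
    """Per-measurement word classifier over a cohort of kinematic traces."""

    def __init__(
        self,
        store: TraceStore,
        word_order: tuple[str, ...] = WORDS,
        aggregation_maps: dict[str, AggregationMap] | None = None,
    ):
        self.store = store
        self.word_order = tuple(w for w in word_order if w in store.words)
        self.aggregation_maps = aggregation_maps or default_aggregation_maps()

    @classmethod
    def from_csv(cls, landmark_file, timings_file, refine: bool = True, **extract_kw):
        """Build the model straight from the landmark/timings CSV dialect."""
        from .landmarks import load_recordings

        recs = load_recordings(landmark_file, timings_file)
        store = extract_traces(recs, refine=refine, **extract_kw)
        return cls(store)

    def fit(self) -> "ClassificationResults":
        """LOOCV-classify every (stream, derivative order) and collect metrics."""
        confusions: dict[tuple[str, int], ConfusionMatrix] = {}
        for stream in self.store.streams:
            for order in self.store.orders:
                traces = self.store.traces_for(stream, order)
                confusions[(stream, order)] = loocv_classify(traces, self.word_order)
        return ClassificationResults(model=self, confusions=confusions)


@dataclass
class SignificanceReport:
    """Thresholds, flags, and the per-level F1 tables they were tested on."""

    alpha: float
    word_threshold: float             # per-word null threshold (F1 fraction)
    word_thresholds: ThresholdTable
    class_thresholds: ThresholdTable
    group_thresholds: ThresholdTable
    word_significant: pd.DataFrame    # streams x orders bool (avg F1 > threshold)
    class_significant: dict[str, pd.DataFrame] = field(default_factory=dict)


@dataclass
class ClassificationResults:
    """Fitted LOOCV classification results for one cohort."""

    model: SpeechKinematicClassifier
    confusions: dict[tuple[str, int], ConfusionMatrix]

    def confusion(self, stream: str, order: int, level: str = "word") -> ConfusionMatrix:
        cm = self.confusions[(stream, order)]
        if level == "word":
            return cm
        return aggregate_confusion(cm, self.model.aggregation_maps[level])

    def metrics(self, stream: str, order: int, level: str = "word") -> MetricsTable:
        return compute_metrics(self.confusion(stream, order, level))

    def f1_table(self, level: str = "word") -> pd.DataFrame:
        """Average F1 (x100) per stream (rows) and derivative order (columns)."""
        orders = self.model.store.orders
        data = {
            _ORDER_NAMES.get(o, str(o)): [
                100.0 * self.metrics(s, o, level).average_f1
                for s in self.model.store.streams
            ]
            for o in orders
        }
        return pd.DataFrame(data, index=list(self.model.store.streams))

    def class_f1_table(self, order: int | None = None) -> pd.DataFrame:
        """Per-class F1 (fractions) per stream; averaged over orders if None."""
        classes = self.model.aggregation_maps["class"].label_order
        rows = {}
        orders = self.model.store.orders if order is None else (order,)
        for s in self.model.store.streams:
            per = np.mean(
                [self.metrics(s, o, "class").table["F1"].to_numpy() for o in orders],
                axis=0,
            )
            rows[s] = per
        return pd.DataFrame(rows, index=list(classes)).T

    def significance(
        self, alpha: float = 0.05, n_sim: int = 100_000, seed: int | None = None
    ) -> SignificanceReport:
        """Monte-Carlo null thresholds and significance flags for this cohort.

        Word-level significance compares each measurement's average-over-words
        F1 against the per-word null threshold (the convention of the
        word-level report tables); class-level flags compare per-class F1
        against per-class thresholds.
        """
        store = self.model.store
        n = len(store.participants)
        rng = np.random.default_rng(seed)
        word_tt = mc_f1_threshold(
            NullModelSpec.per_word(self.model.word_order, n, n_sim=n_sim,
                                   alpha=alpha, seed=seed), rng,
        )
        class_map = self.model.aggregation_maps["class"]
        class_sizes = {
            c: sum(1 for w in self.model.word_order
                   if class_map.mapping.get(w) == c)
            for c in class_map.label_order
        }
        class_tt = mc_f1_threshold(
            NullModelSpec.per_class(class_sizes, n, n_sim=n_sim, alpha=alpha, seed=seed),
            rng,
        )
        group_map = self.model.aggregation_maps["group"]
        group_sizes = {
            g: sum(1 for w in self.model.word_order if group_map.mapping.get(w) == g)
            for g in group_map.label_order
        }
        group_tt = mc_f1_threshold(
            NullModelSpec.per_class(group_sizes, n, n_sim=n_sim, alpha=alpha, seed=seed),
            rng,
        )
        word_thr = float(np.mean(word_tt.thresholds))
        f1 = self.f1_table("word") / 100.0
        word_sig = f1 > word_thr
        class_sig = {}
        for o in store.orders:
            tbl = pd.DataFrame(
                {s: self.metrics(s, o, "class").table["F1"].to_numpy()
                 for s in store.streams},
                index=list(class_map.label_order),
            ).T
            class_sig[_ORDER_NAMES.get(o, str(o))] = tbl > class_tt.thresholds[None, :]
        return SignificanceReport(
            alpha=alpha, word_threshold=word_thr, word_thresholds=word_tt,
            class_thresholds=class_tt, group_thresholds=group_tt,
            word_significant=word_sig, class_significant=class_sig,
        )

    def summary(
        self, significance: SignificanceReport | None = None, n_sim: int = 20_000,
        seed: int | None = 0,
    ) -> str:
        """Word-level average-F1 table (x100), significant entries starred."""
        sig = significance or self.significance(n_sim=n_sim, seed=seed)
        f1 = self.f1_table("word")
        lines = [
            "Word classification, average F1 x100 "
            f"(n={len(self.model.store.participants)} participants, "
            f"threshold {100 * sig.word_threshold:.1f} at alpha={sig.alpha})",
            "",
            f"{'Measurement':<30}" + "".join(f"{c:>10}" for c in f1.columns),
        ]
        for name, row in f1.iterrows():
            cells = "".join(
                f"{v:>9.1f}{'*' if sig.word_significant.loc[name, c] else ' '}"
                for c, v in row.items()
            )
            lines.append(f"{name:<30}{cells}")
        lines.append("")
        lines.append("* significant at the Monte-Carlo null threshold")
        return "\n".join(lines)

    def plot_profile(self, word: str, stream: str, order: int = 0, ax=None):
        """Spatiotemporal profile plot: cohort mean with 95% CI and SD bands."""
        import matplotlib.pyplot as plt

        store = self.model.store
        i = store.words.index(word)
        s = store.streams.index(stream)
        o = store.orders.index(order)
        traces = store.values[:, i, s, o]
        traces = traces[np.all(np.isfinite(traces), axis=1)]
        mean = traces.mean(axis=0)
        sd = traces.std(axis=0, ddof=0)
        ci = 1.96 * sd / np.sqrt(len(traces))
        x = np.linspace(0, 1, traces.shape[1])
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(x, mean, color="black", label="cohort mean")
        ax.fill_between(x, mean - ci, mean + ci, alpha=0.3, label="95% CI")
        for k, style in ((1, ":"), (2, "-")):
            ax.plot(x, mean + k * sd, style, color="tab:blue", lw=0.8)
            ax.plot(x, mean - k * sd, style, color="tab:blue", lw=0.8)
        ax.set_xlabel("normalized time")
        ax.set_ylabel(f"{stream} ({_ORDER_NAMES.get(order, order)})")
        ax.set_title(f"{word!r} spatiotemporal profile (n={len(traces)})")
        ax.legend(loc="best", fontsize="small")
        return ax
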