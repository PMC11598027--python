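"""End-to-end trace extraction: recordings -> canonical frames -> 1000-point traces.

For each recording the frames inside the padded word window are
canonicalized (per-frame head pose), the 30 measurement streams are
evaluated per frame, derivatives are taken on the raw time base, word
boundaries are optionally refined against the cohort's Mouth Opening mean,
and every (stream, derivative) series is linearly time-normalized to 1000
points.  Results live in a dense :class:`TraceStore`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import kinematics as kin
from .classification import WORDS
from .landmarks import LandmarkMap, Recording, default_landmark_map, to_canonical
from .measurements import MEASUREMENTS, STREAMS, measure_sequence

logger = logging.getLogger(__name__)

__all__ = ["TraceStore", "extract_traces", "DERIVATIVE_ORDERS"]

DERIVATIVE_ORDERS: tuple[int, ...] = (0, 1, 2)  # displacement, velocity, acceleration


@dataclass
class TraceStore:
    """Dense array of normalized-time traces with labeled axes.

    ``values`` has shape (participants, words, streams, orders, n_points);
    missing (participant, word) combinations are NaN.
    """

    values: np.ndarray
    participants: tuple[str, ...]
    words: tuple[str, ...]
    streams: tuple[str, ...]
    orders: tuple[int, ...]

    def __post_init__(self):
        exp = (len(self.participants), len(self.words), len(self.streams),
               len(self.orders), self.values.shape[-1])
        if self.values.shape != exp:
            raise ValueError(f"values shape {self.values.shape} != labeled shape {exp}")

    @property
    def n_points(self) -> int:
        return self.values.shape[-1]

    def get(self, participant: str, word: str, stream: str, order: int) -> np.ndarray:
        return self.values[
            self.participants.index(participant), self.words.index(word),
            self.streams.index(stream), self.orders.index(order),
        ]

    def traces_for(self, stream: str, order: int) -> dict[str, dict[str, np.ndarray]]:
        """Nested participant -> word -> trace mapping for one (stream, order)."""
        s, o = self.streams.index(stream), self.orders.index(order)
        out: dict[str, dict[str, np.ndarray]] = {}
        for i, p in enumerate(self.participants):
            d = {}
            for j, w in enumerate(self.words):
                tr = self.values[i, j, s, o]
                if np.all(np.isfinite(tr)):
                    d[w] = tr
            out[p] = d
        return out

    def save(self, path) -> None:
        """Write the store as an .npz plus a JSON label sidecar."""
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), values=self.values.astype(np.float32))
        meta = {
            "participants": list(self.participants), "words": list(self.words),
            "streams": list(self.streams), "orders": list(self.orders),
        }
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path) -> "TraceStore":
        path = Path(path)
        values = np.load(path.with_suffix(".npz"))["values"].astype(np.float64)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            values=values,
            participants=tuple(meta["participants"]),
            words=tuple(meta["words"]),
            streams=tuple(meta["streams"]),
            orders=tuple(int(o) for o in meta["orders"]),
        )


def extract_traces(
    recordings: Sequence[Recording],
    landmark_map: LandmarkMap | None = None,
    orders: Sequence[int] = DERIVATIVE_ORDERS,
    n_points: int = kin.N_POINTS,
    pad_s: float = 0.5,
    refine: bool = True,
    cubic: bool = False,
    face_size_weights: Sequence[float] | None = None,
) -> TraceStore:
    """Run the measurement/kinematics pipeline over a set of recordings.

    Word-boundary refinement (on by default) aligns each word's cohort by the
    Mouth Opening displacement trace before resampling; it needs at least two
    participants per word and is skipped (with a log message) otherwise.
    """
    lm = landmark_map or default_landmark_map()
    if len(recordings) == 0:
        raise ValueError("no recordings to extract")

    participants = tuple(sorted({r.participant_id for r in recordings}))
    words = tuple(w for w in WORDS if any(r.word == w for r in recordings))
    extra = sorted({r.word for r in recordings} - set(words))
    words = words + tuple(extra)

    # Per-recording measurement series on the padded raw time base.
    series: dict[tuple[str, str], tuple[np.ndarray, dict[str, np.ndarray]]] = {}
    windows: dict[tuple[str, str], kin.TimingWindow] = {}
    fps = recordings[0].fps
    for rec in recordings:
        w = kin.TimingWindow(rec.onset_s, rec.offset_s, pad_s)
        t0, t1 = w.onset_s - w.pad_s, w.offset_s + w.pad_s
        frames = [f for f in rec.frames if t0 - 1e-9 <= f.time_s <= t1 + 1e-9]
        if not frames:
            raise ValueError(
                f"empty padded window for ({rec.participant_id}, {rec.word})"
            )
        canon = [
            to_canonical(f, landmark_map=lm, face_size_weights=face_size_weights)
            for f in frames
        ]
        series[(rec.participant_id, rec.word)] = measure_sequence(canon, MEASUREMENTS)
        windows[(rec.participant_id, rec.word)] = w

    # Cohort-wise timing refinement against Mouth Opening.
    if refine:
        for word in words:
            pids = [p for p in participants if (p, word) in series]
            if len(pids) < 2:
                logger.info("skipping timing refinement for %r (<2 participants)", word)
                continue
            mo = {p: (series[(p, word)][0], series[(p, word)][1]["Mouth Opening"]) for p in pids}
            refined = kin.refine_timings(
                mo, {p: windows[(p, word)] for p in pids}, fps=fps, n_points=n_points
            )
            for p in pids:
                windows[(p, word)] = refined[p]

    values = np.full(
        (len(participants), len(words), len(STREAMS), len(orders), n_points), np.nan
    )
    for (pid, word), (times, streams_dict) in series.items():
        i, j = participants.index(pid), words.index(word)
        w = windows[(pid, word)]
        for s, stream in enumerate(STREAMS):
            raw = streams_dict[stream]
            for o, order in enumerate(orders):
                v = kin.differentiate(times, raw, order) if order else raw
                values[i, j, s, o] = kin.resample_trace(times, v, w, n_points, cubic=cubic)
    return TraceStore(
        values=values, participants=participants, words=words,
        streams=tuple(STREAMS), orders=tuple(orders),
    )
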