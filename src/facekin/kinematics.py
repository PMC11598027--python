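"""Windowing, differentiation, time normalization and cohort profiles.

Order of operations is fixed and deliberate: derivatives are taken on the raw
(per-second) time base first, then the word window is linearly time-normalized
and resampled to 1000 points.  Velocity and acceleration therefore keep
physical per-second units and remain comparable across participants whose
word durations differ.

Word boundary refinement aligns each participant's Mouth Opening trace to the
cohort mean by a bounded grid search over onset/offset shifts (frame
resolution, within the +-0.5 s annotation padding), iterating template
rebuild + realignment until the total residual sum of squares stops
improving.  Shifts only -- duration differences are absorbed by the linear
time normalization itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "TimingWindow",
    "KinematicTrace",
    "CohortProfile",
    "differentiate",
    "resample_trace",
    "refine_timings",
    "build_profile",
    "N_POINTS",
]

N_POINTS = 1000  #: samples per normalized-time trace


@dataclass(frozen=True)
class TimingWindow:
    onset_s: float
    offset_s: float
    pad_s: float = 0.5

    def __post_init__(self):
        if not self.offset_s > self.onset_s:
            raise ValueError("offset must follow onset")
        if self.pad_s < 0:
            raise ValueError("padding must be nonnegative")


@dataclass(frozen=True)
class KinematicTrace:
    """One (participant, word, measurement, derivative) trace on normalized time."""

    participant_id: str
    word: str
    measurement: str
    derivative_order: int
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_POINTS,):
            raise ValueError(f"trace must have exactly {N_POINTS} values")
        if not np.all(np.isfinite(v)):
            raise ValueError("trace values must be finite")


@dataclass(frozen=True)
class CohortProfile:
    """Pointwise mean/SD spatiotemporal profile over a cohort."""

    word: str
    measurement: str
    derivative_order: int
    mean: np.ndarray
    sd: np.ndarray
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("a cohort profile needs at least 2 contributing traces")
        if np.any(np.asarray(self.sd) < 0):
            raise ValueError("sd must be nonnegative")


def differentiate(times: np.ndarray, values: np.ndarray, order: int) -> np.ndarray:
    """Finite-difference derivative of the given order on the raw time base.

    Central differences in the interior, one-sided at the endpoints
    (``np.gradient`` semantics), applied ``order`` times.  Units: input per
    second (velocity), per second squared (acceleration).
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if order < 0:
        raise ValueError("order must be >= 0")
    if len(v) < order + 1 or (order > 0 and len(v) < 2):
        raise ValueError(f"need at least {max(order + 1, 2)} samples for order {order}")
    for _ in range(order):
        v = np.gradient(v, t)
    return v


def resample_trace(
    times: np.ndarray,
    values: np.ndarray,
    window: TimingWindow,
    n_points: int = N_POINTS,
    cubic: bool = False,
) -> np.ndarray:
    """Linearly time-normalize a series over [onset, offset] at n_points samples.

    The sample grid spans the window inclusively (first point at onset, last
    at offset), so endpoint values of the resampled trace equal the series
    values at the boundaries.  Piecewise-linear interpolation by default; a
    cubic-spline option is available behind the ``cubic`` flag.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    eps = 1e-9 * max(1.0, abs(t[-1]))
    if window.onset_s < t[0] - eps or window.offset_s > t[-1] + eps:
        raise ValueError(
            f"window [{window.onset_s}, {window.offset_s}] outside series span [{t[0]}, {t[-1]}]"
        )
    grid = np.linspace(window.onset_s, window.offset_s, n_points)
    if cubic:
        from scipy.interpolate import CubicSpline

        return CubicSpline(t, v)(grid)
    return np.interp(grid, t, v)


def build_profile(
    traces: np.ndarray,
    word: str = "",
    measurement: str = "",
    derivative_order: int = 0,
) -> CohortProfile:
    """Pointwise mean and population SD of a stack of traces (rows = traces)."""
    arr = np.asarray(traces, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need a 2-D stack of at least 2 traces")
    return CohortProfile(
        word=word,
        measurement=measurement,
        derivative_order=derivative_order,
        mean=arr.mean(axis=0),
        sd=arr.std(axis=0, ddof=0),
        n=arr.shape[0],
    )


def _candidate_shifts(max_frames: int, stride: int) -> np.ndarray:
    s = np.arange(-max_frames, max_frames + 1, stride)
    if 0 not in s:
        s = np.sort(np.append(s, 0))
    return s


def _best_shift(
    t: np.ndarray,
    v: np.ndarray,
    window: TimingWindow,
    template: np.ndarray,
    d_on: np.ndarray,
    d_off: np.ndarray,
    n_points: int,
) -> tuple[float, float, float]:
    """Grid-search onset/offset shifts minimizing RSS to the template.

    Candidates are ordered by shift magnitude so exact ties prefer the
    smallest adjustment (zero first).
    """
    combos = [(a, b) for a in d_on for b in d_off]
    combos.sort(key=lambda ab: (max(abs(ab[0]), abs(ab[1])), abs(ab[0]) + abs(ab[1]), ab))
    onsets = np.array([window.onset_s + a for a, _ in combos])
    offsets = np.array([window.offset_s + b for _, b in combos])
    ok = offsets > onsets + 1e-9
    onsets, offsets = onsets[ok], offsets[ok]
    kept = [c for c, k in zip(combos, ok) if k]
    u = np.linspace(0.0, 1.0, n_points)
    grids = onsets[:, None] + (offsets - onsets)[:, None] * u[None, :]
    samples = np.interp(grids.ravel(), t, v).reshape(len(kept), n_points)
    rss = ((samples - template[None, :]) ** 2).sum(axis=1)
    i = int(np.argmin(rss))
    return kept[i][0], kept[i][1], float(rss[i])


def refine_timings(
    series: dict[str, tuple[np.ndarray, np.ndarray]],
    windows: dict[str, TimingWindow],
    fps: float = 60.0,
    n_points: int = N_POINTS,
    max_iter: int = 20,
    tol: float = 1e-6,
) -> dict[str, TimingWindow]:
    """Refine per-participant onset/offset against the cohort Mouth Opening mean.

    ``series`` maps participant id -> (times, mouth-opening values) for one
    word; ``windows`` holds the annotated boundaries.  Iterates: (1) build the
    mean profile from current windows, (2) per participant (sorted order)
    grid-search frame-resolution onset/offset shifts within the +-pad bound
    minimizing the RSS of the resampled trace against the mean, (3) repeat
    until the total RSS improves by less than ``tol`` or ``max_iter`` rounds.
    A coarse 5-frame pass narrows the fine 1-frame search for speed.  Emits a
    warning and returns the best-so-far windows on non-convergence.
    """
    pids = sorted(series)
    if len(pids) < 2:
        raise ValueError("timing refinement needs at least 2 participants per word")
    orig = {p: windows[p] for p in pids}
    cur = dict(orig)
    frame_dt = 1.0 / fps
    prev_rss = np.inf
    for _ in range(max_iter):
        stack = np.stack([
            resample_trace(*series[p], cur[p], n_points=n_points) for p in pids
        ])
        template = stack.mean(axis=0)
        total_rss = 0.0
        new = {}
        for p in pids:
            t, v = series[p]
            w = orig[p]  # shifts always bounded relative to the annotation
            max_frames = int(round(w.pad_s * fps))
            lim = max_frames * frame_dt + 1e-12
            # coarse pass (stride 5 frames), then fine 1-frame pass around it
            coarse = _candidate_shifts(max_frames, 5) * frame_dt
            a0, b0, _ = _best_shift(t, v, w, template, coarse, coarse, n_points)
            fine_on = a0 + np.arange(-4, 5) * frame_dt
            fine_off = b0 + np.arange(-4, 5) * frame_dt
            fine_on = fine_on[np.abs(fine_on) <= lim]
            fine_off = fine_off[np.abs(fine_off) <= lim]
            a, b, rss = _best_shift(t, v, w, template, fine_on, fine_off, n_points)
            new[p] = replace(w, onset_s=w.onset_s + a, offset_s=w.offset_s + b)
            total_rss += rss
        cur = new
        if prev_rss - total_rss < tol:
            return cur
        prev_rss = total_rss
    warnings.warn("timing refinement did not converge; returning best-so-far windows")
    return cur
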