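"""Synthetic landmark-trajectory cohorts with known ground truth.

The generator emulates what the real acquisition produces -- long-form CSVs
of per-frame 3D face-mesh points at 60 fps plus a word-boundary timings
table -- for cohorts of participants saying the 20 probe words.  Every
pipeline stage is therefore testable end to end without video.

Each word is animated from a neutral 3D face by smooth raised-cosine gesture
curves whose character follows the word's movement class: large single-peak
jaw opening for the low-vowel class, a double-peaked jaw gesture for the
diphthongs, moderate opening for the mid-vowel class, lateral lip spreading
for the retraction class, and lip rounding with anterior protrusion for the
rounding class.  Per-word parameters differ within a class so the full
20-word set is separable by discriminative measurements.  Participants vary
in face scale, speaking rate, gesture amplitude and head-rotation
trajectory; upper-face landmarks stay rigid on the skull so the face-size
normalizer is speech-invariant by construction.  I.i.d. Gaussian landmark
noise emulates detector jitter.

CSV output uses detector image coordinates (y down, z toward camera),
matching what the loader expects; files round-trip losslessly through
``load_recordings``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .classification import WORDS

__all__ = [
    "WordKinematicTemplate",
    "ParticipantParams",
    "SyntheticCohort",
    "WORD_TEMPLATES",
    "NEUTRAL_FACE",
    "generate_cohort",
    "inject_asymmetry",
    "expected_mouth_opening",
]

# ---------------------------------------------------------------------------
# Neutral face geometry (world coordinates: X left, Y superior, Z anterior;
# origin at the mid-tragion point; units arbitrary, face ~0.15 wide).
NEUTRAL_FACE: dict[int, tuple[float, float, float]] = {
    93: (-0.075, 0.000, 0.000),   323: (0.075, 0.000, 0.000),    # tragion R/L
    227: (-0.065, 0.010, 0.040),  447: (0.065, 0.010, 0.040),    # zygion R/L
    # sellion/glabella straddle the vertical through the mid-tragion origin so
    # the canonical up-reference (their midpoint) is purely superior: the
    # head frame of an unrotated neutral face is exactly the identity basis
    168: (0.000, 0.045, 0.012),                                   # sellion
    9: (0.000, 0.065, -0.012),                                    # glabella
    133: (-0.016, 0.045, 0.080),  362: (0.016, 0.045, 0.080),    # inner canthus R/L
    68: (-0.052, 0.072, 0.058),   71: (-0.048, 0.068, 0.062),    # frontotemporale R
    301: (0.052, 0.072, 0.058),   298: (0.048, 0.068, 0.062),    # frontotemporale L
    2: (0.000, -0.005, 0.100),                                    # subnasale
    0: (0.000, -0.024, 0.098),                                    # labrale superius
    17: (0.000, -0.040, 0.095),                                   # labrale inferius
    13: (0.000, -0.029, 0.096),   14: (0.000, -0.032, 0.096),    # stomion sup/inf
    81: (-0.012, -0.0285, 0.094), 311: (0.012, -0.0285, 0.094),  # mid-fissure upper R/L
    178: (-0.012, -0.0325, 0.094), 402: (0.012, -0.0325, 0.094), # mid-fissure lower R/L
    61: (-0.028, -0.0305, 0.088), 291: (0.028, -0.0305, 0.088),  # cheilion R/L
    172: (-0.055, -0.055, 0.020), 397: (0.055, -0.055, 0.020),   # gonion R/L
    199: (0.000, -0.075, 0.080),                                  # pogonion
}

# Displacement direction (unit gesture) per mesh id, scaled by the jaw
# gesture amplitude.  Lower-face points ride the jaw; upper lip rises a touch.
_JAW_DIRS: dict[int, tuple[float, float, float]] = {
    199: (0.0, -1.00, -0.30),
    17: (0.0, -0.92, -0.25),
    14: (0.0, -0.88, -0.22),
    178: (0.0, -0.88, -0.22),
    402: (0.0, -0.88, -0.22),
    172: (0.0, -0.35, -0.28),
    397: (0.0, -0.35, -0.28),
    61: (0.0, -0.45, -0.05),
    291: (0.0, -0.45, -0.05),
    13: (0.0, 0.06, 0.0),
    0: (0.0, 0.06, 0.0),
    81: (0.0, 0.06, 0.0),
    311: (0.0, 0.06, 0.0),
}
_UPPER_JAW_RISE = 0.06   # upper mid-fissure vertical factor (matches _JAW_DIRS)
_LOWER_JAW_DROP = 0.88   # lower mid-fissure vertical factor

_LIP_MIDLINE_IDS = (0, 13, 14, 17, 81, 311, 178, 402)
_JAW_CARRIED_IDS = (199, 17, 14, 178, 402, 172, 397)  # lateral-slide targets


@dataclass(frozen=True)
class WordKinematicTemplate:
    """Gesture parameters animating one word from the neutral face."""

    word: str
    class_id: str          # movement-similarity class ("1".."5"), "" for Papa
    jaw_amp: float         # peak jaw-opening excursion (face units)
    jaw_peaks: tuple[tuple[float, float], ...]  # (center, relative height)
    jaw_width: float       # support width of each jaw bump (normalized time)
    spread_amp: float      # cheilion lateral excursion (retraction)
    round_amp: float       # cheilion medial excursion (rounding)
    protrude_amp: float    # lip anterior excursion accompanying rounding
    duration_s: float      # nominal word duration at unit speaking rate


def _bump(tau: np.ndarray, center: float, width: float) -> np.ndarray:
    """Raised-cosine bump supported on [center - width/2, center + width/2]."""
    u = (tau - center) / width + 0.5
    out = np.zeros_like(tau)
    inside = (u >= 0) & (u <= 1)
    out[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * u[inside]))
    return out


def _gesture(tau: np.ndarray, peaks, width: float) -> np.ndarray:
    g = np.zeros_like(tau)
    for center, height in peaks:
        g = g + height * _bump(tau, center, width)
    return g


def _t(word, cls, jaw, peaks, width, spread=0.0, rnd=0.0, prot=0.0, dur=0.6):
    return WordKinematicTemplate(word, cls, jaw, tuple(peaks), width, spread, rnd, prot, dur)


#: Default gesture templates for the 20-word list, keyed by word.
WORD_TEMPLATES: dict[str, WordKinematicTemplate] = {t.word: t for t in (
    # class 1 -- low vowel height: large single-peak jaw opening
    _t("Ba",   "1", 0.030, [(0.40, 1.0)], 0.80, dur=0.55),
    _t("Map",  "1", 0.026, [(0.50, 1.0)], 0.90, dur=0.60),
    _t("Ham",  "1", 0.028, [(0.55, 1.0)], 0.85, dur=0.65),
    _t("Pam",  "1", 0.024, [(0.45, 1.0)], 0.75, dur=0.62),
    # class 2 -- diphthongs: double-peaked jaw gesture
    _t("Eye",  "2", 0.026, [(0.30, 1.0), (0.70, 0.50)], 0.45, dur=0.60),
    _t("Pie",  "2", 0.022, [(0.35, 1.0), (0.75, 0.60)], 0.40, dur=0.65),
    # class 3 -- mid vowel height: moderate jaw opening
    _t("Umm",  "3", 0.013, [(0.35, 1.0)], 0.80, dur=0.70),
    _t("Bob",  "3", 0.016, [(0.50, 1.0)], 0.75, dur=0.55),
    _t("Pup",  "3", 0.011, [(0.45, 1.0)], 0.70, dur=0.50),
    # Papa -- reduplicated bilabial, unlike any class: two equal jaw bumps
    _t("Papa", "",  0.018, [(0.25, 1.0), (0.65, 1.0)], 0.40, dur=0.70),
    # class 4 -- lip spreading (retraction), small jaw
    _t("Bee",  "4", 0.006, [(0.45, 1.0)], 0.85, spread=0.012, dur=0.55),
    _t("Peep", "4", 0.005, [(0.50, 1.0)], 0.80, spread=0.010, dur=0.60),
    _t("Feet", "4", 0.007, [(0.55, 1.0)], 0.90, spread=0.014, dur=0.62),
    # class 5 -- lip rounding with anterior protrusion
    _t("Boy",   "5", 0.012, [(0.40, 1.0)], 0.85, rnd=0.010, prot=0.008, dur=0.60),
    _t("Bush",  "5", 0.008, [(0.45, 1.0)], 0.80, rnd=0.012, prot=0.009, dur=0.58),
    _t("Moon",  "5", 0.007, [(0.50, 1.0)], 0.90, rnd=0.014, prot=0.012, dur=0.66),
    _t("Phone", "5", 0.010, [(0.55, 1.0)], 0.85, rnd=0.009, prot=0.010, dur=0.68),
    _t("Fish",  "5", 0.007, [(0.40, 1.0)], 0.75, rnd=0.008, prot=0.007, dur=0.52),
    _t("Wash",  "5", 0.011, [(0.50, 1.0)], 0.80, rnd=0.011, prot=0.011, dur=0.63),
    _t("Show",  "5", 0.009, [(0.60, 1.0)], 0.85, rnd=0.013, prot=0.013, dur=0.64),
)}


@dataclass(frozen=True)
class ParticipantParams:
    """Per-participant variation applied to every word's animation."""

    participant_id: str
    face_scale: float = 1.0
    speaking_rate: float = 1.0   # multiplies word duration
    amp_scale: float = 1.0       # multiplies gesture amplitudes
    noise_sd: float = 3e-4       # detector jitter SD (pre-scale units x scale)
    head_rot_amp: float = 0.04   # radians, slow yaw/pitch oscillation
    head_phases: tuple[float, float] = (0.0, 0.0)
    asym_amp: float = 0.0        # lateral jaw-slide excursion (face units)
    seed: int = 0

    def __post_init__(self):
        if self.face_scale <= 0:
            raise ValueError("face scale must be positive")
        if self.noise_sd < 0 or self.asym_amp < 0:
            raise ValueError("noise and asymmetry amplitudes must be nonnegative")


@dataclass
class SyntheticCohort:
    """Generated landmark rows + timings + full ground-truth manifest."""

    landmarks: pd.DataFrame
    timings: pd.DataFrame
    manifest: dict

    def write(self, out_dir) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "landmarks": out / "landmarks.csv",
            "timings": out / "timings.csv",
            "manifest": out / "manifest.json",
        }
        self.landmarks.to_csv(paths["landmarks"], index=False, float_format="%.8f")
        self.timings.to_csv(paths["timings"], index=False, float_format="%.6f")
        paths["manifest"].write_text(json.dumps(self.manifest, indent=1, sort_keys=True))
        return paths


def _rotation(yaw: np.ndarray, pitch: np.ndarray) -> np.ndarray:
    """Per-frame rotation matrices Ry(yaw) @ Rx(pitch), shape (F, 3, 3)."""
    cy, sy = np.cos(yaw), np.sin(yaw)
    cp, sp = np.cos(pitch), np.sin(pitch)
    F = len(yaw)
    Ry = np.zeros((F, 3, 3))
    Ry[:, 0, 0], Ry[:, 0, 2] = cy, sy
    Ry[:, 1, 1] = 1.0
    Ry[:, 2, 0], Ry[:, 2, 2] = -sy, cy
    Rx = np.zeros((F, 3, 3))
    Rx[:, 0, 0] = 1.0
    Rx[:, 1, 1], Rx[:, 1, 2] = cp, -sp
    Rx[:, 2, 1], Rx[:, 2, 2] = sp, cp
    return np.einsum("fij,fjk->fik", Ry, Rx)


def _animate_word(
    template: WordKinematicTemplate,
    params: ParticipantParams,
    fps: float,
    rng: np.random.Generator,
    onset_s: float = 0.7,
    tail_s: float = 0.7,
) -> tuple[np.ndarray, dict[int, np.ndarray], float, float]:
    """Animate one (participant, word) recording.

    Returns (times, {mesh id -> (F, 3) world positions}, onset, offset).
    """
    duration = template.duration_s * params.speaking_rate
    offset_s = onset_s + duration
    n_frames = int(np.ceil((offset_s + tail_s) * fps)) + 1
    times = np.arange(n_frames) / fps
    tau = np.clip((times - onset_s) / duration, 0.0, 1.0)

    amp = params.amp_scale
    g_jaw = _gesture(tau, template.jaw_peaks, template.jaw_width) * template.jaw_amp * amp
    g_lip = _bump(tau, template.jaw_peaks[0][0], max(template.jaw_width, 0.7))
    spread = g_lip * template.spread_amp * amp
    rnd = g_lip * template.round_amp * amp
    prot = g_lip * template.protrude_amp * amp
    asym = g_jaw / max(template.jaw_amp * amp, 1e-12) * params.asym_amp

    pos: dict[int, np.ndarray] = {}
    for mid, base in NEUTRAL_FACE.items():
        p = np.tile(np.asarray(base, dtype=float), (n_frames, 1))
        d = _JAW_DIRS.get(mid)
        if d is not None:
            p += g_jaw[:, None] * np.asarray(d)
        if mid == 291:    # left cheilion: spreading outward (+X), rounding inward
            p[:, 0] += spread - rnd
            p[:, 1] += 0.08 * spread
            p[:, 2] += -0.15 * spread + 0.5 * prot
        elif mid == 61:   # right cheilion, mirrored
            p[:, 0] += -spread + rnd
            p[:, 1] += 0.08 * spread
            p[:, 2] += -0.15 * spread + 0.5 * prot
        if mid in _LIP_MIDLINE_IDS:
            p[:, 2] += prot
        if mid in _JAW_CARRIED_IDS:
            p[:, 0] += asym
        pos[mid] = p

    # rigid participant transform: scale, slow head rotation, noise
    yaw = params.head_rot_amp * np.sin(2 * np.pi * 0.4 * times + params.head_phases[0])
    pitch = 0.6 * params.head_rot_amp * np.sin(2 * np.pi * 0.3 * times + params.head_phases[1])
    R = _rotation(yaw, pitch)
    for mid in pos:
        p = pos[mid] * params.face_scale
        p = np.einsum("fij,fj->fi", R, p)
        if params.noise_sd > 0:
            p = p + rng.normal(0.0, params.noise_sd * params.face_scale, size=p.shape)
        pos[mid] = p
    return times, pos, onset_s, offset_s


def generate_cohort(
    n_participants: int,
    seed: int = 0,
    templates: dict[str, WordKinematicTemplate] | None = None,
    noise_sd: float = 3e-4,
    head_rot_amp: float = 0.04,
    asymmetry: dict[str, float] | None = None,
    fps: float = 60.0,
) -> SyntheticCohort:
    """Generate a full synthetic cohort (n participants x 20 words).

    Participant face scale, speaking rate and gesture amplitude are drawn
    around realistic values (lognormal scale SD ~8%, rate SD ~7%, amplitude
    SD ~6%); the same seed always yields byte-identical output.
    ``asymmetry`` optionally maps words to lateral jaw-slide amplitudes
    applied to every participant (default none).

    Raises if ``n_participants`` < 3 (LOOCV needs at least 3).
    """
    if n_participants < 3:
        raise ValueError("need at least 3 participants for a LOOCV-able cohort")
    tmpl = templates or WORD_TEMPLATES
    missing = [w for w in WORDS if w not in tmpl]
    if missing:
        raise KeyError(f"templates missing for words {missing}")
    asymmetry = asymmetry or {}
    unknown = [w for w in asymmetry if w not in WORDS]
    if unknown:
        raise KeyError(f"unknown word(s) in asymmetry spec: {unknown}")

    master = np.random.default_rng(seed)
    rows_pid, rows_word, rows_frame, rows_time, rows_id = [], [], [], [], []
    rows_xyz = []
    timing_rows = []
    manifest: dict = {
        "seed": int(seed), "n_participants": int(n_participants), "fps": fps,
        "noise_sd": noise_sd, "templates": {w: asdict(t) for w, t in tmpl.items()},
        "participants": {}, "recordings": {},
    }
    for k in range(n_participants):
        pid = f"P{k + 1:03d}"
        prng = np.random.default_rng(master.integers(0, 2**31 - 1))
        params = ParticipantParams(
            participant_id=pid,
            face_scale=float(np.exp(prng.normal(0.0, 0.08))),
            speaking_rate=float(np.clip(prng.normal(1.0, 0.07), 0.8, 1.25)),
            amp_scale=float(np.clip(prng.normal(1.0, 0.06), 0.85, 1.15)),
            noise_sd=noise_sd,
            head_rot_amp=head_rot_amp,
            head_phases=tuple(prng.uniform(0, 2 * np.pi, size=2)),
            seed=int(seed),
        )
        manifest["participants"][pid] = {
            "face_scale": params.face_scale, "speaking_rate": params.speaking_rate,
            "amp_scale": params.amp_scale, "head_rot_amp": head_rot_amp,
            "head_phases": list(params.head_phases),
        }
        for word in WORDS:
            t = tmpl[word]
            if word in asymmetry:
                wparams = replace(params, asym_amp=float(asymmetry[word]))
            else:
                wparams = params
            times, pos, onset, offset = _animate_word(t, wparams, fps, prng)
            ids = sorted(pos)
            F = len(times)
            for mid in ids:
                rows_pid.append(np.full(F, pid, dtype=object))
                rows_word.append(np.full(F, word, dtype=object))
                rows_frame.append(np.arange(F))
                rows_time.append(times)
                rows_id.append(np.full(F, mid))
                # world -> detector image coordinates (flip y and z)
                rows_xyz.append(pos[mid] * np.array([1.0, -1.0, -1.0]))
            timing_rows.append((pid, word, onset, offset))
            manifest["recordings"][f"{pid}/{word}"] = {
                "onset_s": onset, "offset_s": offset,
                "duration_s": offset - onset,
                "asym_amp": float(asymmetry.get(word, 0.0)),
            }

    xyz = np.concatenate(rows_xyz, axis=0)
    landmarks = pd.DataFrame({
        "participant_id": np.concatenate(rows_pid),
        "word": np.concatenate(rows_word),
        "frame": np.concatenate(rows_frame),
        "time_s": np.concatenate(rows_time),
        "point_id": np.concatenate(rows_id).astype(int),
        "x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2],
    })
    landmarks = landmarks.sort_values(
        ["participant_id", "word", "frame", "point_id"], kind="stable"
    ).reset_index(drop=True)
    timings = pd.DataFrame(timing_rows, columns=["participant_id", "word", "onset_s", "offset_s"])
    return SyntheticCohort(landmarks=landmarks, timings=timings, manifest=manifest)


def inject_asymmetry(
    cohort: SyntheticCohort, words: list[str], amplitude: float, fps: float = 60.0
) -> SyntheticCohort:
    """Add a lateral (X) jaw-slide excursion to selected words of a cohort.

    The slide follows each recording's jaw gesture timing (a raised-cosine
    bump over the word window) and is applied to the jaw-carried mesh points
    (pogonion, lower lip, gonions).  Amplitude 0 returns an identical cohort.
    The manifest is updated with the injected amplitudes.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be nonnegative")
    unknown = [w for w in words if w not in WORDS]
    if unknown:
        raise KeyError(f"unknown word(s): {unknown}")
    df = cohort.landmarks.copy()
    manifest = json.loads(json.dumps(cohort.manifest))  # deep copy
    if amplitude > 0:
        tidx = cohort.timings.set_index(["participant_id", "word"])
        jaw_mask = df["point_id"].isin(_JAW_CARRIED_IDS)
        for word in words:
            for pid in cohort.timings["participant_id"].unique():
                row = tidx.loc[(pid, word)]
                sel = jaw_mask & (df["word"] == word) & (df["participant_id"] == pid)
                scale = manifest["participants"][pid]["face_scale"]
                tau = np.clip(
                    (df.loc[sel, "time_s"].to_numpy() - row["onset_s"])
                    / (row["offset_s"] - row["onset_s"]), 0.0, 1.0,
                )
                # X is unchanged by the detector/world flip, so add directly
                df.loc[sel, "x"] += amplitude * scale * _bump(tau, 0.5, 0.9)
                key = f"{pid}/{word}"
                manifest["recordings"][key]["asym_amp"] = (
                    manifest["recordings"][key].get("asym_amp", 0.0) + amplitude
                )
    return SyntheticCohort(landmarks=df, timings=cohort.timings.copy(), manifest=manifest)


def expected_mouth_opening(
    template: WordKinematicTemplate, tau: np.ndarray, amp_scale: float = 1.0
) -> np.ndarray:
    """Ground-truth Mouth Opening ratio implied by a template at times tau.

    Derived from the neutral geometry and gesture directions: the midline
    vertical lip separation over the cheilion lateral width.  Head rotation,
    scale and noise cancel in the ratio, so a noiseless unit-scale pipeline
    extraction must match this closed form.
    """
    g_jaw = _gesture(tau, template.jaw_peaks, template.jaw_width) * template.jaw_amp * amp_scale
    g_lip = _bump(tau, template.jaw_peaks[0][0], max(template.jaw_width, 0.7))
    spread = g_lip * template.spread_amp * amp_scale
    rnd = g_lip * template.round_amp * amp_scale
    y_upper = NEUTRAL_FACE[81][1] + _UPPER_JAW_RISE * g_jaw
    y_lower = NEUTRAL_FACE[178][1] - _LOWER_JAW_DROP * g_jaw
    sep = np.abs(y_upper - y_lower)
    width = (NEUTRAL_FACE[291][0] - NEUTRAL_FACE[61][0]) + 2.0 * (spread - rnd)
    return sep / width
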