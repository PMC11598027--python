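"""The clinically defined jaw/lip measurements computed per canonical frame.

Fourteen base measurements are defined; eight are 3-vectors decomposed into
the lateral (X), superior/inferior (Y) and anterior/posterior (Z) facial axes
and six are scalars, giving 30 per-frame streams in total (8*3 + 6), one per
row of the word-level report (the 29 jaw/lip measurements plus the Face Size
control stream).

Distance-valued measurements are normalized by the per-frame face size so
values are dimensionless ratios comparable across participants; the Mouth
Opening ratio and the Mandibular Angle (radians) are intrinsically
scale-free and left unnormalized.  Mouth Area Symmetry is an area and is
normalized by face_size**2 to stay scale-invariant.

Sign conventions: symmetry measurements are (left half) minus (mirrored
right half), so a perfectly mirror-symmetric face scores exactly zero on
every component and mirroring a face negates them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .landmarks import ClinicalFrame

__all__ = [
    "MeasurementSpec",
    "MeasurementSample",
    "MEASUREMENTS",
    "MEASUREMENT_NAMES",
    "STREAMS",
    "decompose_axes",
    "compute_measurement",
    "measure_sequence",
]

AXES = ("X", "Y", "Z")


def decompose_axes(vector: np.ndarray, pose_axes: np.ndarray) -> tuple[float, float, float]:
    """Project a 3-vector onto orthonormal facial axes (columns X, Y, Z).

    Components are plain dot products; x*X + y*Y + z*Z reconstructs the input.
    """
    a = np.asarray(pose_axes, dtype=float)
    if a.shape != (3, 3) or not np.allclose(a.T @ a, np.eye(3), atol=1e-9):
        raise ValueError("pose axes must be an orthonormal 3x3 matrix")
    v = np.asarray(vector, dtype=float)
    x, y, z = (float(np.dot(v, a[:, i])) for i in range(3))
    return x, y, z


@dataclass(frozen=True)
class MeasurementSpec:
    name: str
    kind: str  # "vector" | "scalar"
    normalized: bool
    landmark_roles: tuple[str, ...]
    func: Callable[[Mapping[str, np.ndarray]], np.ndarray | float]

    def stream_names(self) -> tuple[str, ...]:
        if self.kind == "vector":
            return tuple(f"{self.name} ({ax})" for ax in AXES)
        return (self.name,)


@dataclass(frozen=True)
class MeasurementSample:
    """One measurement evaluated at one frame: axis label -> value."""

    time_s: float
    values: Mapping[str, float]


def _mirror_x(p: np.ndarray) -> np.ndarray:
    return p * np.array([-1.0, 1.0, 1.0])


def _tri_area(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    return 0.5 * float(np.linalg.norm(np.cross(b - a, c - a)))


def _upper_mid(lm) -> np.ndarray:
    return 0.5 * (lm["mid_fissure_upper_left"] + lm["mid_fissure_upper_right"])


def _lower_mid(lm) -> np.ndarray:
    return 0.5 * (lm["mid_fissure_lower_left"] + lm["mid_fissure_lower_right"])


def _cheilion_mid(lm) -> np.ndarray:
    return 0.5 * (lm["cheilion_left"] + lm["cheilion_right"])


def _labial_fissure_width(lm) -> float:
    w = abs(float(lm["cheilion_left"][0] - lm["cheilion_right"][0]))
    return w


def _m_pogonion(lm):
    return lm["pogonion"]


def _m_lower_lip_from_pogonion(lm):
    return lm["labrale_inferius"] - lm["pogonion"]


def _m_lip_action(lm):
    return _lower_mid(lm) - _upper_mid(lm)


def _m_medial_symmetry(lm):
    left = 0.5 * (lm["mid_fissure_upper_left"] + lm["mid_fissure_lower_left"])
    right = 0.5 * (lm["mid_fissure_upper_right"] + lm["mid_fissure_lower_right"])
    return left - _mirror_x(right)


def _m_medial_action(lm):
    mid = 0.25 * (lm["mid_fissure_upper_left"] + lm["mid_fissure_upper_right"]
                  + lm["mid_fissure_lower_left"] + lm["mid_fissure_lower_right"])
    return mid - _cheilion_mid(lm)


def _m_medial_lower_action(lm):
    return _lower_mid(lm) - _cheilion_mid(lm)


def _m_medial_upper_action(lm):
    return _upper_mid(lm) - _cheilion_mid(lm)


def _m_mouth_opening(lm):
    width = _labial_fissure_width(lm)
    if width <= 1e-12:
        raise ValueError("degenerate mouth geometry: zero labial fissure width")
    sep = abs(float(_upper_mid(lm)[1] - _lower_mid(lm)[1]))
    return sep / width


def _m_mouth_area_symmetry(lm):
    left = _tri_area(lm["stomion_superius"], lm["stomion_inferius"], lm["cheilion_left"])
    right = _tri_area(lm["stomion_superius"], lm["stomion_inferius"], lm["cheilion_right"])
    return left - right


def _m_mouth_height(lm):
    mid = 0.5 * (lm["stomion_superius"] + lm["stomion_inferius"])
    return abs(float(mid[1]))


def _m_gonion(lm):
    return 0.5 * (lm["gonion_left"] + lm["gonion_right"]) - lm["subnasale"]


def _m_mandibular_angle(lm):
    d = 0.5 * (lm["gonion_left"] + lm["gonion_right"]) - lm["pogonion"]
    # signed angle about the lateral axis between the pogonion->mid-gonion
    # line and the anterior (+Z) facial direction, in radians
    return float(np.arctan2(d[1], d[2]))


_MID_FISSURE = ("mid_fissure_upper_left", "mid_fissure_upper_right",
                "mid_fissure_lower_left", "mid_fissure_lower_right")
_CHEILIA = ("cheilion_left", "cheilion_right")

MEASUREMENTS: tuple[MeasurementSpec, ...] = (
    MeasurementSpec("Labial Fissure Width", "scalar", True, _CHEILIA, _labial_fissure_width),
    MeasurementSpec("Mouth Height", "scalar", True,
                    ("stomion_superius", "stomion_inferius"), _m_mouth_height),
    MeasurementSpec("Medial 1/3 Symmetry", "vector", True, _MID_FISSURE, _m_medial_symmetry),
    MeasurementSpec("Mouth Area Symmetry", "scalar", True,
                    ("stomion_superius", "stomion_inferius") + _CHEILIA, _m_mouth_area_symmetry),
    MeasurementSpec("Mouth Opening", "scalar", False, _MID_FISSURE + _CHEILIA, _m_mouth_opening),
    MeasurementSpec("Lip Action", "vector", True, _MID_FISSURE, _m_lip_action),
    MeasurementSpec("Medial 1/3 Action", "vector", True, _MID_FISSURE + _CHEILIA, _m_medial_action),
    MeasurementSpec("Medial 1/3 Upper Action", "vector", True,
                    ("mid_fissure_upper_left", "mid_fissure_upper_right") + _CHEILIA,
                    _m_medial_upper_action),
    MeasurementSpec("Medial 1/3 Lower Action", "vector", True,
                    ("mid_fissure_lower_left", "mid_fissure_lower_right") + _CHEILIA,
                    _m_medial_lower_action),
    MeasurementSpec("Pogonion", "vector", True, ("pogonion",), _m_pogonion),
    MeasurementSpec("Gonion", "vector", True, ("gonion_left", "gonion_right", "subnasale"), _m_gonion),
    MeasurementSpec("Lower Lip from Pogonion", "vector", True,
                    ("labrale_inferius", "pogonion"), _m_lower_lip_from_pogonion),
    MeasurementSpec("Mandibular Angle", "scalar", False,
                    ("pogonion", "gonion_left", "gonion_right"), _m_mandibular_angle),
    MeasurementSpec("Face Size", "scalar", False, (), lambda lm: np.nan),  # handled specially
)

MEASUREMENT_NAMES: tuple[str, ...] = tuple(m.name for m in MEASUREMENTS)

#: Flat list of the 30 per-frame streams, in report row order.
STREAMS: tuple[str, ...] = tuple(
    s for spec in MEASUREMENTS for s in spec.stream_names()
)


def compute_measurement(spec: MeasurementSpec, frame: ClinicalFrame) -> MeasurementSample:
    """Evaluate one measurement on one canonical frame.

    Vector measurements return X/Y/Z components (canonical axes); normalized
    measurements are divided by the frame's face size (face_size**2 for the
    area-valued Mouth Area Symmetry).  Missing landmarks raise KeyError.
    """
    lm = frame.landmarks
    for role in spec.landmark_roles:
        if role not in lm:
            raise KeyError(f"landmark '{role}' required by '{spec.name}' missing")
    if spec.name == "Face Size":
        return MeasurementSample(frame.time_s, {"scalar": float(frame.face_size)})
    raw = spec.func(lm)
    if spec.kind == "vector":
        v = np.asarray(raw, dtype=float)
        if spec.normalized:
            v = v / frame.face_size
        return MeasurementSample(frame.time_s, dict(zip(AXES, map(float, v))))
    val = float(raw)
    if spec.normalized:
        div = frame.face_size ** 2 if spec.name == "Mouth Area Symmetry" else frame.face_size
        val = val / div
    return MeasurementSample(frame.time_s, {"scalar": val})


def measure_sequence(
    frames: Sequence[ClinicalFrame],
    specs: Sequence[MeasurementSpec] = MEASUREMENTS,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Evaluate measurements over a sequence of canonical frames.

    Returns ``(times, series)`` where ``series`` maps each stream name
    (e.g. ``"Lip Action (Y)"``) to a 1-D array over frames.
    """
    if len(frames) == 0:
        raise ValueError("empty frame window")
    times = np.array([f.time_s for f in frames])
    series: dict[str, list[float]] = {s: [] for spec in specs for s in spec.stream_names()}
    for f in frames:
        for spec in specs:
            sample = compute_measurement(spec, f)
            if spec.kind == "vector":
                for ax in AXES:
                    series[f"{spec.name} ({ax})"].append(sample.values[ax])
            else:
                series[spec.name].append(sample.values["scalar"])
    return times, {k: np.asarray(v) for k, v in series.items()}
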