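"""Landmark ingestion, clinical-landmark mapping, head-pose removal, face size.

Recordings arrive as long-form CSV of per-frame 3D face-mesh points (one row
per point per frame) in detector image coordinates (x toward the image right,
y down, z toward the camera).  At load time coordinates are converted to the
package's world convention: X toward the participant's anatomical left,
Y superior, Z anterior.  All downstream geometry (head pose, canonical
coordinates, face size) happens in that convention.

The head pose of each frame is estimated from upper-face landmarks only
(tragions, sellion, glabella), which are stable while the participant speaks.
Canonical ("clinical") coordinates place the origin at the mid-tragion point
with axes along the estimated head orientation, so lower-face displacements
are measured relative to the skull, independent of head motion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources as _importlib_resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MeshFrame",
    "LandmarkMap",
    "HeadPose",
    "ClinicalFrame",
    "Recording",
    "default_landmark_map",
    "load_recordings",
    "map_to_clinical",
    "estimate_head_pose",
    "to_canonical",
    "compute_face_size",
    "DEFAULT_FACE_SIZE_PAIRS",
]

# Detector image coordinates are y-down / z-toward-camera; flipping y and z
# yields X=left, Y=superior, Z=anterior.  The transform is an involution.
_DETECTOR_TO_WORLD = np.array([1.0, -1.0, -1.0])


def detector_to_world(xyz: np.ndarray) -> np.ndarray:
    """Convert detector image coordinates to world coordinates (and back)."""
    return np.asarray(xyz, dtype=float) * _DETECTOR_TO_WORLD


@dataclass(frozen=True)
class MeshFrame:
    """All tracked mesh points of one video frame, in world coordinates."""

    time_s: float
    points: Mapping[int, np.ndarray]

    def require(self, ids: Sequence[int], context: str = "") -> None:
        missing = [i for i in ids if i not in self.points]
        if missing:
            where = f" for {context}" if context else ""
            raise KeyError(f"mesh point id(s) {missing} missing{where} at t={self.time_s}")


@dataclass(frozen=True)
class LandmarkMap:
    """Clinical-landmark name -> mesh point ids (averaged when more than one)."""

    entries: Mapping[str, tuple[int, ...]]
    sides: Mapping[str, str] = field(default_factory=dict)
    version: int = 1

    @classmethod
    def from_json(cls, path_or_text) -> "LandmarkMap":
        text = str(path_or_text)
        if not text.lstrip().startswith("{"):
            text = Path(path_or_text).read_text()
        data = json.loads(text)
        entries = {name: tuple(spec["ids"]) for name, spec in data["landmarks"].items()}
        sides = {name: spec.get("side", "mid") for name, spec in data["landmarks"].items()}
        return cls(entries=entries, sides=sides, version=data.get("version", 1))

    @property
    def all_ids(self) -> tuple[int, ...]:
        out: list[int] = []
        for ids in self.entries.values():
            out.extend(ids)
        return tuple(sorted(set(out)))

    def __contains__(self, name: str) -> bool:
        return name in self.entries


def default_landmark_map() -> LandmarkMap:
    """The shipped face-mesh -> clinical landmark association table."""
    text = _importlib_resources.files("facekin.resources").joinpath("landmark_map.json").read_text()
    return LandmarkMap.from_json(text)


@dataclass(frozen=True)
class HeadPose:
    """Head orientation frame: origin at mid-tragion, orthonormal right-handed axes.

    ``axes`` columns are the X (lateral, toward the participant's left),
    Y (superior) and Z (anterior) unit vectors expressed in world coordinates.
    """

    origin: np.ndarray
    axes: np.ndarray  # 3x3, columns = X, Y, Z

    def __post_init__(self):
        a = np.asarray(self.axes, dtype=float)
        if a.shape != (3, 3):
            raise ValueError("axes must be a 3x3 matrix with columns X, Y, Z")
        if not np.allclose(a.T @ a, np.eye(3), atol=1e-9):
            raise ValueError("pose axes must be orthonormal")
        if np.linalg.det(a) < 0:
            raise ValueError("pose axes must be right-handed")


@dataclass(frozen=True)
class ClinicalFrame:
    """Named clinical landmarks in canonical facial coordinates plus face size.

    Canonical coordinates are pose-removed: origin at the mid-tragion point,
    X lateral (participant's left), Y superior, Z anterior.
    """

    time_s: float
    landmarks: Mapping[str, np.ndarray]
    face_size: float

    def __post_init__(self):
        if not self.face_size > 0:
            raise ValueError("face_size must be positive")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.landmarks[name]


@dataclass
class Recording:
    """One participant saying one word: time-ordered mesh frames + annotations."""

    participant_id: str
    word: str
    fps: float
    frames: list[MeshFrame]
    onset_s: float
    offset_s: float

    def __post_init__(self):
        times = np.array([f.time_s for f in self.frames])
        if len(times) >= 2 and not np.all(np.diff(times) > 0):
            raise ValueError(
                f"frame times not strictly increasing for ({self.participant_id}, {self.word})"
            )
        if not self.onset_s < self.offset_s:
            raise ValueError(
                f"onset must precede offset for ({self.participant_id}, {self.word})"
            )

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time_s for f in self.frames])


def load_recordings(
    landmark_file,
    timings_file,
    fps: float = 60.0,
    landmark_map: LandmarkMap | None = None,
) -> list[Recording]:
    """Read the long-form landmark CSV and the timings CSV into Recordings.

    The landmark CSV has columns ``participant_id,word,frame,time_s,point_id,x,y,z``
    (detector coordinates); the timings CSV ``participant_id,word,onset_s,offset_s``.
    One Recording is produced per (participant, word); frames are sorted by time
    and coordinates converted to world convention.

    Raises on duplicated (frame, point_id) rows, non-monotone frame times, and
    (participant, word) pairs without a timing row.
    """
    lm = landmark_map or default_landmark_map()
    df = pd.read_csv(landmark_file)
    required_cols = ["participant_id", "word", "frame", "time_s", "point_id", "x", "y", "z"]
    missing_cols = [c for c in required_cols if c not in df.columns]
    if missing_cols:
        raise ValueError(f"landmark CSV missing columns: {missing_cols}")
    timings = pd.read_csv(timings_file).set_index(["participant_id", "word"])

    dup = df.duplicated(subset=["participant_id", "word", "frame", "point_id"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            "duplicated (frame, point_id) row: "
            f"({row.participant_id}, {row.word}, frame {row.frame}, point {row.point_id})"
        )

    recordings: list[Recording] = []
    for (pid, word), g in df.groupby(["participant_id", "word"], sort=True):
        try:
            t_row = timings.loc[(pid, word)]
        except KeyError:
            raise KeyError(f"no timing row for ({pid}, {word})") from None
        frames: list[MeshFrame] = []
        for (_, time_s), fg in g.groupby(["frame", "time_s"], sort=True):
            pts = {
                int(r.point_id): detector_to_world(np.array([r.x, r.y, r.z]))
                for r in fg.itertuples()
            }
            frames.append(MeshFrame(time_s=float(time_s), points=pts))
        frames.sort(key=lambda f: f.time_s)
        rec = Recording(
            participant_id=str(pid),
            word=str(word),
            fps=fps,
            frames=frames,
            onset_s=float(t_row["onset_s"]),
            offset_s=float(t_row["offset_s"]),
        )
        rec.frames[0].require(lm.all_ids, context="landmark map")
        recordings.append(rec)
    return recordings


def map_to_clinical(frame: MeshFrame, landmark_map: LandmarkMap | None = None) -> dict[str, np.ndarray]:
    """Resolve clinical landmark positions from a mesh frame.

    Multi-id entries are the arithmetic mean of their mesh points; single-id
    entries are copied.  Raises KeyError naming the landmark if an id is absent.
    """
    lm = landmark_map or default_landmark_map()
    out: dict[str, np.ndarray] = {}
    for name, ids in lm.entries.items():
        try:
            pts = [frame.points[i] for i in ids]
        except KeyError as e:
            raise KeyError(f"mesh id {e.args[0]} for landmark '{name}' missing") from None
        out[name] = np.mean(np.asarray(pts, dtype=float), axis=0)
    return out


def estimate_head_pose(landmarks: Mapping[str, np.ndarray]) -> HeadPose:
    """Orthonormal head frame from upper-face landmarks.

    X is the unit vector from the right to the left tragion; Y is the direction
    from the mid-tragion point toward the midpoint of sellion and glabella,
    Gram-Schmidt orthogonalized against X; Z = X x Y (anterior).  Deterministic
    and closed form; uses only landmarks that stay rigid during speech.
    """
    for name in ("tragion_left", "tragion_right", "sellion", "glabella"):
        if name not in landmarks:
            raise KeyError(f"landmark '{name}' required for head pose")
    tl = np.asarray(landmarks["tragion_left"], dtype=float)
    tr = np.asarray(landmarks["tragion_right"], dtype=float)
    origin = 0.5 * (tl + tr)
    x = tl - tr
    nx = np.linalg.norm(x)
    scale = max(nx, 1e-30)
    if nx < 1e-12:
        raise ValueError("degenerate pose: tragions coincident")
    x = x / nx
    up_ref = 0.5 * (np.asarray(landmarks["sellion"], dtype=float)
                    + np.asarray(landmarks["glabella"], dtype=float)) - origin
    y = up_ref - np.dot(up_ref, x) * x
    ny = np.linalg.norm(y)
    if ny < 1e-9 * scale:
        raise ValueError("degenerate pose: upper-face landmarks collinear with tragion axis")
    y = y / ny
    z = np.cross(x, y)
    return HeadPose(origin=origin, axes=np.column_stack([x, y, z]))


DEFAULT_FACE_SIZE_PAIRS: tuple[tuple[str, str], ...] = (
    ("tragion_left", "tragion_right"),
    ("zygion_left", "zygion_right"),
    ("inner_canthus_left", "inner_canthus_right"),
    ("frontotemporale_left", "frontotemporale_right"),
    ("sellion", "glabella"),
)


def compute_face_size(
    landmarks: Mapping[str, np.ndarray],
    pairs: Sequence[tuple[str, str]] = DEFAULT_FACE_SIZE_PAIRS,
    weights: Sequence[float] | None = None,
) -> float:
    """Weighted mean of upper-face inter-landmark distances.

    The combination uses only forehead/eye-region landmarks that barely move
    while the participant speaks, so it is a per-frame scale factor that is
    (by design) invariant to speech movements of the jaw and lips.  Weights
    default to equal; homogeneous of degree 1 under uniform scaling.
    """
    if weights is None:
        w = np.full(len(pairs), 1.0 / len(pairs))
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) != len(pairs):
            raise ValueError("one weight per distance pair required")
        w = w / w.sum()
    dists = []
    for a, b in pairs:
        d = float(np.linalg.norm(np.asarray(landmarks[a]) - np.asarray(landmarks[b])))
        if d <= 0.0:
            raise ValueError(f"zero distance between '{a}' and '{b}'")
        dists.append(d)
    return float(np.dot(w, dists))


def to_canonical(
    frame: MeshFrame,
    pose: HeadPose | None = None,
    landmark_map: LandmarkMap | None = None,
    face_size_pairs: Sequence[tuple[str, str]] = DEFAULT_FACE_SIZE_PAIRS,
    face_size_weights: Sequence[float] | None = None,
) -> ClinicalFrame:
    """Express a mesh frame's clinical landmarks in canonical facial coordinates.

    Each landmark is projected onto the pose axes after subtracting the
    mid-tragion origin, removing head translation and rotation.  If ``pose``
    is None it is estimated from this frame.  Face size is computed from the
    mapped landmarks (rigid-invariant either way).
    """
    named = map_to_clinical(frame, landmark_map)
    if pose is None:
        pose = estimate_head_pose(named)
    R = pose.axes  # columns X, Y, Z
    canon = {name: R.T @ (p - pose.origin) for name, p in named.items()}
    fs = compute_face_size(named, pairs=face_size_pairs, weights=face_size_weights)
    return ClinicalFrame(time_s=frame.time_s, landmarks=canon, face_size=fs)
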