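"""Per-frame measurement definitions: examples, symmetry, scale invariance."""

import numpy as np
import pytest

import facekin as fk
from facekin.landmarks import ClinicalFrame
from facekin.measurements import AXES, MEASUREMENTS, STREAMS, decompose_axes
from tests.conftest import neutral_mesh_frame

SPEC_BY_NAME = {m.name: m for m in MEASUREMENTS}


def _frame(overrides=None, face_size=1.0):
    """Clinical frame built on the neutral synthetic face, with overrides."""
    base = fk.to_canonical(neutral_mesh_frame())
    lms = {k: v.copy() for k, v in base.landmarks.items()}
    for k, v in (overrides or {}).items():
        lms[k] = np.asarray(v, dtype=float)
    return ClinicalFrame(time_s=0.0, landmarks=lms, face_size=face_size)


def _mirror_frame(frame):
    """Reflect a clinical frame across the mid-sagittal (x=0) plane."""
    flip = np.array([-1.0, 1.0, 1.0])
    out = {}
    for name, p in frame.landmarks.items():
        if name.endswith("_left"):
            out[name.removesuffix("_left") + "_right"] = p * flip
        elif name.endswith("_right"):
            out[name.removesuffix("_right") + "_left"] = p * flip
        else:
            out[name] = p * flip
    return ClinicalFrame(frame.time_s, out, frame.face_size)


class TestDecomposeAxes:
    def test_axis_aligned_vector(self):
        x, y, z = decompose_axes([3.0, 0.0, 0.0], np.eye(3))
        assert (x, y, z) == (3.0, 0.0, 0.0)

    def test_identity_axes_pass_through(self):
        assert decompose_axes([1.0, -2.0, 0.5], np.eye(3)) == (1.0, -2.0, 0.5)

    def test_reconstruction_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            # random orthonormal right-handed basis via QR
            q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            if np.linalg.det(q) < 0:
                q[:, 0] *= -1
            v = rng.normal(size=3)
            x, y, z = decompose_axes(v, q)
            # brute-force oracle: components are plain dot products
            expect = [float(v @ q[:, i]) for i in range(3)]
            np.testing.assert_allclose([x, y, z], expect, atol=1e-12)
            np.testing.assert_allclose(x * q[:, 0] + y * q[:, 1] + z * q[:, 2], v, atol=1e-9)

    def test_non_orthonormal_rejected(self):
        with pytest.raises(ValueError):
            decompose_axes([1, 0, 0], np.ones((3, 3)))


class TestMeasurementExamples:
    def test_mouth_opening_symmetric_construction(self):
        f = _frame({
            "mid_fissure_upper_left": [0, 1, 0], "mid_fissure_upper_right": [0, 1, 0],
            "mid_fissure_lower_left": [0, -1, 0], "mid_fissure_lower_right": [0, -1, 0],
            "cheilion_left": [2, 0, 0], "cheilion_right": [-2, 0, 0],
        })
        s = fk.compute_measurement(SPEC_BY_NAME["Mouth Opening"], f)
        assert s.values["scalar"] == pytest.approx(0.5)

    def test_zero_fissure_width_rejected(self):
        f = _frame({"cheilion_left": [0, 0, 0], "cheilion_right": [0, 0, 0]})
        with pytest.raises(ValueError, match="degenerate mouth"):
            fk.compute_measurement(SPEC_BY_NAME["Mouth Opening"], f)

    def test_symmetric_frame_scores_zero_symmetry(self, neutral_clinical):
        sym = fk.compute_measurement(SPEC_BY_NAME["Medial 1/3 Symmetry"], neutral_clinical)
        assert all(abs(sym.values[a]) < 1e-12 for a in AXES)
        area = fk.compute_measurement(SPEC_BY_NAME["Mouth Area Symmetry"], neutral_clinical)
        assert abs(area.values["scalar"]) < 1e-12

    def test_mandibular_angle_trig_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            pog = rng.normal(size=3)
            gl = rng.normal(size=3)
            gr = rng.normal(size=3)
            f = _frame({"pogonion": pog, "gonion_left": gl, "gonion_right": gr})
            got = fk.compute_measurement(SPEC_BY_NAME["Mandibular Angle"], f).values["scalar"]
            d = 0.5 * (gl + gr) - pog
            # independent trig oracle: angle of the sagittal-plane projection
            # of the pogonion->mid-gonion line vs the anterior axis
            expect = np.arctan2(d[1], d[2])
            assert got == pytest.approx(expect, abs=1e-12)

    def test_missing_landmark_names_role(self, neutral_clinical):
        lms = {k: v for k, v in neutral_clinical.landmarks.items() if k != "pogonion"}
        f = ClinicalFrame(0.0, lms, neutral_clinical.face_size)
        with pytest.raises(KeyError, match="pogonion"):
            fk.compute_measurement(SPEC_BY_NAME["Pogonion"], f)


class TestInvariants:
    def test_stream_row_list(self):
        """Exactly the 30 report rows: 8 vector measurements x3 axes + 6 scalars."""
        assert len(STREAMS) == 30
        assert STREAMS == (
            "Labial Fissure Width", "Mouth Height",
            "Medial 1/3 Symmetry (X)", "Medial 1/3 Symmetry (Y)", "Medial 1/3 Symmetry (Z)",
            "Mouth Area Symmetry", "Mouth Opening",
            "Lip Action (X)", "Lip Action (Y)", "Lip Action (Z)",
            "Medial 1/3 Action (X)", "Medial 1/3 Action (Y)", "Medial 1/3 Action (Z)",
            "Medial 1/3 Upper Action (X)", "Medial 1/3 Upper Action (Y)", "Medial 1/3 Upper Action (Z)",
            "Medial 1/3 Lower Action (X)", "Medial 1/3 Lower Action (Y)", "Medial 1/3 Lower Action (Z)",
            "Pogonion (X)", "Pogonion (Y)", "Pogonion (Z)",
            "Gonion (X)", "Gonion (Y)", "Gonion (Z)",
            "Lower Lip from Pogonion (X)", "Lower Lip from Pogonion (Y)", "Lower Lip from Pogonion (Z)",
            "Mandibular Angle", "Face Size",
        )

    def test_scale_invariance_of_measurements(self):
        """Every stream except Face Size is invariant to uniform scaling."""
        c1 = fk.to_canonical(neutral_mesh_frame())
        c2 = fk.to_canonical(neutral_mesh_frame(scale=3.0))
        for spec in MEASUREMENTS:
            s1 = fk.compute_measurement(spec, c1)
            s2 = fk.compute_measurement(spec, c2)
            for ax, v in s1.values.items():
                if spec.name == "Face Size":
                    assert s2.values[ax] == pytest.approx(3 * v, rel=1e-9)
                else:
                    assert s2.values[ax] == pytest.approx(v, abs=1e-9)

    def test_mirror_property(self):
        """Mirroring negates X components and both symmetry measurements."""
        rng = np.random.default_rng(5)
        base = fk.to_canonical(neutral_mesh_frame())
        lms = {k: v + rng.normal(0, 2e-3, 3) for k, v in base.landmarks.items()}
        f = ClinicalFrame(0.0, lms, base.face_size)
        m = _mirror_frame(f)
        for spec in MEASUREMENTS:
            if spec.name == "Face Size":
                continue
            s0 = fk.compute_measurement(spec, f).values
            s1 = fk.compute_measurement(spec, m).values
            if "Symmetry" in spec.name:
                for ax in s0:
                    assert s1[ax] == pytest.approx(-s0[ax], abs=1e-9)
            elif spec.kind == "vector":
                assert s1["X"] == pytest.approx(-s0["X"], abs=1e-9)
                assert s1["Y"] == pytest.approx(s0["Y"], abs=1e-9)
                assert s1["Z"] == pytest.approx(s0["Z"], abs=1e-9)
            else:
                assert s1["scalar"] == pytest.approx(s0["scalar"], abs=1e-9)


class TestMeasureSequence:
    def test_constant_frames_constant_series(self, neutral_clinical):
        frames = [
            ClinicalFrame(t, neutral_clinical.landmarks, neutral_clinical.face_size)
            for t in (0.0, 0.1, 0.2)
        ]
        times, series = fk.measure_sequence(frames)
        assert len(times) == 3
        for s in STREAMS:
            assert np.ptp(series[s]) == pytest.approx(0.0, abs=1e-12)

    def test_two_frame_series_lengths(self, neutral_clinical):
        frames = [ClinicalFrame(t, neutral_clinical.landmarks, 1.0) for t in (0.0, 0.1)]
        _, series = fk.measure_sequence(frames)
        assert all(len(series[s]) == 2 for s in STREAMS)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fk.measure_sequence([])

    def test_programmed_mouth_opening_peak(self, small_cohort, small_store):
        """Pipeline Mouth Opening peak matches the generator's programmed gesture."""
        from facekin.synthdata import WORD_TEMPLATES, expected_mouth_opening

        cohort, _ = small_cohort
        amp = cohort.manifest["participants"]["P001"]["amp_scale"]
        tau = np.linspace(0, 1, 1000)
        expect = expected_mouth_opening(WORD_TEMPLATES["Map"], tau, amp)
        got = small_store.get("P001", "Map", "Mouth Opening", 0)
        assert abs(got.max() - expect.max()) / expect.max() < 0.02
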