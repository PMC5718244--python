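"""Synthetic dose model, packaged response profiles, and simulation."""

import math

import numpy as np
import pytest
from scipy.special import erf

import arrayqa as aq
from arrayqa.errors import ValidationError
from arrayqa.synthetic import CALIBRATION_FIELD, DEFAULT_MU, DEFAULT_SAD


class TestTrueDosePlane:
    def test_vertical_beam_symmetry(self):
        beam = aq.BeamSpec(energy="6MV", field_size=(10, 10), gantry_angle=0.0)
        p = aq.true_dose_plane(beam)
        assert np.allclose(p.values, p.values[:, ::-1], rtol=1e-10)  # x mirror
        assert np.allclose(p.values, p.values[::-1, :], rtol=1e-10)  # y mirror

    def test_opposed_beams_symmetric_in_depth(self):
        plan = aq.PlanSpec([
            aq.BeamSpec(gantry_angle=90.0, field_size=(10, 10)),
            aq.BeamSpec(gantry_angle=270.0, field_size=(10, 10)),
        ])
        p = aq.composite_true_plane(plan)
        # the two lateral beams traverse x in opposite senses: x-mirror symmetry
        assert np.allclose(p.values, p.values[:, ::-1], rtol=1e-10)

    def test_centre_dose_matches_closed_form(self, grid):
        """Hand-computed fluence x attenuation x inverse-square at the centre."""
        beam = aq.BeamSpec(energy="6MV", field_size=(10, 10), gantry_angle=0.0)
        p = aq.true_dose_plane(beam, grid)
        centre = aq.central_detector_dose(aq.frame_to_plane(
            aq.DoseFrame(dose=p.values), grid))
        # independent spot check at detector (17, 17) = (+3.81, +3.81) mm
        x = y = 3.81
        s = math.sqrt(2) * 3.0
        fl = (0.5 * (erf((50 - x) / s) + erf((50 + x) / s))
              * 0.5 * (erf((50 - y) / s) + erf((50 + y) / s)))
        depth = 110.0 * math.sqrt(x * x + y * y + DEFAULT_SAD**2) / DEFAULT_SAD
        # entry point: ray from source (0,0,1000) to (x, y, 0) crosses z=110
        dist = math.sqrt(x * x + y * y + DEFAULT_SAD**2)
        t_entry = dist * (DEFAULT_SAD - 110.0) / DEFAULT_SAD
        depth = dist - t_entry
        expect = 100.0 * fl * math.exp(-DEFAULT_MU["6MV"] * depth) * (DEFAULT_SAD / DEFAULT_SAD) ** 2
        got = p.values[16, 16]
        assert got == pytest.approx(expect, rel=1e-10)

    def test_arc_beam_requires_segment_angle(self):
        beam = aq.BeamSpec(arc=(185.0, 175.0, "cw"))
        with pytest.raises(ValidationError):
            aq.true_dose_plane(beam)
        p = aq.true_dose_plane(beam, gantry_angle=90.0)
        assert p.values.shape == (32, 32)


class TestArcGeometry:
    def test_full_arc_span(self):
        beam = aq.BeamSpec(arc=(185.0, 175.0, "cw"))
        assert beam.arc_span() == pytest.approx(350.0)
        angles = beam.arc_angles(step=2.0)
        assert len(angles) == 175
        assert np.all((angles >= 0) & (angles < 360))

    def test_ccw_arc(self):
        beam = aq.BeamSpec(arc=(200.0, 160.0, "ccw"))
        assert beam.arc_span() == pytest.approx(40.0)


class TestDefaultResponseModel:
    def test_unity_at_zero_for_all_columns(self):
        for e in ("6MV", "10MV"):
            m = aq.default_response_model(e)
            assert np.allclose(m.response(0.0), 1.0, atol=1e-12)

    @pytest.mark.parametrize(
        "energy,angle,expected",
        [
            ("6MV", 90.0, 1.06), ("6MV", 92.0, 0.85), ("6MV", 180.0, 0.92),
            ("10MV", 90.0, 1.04), ("10MV", 92.0, 0.89), ("10MV", 180.0, 0.95),
        ],
    )
    def test_central_extrema(self, energy, angle, expected):
        m = aq.default_response_model(energy)
        assert m.central_response(angle) == pytest.approx(expected, abs=1e-12)

    def test_anchors_on_calibration_grid(self):
        m = aq.default_response_model("6MV")
        assert np.array_equal(m.anchor_angles, aq.calibration_angles())
        assert len(aq.calibration_angles()) == 37

    def test_mirror_fold_past_180(self):
        m = aq.default_response_model("6MV")
        assert np.allclose(m.response(270.0), m.response(90.0), atol=1e-12)

    def test_unknown_energy_rejected(self):
        with pytest.raises(ValidationError):
            aq.default_response_model("15MV")


class TestSimulateMeasurement:
    def test_identity_response_accumulates_to_truth(self):
        model = aq.AngularResponseModel(
            energy="6MV",
            anchor_angles=np.array([0.0, 180.0]),
            column_response=np.ones((32, 2)),
            noise_sigma=0.0,
        )
        plan = aq.PlanSpec([
            aq.BeamSpec(gantry_angle=0.0, field_size=(10, 10)),
            aq.BeamSpec(gantry_angle=90.0, field_size=(10, 10)),
        ])
        movie = aq.simulate_measurement(plan, model, seed=0, noise_sigma=0.0)
        truth = aq.composite_true_plane(plan)
        assert np.allclose(aq.accumulate(movie).dose, truth.values, rtol=1e-10)

    def test_fixed_seed_is_bitwise_reproducible(self):
        model = aq.default_response_model("6MV")
        plan = aq.PlanSpec([aq.BeamSpec(gantry_angle=45.0)])
        a = aq.simulate_measurement(plan, model, seed=99)
        b = aq.simulate_measurement(plan, model, seed=99)
        for fa, fb in zip(a.frames, b.frames):
            assert np.array_equal(fa.dose, fb.dose)

    def test_noise_sigma_recovered_by_monte_carlo(self):
        """Sample relative sigma of repeated constant-field frames ~ 0.3%."""
        model = aq.default_response_model("6MV")
        plan = aq.PlanSpec([aq.BeamSpec(gantry_angle=0.0, field_size=(20, 20))])
        movie = aq.simulate_measurement(
            plan, model, seed=3, frames_per_beam=10_000, noise_sigma=0.003
        )
        doses = np.array([f.dose[15, 15] for f in movie.frames])
        rel_sigma = doses.std() / doses.mean()
        assert abs(rel_sigma - 0.003) < 0.003 * 0.05

    def test_arc_movie_frame_count_and_angles(self):
        model = aq.default_response_model("6MV")
        plan = aq.PlanSpec([aq.BeamSpec(arc=(185.0, 175.0, "cw"))])
        movie = aq.simulate_measurement(plan, model, seed=0, noise_sigma=0.0)
        assert len(movie) == 175
        assert all(f.gantry_angle is not None for f in movie.frames)


class TestReferenceAtDetectors:
    def test_covers_37_distinct_angles_with_zero(self):
        ref = aq.reference_at_detectors("6MV")
        assert len(ref) == 37
        assert 0.0 in ref

    def test_wrapper_identity(self):
        ref = aq.reference_at_detectors("6MV")
        beam = aq.BeamSpec(energy="6MV", field_size=CALIBRATION_FIELD, gantry_angle=0.0)
        direct = aq.true_dose_plane(beam, gantry_angle=110.0)
        assert np.allclose(ref[110.0].values, direct.values, rtol=1e-14)
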