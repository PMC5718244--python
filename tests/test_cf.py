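"""Correction-factor derivation, interpolation, and application."""

import numpy as np
import pytest

import arrayqa as aq
from arrayqa.errors import ValidationError


def const_frame(value, angle):
    return aq.DoseFrame(dose=np.full((32, 32), float(value)), gantry_angle=angle)


def make_table(angles, central, columns=None, energy="6MV"):
    angles = np.asarray(angles, dtype=float)
    central = np.asarray(central, dtype=float)
    if columns is None:
        columns = np.tile(central, (32, 1))
    return aq.CFTable(energy=energy, angles=angles, central_cf=central,
                      column_cf=np.asarray(columns, dtype=float),
                      normalization={})


class TestDeriveCF:
    def test_identical_inputs_give_unity(self, rng):
        angles = [0.0, 45.0, 90.0]
        doses = {a: rng.uniform(1, 10, (32, 32)) for a in angles}
        measured = {a: aq.DoseFrame(dose=d, gantry_angle=a) for a, d in doses.items()}
        table = aq.derive_cf(measured, doses, "6MV")
        assert np.allclose(table.central_cf, 1.0, atol=1e-12)
        assert np.allclose(table.column_cf, 1.0, atol=1e-12)

    def test_forced_ratio_arithmetic(self):
        measured = {0.0: const_frame(50.0, 0.0), 90.0: const_frame(53.0, 90.0)}
        reference = {0.0: np.full((32, 32), 50.0), 90.0: np.full((32, 32), 50.0)}
        table = aq.derive_cf(measured, reference, "6MV")
        assert aq.cf_central_at(table, 90.0) == pytest.approx(1.06, abs=1e-12)

    def test_noiseless_roundtrip_reproduces_response_model(self, cf_table_6mv):
        model = aq.default_response_model("6MV")
        for k, a in enumerate(cf_table_6mv.angles):
            r = model.response(a)
            r0 = model.response(0.0)
            assert np.allclose(cf_table_6mv.column_cf[:, k], r / r0, atol=1e-12)

    def test_missing_zero_angle_rejected(self):
        measured = {10.0: const_frame(1, 10.0)}
        reference = {10.0: np.ones((32, 32))}
        with pytest.raises(ValidationError):
            aq.derive_cf(measured, reference, "6MV")

    def test_nonpositive_reference_rejected(self):
        measured = {0.0: const_frame(1, 0.0)}
        reference = {0.0: np.zeros((32, 32))}
        with pytest.raises(ValidationError):
            aq.derive_cf(measured, reference, "6MV")


class TestCFTableInvariants:
    def test_unity_at_zero_enforced(self):
        with pytest.raises(ValidationError):
            make_table([0.0, 90.0], [1.01, 1.06])

    def test_positive_cf_enforced(self):
        with pytest.raises(ValidationError):
            make_table([0.0, 90.0], [1.0, -0.5])


class TestCFLookup:
    def test_unity_at_zero_for_all_columns(self, cf_table_6mv):
        for j in range(1, 33):
            assert aq.cf_at(cf_table_6mv, j, 0.0) == pytest.approx(1.0, abs=1e-12)

    def test_mirror_symmetry(self, cf_table_6mv):
        for j in (1, 16, 32):
            for theta in (190.0, 270.0, 300.5, 359.0):
                assert aq.cf_at(cf_table_6mv, j, theta) == pytest.approx(
                    aq.cf_at(cf_table_6mv, j, 360.0 - theta), abs=1e-12
                )
        assert aq.cf_central_at(cf_table_6mv, 270.0) == pytest.approx(
            aq.cf_central_at(cf_table_6mv, 90.0), abs=1e-12
        )

    def test_linear_midpoint(self):
        table = make_table([0.0, 100.0, 110.0], [1.0, 0.95, 0.97])
        assert aq.cf_central_at(table, 105.0) == pytest.approx(0.96, abs=1e-12)

    def test_out_of_range_angle_warns_and_wraps(self, cf_table_6mv):
        with pytest.warns(UserWarning):
            v = aq.cf_central_at(cf_table_6mv, 450.0)
        assert v == pytest.approx(aq.cf_central_at(cf_table_6mv, 90.0))

    def test_difference_statistic(self):
        columns = np.tile(np.linspace(1.0, 1.0, 2), (32, 1))
        columns[:, 1] = 1.0
        table = make_table([0.0, 90.0], [1.0, 1.0], columns)
        assert aq.cf_difference(table, 5, 90.0) == pytest.approx(0.0)
        # the extreme spread of the lateral window: +7.0% and -6.1%
        columns = np.ones((32, 2))
        columns[0, 1] = 0.939
        columns[31, 1] = 1.070
        table = make_table([0.0, 90.0], [1.0, 1.0], columns)
        assert aq.cf_difference(table, 32, 90.0) == pytest.approx(7.0)
        assert aq.cf_difference(table, 1, 90.0) == pytest.approx(-6.1)


class TestApplyCorrection:
    def test_none_scheme_is_identity(self, cf_table_6mv):
        f = const_frame(5.0, 92.0)
        out = aq.apply_correction(f, cf_table_6mv, "none")
        assert np.array_equal(out.dose, f.dose)

    def test_central_scheme_divides_by_cf(self):
        table = make_table([0.0, 90.0], [1.0, 1.06])
        out = aq.apply_correction(const_frame(106.0, 90.0), table, "central")
        assert np.allclose(out.dose, 100.0)
        assert out.gantry_angle == 90.0

    def test_entire_roundtrip_multiplication(self, cf_table_6mv, rng):
        f = aq.DoseFrame(dose=rng.uniform(1, 10, (32, 32)), gantry_angle=101.0)
        out = aq.apply_correction(f, cf_table_6mv, "entire")
        cfs = np.array([aq.cf_at(cf_table_6mv, j, 101.0) for j in range(1, 33)])
        assert np.allclose(out.dose * cfs[None, :], f.dose, rtol=1e-12)

    def test_entire_recovers_truth_on_synthetic_frame(self, cf_table_6mv):
        model = aq.default_response_model("6MV")
        beam = aq.BeamSpec(energy="6MV", field_size=(30.0, 10.0), gantry_angle=100.0)
        true = aq.true_dose_plane(beam)
        reading = true.values * model.response(100.0)[None, :]
        frame = aq.DoseFrame(dose=reading, gantry_angle=100.0)
        out = aq.apply_correction(frame, cf_table_6mv, "entire")
        # response at 0 deg is not exactly 1 per column; correction restores the
        # 0-degree-normalised reading, i.e. truth times R_j(0)
        r0 = model.response(0.0)
        assert np.allclose(out.dose, true.values * r0[None, :], rtol=1e-12)

    def test_missing_angle_rejected(self, cf_table_6mv):
        f = aq.DoseFrame(dose=np.ones((32, 32)), gantry_angle=None)
        with pytest.raises(ValidationError):
            aq.apply_correction(f, cf_table_6mv, "entire")

    def test_schemes_identical_when_columns_equal_central(self, rng):
        central = np.array([1.0, 1.05, 0.9])
        table = make_table([0.0, 90.0, 180.0], central)
        f = aq.DoseFrame(dose=rng.uniform(1, 5, (32, 32)), gantry_angle=135.0)
        a = aq.apply_correction(f, table, "central")
        b = aq.apply_correction(f, table, "entire")
        assert np.allclose(a.dose, b.dose, rtol=1e-14)


class TestCorrectMovie:
    def test_single_frame_equals_apply(self, cf_table_6mv):
        f = const_frame(10.0, 92.0)
        movie = aq.DoseMovie([f])
        a = aq.correct_movie(movie, cf_table_6mv, "entire")
        b = aq.apply_correction(f, cf_table_6mv, "entire")
        assert np.allclose(a.dose, b.dose)

    def test_unity_table_equals_accumulate(self, rng):
        table = make_table([0.0, 180.0], [1.0, 1.0])
        frames = [
            aq.DoseFrame(dose=rng.uniform(0, 5, (32, 32)), gantry_angle=a)
            for a in np.linspace(185, 355, 18) % 360
        ]
        movie = aq.DoseMovie(frames)
        out = aq.correct_movie(movie, table, "entire")
        assert np.allclose(out.dose, aq.accumulate(movie).dose, rtol=1e-12)

    def test_frame_without_angle_rejected(self, cf_table_6mv):
        movie = aq.DoseMovie([aq.DoseFrame(dose=np.ones((32, 32)))])
        with pytest.raises(ValidationError):
            aq.correct_movie(movie, cf_table_6mv, "central")


class TestNoisyCalibration:
    def test_cf_error_below_one_percent_with_default_noise(self):
        """0.3% multiplicative reading noise keeps per-angle CF errors < 1%."""
        model = aq.default_response_model("6MV")
        ref = aq.reference_at_detectors("6MV")
        noisy = aq.calibration_measurement("6MV", model, noise_sigma=0.003, seed=7)
        table = aq.derive_cf(noisy, ref, "6MV")
        clean = aq.calibration_measurement("6MV", model)
        exact = aq.derive_cf(clean, ref, "6MV")
        rel_err = np.abs(table.column_cf / exact.column_cf - 1.0)
        # 3-sigma claim: 99.7% of per-angle, per-column CFs within 1%
        assert np.quantile(rel_err, 0.997) < 0.01
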