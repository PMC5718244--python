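"""Validation studies: calibration round trips and corrected-dose benchmarks.

These functions compose the synthetic simulator with the correction chain
under the study conditions used to validate the method: a noiseless
calibration at the standard angle grid, static-field sweeps with default
measurement noise, and the six-plan simple-plan library (opposed pairs,
four- and six-field arrangements, and a full arc).
"""

from __future__ import annotations

import numpy as np

from .array_model import frame_to_plane, roi_mean
from .cf import CFTable, correct_movie, derive_cf
from .synthetic import (
    BeamSpec,
    PlanSpec,
    calibration_measurement,
    composite_true_plane,
    default_response_model,
    reference_at_detectors,
    simulate_measurement,
)

ENERGIES = ("6MV", "10MV")


def derive_default_cf_table(energy: str) -> CFTable:
    """CF table from a noiseless synthetic calibration with the packaged
    response model (30 x 10 cm field, standard angle grid)."""
    model = default_response_model(energy)
    measured = calibration_measurement(energy, model, noise_sigma=0.0)
    reference = reference_at_detectors(energy)
    return derive_cf(measured, reference, energy=energy)


def central_extrema_percent(table: CFTable) -> dict[float, float]:
    """Percent deviation from unity of the central-detector CF at the three
    benchmark angles: +x means over-response at 90, the 92/180 entries are
    reported as under-response magnitudes (positive)."""
    from .cf import cf_central_at

    return {
        90.0: 100.0 * (cf_central_at(table, 90.0) - 1.0),
        92.0: 100.0 * (1.0 - cf_central_at(table, 92.0)),
        180.0: 100.0 * (1.0 - cf_central_at(table, 180.0)),
    }


def simple_plan_library(energy: str, field: float = 10.0) -> list[PlanSpec]:
    """The six-geometry simple-plan set (square ``field`` cm beams):
    opposed vertical, opposed lateral, four-field box, oblique four-field,
    six-field, and a full 185-to-175-degree arc."""
    fs = (field, field)

    def static(*angles):
        return PlanSpec([BeamSpec(energy=energy, field_size=fs, gantry_angle=a)
                         for a in angles])

    return [
        static(0.0, 180.0),
        static(90.0, 270.0),
        static(0.0, 90.0, 180.0, 270.0),
        static(60.0, 120.0, 240.0, 300.0),
        static(45.0, 90.0, 135.0, 225.0, 270.0, 315.0),
        PlanSpec([BeamSpec(energy=energy, field_size=fs, arc=(185.0, 175.0, "cw"))]),
    ]


def _central_axis_percent_dev(plan: PlanSpec, table: CFTable, seed: int,
                              noise_sigma: float = 0.003) -> float:
    """Entire-scheme-corrected ROI central-axis dose vs noiseless truth, %."""
    energy = plan.beams[0].energy
    model = default_response_model(energy)
    movie = simulate_measurement(plan, model, seed=seed, noise_sigma=noise_sigma)
    corrected = correct_movie(movie, table, "entire")
    truth = composite_true_plane(plan)
    got = roi_mean(frame_to_plane(corrected), (0.0, 0.0), side=10.0)
    want = roi_mean(truth, (0.0, 0.0), side=10.0)
    return 100.0 * (got - want) / want


def static_field_max_deviation(seed: int = 0, field: float = 10.0,
                               tables: dict[str, CFTable] | None = None) -> float:
    """Max |%| central-axis deviation of corrected static fields.

    One square-``field`` beam per gantry angle 0..180 in 10-degree steps,
    simulated with default 0.3% reading noise, corrected with the entire
    scheme; both energies.
    """
    worst = 0.0
    rng = np.random.default_rng(seed)
    for energy in ENERGIES:
        table = (tables or {}).get(energy) or derive_default_cf_table(energy)
        for theta in np.arange(0.0, 181.0, 10.0):
            plan = PlanSpec([BeamSpec(energy=energy, field_size=(field, field),
                                      gantry_angle=float(theta))])
            dev = _central_axis_percent_dev(plan, table,
                                            seed=int(rng.integers(2**31)))
            worst = max(worst, abs(dev))
    return worst


def simple_plan_max_deviation(seed: int = 0, field: float = 10.0,
                              tables: dict[str, CFTable] | None = None) -> float:
    """Max |%| central-axis deviation of corrected composite doses over the
    six simple-plan geometries, both energies, default noise."""
    worst = 0.0
    rng = np.random.default_rng(seed)
    for energy in ENERGIES:
        table = (tables or {}).get(energy) or derive_default_cf_table(energy)
        for plan in simple_plan_library(energy, field):
            dev = _central_axis_percent_dev(plan, table,
                                            seed=int(rng.integers(2**31)))
            worst = max(worst, abs(dev))
    return worst
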