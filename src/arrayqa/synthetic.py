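"""Synthetic phantom, beam, and angular-response simulator.

Every other module is testable end-to-end without measured data: this module
provides (a) a deliberately simple analytic ground-truth dose model for
static and arc photon beams through a rectangular solid-water phantom, and
(b) a parametric column-wise angular response model of the chamber array
with the over/under-response structure seen on the physical device (sharp
over-response with the beam edge-on at 90 degrees, sharp under-response just
past it, smooth under-response toward 180 degrees).

The dose model is fluence x attenuation x inverse-square only — a test
harness, not a dose engine.  Its virtues are smoothness, correct beam
geometry, and determinism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.special import erf

from .array_model import (
    DetectorGrid,
    DoseFrame,
    DoseMovie,
    DosePlane,
    N_COLS,
)
from .errors import ValidationError

#: source-axis distance, mm (stand-in default; not device-calibrated)
DEFAULT_SAD = 1000.0
#: effective linear attenuation per mm of solid water (stand-in defaults)
DEFAULT_MU = {"6MV": 0.0049, "10MV": 0.0041}
#: penumbra width parameter (mm) of the error-function field edges
DEFAULT_PENUMBRA_SIGMA = 3.0
#: dose scale: open-field dose at zero depth on the axis, cGy per unit weight
DEFAULT_DOSE_SCALE = 100.0

ENERGIES = ("6MV", "10MV")


@dataclass(frozen=True)
class Phantom:
    """Rectangular solid-water phantom centred on the isocentre.

    Axes: x = cross-line (columns), y = in-line (rows, along the couch),
    z = vertical.  The detector plane is the z = 0 mid-plane.
    Defaults are the 34 x 31.4 x 22 cm cube-phantom dimensions.
    """

    width: float = 340.0  # x extent, mm
    length: float = 314.0  # y extent, mm
    height: float = 220.0  # z extent, mm

    def __post_init__(self) -> None:
        if min(self.width, self.length, self.height) <= 0:
            raise ValidationError("phantom dimensions must be positive")

    @property
    def half(self) -> np.ndarray:
        return np.array([self.width, self.length, self.height]) / 2.0


@dataclass(frozen=True)
class BeamSpec:
    """One static or arc photon beam.

    ``field_size`` is (cross-line, in-line) in cm at the isocentre; a scalar
    means a square field.  Exactly one of ``gantry_angle`` (static, degrees)
    or ``arc`` ((start, stop, direction)) must be set; ``direction`` is
    ``"cw"`` (increasing degrees) or ``"ccw"``.  ``weight`` is the relative
    monitor-unit weight.
    """

    energy: str = "6MV"
    field_size: tuple[float, float] = (10.0, 10.0)
    gantry_angle: float | None = None
    arc: tuple[float, float, str] | None = None
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.energy not in ENERGIES:
            raise ValidationError(f"unknown energy {self.energy!r}")
        fs = self.field_size
        if np.isscalar(fs):
            fs = (float(fs), float(fs))
        fs = (float(fs[0]), float(fs[1]))
        if min(fs) <= 0:
            raise ValidationError("field_size must be positive")
        object.__setattr__(self, "field_size", fs)
        if (self.gantry_angle is None) == (self.arc is None):
            raise ValidationError("set exactly one of gantry_angle or arc")
        if self.gantry_angle is not None:
            object.__setattr__(self, "gantry_angle", float(self.gantry_angle) % 360.0)
        else:
            start, stop, direction = self.arc
            if direction not in ("cw", "ccw"):
                raise ValidationError("arc direction must be 'cw' or 'ccw'")
            object.__setattr__(
                self, "arc", (float(start) % 360.0, float(stop) % 360.0, direction)
            )
        if not self.weight > 0:
            raise ValidationError("weight must be positive")

    @property
    def is_arc(self) -> bool:
        return self.arc is not None

    def arc_span(self) -> float:
        """Swept angle in degrees (0, 360]."""
        start, stop, direction = self.arc
        span = (stop - start) % 360.0 if direction == "cw" else (start - stop) % 360.0
        return 360.0 if span == 0 else span

    def arc_angles(self, step: float = 2.0) -> np.ndarray:
        """Discretised gantry angles (segment mid-points) for an arc."""
        span = self.arc_span()
        n = max(1, int(math.ceil(span / step)))
        seg = span / n
        start, _, direction = self.arc
        sign = 1.0 if direction == "cw" else -1.0
        return (start + sign * seg * (np.arange(n) + 0.5)) % 360.0


@dataclass(frozen=True)
class PlanSpec:
    """Ordered beam list plus the movie-mode frame duration (s)."""

    beams: tuple[BeamSpec, ...]
    frame_duration: float = 0.2

    def __init__(self, beams, frame_duration: float = 0.2):
        beams = tuple(beams)
        if not beams:
            raise ValidationError("a plan needs at least one beam")
        object.__setattr__(self, "beams", beams)
        if not frame_duration > 0:
            raise ValidationError("frame_duration must be positive")
        object.__setattr__(self, "frame_duration", float(frame_duration))


def calibration_angles() -> np.ndarray:
    """The calibration gantry-angle grid: 10-degree steps over 0-180 plus
    1-degree steps over the lateral 90-110 window (37 distinct angles)."""
    coarse = np.arange(0.0, 181.0, 10.0)
    fine = np.arange(90.0, 111.0, 1.0)
    return np.unique(np.concatenate([coarse, fine]))


def _edge_profile(t: np.ndarray, width: float, sigma: float) -> np.ndarray:
    """Error-function field-edge profile: ~1 inside |t| < width/2, ~0 outside."""
    s = math.sqrt(2.0) * sigma
    return 0.5 * (erf((width / 2.0 - t) / s) + erf((width / 2.0 + t) / s))


def _ray_entry_depth(points: np.ndarray, src: np.ndarray, half: np.ndarray) -> np.ndarray:
    """Path length (mm) from the phantom entry surface to each point.

    ``points`` is (N, 3); rays run from ``src`` to each point.  Points are
    assumed inside the box (the detector plane lies inside the phantom).
    """
    d = points - src[None, :]
    dist = np.linalg.norm(d, axis=1)
    u = d / dist[:, None]
    with np.errstate(divide="ignore"):
        t1 = (-half[None, :] - src[None, :]) / u
        t2 = (half[None, :] - src[None, :]) / u
    # axes the ray is parallel to: inside that slab for interior points
    par = np.abs(u) < 1e-12
    t1 = np.where(par, -np.inf, t1)
    t2 = np.where(par, np.inf, t2)
    t_near = np.minimum(t1, t2).max(axis=1)
    return np.clip(dist - t_near, 0.0, None)


def _static_dose_at_points(
    xy: np.ndarray,
    angle_deg: float,
    field_mm: tuple[float, float],
    phantom: Phantom,
    mu: float,
    sad: float,
    sigma: float,
    scale: float,
) -> np.ndarray:
    """Dose at z=0 plane points ``xy`` (N, 2) for one static beam of unit weight."""
    th = math.radians(angle_deg)
    sin, cos = math.sin(th), math.cos(th)
    x, y = xy[:, 0], xy[:, 1]
    pts3 = np.column_stack([x, y, np.zeros_like(x)])
    src = np.array([sad * sin, 0.0, sad * cos])
    # distance of the point along the beam axis from the source
    w = sad - x * sin
    # lateral offsets in the beam frame, projected back to the isocentre plane
    u_iso = (x * cos) * sad / w
    v_iso = y * sad / w
    fluence = _edge_profile(u_iso, field_mm[0], sigma) * _edge_profile(v_iso, field_mm[1], sigma)
    depth = _ray_entry_depth(pts3, src, phantom.half)
    return scale * fluence * np.exp(-mu * depth) * (sad / w) ** 2


def true_dose_plane(
    beam: BeamSpec,
    grid: DetectorGrid | None = None,
    phantom: Phantom | None = None,
    *,
    gantry_angle: float | None = None,
    mu: float | None = None,
    sad: float = DEFAULT_SAD,
    penumbra_sigma: float = DEFAULT_PENUMBRA_SIGMA,
    dose_scale: float = DEFAULT_DOSE_SCALE,
) -> DosePlane:
    """Analytic ground-truth dose of one static beam at the chamber positions.

    The model is primary fluence (product of error-function penumbra
    profiles of the stated field size, in the beam's rotated frame) times
    exponential attenuation along the ray from the phantom entry surface,
    times inverse-square from the source.  Deterministic.

    ``gantry_angle`` overrides the beam's static angle (used to discretise
    arcs); for an arc beam it is required.
    """
    grid = grid or DetectorGrid()
    phantom = phantom or Phantom()
    angle = gantry_angle if gantry_angle is not None else beam.gantry_angle
    if angle is None:
        raise ValidationError("arc beams need an explicit gantry_angle per segment")
    if mu is None:
        mu = DEFAULT_MU[beam.energy]
    half = phantom.half
    xs, ys = grid.xs(), grid.ys()
    if np.abs(xs).max() > half[0] or np.abs(ys).max() > half[1]:
        raise ValidationError("detector grid extends outside the phantom")
    gx, gy = np.meshgrid(xs, ys)  # rows vary with y, cols with x
    xy = np.column_stack([gx.ravel(), gy.ravel()])
    fs_mm = (beam.field_size[0] * 10.0, beam.field_size[1] * 10.0)
    dose = _static_dose_at_points(
        xy, angle, fs_mm, phantom, mu, sad, penumbra_sigma, dose_scale
    ) * beam.weight
    return DosePlane(values=dose.reshape(32, 32), spacing=grid.pitch, origin=grid.origin)


def composite_true_plane(
    plan: PlanSpec,
    grid: DetectorGrid | None = None,
    phantom: Phantom | None = None,
    *,
    arc_step: float = 2.0,
    **model_kw,
) -> DosePlane:
    """Noiseless composite ground-truth dose of a plan (arcs discretised)."""
    grid = grid or DetectorGrid()
    total = None
    for beam in plan.beams:
        if beam.is_arc:
            angles = beam.arc_angles(arc_step)
            for a in angles:
                p = true_dose_plane(beam, grid, phantom, gantry_angle=float(a), **model_kw)
                v = p.values / len(angles)
                total = v if total is None else total + v
        else:
            p = true_dose_plane(beam, grid, phantom, **model_kw)
            total = p.values if total is None else total + p.values
    return DosePlane(values=total, spacing=grid.pitch, origin=grid.origin)


@dataclass(frozen=True)
class AngularResponseModel:
    """Column-wise relative response of the array versus gantry angle.

    ``column_response[j-1, k]`` is the ratio of the chamber reading to the
    true dose for column ``j`` at ``anchor_angles[k]`` (degrees, in
    [0, 180]); between anchors the response is piecewise-linear, and angles
    past 180 use the mirror 360 - theta.  The response at 0 degrees need not
    be 1 — normalisation belongs to the correction module.
    ``noise_sigma`` is the relative (1 sigma) multiplicative reading noise
    per chamber per snapshot.
    """

    energy: str
    anchor_angles: np.ndarray
    column_response: np.ndarray
    noise_sigma: float = 0.003

    def __post_init__(self) -> None:
        ang = np.asarray(self.anchor_angles, dtype=float)
        resp = np.asarray(self.column_response, dtype=float)
        if ang.ndim != 1 or np.any(np.diff(ang) <= 0):
            raise ValidationError("anchor_angles must be strictly increasing")
        if ang[0] < 0 or ang[-1] > 180:
            raise ValidationError("anchor_angles must lie in [0, 180]")
        if resp.shape != (N_COLS, ang.size):
            raise ValidationError("column_response must be 32 x n_anchor")
        if np.any(resp <= 0):
            raise ValidationError("responses must be positive")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be non-negative")
        object.__setattr__(self, "anchor_angles", ang)
        object.__setattr__(self, "column_response", resp)

    def response(self, gantry_angle: float) -> np.ndarray:
        """Per-column response (32,) at a gantry angle in [0, 360)."""
        a = float(gantry_angle) % 360.0
        if a > 180.0:
            a = 360.0 - a
        out = np.empty(N_COLS)
        for j in range(N_COLS):
            out[j] = np.interp(a, self.anchor_angles, self.column_response[j])
        return out

    def central_response(self, gantry_angle: float) -> float:
        """Mean response of the two central columns (16, 17)."""
        r = self.response(gantry_angle)
        return float((r[15] + r[16]) / 2.0)


# Control points of the packaged response curves.  Central-curve extrema are
# the device's printed over/under-responses (6%/4% over at 90 deg, 15%/11%
# under at 92 deg, 8%/5% under at 180 deg for 6/10 MV); the spread amplitude
# A peaks at 7%/6% near 92 deg and stays small elsewhere.  Intermediate
# values are smooth monotone fill-in, not device-measured numbers.
_CTRL_ANGLES = np.array(
    [0, 10, 20, 30, 40, 50, 60, 70, 80, 90, 91, 92, 93, 95, 100, 105, 110, 120, 140, 160, 180],
    dtype=float,
)
_CENTRAL_CURVE = {
    "6MV": np.array(
        [1.000, 0.999, 0.998, 0.997, 0.996, 0.995, 0.994, 0.993, 0.992,
         1.060, 0.950, 0.850, 0.865, 0.890, 0.925, 0.945, 0.955,
         0.952, 0.944, 0.932, 0.920]
    ),
    "10MV": np.array(
        [1.000, 0.9995, 0.999, 0.9985, 0.998, 0.9975, 0.997, 0.9965, 0.996,
         1.040, 0.960, 0.890, 0.901, 0.920, 0.945, 0.958, 0.965,
         0.9635, 0.960, 0.9555, 0.950]
    ),
}
_SPREAD_AMPLITUDE = {
    "6MV": np.array(
        [0.000, 0.006, 0.008, 0.010, 0.012, 0.014, 0.016, 0.018, 0.030,
         0.050, 0.060, 0.070, 0.065, 0.055, 0.040, 0.030, 0.025,
         0.020, 0.018, 0.016, 0.015]
    ),
    "10MV": np.array(
        [0.000, 0.006, 0.007, 0.009, 0.011, 0.012, 0.014, 0.016, 0.025,
         0.045, 0.052, 0.060, 0.056, 0.048, 0.035, 0.026, 0.022,
         0.018, 0.016, 0.014, 0.013]
    ),
}


def default_response_model(energy: str, noise_sigma: float = 0.003) -> AngularResponseModel:
    """The packaged angular response profile for ``energy`` in {6MV, 10MV}.

    The central-column curve is anchored at unity at 0 degrees, rises to the
    device's reported over-response with the beam edge-on at 90 degrees,
    drops sharply to the reported under-response at 92 degrees, recovers,
    and declines smoothly to the reported under-response at 180 degrees.
    Outer columns are offset by a linear cross-array ramp whose amplitude
    peaks near 92 degrees, so the central-vs-off-axis spread is largest in
    the lateral window.  Anchors sit on the calibration angle grid.
    """
    if energy not in ENERGIES:
        raise ValidationError(f"unknown energy {energy!r}; expected one of {ENERGIES}")
    anchors = calibration_angles()
    central = np.interp(anchors, _CTRL_ANGLES, _CENTRAL_CURVE[energy])
    amp = np.interp(anchors, _CTRL_ANGLES, _SPREAD_AMPLITUDE[energy])
    w = (np.arange(1, N_COLS + 1) - 16.5) / 15.5  # -1 at j=1 .. +1 at j=32
    resp = central[None, :] * (1.0 + w[:, None] * amp[None, :])
    return AngularResponseModel(
        energy=energy, anchor_angles=anchors, column_response=resp, noise_sigma=noise_sigma
    )


def simulate_measurement(
    plan: PlanSpec,
    model: AngularResponseModel,
    grid: DetectorGrid | None = None,
    phantom: Phantom | None = None,
    seed: int | None = 0,
    *,
    frames_per_beam: int = 5,
    arc_step: float = 2.0,
    noise_sigma: float | None = None,
    **model_kw,
) -> DoseMovie:
    """Movie-mode acquisition of a plan through the angular response model.

    Each static beam is split into ``frames_per_beam`` snapshots at its
    gantry angle; arcs are discretised at ``arc_step`` degrees per frame.
    Frame readings are the true dose fraction times the column response
    R_j(theta) times multiplicative Gaussian noise (1 + eps),
    eps ~ N(0, noise_sigma), independent per chamber and frame.  Seeded and
    bit-reproducible.
    """
    grid = grid or DetectorGrid()
    if noise_sigma is None:
        noise_sigma = model.noise_sigma
    rng = np.random.default_rng(seed)
    frames: list[DoseFrame] = []
    for beam in plan.beams:
        if beam.is_arc:
            angles = beam.arc_angles(arc_step)
        else:
            angles = np.full(frames_per_beam, beam.gantry_angle)
        n = len(angles)
        for a in angles:
            true = true_dose_plane(beam, grid, phantom, gantry_angle=float(a), **model_kw)
            reading = true.values / n * model.response(float(a))[None, :]
            if noise_sigma > 0:
                reading = reading * (1.0 + rng.normal(0.0, noise_sigma, size=reading.shape))
            reading = np.clip(reading, 0.0, None)
            frames.append(
                DoseFrame(dose=reading, gantry_angle=float(a), duration=plan.frame_duration)
            )
    return DoseMovie(frames)


#: calibration field size, cm (cross-line x in-line)
CALIBRATION_FIELD = (30.0, 10.0)


def reference_at_detectors(
    energy: str,
    grid: DetectorGrid | None = None,
    phantom: Phantom | None = None,
    angles: np.ndarray | None = None,
    **model_kw,
) -> dict[float, DosePlane]:
    """Per-angle noiseless reference doses for correction-factor derivation.

    Wraps :func:`true_dose_plane` with the 30 x 10 cm calibration field over
    the calibration angle grid; the stand-in for the treatment-planning
    Monte-Carlo reference.
    """
    if angles is None:
        angles = calibration_angles()
    beam = BeamSpec(energy=energy, field_size=CALIBRATION_FIELD, gantry_angle=0.0)
    return {
        float(a): true_dose_plane(beam, grid, phantom, gantry_angle=float(a), **model_kw)
        for a in angles
    }


def calibration_measurement(
    energy: str,
    model: AngularResponseModel,
    grid: DetectorGrid | None = None,
    phantom: Phantom | None = None,
    angles: np.ndarray | None = None,
    noise_sigma: float = 0.0,
    seed: int | None = 0,
    **model_kw,
) -> dict[float, DoseFrame]:
    """Simulated array readings of the calibration run, one frame per angle.

    Noiseless by default so that correction factors can be derived exactly;
    set ``noise_sigma`` for a realistic run.
    """
    if angles is None:
        angles = calibration_angles()
    rng = np.random.default_rng(seed)
    beam = BeamSpec(energy=energy, field_size=CALIBRATION_FIELD, gantry_angle=0.0)
    out: dict[float, DoseFrame] = {}
    for a in angles:
        true = true_dose_plane(beam, grid, phantom, gantry_angle=float(a), **model_kw)
        reading = true.values * model.response(float(a))[None, :]
        if noise_sigma > 0:
            reading = reading * (1.0 + rng.normal(0.0, noise_sigma, size=reading.shape))
        out[float(a)] = DoseFrame(dose=np.clip(reading, 0.0, None), gantry_angle=float(a))
    return out
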