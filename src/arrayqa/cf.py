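"""Gantry-angle-dependent correction factors: derivation and application.

A correction factor CF_j(theta) is the ratio of the array-measured dose to
the reference (calculated) dose at gantry angle theta, normalised so every
curve equals 1 at theta = 0.  Corrected dose = reading / CF.  Two
application schemes exist:

* ``central`` — the central-detector CF is applied to every chamber;
* ``entire`` — each column's own CF (from the central rows 16-17 of that
  column) is applied to all rows of that column.

Angles past 180 degrees are folded by the mirror assumption
CF(theta) = CF(360 - theta); between calibration angles the curves are
piecewise-linear.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .array_model import (
    CENTRAL_COLS,
    CENTRAL_ROWS,
    DoseFrame,
    DoseMovie,
    DosePlane,
    N_COLS,
    accumulate,
)
from .errors import ValidationError

SCHEMES = ("central", "entire", "none")


@dataclass(frozen=True)
class CorrectionScheme:
    """Which correction to apply: ``central``, ``entire``, or ``none``."""

    mode: str = "entire"

    def __post_init__(self) -> None:
        if self.mode not in SCHEMES:
            raise ValidationError(f"scheme must be one of {SCHEMES}")


def _as_scheme(scheme) -> str:
    if isinstance(scheme, CorrectionScheme):
        return scheme.mode
    return CorrectionScheme(str(scheme)).mode


@dataclass(frozen=True)
class CFTable:
    """Correction factors on the calibration angle grid.

    ``angles`` are strictly increasing degrees in [0, 180] including 0;
    ``central_cf`` (n,) is the central-detector curve; ``column_cf``
    (32, n) holds one curve per column j (rows 16-17 averaged).
    ``normalization`` records the factors N (central) and N_j (per column)
    that scaled the raw measured/reference ratios to 1 at 0 degrees.
    """

    energy: str
    angles: np.ndarray
    central_cf: np.ndarray
    column_cf: np.ndarray
    normalization: dict

    def __post_init__(self) -> None:
        ang = np.asarray(self.angles, dtype=float)
        cen = np.asarray(self.central_cf, dtype=float)
        col = np.asarray(self.column_cf, dtype=float)
        if ang.ndim != 1 or np.any(np.diff(ang) <= 0):
            raise ValidationError("angles must be strictly increasing")
        if ang[0] < 0 or ang[-1] > 180:
            raise ValidationError("angles must lie in [0, 180]")
        if not np.any(np.isclose(ang, 0.0)):
            raise ValidationError("the normalisation angle 0 must be in the table")
        if cen.shape != ang.shape:
            raise ValidationError("central_cf must match angles")
        if col.shape != (N_COLS, ang.size):
            raise ValidationError("column_cf must be 32 x n_angles")
        if np.any(cen <= 0) or np.any(col <= 0):
            raise ValidationError("correction factors must be positive")
        i0 = int(np.argmin(np.abs(ang)))
        if abs(cen[i0] - 1.0) > 1e-9 or np.max(np.abs(col[:, i0] - 1.0)) > 1e-9:
            raise ValidationError("correction factors must equal 1 at 0 degrees")
        object.__setattr__(self, "angles", ang)
        object.__setattr__(self, "central_cf", cen)
        object.__setattr__(self, "column_cf", col)

    @property
    def n_angles(self) -> int:
        return self.angles.size


def _dose_array(obj) -> np.ndarray:
    if isinstance(obj, DoseFrame):
        return obj.dose
    if isinstance(obj, DosePlane):
        return obj.values
    return np.asarray(obj, dtype=float)


def _column_pair_means(dose: np.ndarray) -> np.ndarray:
    """Mean over the central rows 16-17 for each column (32,)."""
    return dose[CENTRAL_ROWS[0] - 1 : CENTRAL_ROWS[1], :].mean(axis=0)


def _central_mean(dose: np.ndarray) -> float:
    return float(
        dose[CENTRAL_ROWS[0] - 1 : CENTRAL_ROWS[1], CENTRAL_COLS[0] - 1 : CENTRAL_COLS[1]].mean()
    )


def derive_cf(
    measured: Mapping[float, "DoseFrame | np.ndarray"],
    reference: Mapping[float, "DoseFrame | DosePlane | np.ndarray"],
    energy: str,
) -> CFTable:
    """Derive a correction-factor table from per-angle measured/reference doses.

    For each calibration angle and column j, the raw ratio is
    mean(measured rows 16-17, column j) / mean(reference rows 16-17,
    column j); the central ratio uses the four central chambers.  Each curve
    is then scaled by its normalisation factor N so it equals 1 at 0
    degrees.

    ``measured`` and ``reference`` map gantry angle (deg) to 32x32 doses;
    both must cover the same angle set, including 0.
    """
    m_angles = sorted(float(a) for a in measured)
    r_angles = sorted(float(a) for a in reference)
    if not np.allclose(m_angles, r_angles):
        raise ValidationError("measured and reference must cover the same angles")
    angles = np.asarray(m_angles, dtype=float)
    if not np.any(np.isclose(angles, 0.0)):
        raise ValidationError("cannot normalise: angle 0 missing from the calibration set")

    n = angles.size
    col_ratio = np.empty((N_COLS, n))
    cen_ratio = np.empty(n)
    m_by = {float(a): v for a, v in measured.items()}
    r_by = {float(a): v for a, v in reference.items()}
    for k, a in enumerate(angles):
        md = _dose_array(m_by[a])
        rd = _dose_array(r_by[a])
        if np.any(_column_pair_means(rd) <= 0) or _central_mean(rd) <= 0:
            raise ValidationError(f"reference dose must be positive at angle {a}")
        col_ratio[:, k] = _column_pair_means(md) / _column_pair_means(rd)
        cen_ratio[k] = _central_mean(md) / _central_mean(rd)

    i0 = int(np.argmin(np.abs(angles)))
    if np.any(col_ratio[:, i0] <= 0) or cen_ratio[i0] <= 0:
        raise ValidationError("measured dose at 0 degrees must be positive")
    n_col = 1.0 / col_ratio[:, i0]
    n_cen = 1.0 / cen_ratio[i0]
    table = CFTable(
        energy=energy,
        angles=angles,
        central_cf=cen_ratio * n_cen,
        column_cf=col_ratio * n_col[:, None],
        normalization={"central": n_cen, "column": n_col.tolist()},
    )
    return table


def _fold_angle(angle: float) -> float:
    a = float(angle)
    if not 0.0 <= a < 360.0:
        warnings.warn(
            f"gantry angle {angle} outside [0, 360); normalised modulo 360",
            stacklevel=3,
        )
        a = a % 360.0
    if a > 180.0:
        a = 360.0 - a
    return a


def cf_central_at(table: CFTable, gantry_angle: float) -> float:
    """Central-detector CF at any gantry angle (mirror-folded, interpolated)."""
    a = _fold_angle(gantry_angle)
    return float(np.interp(a, table.angles, table.central_cf))


def cf_at(table: CFTable, j: int, gantry_angle: float) -> float:
    """Column-j CF at any gantry angle in [0, 360).

    Angles past 180 are mapped to 360 - theta (mirror assumption); between
    calibration angles the curve is piecewise-linear and exact at grid
    angles.
    """
    if not 1 <= j <= N_COLS:
        raise IndexError(f"column {j} out of range 1..32")
    a = _fold_angle(gantry_angle)
    return float(np.interp(a, table.angles, table.column_cf[j - 1]))


def _column_cf_vector(table: CFTable, gantry_angle: float) -> np.ndarray:
    a = _fold_angle(gantry_angle)
    out = np.empty(N_COLS)
    for j in range(N_COLS):
        out[j] = np.interp(a, table.angles, table.column_cf[j])
    return out


def cf_difference(table: CFTable, j: int, gantry_angle: float) -> float:
    """Percent difference of column j's CF from the central CF at an angle:
    100 * (CF_j - CF_central) / CF_central."""
    cen = cf_central_at(table, gantry_angle)
    col = cf_at(table, j, gantry_angle)
    return 100.0 * (col - cen) / cen


def apply_correction(frame: DoseFrame, table: CFTable, scheme) -> DoseFrame:
    """Correct one frame for angular dependence: dose / CF(theta).

    ``central`` divides every chamber by the central-detector CF at the
    frame's gantry angle; ``entire`` divides each column by its own CF
    (broadcast over rows); ``none`` returns the frame unchanged.
    """
    mode = _as_scheme(scheme)
    if mode == "none":
        return frame
    if frame.gantry_angle is None:
        raise ValidationError("frame has no gantry angle; cannot correct")
    if mode == "central":
        cf = cf_central_at(table, frame.gantry_angle)
        corrected = frame.dose / cf
    else:  # entire
        cf = _column_cf_vector(table, frame.gantry_angle)
        corrected = frame.dose / cf[None, :]
    return DoseFrame(dose=corrected, gantry_angle=frame.gantry_angle, duration=frame.duration)


def correct_movie(movie: DoseMovie, table: CFTable, scheme) -> DoseFrame:
    """Per-frame angular correction of a movie, then cumulative sum.

    Each frame is corrected with the CF at its own tagged gantry angle, so
    arcs are corrected segment by segment; equals
    accumulate(map(apply_correction, frames)).
    """
    mode = _as_scheme(scheme)
    if mode != "none":
        for f in movie.frames:
            if f.gantry_angle is None:
                raise ValidationError("every movie frame needs a gantry angle")
    corrected = DoseMovie([apply_correction(f, table, mode) for f in movie.frames])
    return accumulate(corrected)
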