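"""Data model for a 32x32 ionization-chamber array and resampled dose planes.

The array measures a coronal dose plane inside a solid phantom.  Detector
indices follow the device convention: 1-based row ``i`` (in-line, y) and
column ``j`` (cross-line, x), with the grid centred on the beam axis so the
physical centre of the chamber layout maps to (0, 0) mm.

Movie-mode acquisitions are sequences of gantry-tagged dose snapshots
(:class:`DoseFrame` inside a :class:`DoseMovie`); composite doses are the
element-wise sum of the frames.  High-resolution calculated or resampled
distributions are carried by :class:`DosePlane`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .errors import ValidationError

N_ROWS = 32
N_COLS = 32
DEFAULT_PITCH = 7.62  # mm, centre-to-centre chamber spacing
#: 1-based indices of the central 2x2 chamber block
CENTRAL_ROWS = (16, 17)
CENTRAL_COLS = (16, 17)


def _as_dose_array(dose: Iterable, shape: tuple[int, int] | None = None) -> np.ndarray:
    arr = np.asarray(dose, dtype=float)
    if shape is not None and arr.shape != shape:
        raise ValidationError(f"dose array has shape {arr.shape}, expected {shape}")
    if arr.ndim != 2:
        raise ValidationError(f"dose array must be 2D, got ndim={arr.ndim}")
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ValidationError("dose values must be finite and non-negative")
    return arr


@dataclass(frozen=True)
class DetectorGrid:
    """Geometry of the chamber array.

    Parameters
    ----------
    n_rows, n_cols:
        Number of chamber rows/columns; the supported device is 32x32.
    pitch:
        Centre-to-centre chamber spacing in mm.
    active_mask:
        Boolean (n_rows, n_cols) array marking physically present chambers.
        Defaults to all-true; :meth:`device_mask` gives the device-faithful
        variant without the four corner chambers.
    origin:
        Physical (x, y) mm coordinate of the centre of detector (1, 1).
        Defaults so the grid centre is at (0, 0).
    """

    n_rows: int = N_ROWS
    n_cols: int = N_COLS
    pitch: float = DEFAULT_PITCH
    active_mask: np.ndarray | None = None
    origin: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n_rows != N_ROWS or self.n_cols != N_COLS:
            raise ValidationError("only the 32x32 array geometry is supported")
        if not self.pitch > 0:
            raise ValidationError("pitch must be positive")
        if self.active_mask is None:
            mask = np.ones((self.n_rows, self.n_cols), dtype=bool)
        else:
            mask = np.asarray(self.active_mask, dtype=bool)
            if mask.shape != (self.n_rows, self.n_cols):
                raise ValidationError("active_mask shape must match the grid")
            if not mask.any():
                raise ValidationError("active_mask must have at least one active chamber")
        object.__setattr__(self, "active_mask", mask)
        if self.origin is None:
            half = (self.n_cols - 1) / 2.0 * self.pitch
            object.__setattr__(self, "origin", (-half, -half))
        else:
            object.__setattr__(self, "origin", (float(self.origin[0]), float(self.origin[1])))

    @classmethod
    def device_mask(cls, pitch: float = DEFAULT_PITCH) -> "DetectorGrid":
        """Grid with the four corner chambers absent, as on the physical device."""
        mask = np.ones((N_ROWS, N_COLS), dtype=bool)
        for i in (0, N_ROWS - 1):
            for j in (0, N_COLS - 1):
                mask[i, j] = False
        return cls(pitch=pitch, active_mask=mask)

    def xs(self) -> np.ndarray:
        """x coordinates (mm) of the 32 columns."""
        return self.origin[0] + np.arange(self.n_cols) * self.pitch

    def ys(self) -> np.ndarray:
        """y coordinates (mm) of the 32 rows."""
        return self.origin[1] + np.arange(self.n_rows) * self.pitch


def detector_position(grid: DetectorGrid, i: int, j: int) -> tuple[float, float]:
    """Physical (x, y) mm centre of detector at 1-based row ``i``, column ``j``."""
    if not (1 <= i <= grid.n_rows and 1 <= j <= grid.n_cols):
        raise IndexError(f"detector index ({i}, {j}) out of range 1..32")
    x = grid.origin[0] + (j - 1) * grid.pitch
    y = grid.origin[1] + (i - 1) * grid.pitch
    return (x, y)


@dataclass(frozen=True)
class DoseFrame:
    """One movie-mode snapshot: a 32x32 dose map tagged with the gantry angle.

    ``gantry_angle`` is in degrees, normalised to [0, 360); ``None`` marks a
    cumulative frame whose angle is undefined.  ``duration`` is the snapshot
    integration time in seconds (device default 0.2 s).
    """

    dose: np.ndarray
    gantry_angle: float | None = None
    duration: float = 0.2

    def __post_init__(self) -> None:
        object.__setattr__(self, "dose", _as_dose_array(self.dose, (N_ROWS, N_COLS)))
        if self.gantry_angle is not None:
            object.__setattr__(self, "gantry_angle", float(self.gantry_angle) % 360.0)
        if not self.duration > 0:
            raise ValidationError("duration must be positive")


@dataclass(frozen=True)
class DoseMovie:
    """Ordered sequence of movie-mode frames of identical shape."""

    frames: tuple[DoseFrame, ...]

    def __init__(self, frames: Sequence[DoseFrame]):
        frames = tuple(frames)
        if len(frames) == 0:
            raise ValidationError("a movie needs at least one frame")
        shape = frames[0].dose.shape
        for f in frames:
            if f.dose.shape != shape:
                raise ValidationError("all frames must share one shape")
        object.__setattr__(self, "frames", frames)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


@dataclass(frozen=True)
class DosePlane:
    """2D dose distribution on a regular isotropic grid.

    ``values[r, c]`` lives at physical position
    ``(origin[0] + c * spacing, origin[1] + r * spacing)`` mm.
    """

    values: np.ndarray
    spacing: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", _as_dose_array(self.values))
        if not self.spacing > 0:
            raise ValidationError("spacing must be positive")
        object.__setattr__(self, "origin", (float(self.origin[0]), float(self.origin[1])))

    @property
    def xs(self) -> np.ndarray:
        return self.origin[0] + np.arange(self.values.shape[1]) * self.spacing

    @property
    def ys(self) -> np.ndarray:
        return self.origin[1] + np.arange(self.values.shape[0]) * self.spacing

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of pixel centres, mm."""
        return (self.xs[0], self.xs[-1], self.ys[0], self.ys[-1])

    def interpolator(self) -> RegularGridInterpolator:
        """Bilinear interpolator value(y, x) over the plane."""
        return RegularGridInterpolator(
            (self.ys, self.xs), self.values, method="linear", bounds_error=True
        )


def frame_to_plane(frame: DoseFrame, grid: DetectorGrid | None = None) -> DosePlane:
    """View a detector frame as a coarse dose plane at the chamber positions."""
    grid = grid or DetectorGrid()
    return DosePlane(values=frame.dose, spacing=grid.pitch, origin=grid.origin)


def accumulate(movie: DoseMovie) -> DoseFrame:
    """Element-wise cumulative dose of a movie.

    The result has no gantry angle (it mixes angles) and a duration equal to
    the summed frame durations.
    """
    total = np.zeros_like(movie.frames[0].dose)
    duration = 0.0
    for f in movie.frames:
        total = total + f.dose
        duration += f.duration
    return DoseFrame(dose=total, gantry_angle=None, duration=duration)


def _frame_dose(obj) -> np.ndarray:
    if isinstance(obj, DoseFrame):
        return obj.dose
    return _as_dose_array(obj, (N_ROWS, N_COLS))


def central_detector_dose(obj, grid: DetectorGrid | None = None) -> float:
    """Mean dose of the four central chambers (rows 16-17, columns 16-17).

    Accepts a :class:`DoseFrame` (or bare 32x32 array), or a
    :class:`DosePlane`, in which case the plane is bilinearly sampled at the
    four central chamber positions of ``grid``.
    """
    grid = grid or DetectorGrid()
    if isinstance(obj, DosePlane):
        interp = obj.interpolator()
        pts = [
            detector_position(grid, i, j)[::-1]  # (y, x)
            for i in CENTRAL_ROWS
            for j in CENTRAL_COLS
        ]
        return float(np.mean(interp(np.array(pts))))
    if not all(
        grid.active_mask[i - 1, j - 1] for i in CENTRAL_ROWS for j in CENTRAL_COLS
    ):
        raise ValidationError("central chambers are not all active")
    dose = _frame_dose(obj)
    block = dose[CENTRAL_ROWS[0] - 1 : CENTRAL_ROWS[1], CENTRAL_COLS[0] - 1 : CENTRAL_COLS[1]]
    return float(block.mean())


def offaxis_pair_dose(obj, j: int) -> float:
    """Mean dose of the two central-row chambers (rows 16-17) in column ``j``."""
    if not 1 <= j <= N_COLS:
        raise IndexError(f"column {j} out of range 1..32")
    dose = _frame_dose(obj)
    return float(dose[CENTRAL_ROWS[0] - 1 : CENTRAL_ROWS[1], j - 1].mean())


def roi_mean(
    plane: DosePlane,
    center: tuple[float, float] = (0.0, 0.0),
    side: float = 10.0,
    step: float = 0.5,
) -> float:
    """Mean dose over a square ROI, emulating a thimble-chamber cross-read.

    The plane is bilinearly interpolated on a sub-grid of pitch ``step`` mm
    covering a ``side`` x ``side`` mm square centred at ``center`` (mm).
    A 1x1 cm ROI covers the sensitive volume of the reference ion chamber.
    """
    if not side > 0 or not step > 0:
        raise ValidationError("side and step must be positive")
    cx, cy = float(center[0]), float(center[1])
    half = side / 2.0
    xmin, xmax, ymin, ymax = plane.extent
    if cx - half < xmin or cx + half > xmax or cy - half < ymin or cy + half > ymax:
        raise ValidationError("ROI extends outside the dose plane")
    n = int(round(side / step)) + 1
    offs = np.linspace(-half, half, n)
    gy, gx = np.meshgrid(cy + offs, cx + offs, indexing="ij")
    interp = plane.interpolator()
    vals = interp(np.column_stack([gy.ravel(), gx.ravel()]))
    return float(vals.mean())
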