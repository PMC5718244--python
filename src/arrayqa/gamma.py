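"""2D gamma-index evaluation between measured and calculated dose planes.

The gamma index combines a dose-difference tolerance (percent of a
normalisation dose) and a distance-to-agreement (DTA, mm) into a single
per-pixel figure; a reference pixel passes when some nearby evaluated point
agrees within the combined tolerance (gamma <= 1).  Reference pixels below
a low-dose threshold are excluded from scoring.

Note the metric is asymmetric: gamma(reference, evaluated) searches the
evaluated distribution around each reference pixel, so the two roles are
not interchangeable except at identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .array_model import DetectorGrid, DoseFrame, DosePlane, frame_to_plane
from .errors import ValidationError


@dataclass(frozen=True)
class GammaCriteria:
    """Gamma criteria: dose tolerance (% of normalisation dose), DTA (mm),
    low-dose threshold (% of the reference global maximum), normalisation
    mode, and the DTA search geometry.

    ``search_radius`` caps the spatial search (default 3 x DTA);
    ``search_step`` is the sub-sampling step of the evaluated distribution
    during the search (default DTA / 10, bilinear between pixels).
    ``normalization`` is ``"global_max"`` (reference maximum; default) or
    ``"local"`` (reference dose at each pixel; experimental).
    """

    dose_tol: float = 3.0
    dta: float = 3.0
    threshold: float = 5.0
    normalization: str = "global_max"
    search_radius: float | None = None
    search_step: float | None = None

    def __post_init__(self) -> None:
        if not self.dose_tol > 0 or not self.dta > 0:
            raise ValidationError("dose_tol and dta must be positive")
        if not 0 <= self.threshold < 100:
            raise ValidationError("threshold must be in [0, 100)")
        if self.normalization not in ("global_max", "local"):
            raise ValidationError("normalization must be 'global_max' or 'local'")
        if self.search_radius is None:
            object.__setattr__(self, "search_radius", 3.0 * self.dta)
        if self.search_step is None:
            object.__setattr__(self, "search_step", self.dta / 10.0)
        if not self.search_radius > 0 or not self.search_step > 0:
            raise ValidationError("search_radius and search_step must be positive")


@dataclass(frozen=True)
class GammaResult:
    """Gamma map (NaN where excluded), evaluated mask, pass rate (percent of
    evaluated pixels with gamma <= 1; NaN when nothing is evaluated), and
    the criteria used."""

    gamma_map: np.ndarray
    evaluated_mask: np.ndarray
    pass_rate: float
    criteria: GammaCriteria

    @property
    def n_evaluated(self) -> int:
        return int(self.evaluated_mask.sum())


def _to_plane(obj, grid: DetectorGrid | None = None) -> DosePlane:
    if isinstance(obj, DoseFrame):
        return frame_to_plane(obj, grid)
    if isinstance(obj, DosePlane):
        return obj
    raise ValidationError("expected a DosePlane or DoseFrame")


def resample_to_common_grid(
    a, b, pixel: float = 1.0, grid: DetectorGrid | None = None
) -> tuple[DosePlane, DosePlane]:
    """Bilinearly resample two distributions onto one isotropic grid.

    The common grid covers the intersection of the two extents at ``pixel``
    mm spacing (default 1 mm).  A :class:`DoseFrame` input is first viewed
    as a coarse plane at the chamber positions.
    """
    pa, pb = _to_plane(a, grid), _to_plane(b, grid)
    ax0, ax1, ay0, ay1 = pa.extent
    bx0, bx1, by0, by1 = pb.extent
    x0, x1 = max(ax0, bx0), min(ax1, bx1)
    y0, y1 = max(ay0, by0), min(ay1, by1)
    if x1 - x0 <= 0 or y1 - y0 <= 0:
        raise ValidationError("dose planes do not overlap")
    nx = int(math.floor((x1 - x0) / pixel)) + 1
    ny = int(math.floor((y1 - y0) / pixel)) + 1
    xs = x0 + np.arange(nx) * pixel
    ys = y0 + np.arange(ny) * pixel
    gy, gx = np.meshgrid(ys, xs, indexing="ij")
    pts = np.column_stack([gy.ravel(), gx.ravel()])
    out = []
    for p in (pa, pb):
        vals = p.interpolator()(pts).reshape(ny, nx)
        out.append(DosePlane(values=np.clip(vals, 0.0, None), spacing=pixel, origin=(x0, y0)))
    return out[0], out[1]


def gamma_map(
    reference: DosePlane, evaluated: DosePlane, criteria: GammaCriteria
) -> GammaResult:
    """Gamma index of ``evaluated`` against ``reference`` on a shared grid.

    For each reference pixel r above the threshold,

        gamma(r) = min over e within search_radius of
                   sqrt((D_eval(e) - D_ref(r))^2 / dD^2 + |r - e|^2 / dta^2)

    with dD = dose_tol percent of the normalisation dose.  The evaluated
    distribution is sampled on a sub-grid of step ``search_step`` with
    bilinear interpolation; positions outside the evaluated grid are
    skipped, so boundary pixels face a clipped neighbourhood.
    """
    if reference.values.shape != evaluated.values.shape:
        raise ValidationError("planes must share one grid; resample first")
    if abs(reference.spacing - evaluated.spacing) > 1e-9 or not np.allclose(
        reference.origin, evaluated.origin
    ):
        raise ValidationError("planes must share one grid; resample first")

    ref = reference.values
    ev = evaluated.values
    spacing = reference.spacing
    ref_max = float(ref.max())
    if ref_max <= 0:
        raise ValidationError("reference plane is empty")
    mask = ref >= criteria.threshold / 100.0 * ref_max
    gamma = np.full(ref.shape, np.nan)
    if not mask.any():
        return GammaResult(gamma_map=gamma, evaluated_mask=mask, pass_rate=float("nan"),
                           criteria=criteria)

    if criteria.normalization == "global_max":
        dd = criteria.dose_tol / 100.0 * ref_max
        dd_sq = np.full(ref.shape, dd * dd)
    else:  # local
        dd = criteria.dose_tol / 100.0 * ref
        with np.errstate(divide="ignore"):
            dd_sq = np.where(ref > 0, dd * dd, np.inf)

    # offsets of the DTA search, sorted by distance for early termination
    nstep = int(math.floor(criteria.search_radius / criteria.search_step))
    offs = np.arange(-nstep, nstep + 1) * criteria.search_step
    oy, ox = np.meshgrid(offs, offs, indexing="ij")
    d2 = oy**2 + ox**2
    keep = d2 <= criteria.search_radius**2 + 1e-12
    order = np.argsort(d2[keep], kind="stable")
    off_y = oy[keep][order]
    off_x = ox[keep][order]
    dist2 = d2[keep][order]

    ny, nx = ref.shape
    iy, ix = np.nonzero(mask)
    ref_m = ref[mask]
    dd_sq_m = dd_sq[mask]
    best = np.full(ref_m.shape, np.inf)
    dta2 = criteria.dta**2
    for dy, dx, r2 in zip(off_y, off_x, dist2):
        spatial = r2 / dta2
        if spatial >= best.max():
            break  # no pixel can improve: offsets are distance-sorted
        cy = iy + dy / spacing
        cx = ix + dx / spacing
        vals = ndimage.map_coordinates(
            ev, np.vstack([cy, cx]), order=1, mode="constant", cval=np.nan
        )
        cand = (vals - ref_m) ** 2 / dd_sq_m + spatial
        np.fmin(best, cand, out=best)  # fmin ignores NaN candidates
    gamma[mask] = np.sqrt(best)
    finite = np.isfinite(gamma[mask])
    passing = (gamma[mask] <= 1.0) & finite
    pass_rate = 100.0 * passing.sum() / mask.sum()
    return GammaResult(gamma_map=gamma, evaluated_mask=mask, pass_rate=float(pass_rate),
                       criteria=criteria)


def pass_rate_report(results, labels=None) -> pd.DataFrame:
    """Tabulate pass rates of several gamma results.

    Returns a DataFrame with one row per result in input order, columns
    ``label, dose_tol, dta, threshold, n_evaluated, pass_rate`` —
    serialisable to CSV for plan-by-plan summaries.
    """
    results = list(results)
    if not results:
        raise ValidationError("need at least one result")
    if labels is None:
        labels = [f"result_{k}" for k in range(len(results))]
    labels = list(labels)
    if len(labels) != len(results):
        raise ValidationError("labels must match results")
    rows = [
        {
            "label": lab,
            "dose_tol": r.criteria.dose_tol,
            "dta": r.criteria.dta,
            "threshold": r.criteria.threshold,
            "n_evaluated": r.n_evaluated,
            "pass_rate": r.pass_rate,
        }
        for lab, r in zip(labels, results)
    ]
    return pd.DataFrame(rows, columns=["label", "dose_tol", "dta", "threshold",
                                       "n_evaluated", "pass_rate"])
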