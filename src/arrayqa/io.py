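"""Readers and writers for the package's text formats.

All files are JSON (plans may also be YAML) with a ``format_version`` field.
Dose values are serialised in cGy rounded to 6 significant digits;
correction-factor tables keep full float precision so a table round-trips
bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .array_model import DoseFrame, DoseMovie, DosePlane
from .cf import CFTable
from .errors import ValidationError
from .synthetic import BeamSpec, PlanSpec

FORMAT_VERSION = "1.0"


def _q6(x: float) -> float:
    """Round to 6 significant digits (dose serialisation precision)."""
    return float(f"{float(x):.6g}")


def _q6_grid(a: np.ndarray) -> list:
    return [[_q6(v) for v in row] for row in np.asarray(a, dtype=float)]


def _check_version(doc: dict, path) -> None:
    if "format_version" not in doc:
        raise ValidationError(f"{path}: missing format_version")


def _load_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _dump_json(doc: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------- movies

def write_movie(movie: DoseMovie, path, energy: str | None = None) -> None:
    doc = {
        "format_version": FORMAT_VERSION,
        "type": "movie",
        "energy": energy,
        "frames": [
            {
                "gantry_angle": None if f.gantry_angle is None else _q6(f.gantry_angle),
                "duration": _q6(f.duration),
                "dose": _q6_grid(f.dose),
            }
            for f in movie.frames
        ],
    }
    _dump_json(doc, path)


def read_movie(path) -> DoseMovie:
    doc = _load_json(path)
    _check_version(doc, path)
    if doc.get("type") != "movie":
        raise ValidationError(f"{path}: not a movie file")
    frames = [
        DoseFrame(
            dose=np.asarray(f["dose"], dtype=float),
            gantry_angle=f.get("gantry_angle"),
            duration=f.get("duration", 0.2),
        )
        for f in doc["frames"]
    ]
    return DoseMovie(frames)


def write_frame(frame: DoseFrame, path, energy: str | None = None) -> None:
    """Single-frame convenience wrapper around the movie format."""
    write_movie(DoseMovie([frame]), path, energy=energy)


# ---------------------------------------------------------------- planes

def write_plane(plane: DosePlane, path) -> None:
    doc = {
        "format_version": FORMAT_VERSION,
        "type": "plane",
        "spacing": float(plane.spacing),
        "origin": [float(plane.origin[0]), float(plane.origin[1])],
        "values": _q6_grid(plane.values),
    }
    _dump_json(doc, path)


def read_plane(path) -> DosePlane:
    doc = _load_json(path)
    _check_version(doc, path)
    if doc.get("type") != "plane":
        raise ValidationError(f"{path}: not a plane file")
    return DosePlane(
        values=np.asarray(doc["values"], dtype=float),
        spacing=doc["spacing"],
        origin=tuple(doc["origin"]),
    )


# ---------------------------------------------------------------- CF tables

def write_cf_table(table: CFTable, path) -> None:
    """Write a CF table; float values keep full precision (bit-exact
    round-trip through :func:`read_cf_table`)."""
    doc = {
        "format_version": FORMAT_VERSION,
        "type": "cf_table",
        "energy": table.energy,
        "normalization_angle": 0.0,
        "normalization": table.normalization,
        "angles": table.angles.tolist(),
        "central_cf": table.central_cf.tolist(),
        "column_cf": table.column_cf.tolist(),
    }
    _dump_json(doc, path)


def read_cf_table(path) -> CFTable:
    doc = _load_json(path)
    _check_version(doc, path)
    if doc.get("type") != "cf_table":
        raise ValidationError(f"{path}: not a CF table file")
    return CFTable(
        energy=doc["energy"],
        angles=np.asarray(doc["angles"], dtype=float),
        central_cf=np.asarray(doc["central_cf"], dtype=float),
        column_cf=np.asarray(doc["column_cf"], dtype=float),
        normalization=doc.get("normalization", {}),
    )


# ---------------------------------------------------------------- plans

def _beam_to_dict(beam: BeamSpec) -> dict[str, Any]:
    d: dict[str, Any] = {
        "energy": beam.energy,
        "field_size": list(beam.field_size),
        "weight": beam.weight,
    }
    if beam.is_arc:
        start, stop, direction = beam.arc
        d["arc"] = {"start": start, "stop": stop, "direction": direction}
    else:
        d["gantry_angle"] = beam.gantry_angle
    return d


def _beam_from_dict(d: dict) -> BeamSpec:
    kw: dict[str, Any] = {
        "energy": d.get("energy", "6MV"),
        "field_size": d.get("field_size", (10.0, 10.0)),
        "weight": d.get("weight", 1.0),
    }
    if isinstance(kw["field_size"], (int, float)):
        kw["field_size"] = (float(kw["field_size"]), float(kw["field_size"]))
    else:
        kw["field_size"] = tuple(kw["field_size"])
    if "arc" in d:
        a = d["arc"]
        kw["arc"] = (a["start"], a["stop"], a.get("direction", "cw"))
    else:
        kw["gantry_angle"] = d["gantry_angle"]
    return BeamSpec(**kw)


def write_plan(plan: PlanSpec, path) -> None:
    doc = {
        "format_version": FORMAT_VERSION,
        "type": "plan",
        "frame_duration": plan.frame_duration,
        "beams": [_beam_to_dict(b) for b in plan.beams],
    }
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)
    else:
        _dump_json(doc, path)


def read_plan(path) -> PlanSpec:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = _load_json(path)
    _check_version(doc, path)
    if doc.get("type") != "plan":
        raise ValidationError(f"{path}: not a plan file")
    beams = [_beam_from_dict(b) for b in doc["beams"]]
    return PlanSpec(beams, frame_duration=doc.get("frame_duration", 0.2))


# ---------------------------------------------------------------- DICOM (optional)

def read_rtdose_plane(path, plane_index: int | None = None) -> DosePlane:
    """Extract one plane of a DICOM RT-Dose grid as a :class:`DosePlane`.

    Requires ``pydicom`` (optional dependency).  For a 3D dose grid the
    plane at ``plane_index`` along the frame axis is taken (middle frame by
    default); a 2D grid is used directly.  Pixel spacing must be isotropic
    in-plane.  Dose is converted to cGy assuming the DICOM DoseUnits of GY.
    """
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover
        raise ImportError("read_rtdose_plane requires pydicom") from exc
    ds = pydicom.dcmread(path)
    arr = ds.pixel_array * float(getattr(ds, "DoseGridScaling", 1.0))
    if arr.ndim == 3:
        k = arr.shape[0] // 2 if plane_index is None else plane_index
        arr = arr[k]
    spacing = [float(v) for v in ds.PixelSpacing]
    if abs(spacing[0] - spacing[1]) > 1e-6:
        raise ValidationError("anisotropic in-plane pixel spacing is unsupported")
    ipp = [float(v) for v in getattr(ds, "ImagePositionPatient", [0, 0, 0])]
    scale = 100.0 if str(getattr(ds, "DoseUnits", "GY")).upper() == "GY" else 1.0
    return DosePlane(values=np.asarray(arr, dtype=float) * scale,
                     spacing=spacing[0], origin=(ipp[0], ipp[1]))
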