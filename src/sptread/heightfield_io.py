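"""Reading and writing of height-map grids and wheal-measurement reports.

A height map is a regular grid of surface elevations in millimetres with a
square pixel pitch. Supported on-disk formats:

* single-channel 32-bit float TIFF (pitch stored in the image description
  and in the resolution tags),
* plain CSV grids (one row per grid row, ``nan`` for invalid cells),
* ASCII vertex-only PLY whose vertices lie on a regular grid (one vertex
  per valid cell).

Invalid cells are NaN on disk and carried as a boolean validity mask in
memory.
"""

from __future__ import annotations

import csv
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = [
    "HeightField",
    "read_heightfield",
    "write_heightfield",
    "write_report",
    "read_report",
]


@dataclass
class HeightField:
    """Regular grid of surface elevations in mm.

    Parameters
    ----------
    heights : ndarray of shape (rows, cols)
        Elevations in mm. Cells flagged invalid may hold NaN.
    pitch : float
        Grid spacing in mm per pixel (square pixels).
    origin : (float, float)
        Physical (x, y) position in mm of the grid cell ``[0, 0]``.
        x runs along columns, y along rows.
    mask : ndarray of bool, optional
        Per-cell validity. Defaults to all-valid; non-finite cells are
        marked invalid automatically.
    """

    heights: np.ndarray
    pitch: float
    origin: tuple[float, float] = (0.0, 0.0)
    mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2 or self.heights.size == 0:
            raise ValueError("heights must be a non-empty 2D grid")
        if not (self.pitch > 0):
            raise ValueError(f"pitch must be positive, got {self.pitch}")
        self.origin = (float(self.origin[0]), float(self.origin[1]))
        finite = np.isfinite(self.heights)
        if self.mask is None:
            self.mask = finite
        else:
            self.mask = np.asarray(self.mask, dtype=bool) & finite
        if self.mask.shape != self.heights.shape:
            raise ValueError("mask shape must match heights shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    def x_coords(self) -> np.ndarray:
        """Physical x (mm) of every column."""
        return self.origin[0] + np.arange(self.shape[1]) * self.pitch

    def y_coords(self) -> np.ndarray:
        """Physical y (mm) of every row."""
        return self.origin[1] + np.arange(self.shape[0]) * self.pitch

    def copy_with(self, heights: np.ndarray) -> "HeightField":
        """New field with the same geometry and mask but different heights."""
        return HeightField(heights, self.pitch, self.origin, self.mask.copy())


# ---------------------------------------------------------------------------
# readers


def read_heightfield(path: str | os.PathLike, pitch_mm: float | None = None) -> HeightField:
    """Read a height field from TIFF, CSV or gridded PLY.

    ``pitch_mm`` is used when the file carries no pitch metadata (CSV
    always, TIFF without tags). Non-finite cells become mask-invalid.
    """
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".tif", ".tiff"):
        return _read_tiff(path, pitch_mm)
    if ext == ".csv":
        return _read_csv(path, pitch_mm)
    if ext == ".ply":
        return _read_ply(path, pitch_mm)
    raise ValueError(f"unknown height-field format: {ext!r}")


def _read_tiff(path, pitch_mm):
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        heights = page.asarray().astype(float)
        pitch = None
        origin = (0.0, 0.0)
        desc = page.description
        if desc:
            try:
                meta = json.loads(desc)
                pitch = float(meta.get("pitch_mm"))
                origin = tuple(meta.get("origin_mm", (0.0, 0.0)))
            except (ValueError, TypeError):
                pitch = None
        if pitch is None:
            tags = page.tags
            if "XResolution" in tags and tags.get("ResolutionUnit") is not None:
                num, den = tags["XResolution"].value
                unit = tags["ResolutionUnit"].value
                px_per_unit = num / den
                if px_per_unit > 0:
                    if getattr(unit, "value", unit) == 3:  # centimetre
                        pitch = 10.0 / px_per_unit
                    elif getattr(unit, "value", unit) == 2:  # inch
                        pitch = 25.4 / px_per_unit
    if pitch is None:
        pitch = pitch_mm
    if pitch is None:
        raise ValueError("pitch unavailable from TIFF metadata and no pitch_mm given")
    return HeightField(heights, pitch, origin)


def _read_csv(path, pitch_mm):
    if pitch_mm is None:
        raise ValueError("CSV grids carry no pitch metadata; pitch_mm is required")
    rows = []
    with open(path, newline="") as fh:
        for rec in csv.reader(fh):
            if not rec:
                continue
            rows.append([float(v) if v.strip() else math.nan for v in rec])
    if not rows:
        raise ValueError(f"empty CSV grid: {path}")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError(f"ragged CSV rows in {path}")
    return HeightField(np.array(rows, dtype=float), pitch_mm)


def _read_ply(path, pitch_mm):
    xs, ys, zs = _parse_ply_vertices(path)
    if xs.size == 0:
        raise ValueError(f"empty PLY: {path}")
    pitch, x0 = _grid_axis(xs)
    pitch_y, y0 = _grid_axis(ys)
    if pitch is None and pitch_y is None:
        # single row AND single column would mean one point
        pitch = pitch_mm
        pitch_y = pitch_mm
    pitch = pitch if pitch is not None else pitch_y
    pitch_y = pitch_y if pitch_y is not None else pitch
    if pitch is None:
        raise ValueError("cannot infer pitch from PLY and no pitch_mm given")
    if not math.isclose(pitch, pitch_y, rel_tol=1e-6):
        raise ValueError("PLY grid pixels are not square")
    cols = np.rint((xs - x0) / pitch).astype(int)
    rows = np.rint((ys - y0) / pitch).astype(int)
    if (np.abs(xs - (x0 + cols * pitch)) > 1e-6 * pitch + 1e-9).any() or (
        np.abs(ys - (y0 + rows * pitch)) > 1e-6 * pitch + 1e-9
    ).any():
        raise ValueError("PLY vertices are not on a regular grid (scattered clouds unsupported)")
    grid = np.full((rows.max() + 1, cols.max() + 1), np.nan)
    grid[rows, cols] = zs
    return HeightField(grid, pitch, origin=(x0, y0))


def _grid_axis(values: np.ndarray):
    """Grid spacing and origin along one axis; spacing None if degenerate."""
    uniq = np.unique(values)
    if uniq.size < 2:
        return None, float(uniq[0])
    diffs = np.diff(uniq)
    return float(diffs.min()), float(uniq[0])


def _parse_ply_vertices(path):
    with open(path) as fh:
        if fh.readline().strip() != "ply":
            raise ValueError(f"not a PLY file: {path}")
        n_vertices = None
        props = []
        in_vertex = False
        for line in fh:
            tok = line.split()
            if not tok:
                continue
            if tok[0] == "format" and tok[1] != "ascii":
                raise ValueError("only ASCII PLY is supported")
            if tok[0] == "element":
                in_vertex = tok[1] == "vertex"
                if in_vertex:
                    n_vertices = int(tok[2])
            elif tok[0] == "property" and in_vertex:
                props.append(tok[2])
            elif tok[0] == "end_header":
                break
        if n_vertices is None:
            raise ValueError("PLY has no vertex element")
        idx = {p: i for i, p in enumerate(props)}
        for ax in ("x", "y", "z"):
            if ax not in idx:
                raise ValueError(f"PLY vertex element lacks property {ax!r}")
        data = np.loadtxt(fh, max_rows=n_vertices, ndmin=2)
    return data[:, idx["x"]], data[:, idx["y"]], data[:, idx["z"]]


# ---------------------------------------------------------------------------
# writers


def write_heightfield(fieldobj: HeightField, path: str | os.PathLike) -> str:
    """Write a height field; format chosen by extension (.tif/.tiff, .csv, .ply).

    Invalid cells are stored as NaN (TIFF/CSV) or omitted (PLY, which emits
    one vertex per valid cell at its physical (x, y, z) mm position).
    """
    ext = os.path.splitext(str(path))[1].lower()
    data = fieldobj.heights.copy()
    data[~fieldobj.mask] = np.nan
    if ext in (".tif", ".tiff"):
        meta = {"pitch_mm": fieldobj.pitch, "origin_mm": list(fieldobj.origin)}
        px_per_cm = 10.0 / fieldobj.pitch
        tifffile.imwrite(
            path,
            data.astype(np.float32),
            description=json.dumps(meta),
            resolution=(px_per_cm, px_per_cm),
            resolutionunit="CENTIMETER",
        )
    elif ext == ".csv":
        np.savetxt(path, data, delimiter=",", fmt="%.8g")
    elif ext == ".ply":
        _write_ply(fieldobj, data, path)
    else:
        raise ValueError(f"unsupported height-field format: {ext!r}")
    return str(path)


def _write_ply(fieldobj, data, path):
    rows, cols = np.nonzero(fieldobj.mask)
    xs = fieldobj.origin[0] + cols * fieldobj.pitch
    ys = fieldobj.origin[1] + rows * fieldobj.pitch
    zs = data[rows, cols]
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"comment pitch_mm {fieldobj.pitch:.9g}\n")
        fh.write(f"element vertex {len(xs)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("end_header\n")
        for x, y, z in zip(xs, ys, zs):
            fh.write(f"{x:.9g} {y:.9g} {z:.9g}\n")


# ---------------------------------------------------------------------------
# measurement reports

_REPORT_FIELDS = (
    "id",
    "center_x_mm",
    "center_y_mm",
    "diameter_mm",
    "model_kind",
    "positive",
    "rms_residual_mm",
    "converged",
    "fallback_used",
)


def _measurement_record(m) -> dict:
    return {
        "id": int(m.id),
        "center_x_mm": float(m.center_global[0]),
        "center_y_mm": float(m.center_global[1]),
        "diameter_mm": float(m.diameter_mm),
        "model_kind": str(m.model_kind),
        "positive": bool(m.positive),
        "rms_residual_mm": float(m.rms_residual),
        "converged": bool(m.converged),
        "fallback_used": bool(m.fallback_used),
    }


def write_report(measurements, path: str | os.PathLike, format: str = "csv") -> str:
    """Write wheal measurements as CSV (diameters at 2 decimals) or JSON.

    The JSON form keeps full precision and round-trips losslessly through
    :func:`read_report`.
    """
    records = [_measurement_record(m) for m in measurements]
    if format == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_REPORT_FIELDS)
            writer.writeheader()
            for rec in records:
                rec = dict(rec)
                rec["diameter_mm"] = f"{rec['diameter_mm']:.2f}"
                writer.writerow(rec)
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(records, fh, indent=1)
    else:
        raise ValueError(f"unknown report format: {format!r}")
    return str(path)


def read_report(path: str | os.PathLike):
    """Read a JSON measurement report back as WhealMeasurement objects."""
    from .pipeline import WhealMeasurement  # deferred: avoids an import cycle

    with open(path) as fh:
        records = json.load(fh)
    return [
        WhealMeasurement(
            id=rec["id"],
            center_global=(rec["center_x_mm"], rec["center_y_mm"]),
            diameter_mm=rec["diameter_mm"],
            model_kind=rec["model_kind"],
            positive=rec["positive"],
            rms_residual=rec["rms_residual_mm"],
            converged=rec["converged"],
            fallback_used=rec["fallback_used"],
        )
        for rec in records
    ]
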