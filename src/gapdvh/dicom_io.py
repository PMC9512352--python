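"""RT Dose / RT Structure Set I/O and contour rasterization.

Readers return :class:`~gapdvh.dvh.DoseGrid` and :class:`ContourSet` objects;
:func:`rasterize` converts contours to voxel masks by an even-odd
point-in-polygon test of voxel centers, with no inter-slice interpolation.
Plain-text DVH tables round-trip losslessly through CSV or JSON.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from matplotlib.path import Path as MplPath

from . import _dicom
from .dvh import DVH, DoseGrid, StructureMask
from .errors import FormatError, GeometryError
from ._dicom import RT_DOSE_SOP_CLASS, RT_STRUCT_SOP_CLASS

__all__ = [
    "ContourSet",
    "read_rt_dose",
    "write_rt_dose",
    "read_rt_struct",
    "write_rt_struct",
    "rasterize",
    "write_dvh_table",
    "read_dvh_table",
]

_OFFSET_TOL = 1e-4  # mm; non-uniformity tolerance for frame offsets


@dataclass
class ContourSet:
    """Closed planar contours for one ROI, in patient coordinates (mm)."""

    roi_number: int
    roi_name: str
    polygons: list[np.ndarray] = field(default_factory=list)  # each (n, 3)
    frame_of_reference: str = ""

    def __post_init__(self) -> None:
        self.polygons = [np.asarray(p, dtype=float) for p in self.polygons]
        for p in self.polygons:
            if p.ndim != 2 or p.shape[1] != 3 or p.shape[0] < 3:
                raise FormatError("each polygon needs >= 3 (x, y, z) vertices")


# ---------------------------------------------------------------------------
# RT Dose

def read_rt_dose(path: str) -> DoseGrid:
    """Read an RT Dose object into a :class:`DoseGrid`.

    Stored integers are multiplied by the dose-grid scaling; spacing and
    origin come from PixelSpacing, ImagePositionPatient and the grid frame
    offset vector, which must be uniformly spaced.
    """
    ds = _dicom.read_file(path)
    modality = _dicom.value(ds, (0x0008, 0x0060))
    if modality != "RTDOSE":
        raise FormatError(f"{path}: modality {modality!r}, expected RTDOSE")
    scaling = _dicom.value(ds, (0x3004, 0x000E))
    offsets = _dicom.value(ds, (0x3004, 0x000C))
    spacing_rc = _dicom.value(ds, (0x0028, 0x0030))
    origin = _dicom.value(ds, (0x0020, 0x0032))
    if scaling is None or offsets is None or spacing_rc is None or origin is None:
        raise FormatError(f"{path}: missing dose scaling, offsets, or geometry")
    rows = _dicom.value(ds, (0x0028, 0x0010))
    cols = _dicom.value(ds, (0x0028, 0x0011))
    n_frames = int(_dicom.value(ds, (0x0028, 0x0008), 1))
    bits = _dicom.value(ds, (0x0028, 0x0100), 32)
    pixel_data = _dicom.value(ds, (0x7FE0, 0x0010))
    if pixel_data is None:
        raise FormatError(f"{path}: missing pixel data")

    offsets = np.atleast_1d(np.asarray(offsets, dtype=float))
    if offsets.size != n_frames:
        raise FormatError(f"{path}: frame offset count != number of frames")
    if n_frames > 1:
        steps = np.diff(offsets)
        if np.any(np.abs(steps - steps[0]) > _OFFSET_TOL) or steps[0] <= 0:
            raise FormatError(f"{path}: non-uniform grid frame offset vector")
        dz = float(steps[0])
    else:
        dz = 1.0

    dtype = {16: "<u2", 32: "<u4"}.get(int(bits))
    if dtype is None:
        raise FormatError(f"{path}: unsupported bits allocated {bits}")
    raw = np.frombuffer(pixel_data, dtype=dtype)
    if raw.size != n_frames * rows * cols:
        raise FormatError(f"{path}: pixel data size mismatch")
    values = raw.reshape(n_frames, rows, cols).astype(float) * float(scaling)

    row_spacing, col_spacing = float(spacing_rc[0]), float(spacing_rc[1])
    x0, y0, z0 = (float(v) for v in origin)
    return DoseGrid(
        values=values,
        spacing=(col_spacing, row_spacing, dz),
        origin=(x0, y0, z0 + float(offsets[0])),
        dose_scaling=float(scaling),
    )


def write_rt_dose(
    grid: DoseGrid,
    path: str,
    scaling: Optional[float] = None,
    sop_instance_uid: str = "1.2.826.0.1.3680043.10.1291.2.1",
    frame_of_reference: str = "1.2.826.0.1.3680043.10.1291.3.1",
    dose_summation_type: str = "PLAN",
) -> float:
    """Write a :class:`DoseGrid` as an uncompressed 32-bit RT Dose object.

    Values are stored as ``round(dose / scaling)``; the scaling used is
    returned so callers can pre-quantize for bit-exact round-trips.
    """
    nz, ny, nx = grid.values.shape
    if scaling is None:
        vmax = float(grid.values.max())
        scaling = vmax / (2**32 - 1) if vmax > 0 else 1.0
    stored = np.round(grid.values / scaling)
    if np.any(stored > 2**32 - 1):
        raise FormatError("dose exceeds 32-bit range at this scaling")
    dx, dy, dz = grid.spacing
    ds: _dicom.Dataset = {
        (0x0008, 0x0016): ("UI", RT_DOSE_SOP_CLASS),
        (0x0008, 0x0018): ("UI", sop_instance_uid),
        (0x0008, 0x0060): ("CS", "RTDOSE"),
        (0x0020, 0x0032): ("DS", list(grid.origin)),
        (0x0020, 0x0037): ("DS", [1, 0, 0, 0, 1, 0]),
        (0x0020, 0x0052): ("UI", frame_of_reference),
        (0x0028, 0x0002): ("US", 1),
        (0x0028, 0x0004): ("CS", "MONOCHROME2"),
        (0x0028, 0x0008): ("IS", nz),
        (0x0028, 0x0010): ("US", ny),
        (0x0028, 0x0011): ("US", nx),
        (0x0028, 0x0030): ("DS", [dy, dx]),  # row spacing, column spacing
        (0x0028, 0x0100): ("US", 32),
        (0x0028, 0x0101): ("US", 32),
        (0x0028, 0x0102): ("US", 31),
        (0x0028, 0x0103): ("US", 0),
        (0x3004, 0x0002): ("CS", "GY"),
        (0x3004, 0x0004): ("CS", "PHYSICAL"),
        (0x3004, 0x000A): ("CS", dose_summation_type),
        (0x3004, 0x000C): ("DS", [i * dz for i in range(nz)]),
        (0x3004, 0x000E): ("DS", scaling),
        (0x7FE0, 0x0010): ("OW", stored.astype("<u4").tobytes()),
    }
    _dicom.write_file(path, RT_DOSE_SOP_CLASS, sop_instance_uid, ds)
    return scaling


# ---------------------------------------------------------------------------
# RT Structure Set

def read_rt_struct(path: str) -> list[ContourSet]:
    """Read an RT Structure Set into a list of :class:`ContourSet`.

    ROI names and numbers are preserved verbatim; an ROI without contour
    data yields a warning and an empty contour set.
    """
    ds = _dicom.read_file(path)
    modality = _dicom.value(ds, (0x0008, 0x0060))
    if modality != "RTSTRUCT":
        raise FormatError(f"{path}: modality {modality!r}, expected RTSTRUCT")
    roi_seq = _dicom.value(ds, (0x3006, 0x0020), [])
    contour_seq = _dicom.value(ds, (0x3006, 0x0039), [])

    info: dict[int, tuple[str, str]] = {}
    for item in roi_seq:
        num = int(_dicom.value(item, (0x3006, 0x0022)))
        name = str(_dicom.value(item, (0x3006, 0x0026), ""))
        frame = str(_dicom.value(item, (0x3006, 0x0024), ""))
        info[num] = (name, frame)

    by_number: dict[int, list[np.ndarray]] = {}
    for item in contour_seq:
        num = int(_dicom.value(item, (0x3006, 0x0084)))
        polys: list[np.ndarray] = []
        for contour in _dicom.value(item, (0x3006, 0x0040), []):
            data = _dicom.value(contour, (0x3006, 0x0050))
            if data is None:
                continue
            polys.append(np.asarray(data, dtype=float).reshape(-1, 3))
        by_number[num] = polys

    out: list[ContourSet] = []
    for num in sorted(info):
        name, frame = info[num]
        polys = by_number.get(num, [])
        if not polys:
            warnings.warn(f"ROI {num} ({name!r}) has no contour data")
        out.append(ContourSet(num, name, polys, frame))
    return out


def write_rt_struct(
    contour_sets: Sequence[ContourSet],
    path: str,
    sop_instance_uid: str = "1.2.826.0.1.3680043.10.1291.2.2",
    frame_of_reference: str = "1.2.826.0.1.3680043.10.1291.3.1",
) -> None:
    """Write contour sets as an RT Structure Set object."""
    roi_seq, contour_seq = [], []
    for cs in contour_sets:
        frame = cs.frame_of_reference or frame_of_reference
        roi_seq.append({
            (0x3006, 0x0022): ("IS", cs.roi_number),
            (0x3006, 0x0024): ("UI", frame),
            (0x3006, 0x0026): ("LO", cs.roi_name),
        })
        items = []
        for poly in cs.polygons:
            items.append({
                (0x3006, 0x0042): ("CS", "CLOSED_PLANAR"),
                (0x3006, 0x0046): ("IS", poly.shape[0]),
                (0x3006, 0x0050): ("DS", [float(v) for v in poly.ravel()]),
            })
        contour_seq.append({
            (0x3006, 0x0040): ("SQ", items),
            (0x3006, 0x0084): ("IS", cs.roi_number),
        })
    ds: _dicom.Dataset = {
        (0x0008, 0x0016): ("UI", RT_STRUCT_SOP_CLASS),
        (0x0008, 0x0018): ("UI", sop_instance_uid),
        (0x0008, 0x0060): ("CS", "RTSTRUCT"),
        (0x3006, 0x0002): ("SH", "gapdvh"),
        (0x3006, 0x0020): ("SQ", roi_seq),
        (0x3006, 0x0039): ("SQ", contour_seq),
    }
    _dicom.write_file(path, RT_STRUCT_SOP_CLASS, sop_instance_uid, ds)


# ---------------------------------------------------------------------------
# rasterization

def rasterize(contours: ContourSet, grid: DoseGrid) -> StructureMask:
    """Convert contours to a voxel mask on the dose grid.

    Each polygon is matched to the nearest grid slice (within half a slice
    spacing); voxel centers are tested against the polygon and multiple
    polygons on one slice combine by the even-odd rule, so holes subtract.
    """
    xs, ys, zs = grid.voxel_centers()
    dz = grid.spacing[2]
    nz, ny, nx = grid.values.shape
    mask = np.zeros((nz, ny, nx), dtype=bool)
    xx, yy = np.meshgrid(xs, ys)
    points = np.column_stack([xx.ravel(), yy.ravel()])
    for poly in contours.polygons:
        z = float(poly[:, 2].mean())
        k = int(np.argmin(np.abs(zs - z)))
        if abs(zs[k] - z) > dz / 2 + 1e-9:
            raise GeometryError(
                f"contour plane z = {z} mm matches no grid slice "
                f"(nearest {zs[k]} mm, spacing {dz} mm)"
            )
        inside = MplPath(poly[:, :2]).contains_points(points).reshape(ny, nx)
        mask[k] ^= inside  # even-odd combination
    return StructureMask(
        name=contours.roi_name, mask=mask, voxel_volume=grid.voxel_volume_cc
    )


# ---------------------------------------------------------------------------
# plain-text DVH tables

def _dvh_record(dvh: DVH) -> dict:
    return {
        "structure": dvh.structure,
        "scale_tag": dvh.scale_tag,
        "alpha_beta_tag": dvh.alpha_beta_tag,
        "relative": dvh.relative,
        "total_volume_ref": dvh.total_volume_ref,
        "bin_edges": [float(v) for v in dvh.bin_edges],
        "differential_volume": [float(v) for v in dvh.differential_volume],
        "bin_doses": (
            None if dvh.bin_doses is None else [float(v) for v in dvh.bin_doses]
        ),
    }


def _dvh_from_record(rec: dict) -> DVH:
    return DVH(
        structure=rec["structure"],
        bin_edges=np.asarray(rec["bin_edges"], dtype=float),
        differential_volume=np.asarray(rec["differential_volume"], dtype=float),
        scale_tag=rec.get("scale_tag", "physical"),
        alpha_beta_tag=rec.get("alpha_beta_tag"),
        bin_doses=(
            None if rec.get("bin_doses") is None
            else np.asarray(rec["bin_doses"], dtype=float)
        ),
        relative=bool(rec.get("relative", False)),
        total_volume_ref=rec.get("total_volume_ref"),
    )


def write_dvh_table(dvh: DVH, path: str, format: str = "csv") -> None:
    """Write a DVH as CSV or JSON; the round trip recovers it exactly."""
    if format == "json":
        with open(path, "w") as fh:
            json.dump(_dvh_record(dvh), fh, indent=1)
        return
    if format != "csv":
        raise FormatError(f"unknown DVH table format {format!r}")
    _, cum = dvh.cumulative()
    with open(path, "w", newline="") as fh:
        fh.write(f"# structure={dvh.structure}\n")
        fh.write(f"# scale_tag={dvh.scale_tag}\n")
        fh.write(f"# alpha_beta_tag={dvh.alpha_beta_tag}\n")
        fh.write(f"# relative={dvh.relative}\n")
        fh.write(f"# total_volume_ref={dvh.total_volume_ref}\n")
        writer = csv.writer(fh)
        writer.writerow(
            ["bin_lower_edge", "bin_upper_edge", "bin_dose",
             "differential_volume", "cumulative_volume"]
        )
        for i in range(dvh.n_bins):
            writer.writerow([
                repr(float(dvh.bin_edges[i])),
                repr(float(dvh.bin_edges[i + 1])),
                repr(float(dvh.doses[i])),
                repr(float(dvh.differential_volume[i])),
                repr(float(cum[i])),
            ])


def read_dvh_table(path: str) -> DVH:
    """Read a DVH table written by :func:`write_dvh_table`."""
    text = open(path).read()
    if text.lstrip().startswith("{"):
        return _dvh_from_record(json.loads(text))
    meta: dict[str, str] = {}
    rows = []
    for line in text.splitlines():
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
        elif line.strip():
            rows.append(line)
    reader = csv.DictReader(rows)
    lower, upper, doses, vols = [], [], [], []
    for row in reader:
        lower.append(float(row["bin_lower_edge"]))
        upper.append(float(row["bin_upper_edge"]))
        doses.append(float(row["bin_dose"]))
        vols.append(float(row["differential_volume"]))
    if not lower:
        raise FormatError(f"{path}: no DVH rows")
    alpha_beta = meta.get("alpha_beta_tag", "None")
    total_ref = meta.get("total_volume_ref", "None")
    return DVH(
        structure=meta.get("structure", ""),
        bin_edges=np.asarray(lower + [upper[-1]], dtype=float),
        differential_volume=np.asarray(vols, dtype=float),
        scale_tag=meta.get("scale_tag", "physical"),
        alpha_beta_tag=None if alpha_beta == "None" else float(alpha_beta),
        bin_doses=np.asarray(doses, dtype=float),
        relative=meta.get("relative", "False") == "True",
        total_volume_ref=None if total_ref == "None" else float(total_ref),
    )
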