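"""Dose-volume histograms: construction from dose grids and summary statistics.

The engine bins each masked voxel by the dose at its center, with no dose-grid
or inter-slice interpolation, so each voxel contributes its full volume to a
single left-closed/right-open dose bin.  Percentile statistics (D_x%, D_xcc,
V_xGy) are read from the cumulative curve with linear interpolation between
bin edges; plateaus resolve to the hottest dose satisfying the volume target.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .errors import (
    CongruenceError,
    EmptyStructureError,
    InvalidParameterError,
)

__all__ = [
    "DoseGrid",
    "StructureMask",
    "DVH",
    "dvh_from_grid",
    "dvh_statistic",
    "rescale_to_relative",
    "rescale_to_absolute",
]

DEFAULT_BIN_WIDTH = 0.01  # Gy (1 cGy)


@dataclass(frozen=True)
class DoseGrid:
    """A 3-D dose array indexed (slice, row, col) in patient coordinates.

    Parameters
    ----------
    values
        Dose in Gy, shape ``(nz, ny, nx)``.
    spacing
        ``(dx, dy, dz)`` voxel spacing in mm (column, row, slice).
    origin
        Patient-space coordinates (mm) of the center of voxel ``[0, 0, 0]``.
    dose_scaling
        Multiplicative scaling already applied to ``values`` on read.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    dose_scaling: float = 1.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 3:
            raise InvalidParameterError("dose grid must be 3-D (slice, row, col)")
        if np.any(values < 0):
            raise InvalidParameterError("dose values must be non-negative")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise InvalidParameterError("voxel spacing components must be positive")

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cm^3."""
        dx, dy, dz = self.spacing
        return dx * dy * dz / 1000.0

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Patient-space x, y, z coordinates (mm) of voxel centers (1-D each)."""
        nz, ny, nx = self.values.shape
        dx, dy, dz = self.spacing
        x0, y0, z0 = self.origin
        return (
            x0 + np.arange(nx) * dx,
            y0 + np.arange(ny) * dy,
            z0 + np.arange(nz) * dz,
        )


@dataclass(frozen=True)
class StructureMask:
    """Boolean voxel mask congruent with a :class:`DoseGrid`."""

    name: str
    mask: np.ndarray
    voxel_volume: float  # cm^3 per voxel

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", mask)
        if self.voxel_volume <= 0:
            raise InvalidParameterError("voxel_volume must be positive")

    @property
    def volume(self) -> float:
        """Total structure volume in cm^3."""
        return float(np.count_nonzero(self.mask)) * self.voxel_volume


@dataclass(frozen=True)
class DVH:
    """Differential dose-volume histogram for a single structure.

    ``bin_edges`` has ``M + 1`` ascending entries delimiting ``M``
    left-closed/right-open bins; ``differential_volume`` holds the volume per
    bin.  ``bin_doses`` carries the representative dose of each bin and
    defaults to bin centers; radiobiological conversion replaces it with the
    exactly mapped dose so statistics stay consistent with the scalar model.
    """

    structure: str
    bin_edges: np.ndarray
    differential_volume: np.ndarray
    scale_tag: str = "physical"  # physical | BED | EQD2
    alpha_beta_tag: Optional[float] = None
    bin_doses: Optional[np.ndarray] = None
    relative: bool = False
    total_volume_ref: Optional[float] = None  # absolute cm^3 behind a relative DVH

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        vols = np.asarray(self.differential_volume, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "differential_volume", vols)
        if edges.ndim != 1 or edges.size < 2:
            raise InvalidParameterError("bin_edges must be 1-D with >= 2 entries")
        if np.any(np.diff(edges) <= 0):
            raise InvalidParameterError("bin_edges must be strictly ascending")
        if vols.shape != (edges.size - 1,):
            raise InvalidParameterError("differential_volume length must equal bin count")
        if np.any(vols < 0):
            raise InvalidParameterError("bin volumes must be non-negative")
        if self.scale_tag not in ("physical", "BED", "EQD2"):
            raise InvalidParameterError(f"unknown scale tag {self.scale_tag!r}")
        if self.bin_doses is not None:
            doses = np.asarray(self.bin_doses, dtype=float)
            if doses.shape != vols.shape:
                raise InvalidParameterError("bin_doses length must equal bin count")
            object.__setattr__(self, "bin_doses", doses)

    # -- derived views ---------------------------------------------------

    @property
    def n_bins(self) -> int:
        return self.bin_edges.size - 1

    @property
    def bin_width(self) -> float:
        """Nominal bin width (median over bins; exact for uniform binning)."""
        return float(np.median(np.diff(self.bin_edges)))

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def doses(self) -> np.ndarray:
        """Representative dose per bin (``bin_doses`` or bin centers)."""
        if self.bin_doses is not None:
            return self.bin_doses
        return self.bin_centers

    @property
    def total_volume(self) -> float:
        return float(self.differential_volume.sum())

    def cumulative(self) -> tuple[np.ndarray, np.ndarray]:
        """Cumulative curve sampled at bin edges.

        Returns ``(edges, volume_at_or_above)`` where entry ``j`` is the
        volume receiving at least ``edges[j]``; the last entry is zero.
        """
        cum = np.concatenate(
            [np.cumsum(self.differential_volume[::-1])[::-1], [0.0]]
        )
        return self.bin_edges, cum

    # -- statistics ------------------------------------------------------

    def statistic(self, metric: str, x: Optional[float] = None) -> float:
        return dvh_statistic(self, metric, x)

    def stats_table(self) -> dict[str, float]:
        """The standard report block: Max/Min/Mean, D100/98/95/2/50%, D2cc."""
        out = {
            "Dmax": self.statistic("Dmax"),
            "Dmin": self.statistic("Dmin"),
            "Dmean": self.statistic("Dmean"),
            "D100%": self.statistic("D_x%", 100.0),
            "D98%": self.statistic("D_x%", 98.0),
            "D95%": self.statistic("D_x%", 95.0),
            "D2%": self.statistic("D_x%", 2.0),
            "D50%": self.statistic("D_x%", 50.0),
        }
        if not self.relative and self.total_volume >= 2.0:
            out["D2cc"] = self.statistic("D_x_cc", 2.0)
        return out


def dvh_from_grid(
    grid: DoseGrid, mask: StructureMask, bin_width: float = DEFAULT_BIN_WIDTH
) -> DVH:
    """Bin the dose at each masked voxel center into a differential DVH.

    Every masked voxel contributes its full voxel volume to the bin containing
    its center dose (left-closed/right-open); no interpolation of the dose
    grid or between slices is performed, so total volume is conserved exactly.
    """
    if bin_width <= 0:
        raise InvalidParameterError("bin_width must be positive")
    if mask.mask.shape != grid.values.shape:
        raise CongruenceError(
            f"mask shape {mask.mask.shape} != grid shape {grid.values.shape}"
        )
    doses = grid.values[mask.mask]
    if doses.size == 0:
        raise EmptyStructureError(f"structure {mask.name!r} has no voxels")
    idx = np.floor(doses / bin_width).astype(np.int64)
    n_bins = int(idx.max()) + 1
    counts = np.bincount(idx, minlength=n_bins)
    edges = np.arange(n_bins + 1, dtype=float) * bin_width
    return DVH(
        structure=mask.name,
        bin_edges=edges,
        differential_volume=counts * mask.voxel_volume,
        scale_tag="physical",
    )


def _inverse_cumulative(dvh: DVH, target_volume: float) -> float:
    """Dose at which the cumulative curve crosses ``target_volume``.

    Plateaus resolve to the hottest dose still covering the target volume,
    so D100% equals the minimum occupied dose rather than the bottom edge.
    """
    edges, cum = dvh.cumulative()
    total = dvh.total_volume
    if target_volume <= 0:
        return float(edges[-1])
    if target_volume > total:
        raise InvalidParameterError(
            f"requested volume {target_volume} exceeds total {total}"
        )
    j = int(np.max(np.nonzero(cum >= target_volume)[0]))
    if cum[j] == target_volume or j == len(edges) - 1:
        return float(edges[j])
    frac = (cum[j] - target_volume) / (cum[j] - cum[j + 1])
    return float(edges[j] + frac * (edges[j + 1] - edges[j]))


def dvh_statistic(dvh: DVH, metric: str, x: Optional[float] = None) -> float:
    """Evaluate a DVH summary statistic.

    ``metric`` is one of ``Dmin``, ``Dmax``, ``Dmean``, ``D_x%``, ``D_x_cc``,
    ``V_x_Gy``; the latter three require ``x`` (percent of volume, cm^3, Gy).
    """
    if dvh.total_volume <= 0:
        raise EmptyStructureError("cannot compute statistics of an empty DVH")
    vols = dvh.differential_volume
    occupied = np.nonzero(vols > 0)[0]
    if metric == "Dmin":
        return float(dvh.doses[occupied[0]])
    if metric == "Dmax":
        return float(dvh.doses[occupied[-1]])
    if metric == "Dmean":
        return float(np.sum(dvh.doses * vols) / dvh.total_volume)
    if metric == "D_x%":
        if x is None or not (0.0 <= x <= 100.0):
            raise InvalidParameterError("D_x% requires x in [0, 100]")
        return _inverse_cumulative(dvh, x / 100.0 * dvh.total_volume)
    if metric == "D_x_cc":
        if x is None or x < 0 or x > dvh.total_volume:
            raise InvalidParameterError("D_x_cc requires 0 <= x <= total volume")
        return _inverse_cumulative(dvh, x)
    if metric == "V_x_Gy":
        if x is None or x < 0:
            raise InvalidParameterError("V_x_Gy requires x >= 0")
        edges, cum = dvh.cumulative()
        return float(np.interp(x, edges, cum, left=dvh.total_volume, right=0.0))
    raise InvalidParameterError(f"unknown DVH metric {metric!r}")


def rescale_to_relative(dvh: DVH) -> DVH:
    """Express bin volumes as percent of total volume (dose axis unchanged)."""
    total = dvh.total_volume
    if total <= 0:
        raise EmptyStructureError("cannot normalize a zero-volume DVH")
    if dvh.relative:
        return dvh
    return replace(
        dvh,
        differential_volume=dvh.differential_volume / total * 100.0,
        relative=True,
        total_volume_ref=total,
    )


def rescale_to_absolute(dvh: DVH) -> DVH:
    """Invert :func:`rescale_to_relative` using the stored total volume."""
    if not dvh.relative:
        return dvh
    if dvh.total_volume_ref is None:
        raise InvalidParameterError("relative DVH lacks a stored total volume")
    return replace(
        dvh,
        differential_volume=dvh.differential_volume / 100.0 * dvh.total_volume_ref,
        relative=False,
        total_volume_ref=None,
    )
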