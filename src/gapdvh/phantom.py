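"""Synthetic dose grids, contoured structures, and schedule fixtures.

Phantoms pair a generated 3-D dose field with polygonal contours of simple
primitives (sphere, box, spherical shell) whose DVHs under the chosen field
have closed forms, so the DVH engine and the DICOM round trip can be tested
without clinical data.  Dose values are quantized to the DICOM storage
scaling at generation time, making the write/read round trip bit-exact.

``build_case_study`` returns the scalar fractionation data of the five
interrupted-treatment worked examples (sites: tonsil, larynx, vocal cord,
lung, parotid) used throughout the plan-accounting tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .dicom_io import ContourSet
from .dvh import DVH, DoseGrid, StructureMask
from .errors import SpecError
from .radiobiology import ScheduleSummary, TissueParams

__all__ = [
    "StructurePrimitive",
    "DoseField",
    "PhantomSpec",
    "build_phantom",
    "CaseStudy",
    "build_case_study",
    "CASE_LABELS",
]

#: dose quantization step (Gy) applied to generated grids; equals the DICOM
#: dose-grid scaling used when the phantom is written out
DOSE_QUANTUM = 1e-6

_CIRCLE_VERTICES = 256


@dataclass(frozen=True)
class StructurePrimitive:
    """A contourable primitive: ``sphere``, ``box``, or ``shell``.

    ``center`` is in patient coordinates (mm).  ``size`` is the radius for a
    sphere, ``(sx, sy, sz)`` full side lengths for a box, and
    ``(r_outer, r_inner)`` for a spherical shell.
    """

    name: str
    kind: str
    center: tuple[float, float, float]
    size: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("sphere", "box", "shell"):
            raise SpecError(f"unknown primitive kind {self.kind!r}")
        if any(s <= 0 for s in self.size):
            raise SpecError("primitive dimensions must be positive")
        if self.kind == "shell" and self.size[0] <= self.size[1]:
            raise SpecError("shell outer radius must exceed inner radius")

    @property
    def volume(self) -> float:
        """Exact volume in cm^3."""
        if self.kind == "sphere":
            return 4.0 / 3.0 * math.pi * self.size[0] ** 3 / 1000.0
        if self.kind == "box":
            sx, sy, sz = self.size
            return sx * sy * sz / 1000.0
        ro, ri = self.size
        return 4.0 / 3.0 * math.pi * (ro**3 - ri**3) / 1000.0

    def extent(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.center)
        if self.kind == "box":
            half = np.asarray(self.size) / 2.0
        else:
            half = np.full(3, self.size[0])
        return c - half, c + half


@dataclass(frozen=True)
class DoseField:
    """The dose field laid over the grid.

    kinds:
      * ``uniform`` — ``dose`` everywhere.
      * ``linear`` — ramp along ``axis`` (0=x, 1=y, 2=z) from ``low`` at the
        grid's low edge to ``high`` at its high edge.
      * ``gaussian`` — radial Gaussian ``peak * exp(-r^2 / (2 sigma^2))``
        about ``center`` (defaults to the grid center).
    """

    kind: str
    dose: float = 0.0
    low: float = 0.0
    high: float = 0.0
    axis: int = 0
    peak: float = 0.0
    sigma: float = 10.0
    center: Optional[tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "linear", "gaussian"):
            raise SpecError(f"unknown dose field kind {self.kind!r}")
        if min(self.dose, self.low, self.high, self.peak) < 0 or self.sigma <= 0:
            raise SpecError("dose field parameters must be non-negative")
        if self.kind == "linear" and self.high < self.low:
            raise SpecError("linear field requires high >= low")


@dataclass(frozen=True)
class PhantomSpec:
    """Grid geometry plus structures and field for :func:`build_phantom`."""

    shape: tuple[int, int, int]  # (nz, ny, nx)
    spacing: tuple[float, float, float]  # (dx, dy, dz) mm
    structures: tuple[StructurePrimitive, ...]
    dose_field: DoseField
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sigma: float = 0.0  # Gy
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        names = [s.name for s in self.structures]
        if len(names) != len(set(names)):
            raise SpecError("structure names must be unique")
        nz, ny, nx = self.shape
        dx, dy, dz = self.spacing
        x0, y0, z0 = self.origin
        lo = np.array([x0, y0, z0]) - np.array([dx, dy, dz]) / 2.0
        hi = lo + np.array([nx * dx, ny * dy, nz * dz])
        for s in self.structures:
            s_lo, s_hi = s.extent()
            if np.any(s_lo < lo - 1e-9) or np.any(s_hi > hi + 1e-9):
                raise SpecError(f"structure {s.name!r} does not fit inside the grid")


# ---------------------------------------------------------------------------
# field evaluation

def _grid_extent(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    nz, ny, nx = spec.shape
    dx, dy, dz = spec.spacing
    x0, y0, z0 = spec.origin
    lo = np.array([x0 - dx / 2, y0 - dy / 2, z0 - dz / 2])
    hi = lo + np.array([nx * dx, ny * dy, nz * dz])
    return lo, hi


def _field_dose(spec: PhantomSpec, x: np.ndarray, y: np.ndarray,
                z: np.ndarray) -> np.ndarray:
    f = spec.dose_field
    if f.kind == "uniform":
        return np.full(np.broadcast(x, y, z).shape, float(f.dose))
    if f.kind == "linear":
        lo, hi = _grid_extent(spec)
        coord = (x, y, z)[f.axis]
        span = hi[f.axis] - lo[f.axis]
        return f.low + (f.high - f.low) * (coord - lo[f.axis]) / span
    center = f.center
    if center is None:
        lo, hi = _grid_extent(spec)
        center = tuple((lo + hi) / 2.0)
    r2 = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
    return f.peak * np.exp(-r2 / (2.0 * f.sigma**2))


# ---------------------------------------------------------------------------
# contours

def _circle(cx: float, cy: float, z: float, radius: float) -> np.ndarray:
    theta = np.linspace(0.0, 2.0 * math.pi, _CIRCLE_VERTICES, endpoint=False)
    return np.column_stack([
        cx + radius * np.cos(theta),
        cy + radius * np.sin(theta),
        np.full(theta.shape, z),
    ])


def _contours(prim: StructurePrimitive, zs: np.ndarray) -> list[np.ndarray]:
    cx, cy, cz = prim.center
    polys: list[np.ndarray] = []
    if prim.kind == "box":
        sx, sy, sz = prim.size
        for z in zs:
            if abs(z - cz) <= sz / 2.0:
                hx, hy = sx / 2.0, sy / 2.0
                polys.append(np.array([
                    [cx - hx, cy - hy, z],
                    [cx + hx, cy - hy, z],
                    [cx + hx, cy + hy, z],
                    [cx - hx, cy + hy, z],
                ]))
        return polys
    radii = (prim.size[0],) if prim.kind == "sphere" else prim.size
    for z in zs:
        for r in radii:
            if abs(z - cz) < r:
                polys.append(_circle(cx, cy, z, math.sqrt(r**2 - (z - cz) ** 2)))
    return polys


def _mask(prim: StructurePrimitive, spec: PhantomSpec,
          x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    cx, cy, cz = prim.center
    if prim.kind == "box":
        sx, sy, sz = prim.size
        return (
            (np.abs(x - cx) <= sx / 2.0)
            & (np.abs(y - cy) <= sy / 2.0)
            & (np.abs(z - cz) <= sz / 2.0)
        )
    r2 = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
    if prim.kind == "sphere":
        return r2 <= prim.size[0] ** 2
    ro, ri = prim.size
    return (r2 <= ro**2) & (r2 > ri**2)


# ---------------------------------------------------------------------------
# analytic DVHs

def _analytic_cumulative(
    prim: StructurePrimitive, spec: PhantomSpec
) -> Optional[Callable[[np.ndarray], np.ndarray]]:
    """Closed-form V(dose >= x) in cm^3, where available."""
    f = spec.dose_field
    vol = prim.volume
    if f.kind == "uniform":
        return lambda x: np.where(np.asarray(x, dtype=float) <= f.dose, vol, 0.0)
    if f.kind == "linear" and prim.kind == "box":
        lo, hi = _grid_extent(spec)
        span = hi[f.axis] - lo[f.axis]
        grad = (f.high - f.low) / span  # Gy per mm
        half = prim.size[f.axis] / 2.0
        c = prim.center[f.axis]
        d_lo = f.low + grad * (c - half - lo[f.axis])
        d_hi = f.low + grad * (c + half - lo[f.axis])
        if d_hi == d_lo:
            return lambda x: np.where(np.asarray(x, dtype=float) <= d_lo, vol, 0.0)

        def cum(x: np.ndarray) -> np.ndarray:
            frac = (d_hi - np.asarray(x, dtype=float)) / (d_hi - d_lo)
            return vol * np.clip(frac, 0.0, 1.0)

        return cum
    if f.kind == "gaussian" and prim.kind == "sphere":
        center = f.center
        if center is None:
            g_lo, g_hi = _grid_extent(spec)
            center = tuple((g_lo + g_hi) / 2.0)
        if not np.allclose(center, prim.center):
            return None
        radius, peak, sigma = prim.size[0], f.peak, f.sigma

        def cum(x: np.ndarray) -> np.ndarray:
            x = np.asarray(x, dtype=float)
            with np.errstate(divide="ignore"):
                r = sigma * np.sqrt(2.0 * np.log(np.maximum(peak / np.maximum(x, 1e-300), 1.0)))
            r = np.minimum(r, radius)
            out = 4.0 / 3.0 * math.pi * r**3 / 1000.0
            return np.where(x > peak, 0.0, np.where(x <= 0, prim.volume, out))

        return cum
    return None


def _binned_analytic(
    prim: StructurePrimitive, spec: PhantomSpec, bin_width: float, max_dose: float
) -> Optional[DVH]:
    cum = _analytic_cumulative(prim, spec)
    if cum is None:
        return None
    n_bins = int(math.floor(max_dose / bin_width)) + 1
    edges = np.arange(n_bins + 1, dtype=float) * bin_width
    cum_vals = cum(edges)
    diff = cum_vals[:-1] - cum_vals[1:]
    return DVH(
        structure=prim.name,
        bin_edges=edges,
        differential_volume=np.maximum(diff, 0.0),
        scale_tag="physical",
    )


# ---------------------------------------------------------------------------
# phantom assembly

def build_phantom(
    spec: PhantomSpec, bin_width: float = 0.01
) -> tuple[DoseGrid, list[ContourSet], dict[str, DVH], dict[str, StructureMask]]:
    """Generate the dose grid, contours, analytic DVHs, and exact masks.

    Returns ``(grid, contour_sets, expected_dvhs, masks)``.  ``expected_dvhs``
    holds the closed-form DVH of each primitive binned at ``bin_width`` for
    the (primitive, field) combinations with a closed form; ``masks`` holds
    the exact voxel-center membership masks (independent of rasterization).
    Grid doses are quantized to the DICOM storage scaling, so writing and
    re-reading the phantom reproduces the grid bit-for-bit.
    """
    nz, ny, nx = spec.shape
    xs, ys, zs = DoseGrid(
        np.zeros(spec.shape), spec.spacing, spec.origin
    ).voxel_centers()
    z3, y3, x3 = np.meshgrid(zs, ys, xs, indexing="ij")
    dose = _field_dose(spec, x3, y3, z3).astype(float)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        dose = np.maximum(dose + rng.normal(0.0, spec.noise_sigma, dose.shape), 0.0)
    dose = np.round(dose / DOSE_QUANTUM) * DOSE_QUANTUM
    grid = DoseGrid(dose, spec.spacing, spec.origin, dose_scaling=DOSE_QUANTUM)

    contour_sets: list[ContourSet] = []
    expected: dict[str, DVH] = {}
    masks: dict[str, StructureMask] = {}
    max_dose = float(dose.max())
    for i, prim in enumerate(spec.structures, start=1):
        contour_sets.append(
            ContourSet(roi_number=i, roi_name=prim.name,
                       polygons=_contours(prim, zs))
        )
        masks[prim.name] = StructureMask(
            name=prim.name,
            mask=_mask(prim, spec, x3, y3, z3),
            voxel_volume=grid.voxel_volume_cc,
        )
        analytic = _binned_analytic(prim, spec, bin_width, max_dose)
        if analytic is not None:
            expected[prim.name] = analytic
    return grid, contour_sets, expected, masks


# ---------------------------------------------------------------------------
# interrupted-treatment case studies

@dataclass(frozen=True)
class CaseStudy:
    """Scalar fractionation data for one interrupted course.

    ``intended`` is the uninterrupted prescription; ``pre_gap`` the fractions
    delivered before the interruption (T = days elapsed at its end);
    ``post_gap`` the remainder, with T the final overall treatment time of
    the uncompensated course.
    """

    label: str
    site: str
    intended: ScheduleSummary
    pre_gap: ScheduleSummary
    post_gap: ScheduleSummary
    gap_days: int

    @property
    def ptv_dose(self) -> float:
        return self.intended.total_dose


_CASES = {
    "A": ("left tonsil", (2.2, 30, 42), (2.2, 18, 26), (2.2, 12, 52), 12),
    "B": ("larynx", (2.0, 35, 50), (2.0, 31, 46), (2.0, 4, 59), 12),
    "C": ("vocal cord", (2.0, 35, 50), (2.0, 6, 9), (2.0, 29, 63), 13),
    "D": ("right lung", (2.0, 30, 44), (2.0, 12, 18), (2.0, 18, 51), 12),
    "E": ("parotid", (2.0, 30, 43), (2.0, 7, 10), (2.0, 23, 49), 12),
}

CASE_LABELS = tuple(_CASES)

#: RCR Category-1 tumor parameters shared by the five case studies
C1_TUMOR = TissueParams(
    name="tumor_c1", alpha_beta=10.0, K=0.9, T_delay=28.0, tissue_class="tumor"
)


def build_case_study(label: str) -> CaseStudy:
    """Return the fractionation summary of one of the five case studies."""
    if label not in _CASES:
        raise SpecError(f"unknown case study {label!r}; choose from {CASE_LABELS}")
    site, intended, pre, post, gap = _CASES[label]
    mk = lambda rec: ScheduleSummary(N=rec[1], d=rec[0], T=rec[2])
    return CaseStudy(
        label=label,
        site=site,
        intended=mk(intended),
        pre_gap=mk(pre),
        post_gap=mk(post),
        gap_days=gap,
    )
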