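"""Linear-quadratic isoeffect conversions with tumor repopulation correction.

Scalar pipeline: ``bed_scalar`` evaluates

    BED = N * d * (1 + d * (1 + h) / (alpha/beta)) - max(0, K * (T - T_delay))

with the repopulation term applied to tumors only and clamped at zero before
the onset day, and ``eqd2_from_bed`` rescales by 1 / (1 + 2 / (alpha/beta)).
``convert_dvh`` applies the same model per dose bin with the variable dose
per fraction ``d_i = D_i / N``, optionally splitting the schedule into
session groups that carry different incomplete-repair factors ``h`` (e.g.
twice-daily days versus single-fraction days).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import yaml

from .dvh import DVH
from .errors import (
    ConsistencyError,
    InvalidParameterError,
    SessionGroupError,
    UnitError,
)

__all__ = [
    "TissueParams",
    "ScheduleSummary",
    "BedValue",
    "incomplete_repair_factor",
    "repopulation_loss",
    "bed_scalar",
    "eqd2_from_bed",
    "segment_bed",
    "convert_dvh",
    "load_tissue_presets",
    "round_report",
]

#: interfraction intervals beyond this (hours) are treated as fully repaired
FULL_REPAIR_INTERVAL_H = 8.0

DOSE_TOL = 1e-6  # Gy; total_dose vs N*d bookkeeping tolerance


@dataclass(frozen=True)
class TissueParams:
    """Radiobiological constants for one structure.

    ``K`` (Gy/day) and ``T_delay`` (days) describe dose lost to rapid cell
    repopulation after its onset; both are zero/ignored for OARs, whose
    repopulation within a treatment course is negligible.
    """

    name: str
    alpha_beta: float  # Gy
    K: float = 0.0  # Gy/day, 0 for OARs
    T_delay: float = 0.0  # calendar days
    repair_half_time: float = 2.0  # hours
    tissue_class: str = "tumor"  # tumor | oar

    def __post_init__(self) -> None:
        if self.alpha_beta <= 0:
            raise InvalidParameterError("alpha_beta must be positive")
        if self.K < 0 or self.T_delay < 0:
            raise InvalidParameterError("K and T_delay must be non-negative")
        if self.repair_half_time <= 0:
            raise InvalidParameterError("repair_half_time must be positive")
        if self.tissue_class not in ("tumor", "oar"):
            raise InvalidParameterError(
                f"tissue_class must be 'tumor' or 'oar', got {self.tissue_class!r}"
            )
        if self.tissue_class == "oar" and self.K != 0:
            raise InvalidParameterError("OARs carry no repopulation term (K must be 0)")

    @property
    def eqd2_factor(self) -> float:
        """EQD2 scaling constant ``1 / (1 + 2 / (alpha/beta))``."""
        return 1.0 / (1.0 + 2.0 / self.alpha_beta)


@dataclass(frozen=True)
class ScheduleSummary:
    """Fractionation bookkeeping for one plan or plan segment.

    ``T`` is the overall treatment time in calendar days (inclusive of
    weekends and gaps); for a segment it is the cumulative overall time at
    the segment's end.  ``TD`` counts twice-daily treatment days and ``m``
    is the same-day interfraction interval in hours.
    """

    N: int
    d: float  # Gy per fraction
    T: float  # calendar days
    TD: int = 0
    m: float = 6.0  # hours

    def __post_init__(self) -> None:
        if self.N < 0:
            raise InvalidParameterError("N must be non-negative")
        if self.N >= 1 and self.T < 1:
            raise InvalidParameterError("T must be >= 1 day for a non-empty schedule")
        if self.TD < 0 or self.TD > self.N // 2:
            raise InvalidParameterError("TD must satisfy 0 <= TD <= floor(N/2)")
        if self.TD > 0 and self.m <= 0:
            raise InvalidParameterError("interfraction interval m must be positive")

    @property
    def total_dose(self) -> float:
        return self.N * self.d


@dataclass(frozen=True)
class BedValue:
    """An isoeffective dose in Gy tagged with the alpha/beta of its unit.

    Addition and subtraction are only defined between values sharing the
    same tag (Gy_10 + Gy_3 is meaningless).  Negative values are legal: a
    segment whose repopulation loss exceeds its delivered dose has BED < 0.
    """

    value: float
    alpha_beta_tag: float

    def _check(self, other: "BedValue") -> None:
        if not isinstance(other, BedValue):
            raise UnitError("BedValue arithmetic requires another BedValue")
        if other.alpha_beta_tag != self.alpha_beta_tag:
            raise UnitError(
                f"cannot combine Gy_{self.alpha_beta_tag:g} with "
                f"Gy_{other.alpha_beta_tag:g}"
            )

    def __add__(self, other: "BedValue") -> "BedValue":
        self._check(other)
        return BedValue(self.value + other.value, self.alpha_beta_tag)

    def __sub__(self, other: "BedValue") -> "BedValue":
        self._check(other)
        return BedValue(self.value - other.value, self.alpha_beta_tag)

    def __float__(self) -> float:
        return self.value


def round_report(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, matching 1-decimal report tables.

    Values are snapped to 9 decimals first so accumulated floating-point
    noise (e.g. 43.74999999999999 for an exact 43.75) does not flip a
    half-way case.
    """
    snapped = Decimal(repr(x)).quantize(Decimal("1e-9"), rounding=ROUND_HALF_UP)
    q = Decimal(1).scaleb(-ndigits)
    return float(snapped.quantize(q, rounding=ROUND_HALF_UP))


def incomplete_repair_factor(repair_half_time: float, interval: float) -> float:
    """Incomplete-repair factor ``h`` for two fractions on the same day.

    ``h = 2 ** (-interval / repair_half_time)``, the fraction of sublethal
    damage from the first fraction still unrepaired when the second is
    delivered.  Intervals longer than 8 h count as fully repaired (h = 0).
    """
    if repair_half_time <= 0 or interval <= 0:
        raise InvalidParameterError("repair_half_time and interval must be positive")
    if interval > FULL_REPAIR_INTERVAL_H:
        return 0.0
    return 2.0 ** (-interval / repair_half_time)


def repopulation_loss(params: TissueParams, T: float) -> float:
    """Dose (Gy, BED scale) lost to repopulation by overall time ``T``.

    ``max(0, K * (T - T_delay))`` — zero before the onset day and always for
    OARs (K = 0).
    """
    if T < 0:
        raise InvalidParameterError("overall time T must be non-negative")
    if params.tissue_class == "oar":
        return 0.0
    return max(0.0, params.K * (T - params.T_delay))


def _lq_term(total_dose: float, d: float, params: TissueParams, h: float) -> float:
    return total_dose * (1.0 + d * (1.0 + h) / params.alpha_beta)


def bed_scalar(
    total_dose: float,
    schedule: ScheduleSummary,
    params: TissueParams,
    h: float = 0.0,
) -> BedValue:
    """Repopulation-corrected BED of a uniform-dose schedule.

    ``total_dose`` must equal ``schedule.N * schedule.d`` within tolerance;
    the repopulation term applies only to tumor tissue.
    """
    if schedule.N < 1:
        if abs(total_dose) > DOSE_TOL:
            raise ConsistencyError("non-zero dose with zero fractions")
        return BedValue(0.0, params.alpha_beta)
    if abs(total_dose - schedule.total_dose) > DOSE_TOL:
        raise ConsistencyError(
            f"total dose {total_dose} Gy inconsistent with "
            f"N*d = {schedule.total_dose} Gy"
        )
    bed = _lq_term(total_dose, schedule.d, params, h)
    bed -= repopulation_loss(params, schedule.T)
    return BedValue(bed, params.alpha_beta)


def eqd2_from_bed(bed: BedValue, params: TissueParams) -> float:
    """Convert BED to the equivalent dose in 2-Gy fractions (sign-preserving)."""
    if bed.alpha_beta_tag != params.alpha_beta:
        raise UnitError(
            f"BED tagged Gy_{bed.alpha_beta_tag:g} cannot be converted with "
            f"alpha/beta = {params.alpha_beta:g} Gy"
        )
    return bed.value * params.eqd2_factor


def segment_bed(
    segment_dose: float,
    segment: ScheduleSummary,
    params: TissueParams,
    prior_loss: float = 0.0,
    h: float = 0.0,
) -> BedValue:
    """BED of one contiguous block of fractions within a longer course.

    The repopulation loss is attributed cumulatively: this segment carries
    ``loss(T_end) - prior_loss``, where ``prior_loss`` is the loss already
    charged to earlier segments.  The result may be negative when the
    remaining loss exceeds the segment's LQ dose term.
    """
    if prior_loss < 0:
        raise ConsistencyError("prior_loss must be non-negative")
    loss_at_end = repopulation_loss(params, segment.T)
    if prior_loss > loss_at_end + DOSE_TOL:
        raise ConsistencyError(
            f"prior_loss {prior_loss} exceeds cumulative loss {loss_at_end} "
            f"at T = {segment.T}"
        )
    if segment.N < 1:
        if abs(segment_dose) > DOSE_TOL:
            raise ConsistencyError("non-zero dose with zero fractions")
        return BedValue(-(loss_at_end - prior_loss), params.alpha_beta)
    if abs(segment_dose - segment.total_dose) > DOSE_TOL:
        raise ConsistencyError(
            f"segment dose {segment_dose} Gy inconsistent with "
            f"N*d = {segment.total_dose} Gy"
        )
    bed = _lq_term(segment_dose, segment.d, params, h)
    return BedValue(bed - (loss_at_end - prior_loss), params.alpha_beta)


def _convert_doses(
    doses: np.ndarray,
    schedule: ScheduleSummary,
    params: TissueParams,
    session_groups: Sequence[tuple[int, float]],
) -> np.ndarray:
    """Map physical doses to EQD2 via the per-bin variable-dose LQ model."""
    doses = np.asarray(doses, dtype=float)
    d_i = doses / schedule.N
    bed = np.zeros_like(doses)
    for n_g, h_g in session_groups:
        bed += doses * (n_g / schedule.N) * (
            1.0 + d_i * (1.0 + h_g) / params.alpha_beta
        )
    bed -= repopulation_loss(params, schedule.T)
    return bed * params.eqd2_factor


def convert_dvh(
    dvh: DVH,
    schedule: ScheduleSummary,
    params: TissueParams,
    session_groups: Optional[Sequence[tuple[int, float]]] = None,
) -> DVH:
    """Convert a physical-dose DVH into a repopulation-corrected EQD2 DVH.

    Each bin's variable dose per fraction is ``d_i = D_i / N``.  The schedule
    may be split into ``session_groups`` of ``(fraction_count, h)`` — e.g.
    ``[(2 * TD, h_bid), (N - 2 * TD, 0.0)]`` for a course with ``TD``
    twice-daily days — whose LQ contributions are apportioned by fraction
    count and summed.  The tumor repopulation loss is subtracted uniformly
    from every bin's BED before EQD2 scaling.  Bin volumes are unchanged;
    bin edges and representative doses are mapped through the same transform.
    """
    if dvh.scale_tag != "physical":
        raise UnitError("convert_dvh requires a physical-dose DVH")
    if schedule.N < 1:
        raise InvalidParameterError("schedule must contain at least one fraction")
    if session_groups is None:
        session_groups = [(schedule.N, 0.0)]
    if any(n_g < 0 for n_g, _ in session_groups):
        raise SessionGroupError("session-group fraction counts must be >= 0")
    if sum(n_g for n_g, _ in session_groups) != schedule.N:
        raise SessionGroupError(
            "session-group fraction counts must sum to schedule.N"
        )
    if dvh.n_bins == 0:
        return dvh

    new_doses = _convert_doses(dvh.doses, schedule, params, session_groups)
    new_edges = _convert_doses(dvh.bin_edges, schedule, params, session_groups)
    return replace(
        dvh,
        bin_edges=new_edges,
        bin_doses=new_doses,
        scale_tag="EQD2",
        alpha_beta_tag=params.alpha_beta,
    )


def load_tissue_presets(path: Optional[str] = None) -> dict[str, TissueParams]:
    """Load tissue parameter presets from a YAML key-value file.

    Without ``path``, the packaged defaults are used: an RCR Category-1
    head-and-neck/lung tumor preset (alpha/beta = 10 Gy, K = 0.9 Gy/day,
    T_delay = 28 days) and generic OAR presets (alpha/beta = 3 Gy; 2 Gy for
    spinal cord).
    """
    if path is None:
        text = (
            resources.files("gapdvh").joinpath("data/tissue_presets.yaml").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    presets: dict[str, TissueParams] = {}
    for name, rec in raw.items():
        presets[name] = TissueParams(
            name=name,
            alpha_beta=float(rec["alpha_beta"]),
            K=float(rec.get("K", 0.0)),
            T_delay=float(rec.get("T_delay", 0.0)),
            repair_half_time=float(rec.get("repair_half_time", 2.0)),
            tissue_class=str(rec.get("class", "tumor")),
        )
    return presets
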