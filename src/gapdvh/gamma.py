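"""1-D gamma analysis between cumulative DVH curves.

For each point (D_r, V_r) on the reference cumulative curve,

    gamma = min over evaluated points of
            sqrt(((D_e - D_r) / (dD * D_max))^2 + ((V_e - V_r) / (dV * V_tot))^2)

where ``dD`` is a fraction of the reference curve's maximum DVH dose and
``dV`` a fraction of the reference total volume.  The evaluated curve is
densified by linear oversampling before the minimum search; a curve pair
passes when the fraction of reference points with gamma <= 1 meets the
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dvh import DVH
from .errors import EmptyStructureError, InvalidParameterError, UnitError

__all__ = ["GammaCriteria", "GammaResult", "gamma_dvh", "cumulative_points"]

OVERSAMPLE = 10
_PASS_TOL = 1e-9  # gamma == 1 counts as passing


@dataclass(frozen=True)
class GammaCriteria:
    """Agreement criteria, both expressed as fractions (0.01 means 1 %)."""

    delta_D: float = 0.01  # of the reference maximum DVH dose
    delta_V: float = 0.01  # of the reference total volume
    pass_threshold: float = 0.95

    def __post_init__(self) -> None:
        if self.delta_D <= 0 or self.delta_V <= 0:
            raise InvalidParameterError("delta_D and delta_V must be positive")
        if not (0.0 < self.pass_threshold <= 1.0):
            raise InvalidParameterError("pass_threshold must be in (0, 1]")


@dataclass(frozen=True)
class GammaResult:
    doses: np.ndarray  # reference doses at which gamma was evaluated
    gamma: np.ndarray
    pass_rate: float
    passed: bool
    criteria: GammaCriteria


def cumulative_points(dvh: DVH) -> tuple[np.ndarray, np.ndarray]:
    """(dose, volume) samples of the cumulative curve at occupied bin edges.

    Edges above the hottest occupied bin are dropped except the one closing
    that bin, so trailing empty bins do not dilute the pass rate.
    """
    edges, cum = dvh.cumulative()
    occupied = np.nonzero(dvh.differential_volume > 0)[0]
    if occupied.size == 0:
        raise EmptyStructureError("DVH has no occupied bins")
    top = occupied[-1] + 1
    return edges[: top + 1], cum[: top + 1]


def _densify(d: np.ndarray, v: np.ndarray, factor: int) -> tuple[np.ndarray, np.ndarray]:
    if d.size < 2 or factor <= 1:
        return d, v
    t = np.linspace(0.0, d.size - 1.0, (d.size - 1) * factor + 1)
    base = np.arange(d.size, dtype=float)
    return np.interp(t, base, d), np.interp(t, base, v)


def gamma_dvh(
    reference: DVH, evaluated: DVH, criteria: GammaCriteria = GammaCriteria()
) -> GammaResult:
    """Gamma analysis of ``evaluated`` against ``reference``."""
    if reference.scale_tag != evaluated.scale_tag:
        raise UnitError(
            f"scale mismatch: {reference.scale_tag} vs {evaluated.scale_tag}"
        )
    d_ref, v_ref = cumulative_points(reference)
    d_eval, v_eval = cumulative_points(evaluated)
    d_max = float(d_ref[-1])
    v_tot = reference.total_volume
    if d_max <= 0:
        raise InvalidParameterError("reference maximum DVH dose must be positive")

    d_eval, v_eval = _densify(d_eval, v_eval, OVERSAMPLE)
    dose_norm = criteria.delta_D * d_max
    vol_norm = criteria.delta_V * v_tot

    gamma = np.empty(d_ref.size)
    chunk = max(1, int(2e6 // max(d_eval.size, 1)))
    for start in range(0, d_ref.size, chunk):
        stop = min(start + chunk, d_ref.size)
        dd = (d_eval[None, :] - d_ref[start:stop, None]) / dose_norm
        dv = (v_eval[None, :] - v_ref[start:stop, None]) / vol_norm
        gamma[start:stop] = np.sqrt(np.min(dd**2 + dv**2, axis=1))

    pass_rate = float(np.mean(gamma <= 1.0 + _PASS_TOL))
    return GammaResult(
        doses=d_ref,
        gamma=gamma,
        pass_rate=pass_rate,
        passed=pass_rate >= criteria.pass_threshold,
        criteria=criteria,
    )
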