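"""CT-density to bone-stiffness calibration.

Trabecular bone stiffness is estimated from CT attenuation through the
standard densitometric chain

    rho_QCT = -0.016404 + 0.00085164 * HU          [g/cm^3]
    rho_ASH = 0.079 + 0.877 * rho_QCT              [g/cm^3]
    rho_APP = rho_ASH / 0.6                        [g/cm^3]
    E       = 4730 * rho_APP**1.56                 [MPa]
            = 10494 * rho_ASH**1.56                [MPa]

where HU is the Hounsfield value of the bone region, rho_QCT the
radiographic (QCT-equivalent) density, rho_ASH the ash density and
rho_APP the apparent (wet) density.  The two power-law forms differ only
by folding the 1/0.6 ash-to-apparent ratio into the coefficient
(4730 * (1/0.6)**1.56 = 10494 to the nearest integer); both are exposed
and are required to agree.

The module also converts the nerve-conduction-block pressure band
(100-200 mmHg) into MPa.  All chained computations keep full double
precision; rounding/truncation is applied only by the display helpers.
"""

from __future__ import annotations

from dataclasses import dataclass
import math
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "CalibrationError",
    "CalibrationPoint",
    "PressureThreshold",
    "RHO_QCT_INTERCEPT",
    "RHO_QCT_SLOPE",
    "RHO_ASH_INTERCEPT",
    "RHO_ASH_SLOPE",
    "ASH_TO_APP_RATIO",
    "E_COEFF_APP",
    "E_COEFF_ASH",
    "E_EXPONENT",
    "MMHG_TO_MPA",
    "HU_ZERO_CROSSING",
    "DEFAULT_HU_GRADES",
    "hu_to_rho_qct",
    "rho_qct_to_rho_ash",
    "rho_ash_to_rho_app",
    "modulus_from_rho_app",
    "modulus_from_rho_ash",
    "hu_to_modulus",
    "build_calibration_table",
    "mmhg_to_mpa",
    "mpa_to_mmhg",
    "truncate",
    "default_threshold",
]

# Densitometric chain constants (densities in g/cm^3, moduli in MPa).
RHO_QCT_INTERCEPT = -0.016404
RHO_QCT_SLOPE = 0.00085164
RHO_ASH_INTERCEPT = 0.079
RHO_ASH_SLOPE = 0.877
ASH_TO_APP_RATIO = 0.6
E_COEFF_APP = 4730.0
E_COEFF_ASH = 10494.0
E_EXPONENT = 1.56

#: 1 mmHg in MPa.
MMHG_TO_MPA = 133.322e-6

#: HU below which rho_QCT turns negative (physically meaningless).
HU_ZERO_CROSSING = -RHO_QCT_INTERCEPT / RHO_QCT_SLOPE

#: The fourteen trabecular-bone HU grades used by the stiffness sweep,
#: spanning dense (1250 HU ~ 10.5 GPa) to severely atrophic (20 HU ~ 0.2 GPa).
DEFAULT_HU_GRADES: tuple[float, ...] = (
    1250, 1175, 1100, 1000, 900, 800, 700, 575, 450, 375, 300, 210, 105, 20,
)


class CalibrationError(ValueError):
    """Physically invalid input to the density/stiffness chain."""


@dataclass(frozen=True)
class CalibrationPoint:
    """One row of the HU -> rho_QCT -> rho_ASH -> rho_APP -> E chain.

    Densities in g/cm^3, modulus in MPa, all at full precision.
    """

    hu: float
    rho_qct: float
    rho_ash: float
    rho_app: float
    e_modulus: float

    @property
    def e_gpa(self) -> float:
        return self.e_modulus / 1000.0


@dataclass(frozen=True)
class PressureThreshold:
    """Nerve-conduction-block pressure band, in mmHg and MPa."""

    low_mmhg: float
    high_mmhg: float

    def __post_init__(self) -> None:
        if not 0 <= self.low_mmhg < self.high_mmhg:
            raise CalibrationError(
                f"threshold band must satisfy 0 <= low < high, "
                f"got ({self.low_mmhg}, {self.high_mmhg}) mmHg"
            )

    @property
    def low_mpa(self) -> float:
        return mmhg_to_mpa(self.low_mmhg)

    @property
    def high_mpa(self) -> float:
        return mmhg_to_mpa(self.high_mmhg)

    def display_mpa(self, decimals: int = 3) -> tuple[float, float]:
        """The band as printed clinically: truncated, not rounded.

        200 mmHg = 0.0266644 MPa displays as 0.026 MPa.
        """
        return truncate(self.low_mpa, decimals), truncate(self.high_mpa, decimals)


def default_threshold() -> PressureThreshold:
    """The literature 100-200 mmHg conduction-block band."""
    return PressureThreshold(100.0, 200.0)


def _as_float(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise CalibrationError(f"{name} must be finite")
    return arr


def _ret(arr: np.ndarray, scalar: bool):
    return float(arr) if scalar else arr


def hu_to_rho_qct(hu):
    """Radiographic density [g/cm^3] from Hounsfield value.

    Raises :class:`CalibrationError` for HU below ~19.26 where the linear
    calibration turns negative (invalid CT input, not clamped).
    """
    arr = _as_float(hu, "hu")
    rho = RHO_QCT_INTERCEPT + RHO_QCT_SLOPE * arr
    if np.any(rho < 0):
        bad = np.atleast_1d(arr)[np.atleast_1d(rho) < 0]
        raise CalibrationError(
            f"HU={bad.tolist()} below zero-crossing {HU_ZERO_CROSSING:.2f}: "
            "negative radiographic density"
        )
    return _ret(rho, np.isscalar(hu) or np.ndim(hu) == 0)


def rho_qct_to_rho_ash(rho_qct):
    """Ash density [g/cm^3] from radiographic density."""
    arr = _as_float(rho_qct, "rho_qct")
    if np.any(arr < 0):
        raise CalibrationError("rho_qct must be >= 0")
    return _ret(RHO_ASH_INTERCEPT + RHO_ASH_SLOPE * arr,
                np.isscalar(rho_qct) or np.ndim(rho_qct) == 0)


def rho_ash_to_rho_app(rho_ash):
    """Apparent density [g/cm^3] from ash density (rho_APP = rho_ASH / 0.6)."""
    arr = _as_float(rho_ash, "rho_ash")
    if np.any(arr < 0):
        raise CalibrationError("rho_ash must be >= 0")
    return _ret(arr / ASH_TO_APP_RATIO, np.isscalar(rho_ash) or np.ndim(rho_ash) == 0)


def modulus_from_rho_app(rho_app):
    """Young's modulus [MPa] from apparent density: E = 4730 rho_APP^1.56."""
    arr = _as_float(rho_app, "rho_app")
    if np.any(arr < 0):
        raise CalibrationError("rho_app must be >= 0")
    return _ret(E_COEFF_APP * arr ** E_EXPONENT,
                np.isscalar(rho_app) or np.ndim(rho_app) == 0)


def modulus_from_rho_ash(rho_ash):
    """Young's modulus [MPa] from ash density: E = 10494 rho_ASH^1.56.

    Agrees with ``modulus_from_rho_app(rho_ash / 0.6)`` to better than
    0.1% relative (coefficient rounding only).
    """
    arr = _as_float(rho_ash, "rho_ash")
    if np.any(arr < 0):
        raise CalibrationError("rho_ash must be >= 0")
    return _ret(E_COEFF_ASH * arr ** E_EXPONENT,
                np.isscalar(rho_ash) or np.ndim(rho_ash) == 0)


def hu_to_modulus(hu):
    """Young's modulus [MPa] from HU via the full chain, unrounded intermediates."""
    return modulus_from_rho_ash(rho_qct_to_rho_ash(hu_to_rho_qct(hu)))


def build_calibration_table(hu_values: Iterable[float]) -> list[CalibrationPoint]:
    """Evaluate the full chain for each HU value, full precision.

    Raises on an empty input and propagates element-wise range errors.
    """
    values = list(hu_values)
    if not values:
        raise CalibrationError("hu_values must be non-empty")
    points = []
    for hu in values:
        rho_qct = hu_to_rho_qct(hu)
        rho_ash = rho_qct_to_rho_ash(rho_qct)
        rho_app = rho_ash_to_rho_app(rho_ash)
        points.append(CalibrationPoint(
            hu=float(hu),
            rho_qct=rho_qct,
            rho_ash=rho_ash,
            rho_app=rho_app,
            e_modulus=modulus_from_rho_ash(rho_ash),
        ))
    return points


def default_stiffness_grades() -> list[CalibrationPoint]:
    """The fourteen default (HU, E) sweep grades via the full chain."""
    return build_calibration_table(DEFAULT_HU_GRADES)


def mmhg_to_mpa(p):
    """Pressure mmHg -> MPa (1 mmHg = 133.322 Pa)."""
    arr = _as_float(p, "pressure")
    if np.any(arr < 0):
        raise CalibrationError("pressure must be >= 0")
    return _ret(arr * MMHG_TO_MPA, np.isscalar(p) or np.ndim(p) == 0)


def mpa_to_mmhg(p):
    """Pressure MPa -> mmHg, exact inverse of :func:`mmhg_to_mpa`."""
    arr = np.asarray(p, dtype=float)
    return _ret(arr / MMHG_TO_MPA, np.isscalar(p) or np.ndim(p) == 0)


def truncate(x: float, decimals: int = 3) -> float:
    """Truncate (toward zero) at the given number of decimals.

    Clinical displays truncate the threshold band: 0.0266644 -> 0.026.
    """
    factor = 10.0 ** decimals
    return math.trunc(float(x) * factor) / factor


def table_as_rows(points: Sequence[CalibrationPoint],
                  display: bool = False) -> list[dict]:
    """Rows for CSV/report output.

    With ``display=True`` densities are rounded to 3 decimals and the
    modulus is reported in GPa at 1 decimal, mimicking the printed table;
    otherwise full precision with E in MPa.
    """
    rows = []
    for p in points:
        if display:
            rows.append({
                "hu": p.hu,
                "rho_qct": round(p.rho_qct, 3),
                "rho_ash": round(p.rho_ash, 3),
                "rho_app": round(p.rho_app, 3),
                "E_GPa": round(p.e_gpa, 1),
            })
        else:
            rows.append({
                "hu": p.hu,
                "rho_qct": p.rho_qct,
                "rho_ash": p.rho_ash,
                "rho_app": p.rho_app,
                "E_MPa": p.e_modulus,
            })
    return rows
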