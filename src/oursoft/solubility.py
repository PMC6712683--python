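"""Oxygen solubility under prevailing process conditions.

Maximum dissolved-oxygen concentrations are computed from Tromans'
thermodynamic model for water, corrected for culture medium and for the
displacement of oxygen by CO2 in the inlet gas, and dissolved-oxygen probe
readings (% saturation) are converted to absolute concentrations with a
temperature correction for the probe's internal referencing.

Conventions
-----------
Temperatures are Kelvin internally (Celsius is accepted at I/O boundaries
only), concentrations mol L^-1, oxygen partial pressure atm, and the gas
constant R = 8.314 J mol^-1 K^-1 — the combination for which Tromans'
published coefficient set is dimensioned.

The CO2 displacement of oxygen is applied *only* through the medium
relative-solubility line (``co2_slope * y_CO2 + medium_intercept``); the
oxygen partial pressure ``p_O2`` is NOT additionally reduced by the CO2
fraction, which would double-count the effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import DomainError

#: Kelvin range within which liquid water (and the Tromans fit) is meaningful.
T_MIN_K = 273.0
T_MAX_K = 373.0

#: Gas constant matching the dimensioning of the Tromans coefficients.
R_TROMANS = 8.314


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + 273.15


def kelvin_to_celsius(t_k: float) -> float:
    return t_k - 273.15


@dataclass(frozen=True)
class SolubilityModel:
    """Coefficients for oxygen solubility in water and culture medium.

    Parameters
    ----------
    p_o2
        Oxygen partial pressure of the carrier gas, atm. Default 0.2095
        (ambient air at 1 atm headspace).
    r_gas
        Ideal gas constant, J mol^-1 K^-1.
    co2_slope
        Per-percent slope of the medium relative-solubility line
        (dimensionless, <= 0). Default -0.638.
    medium_intercept
        Relative solubility of medium vs water at zero CO2, percent.
        Default 95.63.
    t_cal
        Probe calibration temperature, K. Default 310.15 K (37 C).
    pressure_scale
        Hook scaling p_O2 for non-atmospheric headspace pressure; defaults
        to identity (1 atm).
    """

    p_o2: float = 0.2095
    r_gas: float = R_TROMANS
    co2_slope: float = -0.638
    medium_intercept: float = 95.63
    t_cal: float = 310.15
    pressure_scale: Callable[[float], float] = field(default=lambda p: p)

    def __post_init__(self) -> None:
        if self.p_o2 <= 0:
            raise DomainError(f"p_o2 must be positive, got {self.p_o2}")
        if not (0.0 < self.medium_intercept <= 100.0):
            raise DomainError(
                f"medium_intercept must lie in (0, 100], got {self.medium_intercept}"
            )
        if self.co2_slope > 0:
            raise DomainError(f"co2_slope must be <= 0, got {self.co2_slope}")
        if not (T_MIN_K < self.t_cal < T_MAX_K):
            raise DomainError(
                f"t_cal {self.t_cal} K outside liquid-water range "
                f"({T_MIN_K}, {T_MAX_K}) K"
            )

    @property
    def effective_p_o2(self) -> float:
        return self.pressure_scale(self.p_o2)

    def relative_factor(self, y_co2: float) -> float:
        """Medium relative-solubility factor (co2_slope*y + intercept)/100."""
        factor = (self.co2_slope * float(y_co2) + self.medium_intercept) / 100.0
        if factor <= 0:
            raise DomainError(
                f"relative solubility factor {factor:.4g} is non-positive at "
                f"y_CO2 = {y_co2} %; the CO2 line is only valid while the "
                "factor stays positive"
            )
        return factor


def c_star_water(t_k: float, model: SolubilityModel | None = None) -> float:
    """Maximum oxygen solubility in water, mol L^-1, at temperature ``t_k``.

    Tromans' temperature- and pressure-dependent thermodynamic expression:

        c*(T) = p_O2 * exp{ [0.046 T^2 + 203.357 T ln(T/298)
                             - (299.378 + 0.092 T)(T - 298)
                             - 20.591e3] / (R T) }

    with T in Kelvin and p_O2 in atm. Strictly positive and strictly
    decreasing over the culture-relevant range.
    """
    model = model or SolubilityModel()
    t = float(t_k)
    if not (T_MIN_K < t < T_MAX_K):
        raise DomainError(
            f"temperature {t} K outside liquid-water range ({T_MIN_K}, {T_MAX_K}) K"
        )
    numerator = (
        0.046 * t * t
        + 203.357 * t * math.log(t / 298.0)
        - (299.378 + 0.092 * t) * (t - 298.0)
        - 20.591e3
    )
    return model.effective_p_o2 * math.exp(numerator / (model.r_gas * t))


def co2_inlet_fraction(q_co2: float, q_pa: float) -> float:
    """Molar CO2 fraction of the inlet gas, percent.

    ``y_CO2 = 100 * Q_CO2 / (Q_PA + Q_CO2)`` with both flows in the same
    unit (conventionally L min^-1 from the mass-flow controllers).
    """
    q_co2 = float(q_co2)
    q_pa = float(q_pa)
    if q_co2 < 0 or q_pa < 0:
        raise DomainError("gas flow rates must be non-negative")
    total = q_co2 + q_pa
    if total == 0:
        raise DomainError("inlet gas composition undefined: both flows are zero")
    return 100.0 * q_co2 / total


def c_star_medium(
    t_k: float, y_co2: float, model: SolubilityModel | None = None
) -> float:
    """Maximum oxygen solubility in culture medium, mol L^-1.

    Scales the water solubility by the experimentally determined relative
    line for medium, which also accounts for oxygen displacement by CO2 in
    the inlet gas:

        c*_M(T, y_CO2) = c*(T) * (co2_slope * y_CO2 + medium_intercept) / 100
    """
    model = model or SolubilityModel()
    return c_star_water(t_k, model) * model.relative_factor(y_co2)


def c_do(
    do_pct: float,
    t_proc: float,
    cm_star: float,
    model: SolubilityModel | None = None,
) -> float:
    """Dissolved-oxygen concentration, mol L^-1, from a probe reading.

    The optical probe reports % saturation with an internal temperature
    correction, so the reading is re-referenced from the calibration
    temperature to the prevailing process temperature:

        c_DO = c*_M * (DO% / 100) * c*(T_proc) / c*(T_cal)
    """
    model = model or SolubilityModel()
    if do_pct < 0:
        raise DomainError(f"DO reading must be non-negative, got {do_pct}")
    ratio = c_star_water(t_proc, model) / c_star_water(model.t_cal, model)
    return float(cm_star) * (float(do_pct) / 100.0) * ratio


def do_pct_from_concentration(
    c: float,
    t_proc: float,
    cm_star: float,
    model: SolubilityModel | None = None,
) -> float:
    """Inverse of :func:`c_do`: probe % saturation that reports concentration ``c``."""
    model = model or SolubilityModel()
    ratio = c_star_water(t_proc, model) / c_star_water(model.t_cal, model)
    return 100.0 * float(c) / (float(cm_star) * ratio)
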