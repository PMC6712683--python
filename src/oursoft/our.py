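"""Oxygen transfer and uptake rates from on-line bioreactor records.

Two independent routes to the oxygen uptake rate (OUR):

* the soft-sensor route — ``OUR(t) = kLa_dyn(T, PID) * (c*_M - c_DO) - dC/dt``
  from standard on-line channels only (temperature, DO, PID output, inlet
  gas flows), with the dynamic kLa plane and the solubility corrections;
  the accumulation term dC/dt is negligible at controlled DO and defaults
  to zero;
* the off-gas mass-balance route — oxygen balanced between the gas stream
  entering and leaving the reactor, requiring an off-gas analyzer.

At a controlled (steady) DO the OUR equals the oxygen transfer rate OTR;
the soft-sensor exploits exactly that identity. OUR is reported in
mmol L^-1 h^-1, the common bioprocess convention; cumulative consumption in
mol.

Negative OUR values are flagged, never clamped: they diagnose
supersaturation, probe drift or off-gas analyzer noise (the mass-balance
route is typically negative early in a run).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import trapezoid

from .errors import DataError, DomainError, UnavailableChannelError
from .kla import KlaModel, predict_kla
from .solubility import SolubilityModel, c_do, c_star_medium, co2_inlet_fraction

#: Default inlet gas temperature for the mass balance, K (22 C).
DEFAULT_T_IN = 295.15

#: Headspace pressure, atm, for molar gas volumes.
DEFAULT_PRESSURE_ATM = 1.0

#: O2 molar fraction of dry process air, percent.
O2_IN_AIR_PCT = 20.95

#: Gas constant in L atm mol^-1 K^-1 for molar volume computations.
R_L_ATM = 0.0820574


@dataclass(frozen=True)
class OnlineRecord:
    """One on-line sample of the standard bioreactor channels.

    Required: time (h post-inoculation), temperature (K), DO (% sat),
    PID controller output (%), process-air and CO2 inlet flows (L min^-1),
    liquid volume (L). Optional channels: off-gas O2 (vol %), off-gas
    outlet temperature (K), permittivity (pF cm^-1), conductivity
    (mS cm^-1).
    """

    t: float
    temp_k: float
    do_pct: float
    pid_pct: float
    q_pa: float
    q_co2: float
    volume: float
    offgas_o2_pct: float | None = None
    offgas_temp_k: float | None = None
    permittivity: float | None = None
    conductivity: float | None = None

    def __post_init__(self) -> None:
        if self.q_pa < 0 or self.q_co2 < 0:
            raise DomainError("gas flows must be non-negative")
        if self.volume <= 0:
            raise DomainError("liquid volume must be positive")


@dataclass
class OURTrace:
    """Per-sample soft-sensor output aligned with the input trace."""

    t: np.ndarray  # h
    our: np.ndarray  # mmol L^-1 h^-1
    kla: np.ndarray  # h^-1
    c_star_m: np.ndarray  # mol L^-1
    c_do: np.ndarray  # mol L^-1
    extrapolated: np.ndarray  # bool, kLa evaluated beyond fitted domain
    negative: np.ndarray  # bool, OUR < 0

    def __len__(self) -> int:
        return self.t.size


def otr(kla_h: float, c_star: float, c_o2: float) -> float:
    """Oxygen transfer rate ``kLa * (c* - c_O2)``, mol L^-1 h^-1.

    May be negative under supersaturation; callers flag, not clamp.
    """
    if kla_h < 0:
        raise DomainError("kLa must be non-negative")
    return float(kla_h) * (float(c_star) - float(c_o2))


def our_softsensor(
    record: OnlineRecord,
    kla_model: KlaModel,
    sol: SolubilityModel | None = None,
    dcdt: float = 0.0,
) -> tuple[float, dict]:
    """Soft-sensor OUR for a single on-line record, mmol L^-1 h^-1.

    ``OUR = kLa(T, PID) * (c*_M(T, y_CO2) - c_DO) - dC/dt`` with the CO2
    inlet fraction from the flow ratio, the medium solubility correction and
    the probe temperature correction. ``dcdt`` (mol L^-1 h^-1) defaults to
    zero, the appropriate choice at controlled DO; a finite-difference
    estimate can be passed for diagnostics.

    Returns the OUR and a diagnostics dict (kla, c_star_m, c_do,
    extrapolated, negative).
    """
    sol = sol or SolubilityModel()
    y_co2 = co2_inlet_fraction(record.q_co2, record.q_pa)
    cm_star = c_star_medium(record.temp_k, y_co2, sol)
    c_o2 = c_do(record.do_pct, record.temp_k, cm_star, sol)
    pred = predict_kla(kla_model, record.temp_k, record.pid_pct)
    our_mol = otr(pred.kla, cm_star, c_o2) - dcdt
    our_mmol = our_mol * 1e3
    diag = {
        "kla": pred.kla,
        "c_star_m": cm_star,
        "c_do": c_o2,
        "extrapolated": pred.extrapolated,
        "negative": our_mmol < 0,
    }
    return our_mmol, diag


def our_softsensor_trace(
    records: Sequence[OnlineRecord],
    kla_model: KlaModel,
    sol: SolubilityModel | None = None,
    dcdt: np.ndarray | None = None,
) -> OURTrace:
    """Apply the soft-sensor to a whole trace; see :func:`our_softsensor`."""
    n = len(records)
    if dcdt is None:
        dcdt = np.zeros(n)
    out = {
        k: np.empty(n)
        for k in ("t", "our", "kla", "c_star_m", "c_do")
    }
    extrapolated = np.zeros(n, dtype=bool)
    for i, rec in enumerate(records):
        our_i, diag = our_softsensor(rec, kla_model, sol, dcdt=float(dcdt[i]))
        out["t"][i] = rec.t
        out["our"][i] = our_i
        out["kla"][i] = diag["kla"]
        out["c_star_m"][i] = diag["c_star_m"]
        out["c_do"][i] = diag["c_do"]
        extrapolated[i] = diag["extrapolated"]
    return OURTrace(
        t=out["t"],
        our=out["our"],
        kla=out["kla"],
        c_star_m=out["c_star_m"],
        c_do=out["c_do"],
        extrapolated=extrapolated,
        negative=out["our"] < 0,
    )


def dcdt_central(
    records: Sequence[OnlineRecord],
    sol: SolubilityModel | None = None,
    smooth_window: int = 5,
) -> np.ndarray:
    """Central-difference estimate of dC/dt (mol L^-1 h^-1) for diagnostics.

    The dissolved-oxygen concentration series is optionally smoothed with a
    centered moving average (odd ``smooth_window``; 1 disables) before
    differencing with :func:`numpy.gradient`.
    """
    sol = sol or SolubilityModel()
    t = np.array([r.t for r in records], dtype=float)
    if t.size < 2:
        raise DataError("need at least 2 samples for a dC/dt estimate")
    conc = np.empty_like(t)
    for i, rec in enumerate(records):
        y = co2_inlet_fraction(rec.q_co2, rec.q_pa)
        cm = c_star_medium(rec.temp_k, y, sol)
        conc[i] = c_do(rec.do_pct, rec.temp_k, cm, sol)
    if smooth_window > 1:
        if smooth_window % 2 == 0:
            raise DomainError("smooth_window must be odd")
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        padded = np.pad(conc, pad, mode="edge")
        conc = np.convolve(padded, kernel, mode="valid")
    return np.gradient(conc, t)


def molar_volume(t_k: float, pressure_atm: float = DEFAULT_PRESSURE_ATM) -> float:
    """Ideal-gas molar volume R*T/p, L mol^-1."""
    if t_k <= 0 or pressure_atm <= 0:
        raise DomainError("temperature and pressure must be positive")
    return R_L_ATM * float(t_k) / float(pressure_atm)


def our_mass_balance(
    record: OnlineRecord,
    vol_o2_in_pct: float = O2_IN_AIR_PCT,
    t_in: float = DEFAULT_T_IN,
    pressure_atm: float = DEFAULT_PRESSURE_ATM,
) -> float:
    """Off-gas mass-balance OUR, mmol L^-1 h^-1.

    ``OUR_MB = [y_in*G_in/V_m,in - y_out*G_out/V_m,out] / V_L`` with
    ``G_out = G_in`` (no flow correction), molar volumes from the ideal gas
    law at 1 atm, inlet temperature fixed at 22 C by convention and outlet
    temperature from the measured channel when present (else the inlet
    value). ``vol_o2_in_pct`` is the O2 content of the *process air* stream;
    the CO2 stream is O2-free, so the total-inlet O2 fraction is scaled by
    the air share of the total flow.
    """
    if record.offgas_o2_pct is None:
        raise UnavailableChannelError(
            "off-gas O2 channel missing: the mass-balance OUR requires an "
            "off-gas analyzer"
        )
    g_in = record.q_pa + record.q_co2  # L min^-1
    if g_in == 0:
        return 0.0
    t_out = record.offgas_temp_k if record.offgas_temp_k is not None else t_in
    y_in = vol_o2_in_pct / 100.0 * (record.q_pa / g_in)
    y_out = record.offgas_o2_pct / 100.0
    vm_in = molar_volume(t_in, pressure_atm)
    vm_out = molar_volume(t_out, pressure_atm)
    mol_per_min = y_in * g_in / vm_in - y_out * g_in / vm_out
    # mol min^-1 -> mmol L^-1 h^-1
    return mol_per_min * 60.0 * 1e3 / record.volume


def offgas_o2_from_our(
    our_mmol: float,
    q_pa: float,
    q_co2: float,
    volume: float,
    vol_o2_in_pct: float = O2_IN_AIR_PCT,
    t_in: float = DEFAULT_T_IN,
    t_out: float | None = None,
    pressure_atm: float = DEFAULT_PRESSURE_ATM,
) -> float:
    """Outlet O2 vol% consistent with a known OUR — exact inverse of
    :func:`our_mass_balance`, used by the simulator to emit off-gas data."""
    g_in = q_pa + q_co2
    if g_in <= 0:
        raise DomainError("total gas flow must be positive to define off-gas")
    t_out = t_in if t_out is None else t_out
    y_in = vol_o2_in_pct / 100.0 * (q_pa / g_in)
    vm_in = molar_volume(t_in, pressure_atm)
    vm_out = molar_volume(t_out, pressure_atm)
    mol_per_min = our_mmol / 1e3 / 60.0 * volume
    y_out = (y_in * g_in / vm_in - mol_per_min) * vm_out / g_in
    return y_out * 100.0


def total_o2_consumed(
    t_h: np.ndarray, our_mmol: np.ndarray, volumes_l: np.ndarray | float
) -> float:
    """Cumulative oxygen consumption, mol: trapezoidal integral of OUR*V."""
    t = np.asarray(t_h, dtype=float)
    our = np.asarray(our_mmol, dtype=float)
    if t.size < 2:
        raise DataError("need at least 2 points to integrate")
    if np.any(np.diff(t) <= 0):
        raise DataError("time must be strictly increasing")
    v = np.broadcast_to(np.asarray(volumes_l, dtype=float), t.shape)
    return float(trapezoid(our * v, t)) / 1e3


def specific_our(our_mmol: float, biomass: float) -> float:
    """Specific oxygen consumption rate q_O2 = OUR / biomass.

    ``biomass`` may be a viable cell concentration (cells mL^-1) or a packed
    cell volume (% v/v); the result carries the matching specific unit.
    """
    if biomass <= 0:
        raise DomainError("biomass must be positive for a specific rate")
    return float(our_mmol) / float(biomass)
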