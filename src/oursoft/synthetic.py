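"""Synthetic fed-batch campaign generator.

Forward-simulates a stirred-tank mammalian fed-batch with the mechanistic
structure the soft-sensors assume, so that every estimator in the package
can be exercised end-to-end, with known ground truth, without lab data:

* viable packed cell volume (PCV) grows logistically;
* the true OUR follows a two-segment linear function of viable PCV with a
  kink at the metabolic-shift PCV (the second state consumes less oxygen
  per cell volume);
* a DO control loop holds dissolved oxygen at the setpoint by raising the
  PID output — and with it kLa via the plane model — once the setpoint
  binds; before that, DO falls freely from saturation and the oxygen
  balance is integrated exactly (piecewise-constant coefficients give a
  closed-form exponential step);
* off-gas O2 is derived from the gas-side oxygen balance (what an off-gas
  analyzer would see), permittivity from the capacitance ground truth, and
  conductivity tracks temperature;
* seeded Gaussian noise is added per channel at the end.

In controlled (steady-DO) segments the loop closure algebraically inverts
the soft-sensor equations, so the soft-sensor applied to noise-free output
recovers the true OUR to machine precision by construction; noise then
probes robustness, not correctness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .biomass import CapacitanceModel, SegmentedLinearModel
from .errors import DomainError
from .kla import DEFAULT_TAU_P, DOStepResponse, KlaModel
from .our import O2_IN_AIR_PCT, OnlineRecord, offgas_o2_from_our
from .solubility import (
    SolubilityModel,
    c_star_medium,
    c_star_water,
    celsius_to_kelvin,
    co2_inlet_fraction,
)

#: Package-wide default simulation seed.
DEFAULT_SEED = 20190821


@dataclass(frozen=True)
class NoiseConfig:
    """Per-channel Gaussian noise standard deviations (channel units)."""

    do_pct: float = 0.2
    temp_k: float = 0.02
    pid_pct: float = 0.2
    flow: float = 0.002
    offgas_o2_pct: float = 0.02
    permittivity: float = 0.03
    conductivity: float = 0.02
    offline_rel: float = 0.03  # relative noise on off-line PCV/VCC

    @classmethod
    def noiseless(cls) -> "NoiseConfig":
        return cls(**{f: 0.0 for f in cls.__dataclass_fields__})


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic fed-batch run.

    Defaults emulate a 15 L-class CHO fed-batch: inoculation at 37 C, DO
    setpoint 30 % maintained by a PID output jointly actuating stirrer
    speed (91-228 rpm) and process-air flow (0.3-1.5 L min^-1), optional
    temperature shifts at 72/120/192/240 h, logistic growth of viable PCV,
    and a metabolic shift at ~1.4 % v/v PCV after which the slope of OUR
    versus PCV collapses. The true OUR segments adopt the slope ratio of
    the fitted field model (second-state slope ~1/42 of the first) on a
    mmol L^-1 h^-1 scale, with the second intercept chosen so the segments
    meet at the shift PCV.
    """

    seed: int = DEFAULT_SEED
    duration_h: float = 240.0
    dt_h: float = 0.1
    #: piecewise-constant temperature schedule [(start_h, temp_C), ...]
    temp_schedule: tuple = ((0.0, 37.0),)
    # logistic growth of viable PCV, % v/v
    pcv0: float = 0.3
    growth_rate: float = 0.035  # h^-1
    capacity: float = 3.2  # % v/v
    # two-segment metabolic ground truth, OUR in mmol L^-1 h^-1 per PCV %
    k1: float = 2.52
    d1: float = -0.66
    k2: float = 0.06
    d2: float = 2.784
    x_break: float = 1.4
    # DO control
    do_setpoint: float = 30.0
    do_initial: float = 100.0
    pid_min: float = 0.0
    # actuator maps (kept for emitted metadata; kLa depends on PID directly)
    rpm_range: tuple[float, float] = (91.0, 228.0)
    flow_range: tuple[float, float] = (0.3, 1.5)
    # kLa ground truth (medium)
    kla_truth: KlaModel = field(
        default_factory=lambda: KlaModel(
            beta0=-43.5, beta_pid=0.25, beta_t=0.15,
            fitted_pid_max=60.0, fitted_t_range=(304.15, 310.15),
            liquid="medium",
        )
    )
    solubility: SolubilityModel = field(default_factory=SolubilityModel)
    # CO2 flow for pH control, decaying as the culture acidifies
    q_co2_0: float = 0.03  # L min^-1
    q_co2_tau: float = 40.0  # h
    # liquid volume, fed linearly
    volume0: float = 10.5  # L
    feed_rate: float = 0.0125  # L h^-1
    # capacitance ground truth
    capacitance_truth: CapacitanceModel = field(
        default_factory=lambda: CapacitanceModel(
            cell_factor=0.4, offset=0.0, gamma=0.05, conductivity_ref=11.0
        )
    )
    conductivity_temp_coeff: float = 0.2  # mS cm^-1 K^-1
    conductivity_t_ref: float = 310.15  # K
    # viability decline (stationary/death phase)
    viability0: float = 98.0
    viability_decline_start: float = 180.0  # h
    viability_decline_rate: float = 0.15  # % h^-1
    # mean cell volume, pL, drifting upward (drives OUR-VCC non-linearity)
    mcv_pl0: float = 2.2
    mcv_growth: float = 0.004  # pL h^-1
    # off-line sampling
    offline_interval_h: float = 12.0
    # amino-acid phenomenology: Asp declining (slope break at the shift),
    # Glu rising; the Asp/Glu ratio crosses ~2 at the shift PCV
    asp0_mm: float = 8.0
    asp_slope1: float = 3.0
    asp_slope2: float = 0.5
    glu0_mm: float = 0.5
    glu_slope: float = 1.0
    noise: NoiseConfig = field(default_factory=NoiseConfig)

    def __post_init__(self) -> None:
        if self.duration_h <= 0 or self.dt_h <= 0:
            raise DomainError("duration and sampling interval must be positive")
        if self.pcv0 <= 0 or self.growth_rate <= 0 or self.capacity <= self.pcv0:
            raise DomainError("growth parameters must be positive with capacity > pcv0")
        for t0, _ in self.temp_schedule:
            if t0 > self.duration_h:
                raise DomainError("temperature schedule extends beyond the run")
        if not (0 < self.do_setpoint < 100):
            raise DomainError("DO setpoint must be in (0, 100) %")

    def segmented_truth(self) -> SegmentedLinearModel:
        return SegmentedLinearModel(
            k1=self.k1, d1=self.d1, k2=self.k2, d2=self.d2, x_break=self.x_break
        )

    def temp_at(self, t: float) -> float:
        """Temperature, K, from the piecewise-constant schedule."""
        temp_c = self.temp_schedule[0][1]
        for t0, val in self.temp_schedule:
            if t >= t0:
                temp_c = val
        return celsius_to_kelvin(temp_c)

    def pcv_at(self, t: float) -> float:
        """Logistic viable PCV, % v/v."""
        a = (self.capacity - self.pcv0) / self.pcv0
        return self.capacity / (1.0 + a * math.exp(-self.growth_rate * t))

    def our_true_at(self, pcv: float) -> float:
        if pcv <= self.x_break:
            return self.k1 * pcv + self.d1
        return self.k2 * pcv + self.d2

    def shift_time(self) -> float:
        """Time (h) at which viable PCV crosses the true breakpoint."""
        a = (self.capacity - self.pcv0) / self.pcv0
        if not (self.pcv0 < self.x_break < self.capacity):
            raise DomainError("breakpoint outside the growth range")
        return math.log(a / (self.capacity / self.x_break - 1.0)) / self.growth_rate


@dataclass
class GroundTruth:
    """Per-sample truth recorded alongside the emitted channels."""

    t: np.ndarray
    our: np.ndarray  # mmol L^-1 h^-1
    otr: np.ndarray  # mmol L^-1 h^-1 (gas-side transfer; = OUR at steady state)
    pcv_viable: np.ndarray
    steady_state: np.ndarray  # bool: DO clamped at setpoint by the controller
    state: np.ndarray  # int metabolic state 0/1
    shift_time: float
    pid_saturated: bool
    kla_model: KlaModel
    segmented_model: SegmentedLinearModel
    capacitance_model: CapacitanceModel
    solubility: SolubilityModel


@dataclass
class FedBatchResult:
    online: pd.DataFrame
    offline: pd.DataFrame
    truth: GroundTruth
    config: SimConfig

    def records(self) -> list[OnlineRecord]:
        """Emitted on-line trace as :class:`~oursoft.our.OnlineRecord` objects."""
        out = []
        for row in self.online.itertuples(index=False):
            out.append(
                OnlineRecord(
                    t=row.time_h,
                    temp_k=celsius_to_kelvin(row.temp_C),
                    do_pct=row.do_pct,
                    pid_pct=row.pid_pct,
                    q_pa=row.q_pa_Lmin,
                    q_co2=row.q_co2_Lmin,
                    volume=row.volume_L,
                    offgas_o2_pct=row.offgas_o2_pct,
                    offgas_temp_k=celsius_to_kelvin(row.offgas_temp_C),
                    permittivity=row.permittivity_pFcm,
                    conductivity=row.conductivity_mScm,
                )
            )
        return out


def simulate_fedbatch(config: SimConfig | None = None) -> FedBatchResult:
    """Run one closed-loop fed-batch simulation.

    Per time step: (i) advance viable PCV along the logistic curve and
    evaluate the true OUR from the two-segment ground truth; (ii) while the
    DO setpoint is not binding, hold the PID at its minimum and integrate
    the dissolved-oxygen balance exactly over the step; (iii) once DO
    reaches the setpoint, clamp it there and solve the kLa plane for the
    PID output that transfers exactly the consumed oxygen; (iv) emit
    off-gas O2 consistent with the gas-side transfer, capacitance channels
    from the dielectric ground truth, and per-channel noise.
    """
    cfg = config or SimConfig()
    sol = cfg.solubility
    kla_m = cfg.kla_truth
    rng = np.random.default_rng(cfg.seed)

    n = int(round(cfg.duration_h / cfg.dt_h)) + 1
    t = np.arange(n) * cfg.dt_h

    cols = {
        k: np.empty(n)
        for k in (
            "temp_k", "do_pct", "pid_pct", "q_pa", "q_co2", "volume",
            "offgas_o2", "permittivity", "conductivity",
            "our_true", "otr_true", "pcv_viable",
        )
    }
    steady = np.zeros(n, dtype=bool)
    state_arr = np.zeros(n, dtype=int)
    pid_saturated = False

    ratio_cache: dict[float, float] = {}

    def probe_ratio(t_k: float) -> float:
        if t_k not in ratio_cache:
            ratio_cache[t_k] = c_star_water(t_k, sol) / c_star_water(sol.t_cal, sol)
        return ratio_cache[t_k]

    kla_min_cache: dict[float, float] = {}

    def kla_at(t_k: float, pid: float) -> float:
        return kla_m.beta0 + kla_m.beta_pid * pid + kla_m.beta_t * t_k

    # physical dissolved O2 concentration, mol/L
    t_k0 = cfg.temp_at(0.0)
    y0 = co2_inlet_fraction(cfg.q_co2_0, cfg.flow_range[0])
    c = c_star_medium(t_k0, y0, sol) * (cfg.do_initial / 100.0) * probe_ratio(t_k0)
    controlled = False

    for i in range(n):
        ti = float(t[i])
        t_k = cfg.temp_at(ti)
        pcv = cfg.pcv_at(ti)
        our = cfg.our_true_at(pcv)  # mmol/L/h
        our_mol = our / 1e3
        q_co2 = cfg.q_co2_0 * math.exp(-ti / cfg.q_co2_tau)
        q_pa_min = cfg.flow_range[0]
        y_co2 = co2_inlet_fraction(q_co2, q_pa_min)
        cm = c_star_medium(t_k, y_co2, sol)
        c_set = cm * (cfg.do_setpoint / 100.0) * probe_ratio(t_k)

        kla_free = kla_at(t_k, cfg.pid_min)
        kla_req = our_mol / (cm - c_set)

        if not controlled:
            if kla_req > kla_free:
                # would the free response cross the setpoint within this step?
                c_inf = cm - our_mol / kla_free
                c_next = c_inf + (c - c_inf) * math.exp(-kla_free * cfg.dt_h)
                if c_next <= c_set:
                    controlled = True
            else:
                c_inf = cm - our_mol / kla_free
                c_next = c_inf + (c - c_inf) * math.exp(-kla_free * cfg.dt_h)

        if controlled:
            c = c_set
            pid = (kla_req - kla_m.beta0 - kla_m.beta_t * t_k) / kla_m.beta_pid
            sat_now = pid > 100.0
            if sat_now:
                pid_saturated = True
                pid = 100.0
            pid = max(pid, cfg.pid_min)
            kla_now = kla_at(t_k, pid)
            steady[i] = not sat_now
        else:
            pid = cfg.pid_min
            kla_now = kla_free

        do_reported = 100.0 * c / (cm * probe_ratio(t_k))
        otr_now = kla_now * (cm - c) * 1e3  # mmol/L/h
        frac = pid / 100.0
        q_pa = cfg.flow_range[0] + frac * (cfg.flow_range[1] - cfg.flow_range[0])
        volume = cfg.volume0 + cfg.feed_rate * ti

        # recompute inlet composition with the actual PA flow; keep the CO2
        # fraction used for solubility consistent by scaling q_co2 so that
        # y_CO2 is preserved at the actual total flow
        q_co2_actual = y_co2 / (100.0 - y_co2) * q_pa

        y_out = offgas_o2_from_our(
            otr_now, q_pa, q_co2_actual, volume,
            vol_o2_in_pct=O2_IN_AIR_PCT, t_out=t_k,
        )

        cond = cfg.capacitance_truth.conductivity_ref + cfg.conductivity_temp_coeff * (
            t_k - cfg.conductivity_t_ref
        )
        cap = cfg.capacitance_truth
        perm = (pcv - cap.offset) / cap.cell_factor + cap.gamma * (
            cond - cap.conductivity_ref
        )

        cols["temp_k"][i] = t_k
        cols["do_pct"][i] = do_reported
        cols["pid_pct"][i] = pid
        cols["q_pa"][i] = q_pa
        cols["q_co2"][i] = q_co2_actual
        cols["volume"][i] = volume
        cols["offgas_o2"][i] = y_out
        cols["permittivity"][i] = perm
        cols["conductivity"][i] = cond
        cols["our_true"][i] = our
        cols["otr_true"][i] = otr_now
        cols["pcv_viable"][i] = pcv
        state_arr[i] = 0 if pcv <= cfg.x_break else 1

        if not controlled:
            c = c_next

    nz = cfg.noise
    online = pd.DataFrame(
        {
            "time_h": t,
            "temp_C": cols["temp_k"] - 273.15 + rng.normal(0, nz.temp_k, n),
            "do_pct": np.maximum(cols["do_pct"] + rng.normal(0, nz.do_pct, n), 0.0),
            "pid_pct": np.clip(cols["pid_pct"] + rng.normal(0, nz.pid_pct, n), 0, 100),
            "q_pa_Lmin": np.maximum(cols["q_pa"] + rng.normal(0, nz.flow, n), 0.0),
            "q_co2_Lmin": np.maximum(cols["q_co2"] + rng.normal(0, nz.flow, n), 0.0),
            "volume_L": cols["volume"],
            "offgas_o2_pct": cols["offgas_o2"] + rng.normal(0, nz.offgas_o2_pct, n),
            "offgas_temp_C": cols["temp_k"] - 273.15,
            "permittivity_pFcm": cols["permittivity"]
            + rng.normal(0, nz.permittivity, n),
            "conductivity_mScm": cols["conductivity"]
            + rng.normal(0, nz.conductivity, n),
        }
    )

    offline = _offline_table(cfg, rng)

    truth = GroundTruth(
        t=t,
        our=cols["our_true"],
        otr=cols["otr_true"],
        pcv_viable=cols["pcv_viable"],
        steady_state=steady,
        state=state_arr,
        shift_time=cfg.shift_time(),
        pid_saturated=pid_saturated,
        kla_model=kla_m,
        segmented_model=cfg.segmented_truth(),
        capacitance_model=cfg.capacitance_truth,
        solubility=sol,
    )
    return FedBatchResult(online=online, offline=offline, truth=truth, config=cfg)


def _viability_at(cfg: SimConfig, t: float) -> float:
    v = cfg.viability0
    if t > cfg.viability_decline_start:
        v -= cfg.viability_decline_rate * (t - cfg.viability_decline_start)
    return max(v, 0.0)


def _offline_table(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    times = np.arange(0.0, cfg.duration_h + 1e-9, cfg.offline_interval_h)
    rows = []
    for ti in times:
        pcv_v = cfg.pcv_at(ti)
        viab = _viability_at(cfg, ti)
        pcv_total = pcv_v / (viab / 100.0)
        mcv_pl = cfg.mcv_pl0 + cfg.mcv_growth * ti
        vcc = pcv_v / 100.0 / (mcv_pl * 1e-9)  # cells mL^-1
        if pcv_v <= cfg.x_break:
            asp = cfg.asp0_mm - cfg.asp_slope1 * pcv_v
        else:
            asp = (
                cfg.asp0_mm
                - cfg.asp_slope1 * cfg.x_break
                - cfg.asp_slope2 * (pcv_v - cfg.x_break)
            )
        glu = cfg.glu0_mm + cfg.glu_slope * pcv_v
        rel = rng.normal(0, cfg.noise.offline_rel, 3)
        rows.append(
            {
                "time_h": ti,
                "pcv_pct": pcv_total * (1 + rel[0]),
                "viability_pct": viab,
                "vcc_cells_ml": vcc * (1 + rel[1]),
                "pcv_viable_pct": pcv_v * (1 + rel[2]),
                "asp_mM": max(asp, 0.0),
                "glu_mM": glu,
            }
        )
    return pd.DataFrame(rows)


def simulate_gassing_step(
    kla_h: float,
    tau_p: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = DEFAULT_SEED,
    direction: str = "in",
    n_samples: int = 240,
    span_tau: float = 9.5,
) -> DOStepResponse:
    """Synthetic gassing-in/out DO step response with optional probe lag.

    The liquid-side response is first-order with rate kLa; a first-order
    probe of response time ``tau_p`` (s) gives the measured signal in
    closed form. The trace covers ``span_tau`` process time constants so
    its tail pins the asymptote. Gaussian noise (% saturation) is seeded.
    """
    if kla_h <= 0:
        raise DomainError("kLa must be positive")
    k = kla_h / 3600.0  # s^-1
    t_end = span_tau / k
    times = np.linspace(0.0, t_end, n_samples)

    if tau_p > 0:
        kp = 1.0 / tau_p
        if abs(kp - k) < 1e-12:
            bracket = (1.0 + k * times) * np.exp(-k * times)
        else:
            bracket = (kp * np.exp(-k * times) - k * np.exp(-kp * times)) / (kp - k)
    else:
        bracket = np.exp(-k * times)

    do = 100.0 * (1.0 - bracket) if direction == "in" else 100.0 * bracket
    if noise_sd > 0:
        do = do + np.random.default_rng(seed).normal(0, noise_sd, do.shape)
    # validity checks against the real probe constant even for lag-free traces
    tau_for_check = tau_p if tau_p > 0 else DEFAULT_TAU_P
    return DOStepResponse(times=times, do_pct=do, direction=direction,
                          tau_p=tau_for_check)


def generate_characterization(
    liquid: str = "medium",
    temps_c: tuple = (31.0, 34.0, 37.0),
    pids: tuple = (10.0, 20.0, 30.0, 40.0, 50.0, 60.0),
    noise_rel: float = 0.02,
    seed: int = DEFAULT_SEED,
    kla_truth: KlaModel | None = None,
) -> pd.DataFrame:
    """Synthetic kLa characterization table (averaged triplicates).

    Ground-truth planes: the medium plane of :class:`SimConfig` and a water
    plane roughly one third of it, reflecting the strong positive effect of
    medium components on bubble dispersion.
    """
    if kla_truth is None:
        if liquid == "medium":
            kla_truth = SimConfig().kla_truth
        elif liquid == "water":
            kla_truth = KlaModel(
                beta0=-14.5, beta_pid=0.08, beta_t=0.05,
                fitted_pid_max=max(pids), liquid="water",
            )
        else:
            raise DomainError(f"unknown liquid {liquid!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for tc in temps_c:
        t_k = celsius_to_kelvin(tc)
        for pid in pids:
            true = kla_truth.beta0 + kla_truth.beta_pid * pid + kla_truth.beta_t * t_k
            trip = true * (1 + rng.normal(0, noise_rel, 3))
            rows.append(
                {"liquid": liquid, "temp_C": tc, "pid_pct": pid,
                 "kla_h": float(np.mean(trip))}
            )
    return pd.DataFrame(rows)


#: Temperature shift plans of a 13-run campaign: per run, the temperatures
#: (C) applied at the 72/120/192/240 h shift points (None = no change).
CAMPAIGN_SHIFTS: tuple = (
    (36.3, None, None, None),
    (36.3, None, None, None),
    (34.0, None, None, None),
    (37.0, None, 37.0, None),
    (34.0, 37.0, 34.0, 31.0),
    (31.0, 34.0, 37.0, 34.0),
    (34.0, 31.0, 31.0, 34.0),
    (37.0, 34.0, 31.0, 34.0),
    (34.0, 37.0, 31.0, 37.0),
    (34.0, None, None, None),
    (34.0, None, None, None),
    (34.0, None, None, None),
    (34.0, None, None, None),
)

SHIFT_TIMES_H = (72.0, 120.0, 192.0, 240.0)


def campaign_configs(
    seed: int = DEFAULT_SEED,
    base: SimConfig | None = None,
    duration_h: float = 260.0,
) -> list[SimConfig]:
    """Thirteen run configurations mirroring the campaign design shape:
    batch phase at 37 C, then up to four temperature shifts at
    72/120/192/240 h with setpoints drawn from {31, 34, 36.3, 37} C."""
    base = base or SimConfig()
    configs = []
    for i, shifts in enumerate(CAMPAIGN_SHIFTS):
        schedule = [(0.0, 37.0)]
        for t0, temp in zip(SHIFT_TIMES_H, shifts):
            if temp is not None:
                schedule.append((t0, temp))
        configs.append(
            replace(
                base,
                seed=seed + i,
                duration_h=duration_h,
                temp_schedule=tuple(schedule),
            )
        )
    return configs
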