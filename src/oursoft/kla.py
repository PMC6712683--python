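"""Volumetric oxygen mass transfer coefficient (kLa) estimation and modelling.

Two concerns live here:

* estimating kLa from a dynamic gassing-in / gassing-out dissolved-oxygen
  step response (log-linear regression on the saturation deficit inside the
  20-80 % window), including the probe-response validity check
  ``tau_p <= 1 / kLa``;
* fitting and evaluating the dynamic plane model ``kLa = b0 + b_pid*PID +
  b_T*T`` used by the OUR soft-sensor, with linear extrapolation above the
  characterized PID range.

kLa is expressed in h^-1 throughout; the probe validity check converts to
seconds. The model regresses directly on the PID controller output because
stirrer speed and process-air flow are jointly actuated by it; the maps
PID -> (rpm, gas flow) live in the simulator only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .errors import DataError, DomainError, FitError, InsufficientDataError

#: Experimentally determined response time of the optical DO probe, seconds.
DEFAULT_TAU_P = 49.6

#: Fractional bounds of the saturation window used for the log-linear fit,
#: measured relative to the span of the step response.
DEFAULT_WINDOW = (0.20, 0.80)


@dataclass(frozen=True)
class DOStepResponse:
    """A dissolved-oxygen step response from a gassing experiment.

    ``times`` are seconds from the step; ``do_pct`` is % saturation.
    ``direction`` is ``"in"`` (DO rising toward saturation) or ``"out"``
    (DO falling after switching to nitrogen). ``do_inf`` optionally pins the
    asymptote; when absent the final sample is used, so traces should be
    recorded until the response has settled.
    """

    times: np.ndarray
    do_pct: np.ndarray
    direction: str = "in"
    tau_p: float = DEFAULT_TAU_P
    do_inf: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.do_pct, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "do_pct", y)
        if t.ndim != 1 or t.shape != y.shape:
            raise DataError("times and do_pct must be 1-D arrays of equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise DataError("times must be strictly increasing")
        if self.direction not in ("in", "out"):
            raise DataError(f"direction must be 'in' or 'out', got {self.direction!r}")
        if self.tau_p < 0:
            raise DomainError("probe response time tau_p must be non-negative")


@dataclass(frozen=True)
class KlaEstimate:
    """Result of a gassing-step kLa estimation."""

    kla: float  # h^-1
    valid: bool  # probe-response criterion tau_p <= 1/kLa
    n_window: int  # samples inside the fitting window
    r_squared: float
    tau_p: float  # s, as used for the validity check

    @property
    def time_constant_s(self) -> float:
        """Process time constant 1/kLa in seconds."""
        return 3600.0 / self.kla


def probe_response_valid(kla_h: float, tau_p: float = DEFAULT_TAU_P) -> bool:
    """Whether the probe lag can be neglected: ``tau_p <= 1/kLa`` (seconds)."""
    if kla_h <= 0:
        raise DomainError("kLa must be positive for the validity check")
    return tau_p <= 3600.0 / kla_h


def estimate_kla(
    step: DOStepResponse,
    window: tuple[float, float] = DEFAULT_WINDOW,
    min_points: int = 5,
) -> KlaEstimate:
    """Estimate kLa (h^-1) from a gassing-in/out step response.

    Ordinary least squares of ``ln |DO_inf - DO(t)|`` against time,
    restricted to samples whose saturation lies between 20 % and 80 % of the
    response span (bounds configurable). kLa is the absolute slope,
    converted from s^-1 to h^-1. The returned validity flag records whether
    the probe response time can be neglected (``tau_p <= 1/kLa``).
    """
    t = step.times
    y = step.do_pct
    if t.size < min_points:
        raise InsufficientDataError(
            f"need at least {min_points} samples, got {t.size}"
        )
    span = float(np.max(y) - np.min(y))
    if span <= 0:
        raise DataError("constant DO trace: no step dynamics to fit")

    lo = float(np.min(y)) + window[0] * span
    hi = float(np.min(y)) + window[1] * span
    mask = (y >= lo) & (y <= hi)
    if int(mask.sum()) < min_points:
        raise InsufficientDataError(
            f"only {int(mask.sum())} samples inside the "
            f"{window[0]*100:.0f}-{window[1]*100:.0f}% window; "
            f"need at least {min_points}"
        )

    # asymptote: explicit if given, else the settled tail of the trace
    do_inf = float(y[-1]) if step.do_inf is None else float(step.do_inf)
    deficit = do_inf - y[mask] if step.direction == "in" else y[mask] - do_inf
    if np.any(deficit <= 0):
        raise DataError(
            "non-positive saturation deficit inside the fitting window; "
            "the trace is non-monotone or the asymptote is misspecified"
        )

    x = sm.add_constant(t[mask])
    fit = sm.OLS(np.log(deficit), x).fit()
    slope = float(fit.params[1])  # s^-1, negative for a decaying deficit
    kla_h = abs(slope) * 3600.0
    if kla_h == 0:
        raise DataError("zero slope: no exponential approach to saturation")
    return KlaEstimate(
        kla=kla_h,
        valid=probe_response_valid(kla_h, step.tau_p),
        n_window=int(mask.sum()),
        r_squared=float(fit.rsquared),
        tau_p=step.tau_p,
    )


@dataclass(frozen=True)
class KlaModel:
    """Linear plane ``kLa = beta0 + beta_pid * PID% + beta_T * T`` (h^-1, T in K).

    ``fitted_pid_max`` and ``fitted_t_range`` record the characterized
    domain; predictions beyond it use the same plane (linear extrapolation)
    and are flagged. Working volume carries no term: within the
    characterized 10-15 L range it showed no significant influence.
    """

    beta0: float
    beta_pid: float
    beta_t: float
    fitted_pid_max: float = 60.0
    fitted_t_range: tuple[float, float] = (304.15, 310.15)
    liquid: str = "medium"
    r_squared: float | None = None
    stderr: tuple[float, float, float] | None = None

    def coefficients(self) -> np.ndarray:
        return np.array([self.beta0, self.beta_pid, self.beta_t])


def fit_kla_model(
    temperatures_k: np.ndarray,
    pid_pct: np.ndarray,
    kla_h: np.ndarray,
    liquid: str = "medium",
    fitted_pid_max: float | None = None,
) -> KlaModel:
    """Fit the kLa plane to characterization points (T, PID%, kLa).

    Least squares on ``kLa ~ 1 + PID + T``; the fitted domain (max PID,
    temperature range) is stored so later evaluations can flag
    extrapolation. Requires >= 3 points spanning both regressors.
    """
    t = np.asarray(temperatures_k, dtype=float)
    p = np.asarray(pid_pct, dtype=float)
    k = np.asarray(kla_h, dtype=float)
    if not (t.shape == p.shape == k.shape) or t.ndim != 1:
        raise DataError("temperatures, PID and kLa must be equal-length 1-D arrays")
    if t.size < 3:
        raise InsufficientDataError("need at least 3 characterization points")
    design = np.column_stack([np.ones_like(p), p, t])
    if np.linalg.matrix_rank(design) < 3:
        raise FitError(
            "rank-deficient design: characterization points are collinear "
            "in (T, PID)"
        )
    fit = sm.OLS(k, design).fit()
    b0, bp, bt = (float(v) for v in fit.params)
    return KlaModel(
        beta0=b0,
        beta_pid=bp,
        beta_t=bt,
        fitted_pid_max=float(fitted_pid_max if fitted_pid_max is not None else p.max()),
        fitted_t_range=(float(t.min()), float(t.max())),
        liquid=liquid,
        r_squared=float(fit.rsquared),
        stderr=tuple(float(s) for s in fit.bse),
    )


@dataclass(frozen=True)
class KlaPrediction:
    kla: float  # h^-1
    extrapolated: bool


def predict_kla(model: KlaModel, t_k: float, pid_pct: float) -> KlaPrediction:
    """Evaluate the kLa plane at (T, PID%).

    Above ``fitted_pid_max`` (or outside the fitted temperature range) the
    same plane is evaluated — linear extrapolation, as used on-line when the
    controller exceeds the characterized range — and the extrapolation flag
    is set. A negative prediction is a model-domain error.
    """
    pid = float(pid_pct)
    if not (0.0 <= pid <= 100.0):
        raise DomainError(f"PID output must be in [0, 100] %, got {pid}")
    t = float(t_k)
    kla = model.beta0 + model.beta_pid * pid + model.beta_t * t
    if kla < 0:
        raise DomainError(
            f"kLa model predicts negative kLa ({kla:.4g} h^-1) at "
            f"T = {t} K, PID = {pid} %"
        )
    extrapolated = (
        pid > model.fitted_pid_max
        or t < model.fitted_t_range[0]
        or t > model.fitted_t_range[1]
    )
    return KlaPrediction(kla=float(kla), extrapolated=bool(extrapolated))
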