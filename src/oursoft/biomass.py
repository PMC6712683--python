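"""Biomass soft-sensors: segmented OUR-PCV model and capacitance model.

The oxygen uptake rate tracks viable *cell volume* (packed cell volume,
PCV, % v/v) more faithfully than cell counts. Over a fed-batch the OUR-PCV
relation shows a sharp kink where the culture switches metabolic state, so
a two-segment linear model is fitted with the breakpoint determined
iteratively as the intersection of the two per-side least-squares lines.

The second soft-sensor converts the permittivity signal of a capacitance
probe into viable PCV through a linear cell factor, with the conductivity
channel absorbing temperature effects.

Accuracy of either predictor is summarized with the mean absolute
percentage error (MAPE), normalized by the actual (off-line) values.
Off-line samples below 80 % viability are excluded before fitting: dead and
lysing cells contribute volume but no oxygen demand.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import (
    ConvergenceError,
    DataError,
    DomainError,
    FitError,
    InsufficientDataError,
)

logger = logging.getLogger(__name__)

#: Viability threshold (%, inclusive) below which off-line samples are dropped.
VIABILITY_THRESHOLD = 80.0


def filter_viable(
    samples: pd.DataFrame,
    threshold: float = VIABILITY_THRESHOLD,
    viability_col: str = "viability",
) -> pd.DataFrame:
    """Drop off-line samples below the viability threshold (inclusive at it).

    Returns the retained rows; the number removed is logged. An empty
    result triggers a warning but is returned as-is.
    """
    if viability_col not in samples.columns:
        raise DataError(f"off-line table lacks a {viability_col!r} column")
    keep = samples[viability_col] >= threshold
    removed = int((~keep).sum())
    if removed:
        logger.info("filter_viable: removed %d of %d samples below %.1f%% viability",
                    removed, len(samples), threshold)
    out = samples.loc[keep]
    if out.empty:
        warnings.warn(
            f"all {len(samples)} samples fall below {threshold}% viability",
            stacklevel=2,
        )
    return out


def line_intersection(k1: float, d1: float, k2: float, d2: float) -> float:
    """x-coordinate where ``k1*x + d1`` meets ``k2*x + d2``."""
    if k1 == k2:
        raise FitError("parallel segments: intersection undefined")
    return (d2 - d1) / (k1 - k2)


@dataclass(frozen=True)
class SegmentedLinearModel:
    """Two-segment linear OUR-PCV model with breakpoint at the intersection.

    Segment 1 (``k1*x + d1``) describes the first metabolic state, segment 2
    (``k2*x + d2``) the second; each slope is the specific oxygen uptake per
    unit of cell volume in that state. ``x_break`` is the PCV (% v/v) where
    the fitted lines intersect.
    """

    k1: float
    d1: float
    k2: float
    d2: float
    x_break: float
    n_iter: int | None = None
    sse: float | None = None
    r_squared: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.k1 == self.k2:
            raise FitError("segments must have distinct slopes")

    def segment_params(self, state: int) -> tuple[float, float]:
        if state == 0:
            return self.k1, self.d1
        if state == 1:
            return self.k2, self.d2
        raise DomainError(f"metabolic state must be 0 or 1, got {state}")

    def our_at(self, pcv: float, state: int | None = None) -> float:
        """Forward evaluation: OUR at a given PCV.

        Without an explicit state, the segment is chosen by the breakpoint
        (segment 1 up to and including ``x_break``).
        """
        if state is None:
            state = 0 if pcv <= self.x_break else 1
        k, d = self.segment_params(state)
        return k * float(pcv) + d

    @property
    def intersection_our(self) -> float:
        """OUR value at the segment intersection."""
        return self.our_at(self.x_break, state=0)


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and SSE of a simple least-squares line."""
    design = np.column_stack([x, np.ones_like(x)])
    coef, res, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < 2:
        raise FitError("degenerate side: x values are constant")
    sse = float(res[0]) if res.size else float(np.sum((y - design @ coef) ** 2))
    return float(coef[0]), float(coef[1]), sse


def fit_segmented(
    x: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 100,
    percentile_band: tuple[float, float] = (5.0, 95.0),
    min_per_side: int = 2,
) -> SegmentedLinearModel:
    """Fit the two-segment model with an iteratively determined breakpoint.

    Procedure: (i) initialize the breakpoint at the SSE-minimizing candidate
    among midpoints of consecutive sorted x values inside the inner
    5th-95th percentile band (ties broken toward the smaller SSE, then the
    smaller x); (ii) partition the data at the breakpoint (left side
    inclusive) and fit an ordinary least-squares line per side; (iii) move
    the breakpoint to the intersection of the two lines; repeat (ii)-(iii)
    until the breakpoint moves less than ``tol`` or ``max_iter`` is reached.

    Continuity is *not* imposed: the breakpoint is defined purely as the
    intersection of the two independently fitted lines.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("x and y must be equal-length 1-D arrays")
    if x.size < 2 * min_per_side:
        raise InsufficientDataError(
            f"need at least {2 * min_per_side} points for a segmented fit"
        )

    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]

    lo, hi = np.percentile(xs, percentile_band)
    mids = (xs[:-1] + xs[1:]) / 2.0
    candidates = np.unique(mids[(mids >= lo) & (mids <= hi)])
    if candidates.size == 0:
        candidates = np.unique(mids)
    if candidates.size == 0:
        raise InsufficientDataError("no candidate breakpoints between x values")

    def sides(bp: float):
        left = xs <= bp
        return (xs[left], ys[left]), (xs[~left], ys[~left])

    def two_line_fit(bp: float):
        (xl, yl), (xr, yr) = sides(bp)
        if xl.size < min_per_side or xr.size < min_per_side:
            return None
        k1, d1, sse1 = _ols_line(xl, yl)
        k2, d2, sse2 = _ols_line(xr, yr)
        return k1, d1, k2, d2, sse1 + sse2

    best_bp, best_sse = None, np.inf
    for bp in candidates:  # ascending: ties resolve to the smaller x
        try:
            fitted = two_line_fit(float(bp))
        except FitError:
            continue
        if fitted is not None and fitted[4] < best_sse:
            best_bp, best_sse = float(bp), fitted[4]
    if best_bp is None:
        raise InsufficientDataError(
            "no candidate breakpoint leaves enough points on both sides"
        )

    bp = best_bp
    last_fit = None
    for it in range(1, max_iter + 1):
        fitted = two_line_fit(bp)
        if fitted is None:
            raise ConvergenceError(
                f"breakpoint iterate {bp:.6g} strands a side with fewer than "
                f"{min_per_side} points",
                last_iterate=bp,
            )
        k1, d1, k2, d2, sse = fitted
        last_fit = fitted
        new_bp = line_intersection(k1, d1, k2, d2)
        if abs(new_bp - bp) < tol:
            bp = new_bp
            break
        bp = new_bp
    else:
        raise ConvergenceError(
            f"breakpoint iteration did not converge in {max_iter} steps "
            f"(last iterate {bp:.6g})",
            last_iterate=bp,
        )

    k1, d1, k2, d2, sse = last_fit
    if not (xs[0] <= bp <= xs[-1]):
        raise ConvergenceError(
            f"fitted breakpoint {bp:.6g} lies outside the data range "
            f"[{xs[0]:.6g}, {xs[-1]:.6g}]",
            last_iterate=bp,
        )

    def r2(xv, yv, k, d):
        resid = yv - (k * xv + d)
        tss = float(np.sum((yv - yv.mean()) ** 2))
        return 1.0 - float(np.sum(resid**2)) / tss if tss > 0 else 1.0

    (xl, yl), (xr, yr) = sides(bp)
    return SegmentedLinearModel(
        k1=k1, d1=d1, k2=k2, d2=d2, x_break=float(bp),
        n_iter=it, sse=float(sse),
        r_squared=(r2(xl, yl, k1, d1), r2(xr, yr, k2, d2)),
    )


def predict_pcv_from_our(
    model: SegmentedLinearModel, our: float, state: int
) -> tuple[float, bool]:
    """Invert the segment selected by the metabolic state: PCV = (OUR - d)/k.

    Returns (pcv, negative_flag); a negative inverse is flagged, not
    clamped, since it signals an OUR below the segment's intercept.
    """
    k, d = model.segment_params(state)
    if k == 0:
        raise FitError(f"segment {state + 1} has zero slope: not invertible")
    pcv = (float(our) - d) / k
    return pcv, pcv < 0


@dataclass(frozen=True)
class CapacitanceModel:
    """Linear permittivity -> viable PCV model with conductivity correction.

    ``pcv = cell_factor * (permittivity - gamma * (conductivity -
    conductivity_ref)) + offset``. The cell factor (PCV % per pF cm^-1) is
    the dielectric proportionality between polarized viable cell volume and
    permittivity; the conductivity term absorbs temperature-driven drift of
    the background signal.
    """

    cell_factor: float
    offset: float = 0.0
    gamma: float = 0.0
    conductivity_ref: float = 0.0
    stderr: dict | None = None
    r_squared: float | None = None

    def __post_init__(self) -> None:
        if self.cell_factor <= 0:
            raise FitError("cell_factor must be positive")


def fit_capacitance(
    permittivity: np.ndarray,
    conductivity: np.ndarray,
    pcv: np.ndarray,
    conductivity_ref: float | None = None,
) -> CapacitanceModel:
    """Fit the capacitance PCV model by least squares.

    The model is linear in (permittivity, conductivity deviation), so the
    joint fit is an OLS of ``pcv ~ permittivity + (conductivity - ref) + 1``
    with ``gamma`` recovered from the coefficient ratio. When conductivity
    does not vary, gamma is unidentifiable and fixed at 0 with a warning.
    """
    eps = np.asarray(permittivity, dtype=float)
    cond = np.asarray(conductivity, dtype=float)
    y = np.asarray(pcv, dtype=float)
    if not (eps.shape == cond.shape == y.shape) or eps.ndim != 1:
        raise DataError("permittivity, conductivity and pcv must be aligned 1-D arrays")
    if eps.size < 3:
        raise InsufficientDataError("need at least 3 aligned samples")
    if np.ptp(eps) == 0:
        raise FitError("constant permittivity: cell factor unidentifiable")

    ref = float(conductivity_ref if conductivity_ref is not None else cond.mean())
    dcond = cond - ref

    if np.ptp(dcond) == 0:
        warnings.warn(
            "conductivity is constant; fixing gamma = 0 (temperature "
            "correction unidentifiable)",
            stacklevel=2,
        )
        design = sm.add_constant(eps)
        fit = sm.OLS(y, design).fit()
        const, a = (float(v) for v in fit.params)
        return CapacitanceModel(
            cell_factor=a, offset=const, gamma=0.0, conductivity_ref=ref,
            stderr={"cell_factor": float(fit.bse[1]), "offset": float(fit.bse[0]),
                    "gamma": float("nan")},
            r_squared=float(fit.rsquared),
        )

    design = np.column_stack([np.ones_like(eps), eps, dcond])
    fit = sm.OLS(y, design).fit()
    const, a, b = (float(v) for v in fit.params)
    if a <= 0:
        raise FitError(
            f"fitted cell factor is non-positive ({a:.4g}); permittivity does "
            "not increase with PCV in these data"
        )
    gamma = -b / a
    se_c, se_a, se_b = (float(s) for s in fit.bse)
    # delta-method SE for the ratio gamma = -b/a
    with np.errstate(divide="ignore", invalid="ignore"):
        se_gamma = abs(gamma) * np.sqrt(
            (se_a / a) ** 2 + (se_b / b) ** 2) if b != 0 else se_b / a
    return CapacitanceModel(
        cell_factor=a, offset=const, gamma=gamma, conductivity_ref=ref,
        stderr={"cell_factor": se_a, "offset": se_c, "gamma": float(se_gamma)},
        r_squared=float(fit.rsquared),
    )


def predict_pcv_from_capacitance(
    model: CapacitanceModel,
    permittivity: np.ndarray | float,
    conductivity: np.ndarray | float,
) -> np.ndarray | float:
    """Viable PCV (% v/v) from capacitance channels; negative results are
    the caller's to flag."""
    eps = np.asarray(permittivity, dtype=float)
    cond = np.asarray(conductivity, dtype=float)
    out = model.cell_factor * (
        eps - model.gamma * (cond - model.conductivity_ref)
    ) + model.offset
    return float(out) if out.ndim == 0 else out


def mape(actual: np.ndarray, predicted: np.ndarray) -> float:
    """Mean absolute percentage error, %, normalized by the actual values:
    ``100/n * sum |(actual - predicted)/actual|``."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.ndim != 1 or a.size == 0:
        raise DataError("actual and predicted must be equal-length non-empty 1-D arrays")
    if np.any(a == 0):
        raise DomainError("MAPE undefined: actual values contain zeros")
    return float(np.mean(np.abs((a - p) / a)) * 100.0)


def train_test_mape(
    samples: pd.DataFrame,
    test_runs: Sequence | None = None,
    run_col: str = "run",
    actual_col: str = "pcv_viable",
    predicted_col: str = "pcv_predicted",
) -> dict:
    """MAPE on a train/test split by run identifier.

    Fitting happens upstream; this helper only evaluates predictions under
    the split semantics used for the soft-sensor models: designated runs are
    held out as the test set (e.g. replicate static runs), all others form
    the training set.
    """
    if test_runs is None:
        test_runs = []
    is_test = samples[run_col].isin(list(test_runs))
    out = {}
    for name, mask in (("training", ~is_test), ("test", is_test)):
        sub = samples.loc[mask]
        out[name] = (
            mape(sub[actual_col].to_numpy(), sub[predicted_col].to_numpy())
            if len(sub)
            else float("nan")
        )
    return out
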