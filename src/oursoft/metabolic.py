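"""On-line metabolic-transition sensor.

Combines the two biomass soft-sensors into a binary state signal. Two PCV
estimates are obtained by inverting each segment of the OUR-PCV model at
the current OUR; a third comes from the capacitance model. Near the
metabolic shift the culture sits at the segment intersection, so both
segment inverses agree with each other *and* with the capacitance estimate.
When both agreement conditions hold (within a tolerance, for a debounce
number of consecutive samples) the sensor latches from state 0 (first
metabolic state) to state 1 (second state) and never reverts.

The tolerance (default 0.05 PCV % v/v) and debounce (default 3 samples) are
package choices, reported with every detection; a non-latching diagnostic
mode is available for exploration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .biomass import SegmentedLinearModel, predict_pcv_from_our
from .errors import DataError, DomainError

DEFAULT_TOL = 0.05  # PCV % v/v
DEFAULT_DEBOUNCE = 3  # consecutive samples


@dataclass(frozen=True)
class MetabolicSensorState:
    """Latched sensor state plus the agreement diagnostics that drive it.

    ``gap_segments`` is |PCV_f1 - PCV_f2| at the last sample;
    ``gap_capacitance`` is min_i |PCV_fi - PCV_cap|. ``streak`` counts
    consecutive samples satisfying both conditions (reset on failure,
    frozen once latched).
    """

    state: int = 0
    trigger_time: float | None = None
    streak: int = 0
    gap_segments: float = float("nan")
    gap_capacitance: float = float("nan")

    def __post_init__(self) -> None:
        if self.state not in (0, 1):
            raise DomainError("sensor state must be 0 or 1")
        if (self.trigger_time is not None) != (self.state == 1):
            raise DomainError("trigger_time must be set iff state is 1")


def sensor_step(
    our: float,
    pcv_cap: float,
    model: SegmentedLinearModel,
    t: float,
    prev: MetabolicSensorState | None = None,
    tol: float = DEFAULT_TOL,
    debounce: int = DEFAULT_DEBOUNCE,
    latching: bool = True,
) -> MetabolicSensorState:
    """Advance the sensor by one sample.

    The shift condition at a sample is
    ``|PCV_f1 - PCV_f2| <= tol  and  min_i |PCV_fi - PCV_cap| <= tol``
    with PCV_fi the inverse of segment i at the current OUR. The condition
    must hold for ``debounce`` consecutive samples before the sensor jumps
    from 0 to 1; once latched it stays at 1.
    """
    if tol <= 0:
        raise DomainError("tolerance must be positive")
    if debounce < 1:
        raise DomainError("debounce must be at least 1 sample")
    prev = prev or MetabolicSensorState()

    pcv_f1, _ = predict_pcv_from_our(model, our, state=0)
    pcv_f2, _ = predict_pcv_from_our(model, our, state=1)
    gap_seg = abs(pcv_f1 - pcv_f2)
    gap_cap = min(abs(pcv_f1 - pcv_cap), abs(pcv_f2 - pcv_cap))
    condition = gap_seg <= tol and gap_cap <= tol

    if latching and prev.state == 1:
        return replace(prev, gap_segments=gap_seg, gap_capacitance=gap_cap)

    streak = prev.streak + 1 if condition else 0
    if streak >= debounce:
        return MetabolicSensorState(
            state=1, trigger_time=float(t), streak=streak,
            gap_segments=gap_seg, gap_capacitance=gap_cap,
        )
    return MetabolicSensorState(
        state=0, trigger_time=None, streak=streak,
        gap_segments=gap_seg, gap_capacitance=gap_cap,
    )


@dataclass(frozen=True)
class SensorRun:
    """Full 0/1 signal of a sensor pass over a trace."""

    t: np.ndarray
    signal: np.ndarray  # int 0/1
    trigger_time: float | None
    gap_segments: np.ndarray
    gap_capacitance: np.ndarray
    tol: float
    debounce: int


def sensor_run(
    t: np.ndarray,
    our: np.ndarray,
    pcv_cap: np.ndarray,
    model: SegmentedLinearModel,
    tol: float = DEFAULT_TOL,
    debounce: int = DEFAULT_DEBOUNCE,
    latching: bool = True,
) -> SensorRun:
    """Fold :func:`sensor_step` over aligned OUR and capacitance-PCV series."""
    t = np.asarray(t, dtype=float)
    our = np.asarray(our, dtype=float)
    pcv_cap = np.asarray(pcv_cap, dtype=float)
    if not (t.shape == our.shape == pcv_cap.shape) or t.ndim != 1:
        raise DataError("t, our and pcv_cap must be aligned 1-D series")

    state = MetabolicSensorState()
    signal = np.zeros(t.size, dtype=int)
    gseg = np.empty(t.size)
    gcap = np.empty(t.size)
    for i in range(t.size):
        state = sensor_step(
            float(our[i]), float(pcv_cap[i]), model, float(t[i]),
            prev=state, tol=tol, debounce=debounce, latching=latching,
        )
        signal[i] = state.state
        gseg[i] = state.gap_segments
        gcap[i] = state.gap_capacitance
    return SensorRun(
        t=t, signal=signal, trigger_time=state.trigger_time,
        gap_segments=gseg, gap_capacitance=gcap, tol=tol, debounce=debounce,
    )
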