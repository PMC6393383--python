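"""Coupled rate dynamics of the striatal TAN population and dopamine.

The model tracks four state variables on a uniform time grid:

* ``v_tan`` — normalized firing rate of the striatal cholinergic
  interneuron (TAN) population, in [0, 1).
* ``i_sahp`` — slow after-hyperpolarization current input (non-positive);
  activated when TAN activity exceeds a threshold, it generates the
  characteristic pause that follows a thalamic burst.
* ``i_h`` — depolarizing h-current input (non-negative); activated during
  hyperpolarization, it drives recovery from the pause and is suppressed
  by dopamine through D2 receptors (``exp(-w_da * da)`` scaling).
* ``da`` — striatal dopamine concentration in normalized units.  While
  the TANs fire tonically, acetylcholine clamps release at the baseline;
  when TAN activity drops below the nicotinic threshold during a pause,
  the concentration relaxes toward baseline + RPE — the phasic excursion
  that encodes the reward prediction error.

All relaxations are first-order: ``tau * dx/dt + x = target(state)``.
Dopamine deficiency scales the entire dopamine drive by ``alpha`` and
levodopa adds a constant to it, so the no-stimulus baseline is
``alpha * da0 + ldopa``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "ModelParams",
    "ScenarioContext",
    "StimulusProtocol",
    "SystemState",
    "SimulationTrace",
    "PauseMetrics",
    "sigma",
    "heaviside",
    "derivatives",
    "integrate",
    "steady_state",
    "detect_pause",
    "phasic_da_integral",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelParams:
    """Constants of the TAN–dopamine rate model.

    Defaults are the published calibration against in-vitro TAN
    recordings.  Time constants are in milliseconds; everything else is
    dimensionless (dopamine in normalized concentration units).
    """

    tau_tan: float = 20.0      # TAN activity time constant, ms
    w_thal: float = 4.0        # thalamic synaptic weight
    drv_tan: float = 0.3       # constant drive setting the tonic rate
    tau_sahp: float = 700.0    # sAHP time constant, ms
    g_sahp: float = 5.0        # sAHP activation gain
    theta_sahp: float = 0.3    # sAHP activation threshold on v_tan
    tau_h: float = 700.0       # h-current time constant, ms
    g_h: float = 20.0          # h-current activation gain
    theta_h: float = 0.2       # h-current activation threshold
    w_da: float = 1.0          # dopamine weight on the h-current
    tau_da: float = 20.0       # dopamine time constant, ms
    theta_da: float = 0.01     # nicotinic receptor threshold on v_tan
    da0: float = 1.0           # baseline dopamine concentration

    def __post_init__(self) -> None:
        for name in ("tau_tan", "tau_sahp", "tau_h", "tau_da"):
            if getattr(self, name) <= 0:
                raise ValueError(f"time constant {name} must be > 0")
        for name in ("w_thal", "drv_tan", "g_sahp", "theta_sahp", "g_h",
                     "theta_h", "w_da", "theta_da", "da0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.theta_da < self.theta_h < self.theta_sahp):
            warnings.warn(
                "thresholds violate 0 < theta_da < theta_h < theta_sahp; "
                "the model leaves its calibrated regime",
                stacklevel=2,
            )

    def replace(self, **changes: float) -> "ModelParams":
        return replace(self, **changes)


@dataclass(frozen=True)
class ScenarioContext:
    """Reward and disease context of a simulation.

    ``rpe`` is the reward prediction error in [-1, 1] (silently clamped);
    ``alpha`` scales all dopamine production (1 = healthy, 0 = complete
    nigrostriatal loss); ``ldopa`` is the constant baseline increase from
    levodopa medication.
    """

    rpe: float = 0.0
    alpha: float = 1.0
    ldopa: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "rpe", float(min(1.0, max(-1.0, self.rpe))))
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.ldopa < 0:
            raise ValueError("ldopa must be >= 0")

    def effective_baseline(self, params: ModelParams) -> float:
        """Baseline dopamine under deficiency/levodopa: alpha*da0 + ldopa."""
        return self.alpha * params.da0 + self.ldopa

    def replace(self, **changes: float) -> "ScenarioContext":
        return replace(self, **changes)


@dataclass(frozen=True)
class StimulusProtocol:
    """Binary thalamic input as ordered half-open on-intervals, in ms."""

    intervals: tuple[tuple[float, float], ...]
    total_duration_ms: float

    def __init__(self,
                 intervals: Sequence[tuple[float, float]],
                 total_duration_ms: float) -> None:
        ivs = tuple((float(a), float(b)) for a, b in intervals)
        if total_duration_ms <= 0:
            raise ValueError("total_duration_ms must be > 0")
        prev_end = 0.0
        for a, b in ivs:
            if not (0.0 <= a < b <= total_duration_ms):
                raise ValueError(
                    f"interval ({a}, {b}) not contained in "
                    f"[0, {total_duration_ms})")
            if a < prev_end:
                raise ValueError("stimulus intervals overlap or are unsorted")
            prev_end = b
        object.__setattr__(self, "intervals", ivs)
        object.__setattr__(self, "total_duration_ms", float(total_duration_ms))

    def is_on(self, t: float) -> bool:
        return any(a <= t < b for a, b in self.intervals)

    def indicator(self, t: np.ndarray) -> np.ndarray:
        """Boolean V_Thal(t) on an arbitrary time grid."""
        on = np.zeros(len(t), dtype=bool)
        for a, b in self.intervals:
            on |= (t >= a) & (t < b)
        return on

    @property
    def last_offset_ms(self) -> Optional[float]:
        return self.intervals[-1][1] if self.intervals else None

    @staticmethod
    def none(total_duration_ms: float) -> "StimulusProtocol":
        return StimulusProtocol((), total_duration_ms)


@dataclass
class SystemState:
    """Instantaneous model state (v_tan, i_sahp, i_h, da)."""

    v_tan: float
    i_sahp: float
    i_h: float
    da: float

    def as_array(self) -> np.ndarray:
        return np.array([self.v_tan, self.i_sahp, self.i_h, self.da])


@dataclass
class SimulationTrace:
    """Time-indexed state series plus the inputs that produced it."""

    t: np.ndarray
    v_tan: np.ndarray
    i_sahp: np.ndarray
    i_h: np.ndarray
    da: np.ndarray
    params: ModelParams
    stimulus: StimulusProtocol
    context: ScenarioContext
    dt: float

    def __len__(self) -> int:
        return len(self.t)

    def state_at(self, i: int) -> SystemState:
        return SystemState(float(self.v_tan[i]), float(self.i_sahp[i]),
                           float(self.i_h[i]), float(self.da[i]))


@dataclass
class PauseMetrics:
    """Detected TAN pause and the dopamine excursion inside it.

    ``duration_ms`` is 0 when no pause was detected; ``censored`` flags a
    pause that had not recovered by the end of the simulation horizon.
    """

    onset_ms: Optional[float] = None
    offset_ms: Optional[float] = None
    duration_ms: float = 0.0
    min_da: Optional[float] = None
    max_da: Optional[float] = None
    censored: bool = False

    @property
    def has_pause(self) -> bool:
        return self.onset_ms is not None

    def to_dict(self) -> dict:
        return {
            "onset_ms": self.onset_ms,
            "offset_ms": self.offset_ms,
            "duration_ms": self.duration_ms,
            "min_da": self.min_da,
            "max_da": self.max_da,
            "censored": self.censored,
        }


# --------------------------------------------------------------------------
# right-hand side
# --------------------------------------------------------------------------

def heaviside(x: float) -> float:
    """Step function with the convention H(0) = 0.

    The zero-at-threshold convention keeps every current's target exactly
    zero at its own activation threshold, so the tonic fixed point is an
    exact equilibrium.
    """
    return 1.0 if x > 0 else 0.0


def sigma(x: float) -> float:
    """Rectified hyperbolic tangent, H(x) * tanh(x), with range [0, 1)."""
    if not math.isfinite(x):
        raise ValueError(f"sigma requires finite input, got {x!r}")
    return math.tanh(x) if x > 0 else 0.0


def _targets(v: float, da: float, thal: float,
             p: ModelParams, ctx: ScenarioContext) -> tuple[float, float, float, float]:
    """Relaxation targets of the four state variables."""
    i_tan = p.w_thal * thal + p.drv_tan  # currents added by caller
    sahp_target = -p.g_sahp * (v - p.theta_sahp) * heaviside(v - p.theta_sahp)
    h_target = (-p.g_h * math.exp(-p.w_da * da)
                * (v - p.theta_h) * heaviside(p.theta_h - v))
    da_target = (ctx.alpha
                 * (ctx.rpe * (1.0 - v / p.theta_da) * heaviside(p.theta_da - v)
                    + p.da0)
                 + ctx.ldopa)
    return i_tan, sahp_target, h_target, da_target


def derivatives(state: SystemState, t: float, params: ModelParams,
                stim: StimulusProtocol, ctx: ScenarioContext) -> SystemState:
    """Time derivatives of the state, as written in the model equations.

    Returned as a :class:`SystemState` whose fields hold d/dt values
    (per ms).
    """
    thal = 1.0 if stim.is_on(t) else 0.0
    i_tan, sahp_t, h_t, da_t = _targets(state.v_tan, state.da, thal,
                                        params, ctx)
    drive = i_tan + state.i_sahp + state.i_h
    dv = (sigma(drive) - state.v_tan) / params.tau_tan
    dsahp = (sahp_t - state.i_sahp) / params.tau_sahp
    dh = (h_t - state.i_h) / params.tau_h
    dda = (da_t - state.da) / params.tau_da
    return SystemState(dv, dsahp, dh, dda)


# --------------------------------------------------------------------------
# fixed point
# --------------------------------------------------------------------------

def steady_state(params: ModelParams, ctx: ScenarioContext,
                 max_iter: int = 500, tol: float = 1e-13) -> SystemState:
    """No-stimulus fixed point of the coupled system.

    Solved by damped fixed-point iteration on (v, da); with the default
    parameters the tonic rate tanh(drv_tan) sits strictly between the
    h-current and sAHP thresholds, both current targets vanish, and the
    solution reduces to ``v* = tanh(drv_tan)``, ``da* = alpha*da0 + ldopa``.
    """
    v = sigma(params.drv_tan) if params.drv_tan > 0 else 0.0
    da = ctx.effective_baseline(params)
    for _ in range(max_iter):
        _, sahp_t, h_t, da_t = _targets(v, da, 0.0, params, ctx)
        da_new = max(0.0, da_t)
        v_new = sigma(params.drv_tan + sahp_t + h_t)
        # damping guards against overshoot across the current thresholds
        v_next = 0.5 * (v + v_new)
        da_next = 0.5 * (da + da_new)
        if abs(v_next - v) < tol and abs(da_next - da) < tol:
            _, sahp_t, h_t, da_t = _targets(v_next, da_next, 0.0, params, ctx)
            return SystemState(v_next, sahp_t, h_t, max(0.0, da_t))
        v, da = v_next, da_next
    raise RuntimeError(
        f"steady_state failed to converge within {max_iter} iterations")


# --------------------------------------------------------------------------
# integration
# --------------------------------------------------------------------------

def integrate(params: ModelParams, stim: StimulusProtocol,
              ctx: ScenarioContext, dt: float = 1.0,
              init: Union[SystemState, str] = "rest") -> SimulationTrace:
    """Forward-Euler integration of the model on a uniform grid.

    ``init="rest"`` starts at the analytic no-stimulus fixed point, which
    is the physiological tonic-firing condition.  Deterministic for fixed
    inputs.  Dopamine is clipped at zero from below (a concentration);
    the equations can transiently target negative values for extreme
    combinations of ``alpha`` and negative RPE.

    Raises ``ValueError`` if ``v_tan`` leaves [0, 1), which indicates a
    step size too coarse for the time constants in use.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    n = int(round(stim.total_duration_ms / dt)) + 1
    t = np.arange(n) * dt

    if isinstance(init, str):
        if init != "rest":
            raise ValueError(f"unknown init {init!r}; use 'rest' or a state")
        state0 = steady_state(params, ctx)
    else:
        state0 = init

    thal_on = stim.indicator(t)

    v_arr = np.empty(n)
    sahp_arr = np.empty(n)
    h_arr = np.empty(n)
    da_arr = np.empty(n)

    v, isahp, ih, da = (state0.v_tan, state0.i_sahp, state0.i_h,
                        max(0.0, state0.da))
    p = params
    g_sahp, th_sahp = p.g_sahp, p.theta_sahp
    g_h, th_h, w_da = p.g_h, p.theta_h, p.w_da
    th_da, da0, alpha, rpe, ldopa = p.theta_da, p.da0, ctx.alpha, ctx.rpe, ctx.ldopa
    r_tan, r_sahp, r_h, r_da = (dt / p.tau_tan, dt / p.tau_sahp,
                                dt / p.tau_h, dt / p.tau_da)
    w_thal, drv = p.w_thal, p.drv_tan
    exp = math.exp
    tanh = math.tanh

    for k in range(n):
        v_arr[k] = v
        sahp_arr[k] = isahp
        h_arr[k] = ih
        da_arr[k] = da
        if k == n - 1:
            break
        drive = (w_thal if thal_on[k] else 0.0) + drv + isahp + ih
        v_inf = tanh(drive) if drive > 0 else 0.0
        sahp_t = -g_sahp * (v - th_sahp) if v > th_sahp else 0.0
        h_t = -g_h * exp(-w_da * da) * (v - th_h) if v < th_h else 0.0
        da_t = (alpha * (rpe * (1.0 - v / th_da) + da0) + ldopa
                if v < th_da else alpha * da0 + ldopa)
        v += r_tan * (v_inf - v)
        isahp += r_sahp * (sahp_t - isahp)
        ih += r_h * (h_t - ih)
        da += r_da * (da_t - da)
        if da < 0.0:
            da = 0.0
        if not 0.0 <= v < 1.0:
            raise ValueError(
                f"v_tan left [0, 1) at t={t[k + 1]:.3f} ms; "
                f"dt={dt} ms is too large for these parameters — "
                "use a smaller step")

    return SimulationTrace(t=t, v_tan=v_arr, i_sahp=sahp_arr, i_h=h_arr,
                           da=da_arr, params=params, stimulus=stim,
                           context=ctx, dt=dt)


# --------------------------------------------------------------------------
# measurements on traces
# --------------------------------------------------------------------------

def detect_pause(trace: SimulationTrace,
                 pause_threshold: Union[float, str] = "auto") -> PauseMetrics:
    """Locate the TAN pause following the last stimulus offset.

    The pause onset is the first grid time at or after the last stimulus
    offset at which ``v_tan`` drops below the threshold; the offset is the
    first later grid time at which it recovers.  ``"auto"`` sets the
    threshold to 90% of the resting rate of the same parameters/context.
    A pause that never recovers within the horizon is returned censored,
    with the duration measured to the end of the trace.
    """
    last_off = trace.stimulus.last_offset_ms
    if last_off is None:
        return PauseMetrics()

    if pause_threshold == "auto":
        thr = 0.9 * steady_state(trace.params, trace.context).v_tan
    else:
        thr = float(pause_threshold)

    start = int(np.searchsorted(trace.t, last_off, side="left"))
    v = trace.v_tan
    below = np.flatnonzero(v[start:] < thr)
    if below.size == 0:
        return PauseMetrics()
    i_on = start + int(below[0])

    above = np.flatnonzero(v[i_on:] >= thr)
    if above.size == 0:
        onset = float(trace.t[i_on])
        horizon = float(trace.t[-1])
        warnings.warn(
            "TAN activity did not recover within the simulation horizon; "
            "pause duration is censored", stacklevel=2)
        da_seg = trace.da[i_on:]
        return PauseMetrics(onset_ms=onset, offset_ms=None,
                            duration_ms=horizon - onset,
                            min_da=float(da_seg.min()),
                            max_da=float(da_seg.max()),
                            censored=True)
    i_off = i_on + int(above[0])
    onset = float(trace.t[i_on])
    offset = float(trace.t[i_off])
    da_seg = trace.da[i_on:i_off + 1]
    return PauseMetrics(onset_ms=onset, offset_ms=offset,
                        duration_ms=offset - onset,
                        min_da=float(da_seg.min()),
                        max_da=float(da_seg.max()),
                        censored=False)


def phasic_da_integral(trace: SimulationTrace) -> float:
    """Time integral of the dopamine excursion from its effective baseline.

    The baseline is the context's own steady state ``alpha*da0 + ldopa``,
    so under deficiency or levodopa only the phasic (pause-gated)
    component contributes.  Units: concentration * ms.
    """
    baseline = trace.context.effective_baseline(trace.params)
    return float(np.trapezoid(trace.da - baseline, trace.t))
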