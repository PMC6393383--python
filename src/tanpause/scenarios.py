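"""Named experimental conditions and parameter sweeps.

The pharmacology presets reproduce the calibration conditions of the
in-vitro TAN recordings the model was fit to: sulpiride (D2 antagonism,
``w_da = 0`` so dopamine no longer suppresses the h-current), cocaine
(reuptake blockade, baseline dopamine tripled), and a hypothetical
complete h-current blockade (``g_h = 0``).  Sweeps tabulate TAN-pause
duration against stimulus duration, dopamine-deficiency percentage, or
levodopa level, for a set of reward-prediction-error values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .dynamics import (
    ModelParams,
    PauseMetrics,
    ScenarioContext,
    SimulationTrace,
    StimulusProtocol,
    detect_pause,
    integrate,
)

__all__ = [
    "PharmacologyCondition",
    "CONDITIONS",
    "SweepResult",
    "run_condition",
    "sweep_stim_duration",
    "sweep_deficiency",
    "sweep_ldopa",
]

# horizon long enough for the slowest pause (h-current blockade) to recover
DEFAULT_HORIZON_MS = 4000.0
DEFAULT_RPE_LEVELS = (-1.0, 0.0, 1.0)

_ALLOWED_OVERRIDE_KEYS = frozenset({"w_da", "da0", "g_h"})


@dataclass(frozen=True)
class PharmacologyCondition:
    """A named pharmacological manipulation as partial parameter overrides."""

    name: str
    overrides: Mapping[str, float]

    def __post_init__(self) -> None:
        bad = set(self.overrides) - _ALLOWED_OVERRIDE_KEYS
        if bad:
            raise ValueError(
                f"condition overrides restricted to {sorted(_ALLOWED_OVERRIDE_KEYS)}; "
                f"got {sorted(bad)}")

    def apply(self, params: ModelParams) -> ModelParams:
        """Return a new parameter set with the overrides applied."""
        return params.replace(**dict(self.overrides))


CONDITIONS: dict[str, PharmacologyCondition] = {
    "control": PharmacologyCondition("control", {}),
    "sulpiride": PharmacologyCondition("sulpiride", {"w_da": 0.0}),
    "cocaine": PharmacologyCondition("cocaine", {"da0": 3.0}),
    "h_block": PharmacologyCondition("h_block", {"g_h": 0.0}),
}


def get_condition(name: str) -> PharmacologyCondition:
    try:
        return CONDITIONS[name]
    except KeyError:
        raise ValueError(
            f"unknown condition {name!r}; valid names: "
            f"{sorted(CONDITIONS)}") from None


@dataclass
class SweepResult:
    """Tidy table of TAN-pause duration over one swept axis x RPE levels."""

    axis_name: str
    axis_values: tuple[float, ...]
    rpe_levels: tuple[float, ...]
    tp_ms: np.ndarray  # shape (len(axis_values), len(rpe_levels))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"axis_name": self.axis_name, "axis_value": av,
             "rpe": rpe, "tp_ms": float(self.tp_ms[i, j])}
            for i, av in enumerate(self.axis_values)
            for j, rpe in enumerate(self.rpe_levels)
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SweepResult":
        axis_name = str(df["axis_name"].iloc[0])
        axis_values = tuple(sorted(df["axis_value"].unique()))
        rpe_levels = tuple(sorted(df["rpe"].unique()))
        tp = np.full((len(axis_values), len(rpe_levels)), np.nan)
        for _, row in df.iterrows():
            i = axis_values.index(row["axis_value"])
            j = rpe_levels.index(row["rpe"])
            tp[i, j] = row["tp_ms"]
        if np.isnan(tp).any():
            raise ValueError("sweep table incomplete")
        return cls(axis_name, axis_values, rpe_levels, tp)

    def column(self, rpe: float) -> np.ndarray:
        return self.tp_ms[:, self.rpe_levels.index(rpe)]


def run_condition(cond: PharmacologyCondition | str,
                  stim: StimulusProtocol,
                  ctx: ScenarioContext,
                  params: Optional[ModelParams] = None,
                  dt: float = 1.0) -> tuple[SimulationTrace, PauseMetrics]:
    """Integrate one pharmacological condition and measure its pause.

    The caller's ``params`` are never mutated; overrides are applied to a
    copy.  Combining the cocaine preset (tripled baseline) with a
    deficiency coefficient scales the baseline multiplicatively, which is
    outside the calibrated conditions and triggers a warning.
    """
    if isinstance(cond, str):
        cond = get_condition(cond)
    params = params if params is not None else ModelParams()
    eff = cond.apply(params)
    if cond.name == "cocaine" and ctx.alpha < 1.0:
        warnings.warn(
            "cocaine preset scales baseline dopamine multiplicatively with "
            "the deficiency coefficient; this combination is untested "
            "against data", stacklevel=2)
    trace = integrate(eff, stim, ctx, dt=dt)
    return trace, detect_pause(trace)


def _tp(params: ModelParams, stim: StimulusProtocol, ctx: ScenarioContext,
        dt: float) -> float:
    trace = integrate(params, stim, ctx, dt=dt)
    return detect_pause(trace).duration_ms


def sweep_stim_duration(durations: Sequence[float] = (100, 200, 300, 400),
                        rpe_levels: Sequence[float] = DEFAULT_RPE_LEVELS,
                        params: Optional[ModelParams] = None,
                        alpha: float = 1.0, ldopa: float = 0.0,
                        dt: float = 1.0,
                        horizon_ms: float = DEFAULT_HORIZON_MS) -> SweepResult:
    """TAN-pause duration vs thalamic stimulation duration."""
    params = params if params is not None else ModelParams()
    durations = tuple(float(d) for d in durations)
    rpes = tuple(float(r) for r in rpe_levels)
    if any(not 0 < d < horizon_ms for d in durations):
        raise ValueError("stimulus durations must lie within (0, horizon)")
    tp = np.empty((len(durations), len(rpes)))
    for i, d in enumerate(durations):
        stim = StimulusProtocol([(0.0, d)], horizon_ms)
        for j, rpe in enumerate(rpes):
            tp[i, j] = _tp(params, stim, ScenarioContext(rpe, alpha, ldopa), dt)
    return SweepResult("stim_duration_ms", durations, rpes, tp)


def sweep_deficiency(alphas: Sequence[float] = tuple(np.round(np.arange(0.1, 1.01, 0.1), 2)),
                     rpe_levels: Sequence[float] = DEFAULT_RPE_LEVELS,
                     params: Optional[ModelParams] = None,
                     stim_duration_ms: float = 300.0,
                     ldopa: float = 0.0, dt: float = 1.0,
                     horizon_ms: float = DEFAULT_HORIZON_MS) -> SweepResult:
    """TAN-pause duration vs dopamine-deficiency percentage, 100*(1-alpha).

    The axis is ordered by increasing deficiency (decreasing alpha).
    """
    params = params if params is not None else ModelParams()
    alphas = tuple(sorted((float(a) for a in alphas), reverse=True))
    rpes = tuple(float(r) for r in rpe_levels)
    stim = StimulusProtocol([(0.0, stim_duration_ms)], horizon_ms)
    tp = np.empty((len(alphas), len(rpes)))
    for i, a in enumerate(alphas):
        for j, rpe in enumerate(rpes):
            tp[i, j] = _tp(params, stim, ScenarioContext(rpe, a, ldopa), dt)
    deficiency_pct = tuple(round(100.0 * (1.0 - a), 10) for a in alphas)
    return SweepResult("deficiency_pct", deficiency_pct, rpes, tp)


def sweep_ldopa(ldopa_values: Sequence[float] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
                alpha: float = 0.5,
                rpe_levels: Sequence[float] = DEFAULT_RPE_LEVELS,
                params: Optional[ModelParams] = None,
                stim_duration_ms: float = 300.0, dt: float = 1.0,
                horizon_ms: float = DEFAULT_HORIZON_MS) -> SweepResult:
    """TAN-pause duration vs levodopa level at a fixed deficiency."""
    params = params if params is not None else ModelParams()
    ldopas = tuple(float(x) for x in ldopa_values)
    rpes = tuple(float(r) for r in rpe_levels)
    stim = StimulusProtocol([(0.0, stim_duration_ms)], horizon_ms)
    tp = np.empty((len(ldopas), len(rpes)))
    for i, ld in enumerate(ldopas):
        for j, rpe in enumerate(rpes):
            tp[i, j] = _tp(params, stim, ScenarioContext(rpe, alpha, ld), dt)
    return SweepResult("ldopa", ldopas, rpes, tp)
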