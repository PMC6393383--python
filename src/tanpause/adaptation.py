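"""Reduced non-error-based motor-adaptation task gated by the TAN pause.

Emulates the structure of the prism-perturbation ball-throwing
experiment: a cue activates cortical units whose learned weights onto
direct- (D1) and indirect-pathway (D2) striatal populations gate a set
of candidate motor programs; the executed endpoint is the
activation-weighted combination of the candidates' endpoints on a 1-D
horizontal axis.  Reward falls off linearly with distance to the target,
the reward prediction error (RPE) is the temporal difference between
consecutive rewards, and each trial's RPE drives one TAN–dopamine
simulation whose pause-gated dopamine integral updates the weights.

The Dove-prism perturbation reverses the perceived horizontal error,
defeating error-based correction; because this reduced loop learns only
from reward, the manipulation is realized by mirroring the effective
(rewarded) target about the axis origin during the perturbation phase.
Dopamine deficiency (alpha < 1) shortens the pause and shrinks the
phasic excursion, weakening the learning signal twice over; levodopa
restores the baseline — and with it the pause duration — but not the
phasic amplitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .dynamics import (
    ModelParams,
    ScenarioContext,
    StimulusProtocol,
    detect_pause,
    integrate,
    phasic_da_integral,
)
from .plasticity import PopulationRates, WeightState, update_weights

__all__ = [
    "PHASES",
    "TaskConfig",
    "TrialRecord",
    "select_action",
    "reward_and_rpe",
    "run_trial",
    "run_session",
    "run_experiment",
    "summarize_experiment",
]

logger = logging.getLogger(__name__)

PHASES = ("baseline", "perturbation", "aftereffect")


@dataclass(frozen=True)
class TaskConfig:
    """Configuration of the reduced ball-throwing experiment.

    Candidate motor programs are ``n_actions`` endpoints evenly spaced on
    [-1, 1]; the target sits at ``target_position``.  Each session runs
    25 baseline, 25 perturbation and 25 aftereffect trials; 8 sessions
    are averaged.  ``alpha`` and ``ldopa`` set the dopamine context
    handed to the per-trial TAN–dopamine simulation.
    """

    n_actions: int = 5
    target_position: float = 1.0
    trials_baseline: int = 25
    trials_perturbation: int = 25
    trials_aftereffect: int = 25
    n_sessions: int = 8
    noise_sd: float = 0.15
    seed: int = 0
    alpha: float = 1.0
    ldopa: float = 0.0
    stim_duration_ms: float = 300.0
    horizon_ms: float = 4000.0
    dt: float = 1.0
    w1_init: float = 0.4
    w2_init: float = 0.1
    lambda1: float = 1.0
    lambda2: float = 1.0
    dw: float = 0.01

    def __post_init__(self) -> None:
        if self.n_actions < 2:
            raise ValueError("n_actions must be >= 2")
        for name in ("trials_baseline", "trials_perturbation",
                     "trials_aftereffect", "n_sessions"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not -1.0 <= self.target_position <= 1.0:
            raise ValueError("target_position must lie in [-1, 1]")

    @property
    def action_endpoints(self) -> np.ndarray:
        return np.linspace(-1.0, 1.0, self.n_actions)

    @property
    def error_max(self) -> float:
        """Reward normalization: the span of the action-endpoint grid."""
        eps = self.action_endpoints
        return float(eps[-1] - eps[0])

    @property
    def trials_per_session(self) -> int:
        return (self.trials_baseline + self.trials_perturbation
                + self.trials_aftereffect)

    def phase_of(self, trial_index: int) -> str:
        """Phase of a 0-based trial index within a session."""
        if trial_index < self.trials_baseline:
            return "baseline"
        if trial_index < self.trials_baseline + self.trials_perturbation:
            return "perturbation"
        return "aftereffect"

    def context(self) -> ScenarioContext:
        return ScenarioContext(rpe=0.0, alpha=self.alpha, ldopa=self.ldopa)


@dataclass
class TrialRecord:
    """Everything measured on one trial."""

    session: int
    phase: str
    trial_index: int
    relay_activations: np.ndarray
    endpoint: float
    actual_error: float
    perceived_error: float
    reward: float
    rpe: float
    tp_ms: float
    da_integral: float


def select_action(w: WeightState, cue: np.ndarray, noise_sd: float,
                  rng: np.random.Generator,
                  action_endpoints: np.ndarray) -> tuple[np.ndarray, float, PopulationRates]:
    """Gate candidate motor programs through the learned D1/D2 weights.

    D1 and D2 rates are rectified projections of the cue; exploration
    noise enters through the direct pathway, so every endpoint
    fluctuation is attributable to a D1 rate fluctuation and the
    dopamine-gated update can assign credit for it (adding a second
    independent noise source on D2 would add outcome variance without
    adding exploration).  Each action's relay activation is the
    rectified direct-minus-indirect drive, normalized to sum to one; the
    executed endpoint is the activation-weighted mean of the candidate
    endpoints.  If every relay activation is zero the gate falls back to
    uniform (logged).
    """
    cue = np.asarray(cue, dtype=float)
    if (cue < 0).any():
        raise ValueError("cue rates must be non-negative")
    n_actions = w.w1.shape[1]
    d1 = np.maximum(0.0, cue @ w.w1 + rng.normal(0.0, noise_sd, n_actions))
    d2 = np.maximum(0.0, cue @ w.w2)
    relay = np.maximum(0.0, d1 - d2)
    total = relay.sum()
    if total > 0:
        relay = relay / total
    else:
        logger.info("all relay activations zero; falling back to uniform gate")
        relay = np.full(n_actions, 1.0 / n_actions)
    endpoint = float(relay @ action_endpoints)
    return relay, endpoint, PopulationRates(c=cue, d1=d1, d2=d2)


def reward_and_rpe(endpoint: float, target: float, phase: str,
                   prev_reward: Optional[float], error_max: float
                   ) -> tuple[float, float, float, float]:
    """Distance reward and temporal-difference RPE for one throw.

    During the perturbation phase the effective target is mirrored about
    the origin (the prism relabels which throws are rewarded) and the
    perceived error is the sign-flipped actual error.  Reward falls
    linearly from 1 at zero error to 0 at ``error_max``; the RPE is the
    clamped difference from the previous trial's reward (0 on the first
    trial of a session).

    Returns ``(reward, rpe, actual_error, perceived_error)``.
    """
    effective_target = -target if phase == "perturbation" else target
    actual_error = endpoint - effective_target
    perceived_error = -actual_error if phase == "perturbation" else actual_error
    reward = max(0.0, 1.0 - abs(actual_error) / error_max)
    if prev_reward is None:
        rpe = 0.0
    else:
        rpe = float(np.clip(reward - prev_reward, -1.0, 1.0))
    return reward, rpe, actual_error, perceived_error


def run_trial(w: WeightState, config: TaskConfig, session: int,
              trial_index: int, prev_reward: Optional[float],
              rng: np.random.Generator,
              stim: StimulusProtocol,
              params: Optional[ModelParams] = None
              ) -> tuple[TrialRecord, WeightState, float]:
    """One cue -> action -> reward -> pause-gated update cycle."""
    params = params if params is not None else ModelParams()
    phase = config.phase_of(trial_index)
    cue = np.ones(w.w1.shape[0])
    relay, endpoint, rates = select_action(
        w, cue, config.noise_sd, rng, config.action_endpoints)
    reward, rpe, actual_error, perceived_error = reward_and_rpe(
        endpoint, config.target_position, phase, prev_reward,
        config.error_max)

    ctx = ScenarioContext(rpe=rpe, alpha=config.alpha, ldopa=config.ldopa)
    trace = integrate(params, stim, ctx, dt=config.dt)
    pause = detect_pause(trace)
    integral = phasic_da_integral(trace)

    w_new = update_weights(w, rates, integral)
    record = TrialRecord(
        session=session, phase=phase, trial_index=trial_index,
        relay_activations=relay, endpoint=endpoint,
        actual_error=actual_error, perceived_error=perceived_error,
        reward=reward, rpe=rpe, tp_ms=pause.duration_ms,
        da_integral=integral)
    return record, w_new, reward


def run_session(config: TaskConfig, session: int,
                rng: np.random.Generator,
                params: Optional[ModelParams] = None) -> list[TrialRecord]:
    """One 75-trial session starting from fresh (uniform) weights."""
    params = params if params is not None else ModelParams()
    n_cues = 1
    w = WeightState(
        w1=np.full((n_cues, config.n_actions), config.w1_init),
        w2=np.full((n_cues, config.n_actions), config.w2_init),
        lambda1=config.lambda1, lambda2=config.lambda2, dw=config.dw)
    stim = StimulusProtocol([(0.0, config.stim_duration_ms)],
                            config.horizon_ms)
    records: list[TrialRecord] = []
    prev_reward: Optional[float] = None
    for k in range(config.trials_per_session):
        rec, w, reward = run_trial(w, config, session, k, prev_reward,
                                   rng, stim, params)
        records.append(rec)
        prev_reward = reward
    return records


def run_experiment(config: TaskConfig,
                   params: Optional[ModelParams] = None) -> pd.DataFrame:
    """All sessions of one condition, as a tidy per-trial table.

    Sessions use independent spawns of the config seed, so experiments
    with matched seeds but different dopamine contexts see identical
    exploration noise streams.
    """
    params = params if params is not None else ModelParams()
    root = np.random.SeedSequence(config.seed)
    rows = []
    for s, child in enumerate(root.spawn(config.n_sessions)):
        rng = np.random.default_rng(child)
        for rec in run_session(config, s, rng, params):
            rows.append({
                "session": rec.session, "phase": rec.phase,
                "trial": rec.trial_index, "endpoint": rec.endpoint,
                "error": rec.actual_error,
                "perceived_error": rec.perceived_error,
                "reward": rec.reward, "rpe": rec.rpe,
                "tp_ms": rec.tp_ms, "da_integral": rec.da_integral,
            })
    return pd.DataFrame(rows)


def summarize_experiment(trials: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error of |error| per trial index across sessions."""
    g = trials.assign(abs_error=trials["error"].abs()).groupby(
        ["phase", "trial"], sort=False)["abs_error"]
    out = g.agg(["mean", "sem", "count"]).reset_index()
    out = out.rename(columns={"mean": "abs_error_mean",
                              "sem": "abs_error_sem",
                              "count": "n_sessions"})
    return out
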