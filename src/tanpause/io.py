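"""Configuration loading, stimulus factories and CSV/JSON serialization.

Config files are flat-per-block YAML (JSON parses too) mirroring the
field names of :class:`~tanpause.dynamics.ModelParams`,
:class:`~tanpause.dynamics.ScenarioContext` and
:class:`~tanpause.adaptation.TaskConfig` exactly; unknown keys are
rejected by name.  All tables are written as headered CSV with ``.``
decimal separators; nested metrics go to JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .adaptation import TaskConfig
from .dynamics import (
    ModelParams,
    PauseMetrics,
    ScenarioContext,
    SimulationTrace,
    StimulusProtocol,
)
from .scenarios import SweepResult

__all__ = [
    "RunConfig",
    "load_config",
    "make_stimulus",
    "write_trace",
    "read_trace",
    "write_pause_metrics",
    "write_sweep",
    "read_sweep",
    "write_experiment",
    "write_run_config",
]

logger = logging.getLogger(__name__)

TRACE_COLUMNS = ("t_ms", "v_tan", "i_sahp", "i_h", "da")


@dataclass
class RunConfig:
    """Fully-resolved run configuration (model + scenario + task blocks)."""

    model: ModelParams = field(default_factory=ModelParams)
    scenario: ScenarioContext = field(default_factory=ScenarioContext)
    task: TaskConfig = field(default_factory=TaskConfig)
    dt: float = 1.0
    seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "model": dataclasses.asdict(self.model),
            "scenario": dataclasses.asdict(self.scenario),
            "task": dataclasses.asdict(self.task),
            "dt": self.dt,
            "seed": self.seed,
            "out_dir": self.out_dir,
            "log_level": self.log_level,
        }


def _build_block(cls, block: Mapping[str, Any], block_name: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    clean = {}
    for key, value in block.items():
        if key not in valid:
            raise ValueError(
                f"unknown key {block_name}.{key!r}; valid keys: {sorted(valid)}")
        if isinstance(value, str):
            raise ValueError(
                f"malformed numeric value for {block_name}.{key!r}: {value!r}")
        clean[key] = value
    return cls(**clean)


def load_config(path: Union[str, Path]) -> RunConfig:
    """Parse a YAML/JSON config file, applying defaults for absent keys.

    An empty file yields the published default parameter set.  Unknown
    keys and non-numeric values raise ``ValueError`` naming the
    offending key.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")

    known_top = {"model", "scenario", "task", "dt", "seed", "out_dir",
                 "log_level"}
    bad = set(raw) - known_top
    if bad:
        raise ValueError(
            f"unknown config key(s) {sorted(bad)}; valid keys: {sorted(known_top)}")

    cfg = RunConfig(
        model=_build_block(ModelParams, raw.get("model", {}) or {}, "model"),
        scenario=_build_block(ScenarioContext, raw.get("scenario", {}) or {},
                              "scenario"),
        task=_build_block(TaskConfig, raw.get("task", {}) or {}, "task"),
        dt=float(raw.get("dt", 1.0)),
        seed=int(raw.get("seed", 0)),
        out_dir=str(raw.get("out_dir", ".")),
        log_level=str(raw.get("log_level", "INFO")),
    )
    logger.info("resolved config: %s", json.dumps(cfg.to_dict()))
    return cfg


def write_run_config(cfg: RunConfig, path: Union[str, Path]) -> None:
    """Echo the fully-resolved config next to the outputs (provenance)."""
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))


# --------------------------------------------------------------------------
# stimulus factories
# --------------------------------------------------------------------------

def make_stimulus(kind: str, *, duration_ms: float = 300.0,
                  start_ms: float = 0.0, freq_hz: float = 50.0,
                  n_pulses: int = 10, pulse_width_ms: float = 10.0,
                  total_duration_ms: float = 4000.0) -> StimulusProtocol:
    """Build a canonical stimulus protocol.

    ``block`` is a single on-interval of ``duration_ms``; ``pulse_train``
    is ``n_pulses`` pulses of ``pulse_width_ms`` at ``freq_hz``.  The
    default train (50 Hz x 10, 10 ms wide) matches the protocol used to
    calibrate the model against in-vitro recordings.
    """
    if kind == "block":
        return StimulusProtocol([(start_ms, start_ms + duration_ms)],
                                total_duration_ms)
    if kind == "pulse_train":
        period = 1000.0 / freq_hz
        if pulse_width_ms >= period:
            raise ValueError(
                f"pulse width {pulse_width_ms} ms must be smaller than the "
                f"period {period:.3f} ms at {freq_hz} Hz")
        last_end = start_ms + (n_pulses - 1) * period + pulse_width_ms
        if last_end > total_duration_ms:
            raise ValueError(
                f"pulse train extends to {last_end} ms, beyond the "
                f"{total_duration_ms} ms horizon")
        intervals = [(start_ms + k * period,
                      start_ms + k * period + pulse_width_ms)
                     for k in range(n_pulses)]
        return StimulusProtocol(intervals, total_duration_ms)
    raise ValueError(f"unknown stimulus kind {kind!r}; "
                     "use 'block' or 'pulse_train'")


# --------------------------------------------------------------------------
# writers / readers
# --------------------------------------------------------------------------

def write_trace(trace: SimulationTrace, path: Union[str, Path]) -> None:
    df = pd.DataFrame({
        "t_ms": trace.t, "v_tan": trace.v_tan, "i_sahp": trace.i_sahp,
        "i_h": trace.i_h, "da": trace.da,
    })
    # %.17g keeps the round trip bit-identical for float64
    df.to_csv(path, index=False, float_format="%.17g")


def read_trace(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace file missing columns {sorted(missing)}")
    return df


def write_pause_metrics(metrics: PauseMetrics, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(metrics.to_dict(), indent=2))


def write_sweep(sweep: SweepResult, path: Union[str, Path]) -> None:
    sweep.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_sweep(path: Union[str, Path]) -> SweepResult:
    return SweepResult.from_frame(
        pd.read_csv(path, float_precision="round_trip"))


def write_experiment(trials: pd.DataFrame, summary: pd.DataFrame,
                     out_dir: Union[str, Path],
                     stem: str = "experiment") -> tuple[Path, Path]:
    """Tidy per-trial CSV plus a JSON per-trial-index summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{stem}_trials.csv"
    json_path = out_dir / f"{stem}_summary.json"
    trials.to_csv(csv_path, index=False)
    json_path.write_text(summary.to_json(orient="records", indent=2))
    return csv_path, json_path
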