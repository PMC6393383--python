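"""Corticostriatal weight updates gated by the phasic dopamine integral.

Learning in the striatum is driven by the time integral of the dopamine
excursion from baseline, which is non-zero only during the TAN pause —
so pause duration directly scales the magnitude of potentiation and
depression.  Cortical cue units project to direct-pathway (D1) and
indirect-pathway (D2) medium spiny neurons with opposite dopamine
sensitivity: a positive integral potentiates D1 weights and depresses D2
weights, and vice versa.  A per-trial degradation term slowly decays all
weights, and weights are clamped at zero (firing-rate synapses).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WeightState",
    "PopulationRates",
    "RATE_FACTOR_ABOVE",
    "RATE_FACTOR_BELOW",
    "effective_rate",
    "update_weights",
]

# learning-rate scaling by the sign of the dopamine deviation from baseline
RATE_FACTOR_ABOVE = 0.00125   # [DA] >= baseline
RATE_FACTOR_BELOW = 0.0025    # [DA] < baseline


@dataclass
class WeightState:
    """Cortex -> D1 and cortex -> D2 weight matrices with learning rates.

    ``w1[j, i]`` is the weight from cortical cue unit j to D1 unit i;
    ``w2`` likewise for the indirect pathway.  ``lambda1``/``lambda2``
    are base learning rates (scaled per update by the dopamine-sign
    factor) and ``dw`` is the per-trial degradation rate.
    """

    w1: np.ndarray
    w2: np.ndarray
    lambda1: float = 1.0
    lambda2: float = 1.0
    dw: float = 0.01

    def __post_init__(self) -> None:
        self.w1 = np.asarray(self.w1, dtype=float)
        self.w2 = np.asarray(self.w2, dtype=float)
        if self.w1.shape != self.w2.shape:
            raise ValueError("w1 and w2 must have identical shapes")
        if (self.w1 < 0).any() or (self.w2 < 0).any():
            raise ValueError("weights must be non-negative")

    def copy(self) -> "WeightState":
        return WeightState(self.w1.copy(), self.w2.copy(),
                           self.lambda1, self.lambda2, self.dw)

    # -- serialization -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pathway, w in (("d1", self.w1), ("d2", self.w2)):
            jj, ii = np.indices(w.shape)
            for j, i, v in zip(jj.ravel(), ii.ravel(), w.ravel()):
                rows.append({"pathway": pathway, "i": int(i), "j": int(j),
                             "value": float(v)})
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, lambda1: float = 1.0,
                   lambda2: float = 1.0, dw: float = 0.01) -> "WeightState":
        shape = (df["j"].max() + 1, df["i"].max() + 1)
        w1 = np.zeros(shape)
        w2 = np.zeros(shape)
        for _, row in df.iterrows():
            w = w1 if row["pathway"] == "d1" else w2
            w[int(row["j"]), int(row["i"])] = row["value"]
        return cls(w1, w2, lambda1, lambda2, dw)


@dataclass
class PopulationRates:
    """Firing rates of cortical cue units and D1/D2 MSN populations."""

    c: np.ndarray    # cortical cue rates C_j
    d1: np.ndarray   # direct-pathway MSN rates
    d2: np.ndarray   # indirect-pathway MSN rates

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float)
        self.d1 = np.asarray(self.d1, dtype=float)
        self.d2 = np.asarray(self.d2, dtype=float)
        if (self.c < 0).any() or (self.d1 < 0).any() or (self.d2 < 0).any():
            raise ValueError("population rates must be non-negative")
        if self.d1.shape != self.d2.shape:
            raise ValueError("d1 and d2 must have identical shapes")


def effective_rate(base_lambda: float, da_sign: str) -> float:
    """Learning rate scaled by whether dopamine sat above or below baseline.

    The depression-side factor is twice the potentiation-side one, so
    negative reward prediction errors unlearn faster than positive ones
    learn.
    """
    if base_lambda <= 0:
        raise ValueError("base_lambda must be > 0")
    if da_sign == "above_baseline":
        return base_lambda * RATE_FACTOR_ABOVE
    if da_sign == "below_baseline":
        return base_lambda * RATE_FACTOR_BELOW
    raise ValueError(
        f"da_sign must be 'above_baseline' or 'below_baseline', got {da_sign!r}")


def update_weights(w: WeightState, rates: PopulationRates,
                   da_integral: float) -> WeightState:
    """One trial's weight change from the phasic dopamine integral.

    dW1[j,i] = lam1_eff * C_j * D1_i * integral - dw * W1[j,i]
    dW2[j,i] = -lam2_eff * C_j * D2_i * integral - dw * W2[j,i]

    The sign of ``da_integral`` (the dopamine deviation is single-signed
    within one pause at this model's resolution) selects the effective
    learning-rate factor.  Results are clamped at zero element-wise; the
    input state is not mutated.
    """
    if not np.isfinite(da_integral):
        raise ValueError("da_integral must be finite")
    n_cues, n_units = w.w1.shape
    if rates.c.shape != (n_cues,) or rates.d1.shape != (n_units,):
        raise ValueError(
            f"rates shapes {rates.c.shape}/{rates.d1.shape} do not match "
            f"weight shape {w.w1.shape}")
    sign = "below_baseline" if da_integral < 0 else "above_baseline"
    lam1 = effective_rate(w.lambda1, sign)
    lam2 = effective_rate(w.lambda2, sign)
    outer1 = np.outer(rates.c, rates.d1)
    outer2 = np.outer(rates.c, rates.d2)
    w1 = w.w1 + lam1 * outer1 * da_integral - w.dw * w.w1
    w2 = w.w2 - lam2 * outer2 * da_integral - w.dw * w.w2
    np.clip(w1, 0.0, None, out=w1)
    np.clip(w2, 0.0, None, out=w2)
    return WeightState(w1, w2, w.lambda1, w.lambda2, w.dw)
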