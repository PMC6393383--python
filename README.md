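# tanpause

Rate-based simulator of striatal cholinergic interneuron (TAN) pauses,
their bidirectional coupling with striatal dopamine release, and
pause-gated reinforcement learning.

Striatal cholinergic interneurons — tonically active neurons (TANs) —
fire continuously at 5–10 Hz and fall silent for several hundred
milliseconds after a salient thalamic or cortical input. While they
fire, acetylcholine acting on nicotinic receptors of dopaminergic axon
terminals clamps striatal dopamine at its baseline; during the pause the
clamp is released and dopamine can deviate from baseline in proportion
to the reward prediction error (RPE) carried by nigral firing. Dopamine
in turn suppresses, via D2 receptors, the depolarizing h-current that
ends the pause — so the pause length itself grows with the dopamine
level. The pause is therefore the time window through which reward
information reaches corticostriatal synapses, and anything that shortens
it (e.g. Parkinsonian dopamine deficiency) weakens learning.

## Model

TAN activity `V(t)` (normalized firing rate), the slow
after-hyperpolarization current `I_sAHP`, the h-current `I_H`, and the
dopamine concentration `[DA]` evolve as first-order relaxations
(time constants in ms):

```
tau_TAN  dV/dt      + V      = sigma(W_Thal*V_Thal + Drv + I_sAHP + I_H)
tau_sAHP dI_sAHP/dt + I_sAHP = -g_sAHP * (V - th_sAHP) * H(V - th_sAHP)
tau_H    dI_H/dt    + I_H    = -g_H * exp(-W_DA*[DA]) * (V - th_H) * H(th_H - V)
tau_DA   d[DA]/dt   + [DA]   = alpha*(RPE*(1 - V/th_DA)*H(th_DA - V) + [DA]0) + LDOPA
```

with `sigma(x) = H(x) tanh(x)` and `H` the Heaviside step. `alpha` in
[0, 1] scales all dopamine production (deficiency; 1 = healthy) and
`LDOPA >= 0` is the constant baseline increase from levodopa, so the
resting dopamine level is `alpha*[DA]0 + LDOPA`. Pharmacology presets
reproduce the conditions the model was calibrated against: sulpiride
(`W_DA = 0`), cocaine (`[DA]0 = 3`), and h-current blockade (`g_H = 0`).

Corticostriatal learning is driven by the time integral of the phasic
dopamine excursion over a trial,

```
dW1[j,i] = +lam1_eff * C_j * D1_i * Int([DA]-[DA]base) dt - d_w * W1[j,i]
dW2[j,i] = -lam2_eff * C_j * D2_i * Int([DA]-[DA]base) dt - d_w * W2[j,i]
```

which is non-zero only while the TANs pause — pause duration directly
scales potentiation and depression. A reduced 1-D prism-perturbation
throwing task closes the loop: cue → D1/D2 gating of candidate motor
programs → endpoint → distance reward → temporal-difference RPE → one
TAN–dopamine simulation per trial → weight update.

## Worked example

```python
from tanpause import (ModelParams, ScenarioContext, make_stimulus,
                      integrate, detect_pause, phasic_da_integral)

params = ModelParams()                      # published defaults
stim = make_stimulus("block", duration_ms=300.0)
for rpe in (1.0, 0.0, -1.0):
    trace = integrate(params, stim, ScenarioContext(rpe=rpe))
    p = detect_pause(trace)
    print(f"rpe={rpe:+.0f}: TP={p.duration_ms:.0f} ms  "
          f"min_da={p.min_da:.3f} max_da={p.max_da:.3f} "
          f"integral={phasic_da_integral(trace):+.1f}")
```

prints

```
rpe=+1: TP=1466 ms  min_da=1.000 max_da=2.000 integral=+386.4
rpe=+0: TP=1277 ms  min_da=1.000 max_da=1.000 integral=+0.0
rpe=-1: TP=1128 ms  min_da=0.011 max_da=1.000 integral=-113.8
```

A 300 ms thalamic block evokes a burst and then a pause (TP, measured
from stimulus offset at 90% of the resting rate). With positive RPE
dopamine climbs toward 2.0 during the pause and prolongs it; with
negative RPE dopamine collapses toward 0 and the pause shortens — the
pause duration orders with the reward prediction error, and the phasic
integral (the learning signal, in concentration·ms) follows.

The same machinery is available from the shell:

```
tanpause simulate --condition control --stim-ms 300 --rpe 1 --out trace.csv
tanpause sweep --axis deficiency --out sweep.csv
tanpause adapt --deficiency 0.5 --ldopa 1.0 --out results/
```

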