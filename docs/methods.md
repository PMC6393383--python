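# Methods

## Model

The package simulates the aggregate activity of the striatal
cholinergic-interneuron (TAN) population as a single rate variable
coupled to the striatal dopamine concentration. Four assumptions define
the model:

1. **Homogeneous rate description.** The TAN population is a single
   normalized rate `V(t) = sigma(I(t))` relaxing with `tau_TAN = 20 ms`,
   where `sigma(x) = H(x) tanh(x)`; acetylcholine release and all
   cholinergic receptor activation are proportional to `V`. No spiking,
   no spatial structure.
2. **Pause generation is intrinsic.** A slow after-hyperpolarization
   current activates when `V` exceeds `th_sAHP = 0.3` (i.e. during the
   stimulus-evoked burst) and decays with `tau_sAHP = 700 ms`; it alone
   silences the population after the stimulus ends.
3. **Recovery is dopamine-modulated.** The depolarizing h-current
   activates below `th_H = 0.2` and is scaled by `exp(-W_DA*[DA])` — the
   D2-receptor pathway. Higher dopamine → weaker h-current → slower
   recovery → longer pause. This is the loop that makes pause duration
   increase with dopamine, and hence with positive RPE.
4. **Nicotinic gating of dopamine release.** While `V > th_DA = 0.01`
   the dopamine target is pinned at baseline; only in the deep pause
   does the target move to `baseline + RPE*(1 - V/th_DA)`. Deficiency
   multiplies the whole dopamine drive by `alpha`; levodopa adds a
   constant, so the resting concentration is `alpha*[DA]0 + LDOPA`.
   (The levodopa equation is implemented as a relaxation of `[DA](t)`;
   the alternative reading of its left-hand side as a constant would
   make it a non-dynamical identity inconsistent with the deficiency
   equation.)

Default parameters (the published calibration against in-vitro slice
recordings): `tau_TAN=20`, `W_Thal=4`, `Drv_TAN=0.3`, `tau_sAHP=700`,
`g_sAHP=5`, `th_sAHP=0.3`, `tau_H=700`, `g_H=20`, `th_H=0.2`, `W_DA=1`,
`tau_DA=20`, `th_DA=0.01`, `[DA]0=1`. Time constants are milliseconds;
everything else is dimensionless, dopamine in normalized concentration
units. `tau_DA` carries no printed unit in the source material; it is
read as ms like every other time constant. With these values the
resting rate `tanh(0.3) ≈ 0.291` sits strictly between `th_H` and
`th_sAHP`, so both currents vanish at rest and the tonic state is an
exact fixed point.

## Numerics

* **Integration** is forward Euler on a uniform grid, default
  `dt = 1 ms`. The fastest time constant is 20 ms, so the explicit step
  is comfortably stable; the suite verifies that halving `dt` moves
  every pause duration by < 2% and that a fine-step Euler trace matches
  an adaptive RK45 integration of the identical right-hand side to
  < 0.5% in pause duration. `dt` is configurable everywhere.
* **Step convention** `H(0) = 0`, which keeps each current's target
  exactly zero at its own threshold and `sigma(0) = 0`.
* **Dopamine is clipped at zero from below** after each step: it is a
  concentration, and extreme `alpha`/negative-RPE combinations can
  transiently target negative values.
* **Divergence guard:** if `V` ever leaves `[0, 1)` the integrator
  raises and advises a smaller step.
* **Steady states** are found by damped fixed-point iteration on
  `(V, [DA])`; for the default regime this converges to
  `V* = tanh(Drv_TAN)`, `[DA]* = alpha*[DA]0 + LDOPA` in a handful of
  iterations, and integration from the fixed point drifts by < 1e-9
  over 3 s.

## Pause measurement

The source figures mark pause duration (TP) between dotted lines but
never define the criterion numerically. Here the pause **onset** is the
first grid time at or after the last stimulus offset where `V` drops
below a threshold, the **offset** is the first later time it recovers,
and the default ("auto") threshold is **90% of the resting rate** of the
same parameters and context (so pharmacological presets are measured
against their own baselines). The threshold is a configuration knob for
users who prefer other conventions; the qualitative orderings reported
by the test suite (RPE ordering, pharmacology ordering, sweep trends)
were checked to be insensitive to thresholds between 0.2 and 0.9 of the
resting rate. A pause that has not recovered by the end of the horizon
is returned flagged `censored` with the duration measured to the end of
the trace.

## Stimulus protocols

Two canonical protocols: a single block (default 300 ms, the figure
condition) and a 50 Hz × 10 pulse train (the calibration condition).
The train's pulse width is not printed in the source; the default here
is **10 ms (half the 20 ms period)**. With very narrow pulses (~2 ms)
the rate model's activity never drops below the h-current threshold
after the train, every pharmacological condition then produces the same
pause, and the model cannot express the sulpiride < control < cocaine <
h-block ordering it was calibrated to — a rate model needs a duty cycle
large enough to drive the population into its deep-pause regime. Width
is configurable.

## Scenario presets and sweeps

Pharmacology presets apply partial parameter overrides (sulpiride
`W_DA=0`, cocaine `[DA]0=3`, h-block `g_H=0`) to a copy of the caller's
parameters; presets never mutate inputs. Cocaine scales the baseline
target, so it composes multiplicatively with a deficiency coefficient —
an untested combination that triggers a warning. Sweep grids default to
the figure ranges: stimulus duration 100–400 ms, deficiency 0–90%
(axis is `100*(1-alpha)`), levodopa 0–1.0 at `alpha=0.5`, each crossed
with RPE ∈ {−1, 0, 1}, on a 4 s horizon (long enough for the slowest,
h-blocked pause to recover).

## Plasticity

Weight updates use the trial's phasic dopamine integral
`Int([DA](t) - [DA]base) dt` with the **effective baseline**
`alpha*[DA]0 + LDOPA` — under deficiency or levodopa only the
pause-gated phasic component drives learning, matching the constraint
that levodopa restores the baseline but not phasic release. The base
learning rate is scaled by 0.00125 when dopamine sat above baseline and
0.0025 below (the published factors); because the deviation is
single-signed within one pause at this model's resolution, the sign of
the integral selects the factor. Direct-pathway weights potentiate and
indirect-pathway weights depress for positive integrals, and vice versa;
weights are clamped at zero. The base rates `lambda1 = lambda2 = 1.0`
and the per-trial degradation `d_w = 0.01` live in the predecessor
model's parameter set, which is not reproduced here; these defaults are
documented stand-ins and fully configurable.

## Reduced motor-adaptation task

The full predecessor architecture (two-pathway basal-ganglia network,
spinal circuit, 2-D biomechanical arm) is deliberately not reproduced;
the task keeps only the causal chain this model contributes to: cue →
D1/D2 gating → action → distance reward → temporal-difference RPE →
pause-gated dopamine integral → weight update.

* **Geometry.** Five candidate motor programs with endpoints evenly
  spaced on [−1, 1]; the executed endpoint is the relay-weighted mean.
  The target sits at +1.0, the edge of the grid: the prism flips the
  whole workspace, and an edge target maximizes the distance between
  the rewarded endpoints before and during the perturbation, as in the
  real task where the mirrored target is maximally far from the learned
  aim. Reward falls linearly from 1 at zero error to 0 at the grid span
  (2.0); RPE is the clamped difference from the previous trial's reward,
  0 on each session's first trial.
* **Perturbation.** The Dove prism reverses perceived horizontal error,
  defeating error-based correction; since this reduced loop learns only
  from reward, the manipulation is realized by mirroring the effective
  (rewarded) target about the origin during the 25 perturbation trials.
  The reported per-trial error is the distance to the current phase's
  effective target — the quantity that falls when reward-based learning
  works.
* **Exploration noise** (`sd = 0.15`) enters through the direct-pathway
  rates only. The update rule credits D1 units in proportion to their
  firing, so a D1 fluctuation that improves reward is potentiated on
  exactly the units that caused it; an independent second noise source
  on D2 would double the endpoint variance while its half of the
  fluctuations is invisible to the D1 update, burying the reinforcement
  signal at the session lengths used here.
* **Initial weights** `w1 = 0.4`, `w2 = 0.1`: biasing the direct
  pathway keeps the rectified D1−D2 gate away from its sparse random
  regime at the start of a session.
* **Bookkeeping.** 25 baseline / 25 perturbation / 25 aftereffect
  trials per session, 8 sessions per condition, weights reset each
  session; session RNGs are spawned from the config seed, so conditions
  run with matched seeds see identical exploration noise streams.
  Each trial triggers one 300 ms-stimulus simulation on a 4 s horizon
  at `dt = 1 ms`; a three-condition comparison (control, 50%
  deficiency, deficiency + levodopa 1.0) is 1 800 trials and runs in
  under a minute on one CPU.

## What the synthetic task does and does not emulate

The task reproduces the *structure* of the prism-throwing experiment
(phase layout, session averaging, reward-only learning) and the
*mechanism* under study (pause-gated dopamine integrals driving
corticostriatal weights). It does not emulate biomechanics, perceptual
noise, or the centimeter error scale of the human data — errors here
are in units of the action grid, and only trends and orderings across
conditions are meaningful. Passing tests therefore show that the
TAN–dopamine gate produces the observed *qualitative* pattern (controls
adapt, 50% deficiency abolishes adaptation, levodopa partially restores
it through pause length alone), not that the reduced learner is
quantitatively comparable to human throwing.

## Known limitations

* The aversive-outcome pause (RPE = −1) is the least
  deficiency-sensitive of the three RPE levels, but it is not constant:
  integrating the model equations gives ~24% decline over 0–90%
  deficiency (~11% over 0–50%), at every pause-threshold convention
  tried. The idealization "dopamine reaches zero during the pause for
  every alpha" holds only at `V = 0` exactly; in the trajectory `V`
  hovers near `th_DA`, holding dopamine near `alpha*V/th_DA`, and the
  pause-exit transit is modulated by the alpha-scaled baseline.
* With 8 sessions per condition the paired early-vs-late comparison has
  modest statistical power; the control-adapts / deficiency-does-not
  contrast is reproduced at the default seed and at most others, but
  individual seeds can fall on either side of the 0.05 line.
* Levodopa at 1.0 restores most of the pause duration, so the
  late-perturbation gap between control and levodopa conditions is
  real but small, mirroring the near-recovery described for the
  original simulations.
* Muscarinic projections to medium spiny neurons, accumbens-shell
  acetylcholine kinetics, and spiking-level detail are outside the
  model's scope.
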