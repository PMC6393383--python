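"""Unit and property tests for the coupled TAN-dopamine dynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from tanpause.dynamics import (
    ModelParams,
    PauseMetrics,
    ScenarioContext,
    SimulationTrace,
    StimulusProtocol,
    SystemState,
    derivatives,
    detect_pause,
    integrate,
    phasic_da_integral,
    sigma,
    steady_state,
)

REST_V = math.tanh(0.3)  # tonic rate at the default constant drive


# --------------------------------------------------------------------------
# activation function
# --------------------------------------------------------------------------

@pytest.mark.parametrize("x, expected", [
    (0.0, 0.0),            # gate closed exactly at the origin
    (-1.0, 0.0),           # negative drive fully rectified
    (0.3, 0.2913126124515909),  # tanh(0.3) to double precision
    (5.0, math.tanh(5.0)),
])
def test_sigma_values(x, expected):
    assert sigma(x) == pytest.approx(expected, abs=1e-15)


def test_sigma_rejects_non_finite():
    with pytest.raises(ValueError):
        sigma(float("nan"))
    with pytest.raises(ValueError):
        sigma(float("inf"))


@given(st.floats(-18, 18))
@settings(max_examples=50, deadline=None)
def test_sigma_range(x):
    # strictly below 1 wherever tanh has not saturated to 1.0 in floats
    assert 0.0 <= sigma(x) < 1.0


# --------------------------------------------------------------------------
# domain-type validation
# --------------------------------------------------------------------------

def test_params_reject_nonpositive_time_constant():
    with pytest.raises(ValueError):
        ModelParams(tau_tan=0.0)


def test_params_warn_on_threshold_inversion():
    with pytest.warns(UserWarning):
        ModelParams(theta_h=0.5)  # > theta_sahp


def test_context_clamps_rpe_and_validates():
    assert ScenarioContext(rpe=3.0).rpe == 1.0
    assert ScenarioContext(rpe=-7.0).rpe == -1.0
    with pytest.raises(ValueError):
        ScenarioContext(alpha=1.5)
    with pytest.raises(ValueError):
        ScenarioContext(ldopa=-0.1)


def test_stimulus_rejects_overlap_and_out_of_range():
    with pytest.raises(ValueError):
        StimulusProtocol([(0, 100), (50, 150)], 1000)
    with pytest.raises(ValueError):
        StimulusProtocol([(900, 1100)], 1000)


# --------------------------------------------------------------------------
# right-hand side
# --------------------------------------------------------------------------

def test_derivatives_vanish_at_healthy_rest(params):
    # tanh(0.3) ~ 0.2913 lies strictly between theta_h=0.2 and
    # theta_sahp=0.3, so both current targets are zero and the rest point
    # is an exact equilibrium.
    assert params.theta_h < REST_V < params.theta_sahp
    state = SystemState(v_tan=REST_V, i_sahp=0.0, i_h=0.0, da=1.0)
    stim = StimulusProtocol.none(1000.0)
    d = derivatives(state, 10.0, params, stim, ScenarioContext())
    for value in (d.v_tan, d.i_sahp, d.i_h, d.da):
        assert value == pytest.approx(0.0, abs=1e-12)


def test_da_derivative_during_full_pause(params):
    # with the TAN silent the nicotinic clamp is released: DA relaxes
    # toward baseline + RPE
    stim = StimulusProtocol.none(1000.0)
    state = SystemState(v_tan=0.0, i_sahp=-1.0, i_h=0.0, da=1.0)
    d = derivatives(state, 10.0, params, stim, ScenarioContext(rpe=1.0))
    assert d.da == pytest.approx((2.0 - 1.0) / params.tau_da)


def test_da_target_zero_under_half_deficiency_negative_rpe(params):
    # alpha=0.5, rpe=-1, v=0: target = 0.5 * (1 - 1) = 0
    stim = StimulusProtocol.none(1000.0)
    state = SystemState(v_tan=0.0, i_sahp=-1.0, i_h=0.0, da=1.0)
    d = derivatives(state, 0.0, params, stim,
                    ScenarioContext(rpe=-1.0, alpha=0.5))
    assert d.da == pytest.approx((0.0 - 1.0) / params.tau_da)


# --------------------------------------------------------------------------
# steady state
# --------------------------------------------------------------------------

@pytest.mark.parametrize("alpha, ldopa, expected_da", [
    (1.0, 0.0, 1.0),    # healthy baseline
    (0.5, 0.0, 0.5),    # 50% deficiency exactly halves the baseline
    (0.5, 0.5, 1.0),    # levodopa 0.5 restores the healthy baseline
])
def test_steady_state_baseline_dopamine(params, alpha, ldopa, expected_da):
    ss = steady_state(params, ScenarioContext(alpha=alpha, ldopa=ldopa))
    assert ss.da == pytest.approx(expected_da, abs=1e-12)
    assert ss.v_tan == pytest.approx(REST_V, abs=1e-9)


def test_steady_state_independent_of_rpe(params):
    # tonic firing keeps the nicotinic clamp engaged: rpe is invisible
    for rpe in (-1.0, 0.3, 1.0):
        ss = steady_state(params, ScenarioContext(rpe=rpe))
        assert ss.da == pytest.approx(1.0, abs=1e-12)


# --------------------------------------------------------------------------
# integration
# --------------------------------------------------------------------------

def test_rest_trace_is_stationary(params):
    stim = StimulusProtocol.none(2000.0)
    trace = integrate(params, stim, ScenarioContext(), dt=1.0)
    assert np.max(np.abs(trace.v_tan - REST_V)) < 1e-9
    assert np.max(np.abs(trace.da - 1.0)) < 1e-9


def test_rpe_zero_da_stays_at_baseline(params, block_stim):
    trace = integrate(params, block_stim, ScenarioContext(rpe=0.0))
    assert np.max(np.abs(trace.da - 1.0)) < 1e-6


def test_positive_rpe_da_approaches_two(params, block_stim):
    trace = integrate(params, block_stim, ScenarioContext(rpe=1.0))
    pause = detect_pause(trace)
    assert pause.max_da == pytest.approx(2.0, rel=0.01)


def test_large_dt_raises(params, block_stim):
    with pytest.raises(ValueError, match="smaller step"):
        integrate(params, block_stim, ScenarioContext(), dt=500.0)


def test_state_invariants_hold_along_trace(params, block_stim):
    trace = integrate(params, block_stim, ScenarioContext(rpe=-1.0, alpha=0.5))
    assert np.all((trace.v_tan >= 0) & (trace.v_tan < 1))
    assert np.all(trace.i_sahp <= 1e-12)
    assert np.all(trace.i_h >= -1e-12)
    assert np.all(trace.da >= 0)


@given(
    rpe=st.floats(-1, 1),
    alpha=st.floats(0, 1),
    ldopa=st.floats(0, 1),
    dur=st.floats(50, 500),
)
@settings(max_examples=25, deadline=None)
def test_trace_ranges_property(rpe, alpha, ldopa, dur):
    """v stays in [0,1), sAHP <= 0, h-current >= 0, DA >= 0 everywhere."""
    params = ModelParams()
    stim = StimulusProtocol([(0.0, dur)], 1500.0)
    trace = integrate(params, stim, ScenarioContext(rpe, alpha, ldopa))
    assert np.all((trace.v_tan >= 0) & (trace.v_tan < 1))
    assert np.all(trace.i_sahp <= 1e-12)
    assert np.all(trace.i_h >= -1e-12)
    assert np.all(trace.da >= 0)


# --------------------------------------------------------------------------
# pause detection
# --------------------------------------------------------------------------

def _synthetic_trace(params):
    """Square drop to zero on [500, 900) ms, resting rate elsewhere."""
    stim = StimulusProtocol([(200.0, 500.0)], 1500.0)
    t = np.arange(0.0, 1501.0)
    v = np.full_like(t, 0.29)
    v[(t >= 500) & (t < 900)] = 0.0
    zeros = np.zeros_like(t)
    return SimulationTrace(t=t, v_tan=v, i_sahp=zeros, i_h=zeros,
                           da=np.ones_like(t), params=params,
                           stimulus=stim, context=ScenarioContext(), dt=1.0)


def test_detect_pause_square_trace(params):
    pause = detect_pause(_synthetic_trace(params), pause_threshold=0.26)
    assert pause.duration_ms == pytest.approx(400.0)
    assert pause.onset_ms == pytest.approx(500.0)
    assert not pause.censored


def test_no_stimulus_means_no_pause(params):
    stim = StimulusProtocol.none(1000.0)
    trace = integrate(params, stim, ScenarioContext())
    pause = detect_pause(trace)
    assert pause.duration_ms == 0.0
    assert not pause.has_pause


def test_pause_onset_follows_last_stimulus_offset(params, block_stim):
    trace = integrate(params, block_stim, ScenarioContext())
    pause = detect_pause(trace)
    assert pause.has_pause
    assert pause.onset_ms >= block_stim.last_offset_ms


def test_unrecovered_pause_is_censored(params):
    # h-current blocked and a short horizon: activity cannot recover
    blocked = params.replace(g_h=0.0)
    stim = StimulusProtocol([(0.0, 300.0)], 1000.0)
    trace = integrate(blocked, stim, ScenarioContext())
    with pytest.warns(UserWarning, match="censored"):
        pause = detect_pause(trace)
    assert pause.censored
    assert pause.offset_ms is None
    assert pause.duration_ms == pytest.approx(1000.0 - pause.onset_ms)


def test_pause_duration_orders_with_rpe(tp_by_rpe):
    """Longer pause for reward, shorter for aversive outcomes."""
    assert tp_by_rpe[1.0] > tp_by_rpe[0.0] > tp_by_rpe[-1.0]


# --------------------------------------------------------------------------
# phasic dopamine integral
# --------------------------------------------------------------------------

def test_phasic_integral_signs_and_magnitudes(params, block_stim):
    traces = {rpe: integrate(params, block_stim, ScenarioContext(rpe=rpe))
              for rpe in (-1.0, 0.0, 1.0)}
    ints = {rpe: phasic_da_integral(tr) for rpe, tr in traces.items()}
    assert ints[0.0] == pytest.approx(0.0, abs=1e-3)
    assert ints[1.0] > 0 > ints[-1.0]
    # the reward-side pause is longer, so the positive excursion
    # accumulates over more time
    assert abs(ints[1.0]) > abs(ints[-1.0])


def test_phasic_integral_uses_effective_baseline(params, block_stim):
    # at rpe=0 under deficiency+levodopa the deviation from the
    # context's own baseline is ~0 even though da != da0
    ctx = ScenarioContext(rpe=0.0, alpha=0.5, ldopa=0.3)
    trace = integrate(params, block_stim, ctx)
    assert phasic_da_integral(trace) == pytest.approx(0.0, abs=1e-3)


# --------------------------------------------------------------------------
# numerical soundness
# --------------------------------------------------------------------------

def test_dt_refinement_changes_tp_under_two_percent(params, block_stim):
    for rpe in (-1.0, 0.0, 1.0):
        tp_coarse = detect_pause(
            integrate(params, block_stim, ScenarioContext(rpe=rpe), dt=1.0)
        ).duration_ms
        tp_fine = detect_pause(
            integrate(params, block_stim, ScenarioContext(rpe=rpe), dt=0.5)
        ).duration_ms
        assert abs(tp_fine - tp_coarse) / tp_coarse < 0.02


def test_euler_matches_adaptive_oracle(params):
    """Fine-step Euler and an adaptive-step integrator agree on the pause.

    The oracle integrates the identical right-hand side with scipy's
    RK45 at tight tolerance, stepping the stimulus discontinuities
    explicitly, then measures the pause on a dense output grid.
    """
    stim = StimulusProtocol([(0.0, 300.0)], 2500.0)
    ctx = ScenarioContext(rpe=1.0)

    def rhs(t, y):
        d = derivatives(SystemState(*y), t, params, stim, ctx)
        return [d.v_tan, d.i_sahp, d.i_h, d.da]

    ss = steady_state(params, ctx)
    t_eval = np.arange(0.0, 2500.0 + 0.25, 0.25)
    sol = solve_ivp(rhs, (0.0, 2500.0), ss.as_array(), t_eval=t_eval,
                    max_step=1.0, rtol=1e-8, atol=1e-10)
    assert sol.success
    oracle_trace = SimulationTrace(
        t=sol.t, v_tan=sol.y[0], i_sahp=sol.y[1], i_h=sol.y[2],
        da=np.maximum(sol.y[3], 0.0), params=params, stimulus=stim,
        context=ctx, dt=0.25)
    tp_oracle = detect_pause(oracle_trace).duration_ms

    euler = integrate(params, stim, ctx, dt=0.01)
    tp_euler = detect_pause(euler).duration_ms
    assert abs(tp_euler - tp_oracle) / tp_oracle < 0.005


def test_integrate_from_rest_drift_below_1e9(params):
    stim = StimulusProtocol.none(3000.0)
    trace = integrate(params, stim, ScenarioContext(alpha=0.7, ldopa=0.2))
    ss = steady_state(params, ScenarioContext(alpha=0.7, ldopa=0.2))
    assert np.max(np.abs(trace.v_tan - ss.v_tan)) < 1e-9
    assert np.max(np.abs(trace.da - ss.da)) < 1e-9
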