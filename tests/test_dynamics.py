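"""Limit-cycle detection, measurement, and the second-order reformulation."""

import numpy as np
import pytest

from oscperturb.dynamics import (
    DynamicsConfig,
    SecondOrderState,
    find_limit_cycle,
    integrate_second_order,
    measure_frequency_amplitude,
)
from oscperturb.errors import (
    InsufficientCyclesError,
    NoOscillationError,
    ValidationError,
)
from oscperturb.models import bundled_parameters, build_model
from oscperturb.workbench import make_fixture


# ---------------------------------------------------------------------------
# measure_frequency_amplitude


def test_sinusoid_measurement_recovers_closed_form():
    fx = make_fixture("sinusoid_trace")
    freq, amp = measure_frequency_amplitude(fx.times, fx.values.reshape(1, -1))
    assert freq == pytest.approx(1.0 / fx.period, rel=1e-3)
    assert amp == pytest.approx(fx.amplitude, rel=1e-3)


def test_constant_trace_raises_no_oscillation():
    t = np.linspace(0, 10, 500)
    with pytest.raises(NoOscillationError):
        measure_frequency_amplitude(t, np.full((1, t.size), 3.0))


def test_too_few_cycles_raises():
    t = np.linspace(0, 1.2, 500)  # barely one period
    x = np.sin(2 * np.pi * t).reshape(1, -1)
    with pytest.raises(InsufficientCyclesError):
        measure_frequency_amplitude(t, x)


def test_second_harmonic_does_not_shift_fundamental():
    period = 5.0
    t = np.arange(0.0, 60.0, 0.005)
    x = np.sin(2 * np.pi * t / period) + 0.1 * np.sin(4 * np.pi * t / period)
    freq, _ = measure_frequency_amplitude(t, x.reshape(1, -1))
    assert freq == pytest.approx(1.0 / period, rel=5e-3)


# ---------------------------------------------------------------------------
# find_limit_cycle


def test_bundled_simple_nfo_has_cycle_and_frequency_identity(dynamics_config):
    model = build_model("simple_nfo", 4)
    out = find_limit_cycle(model, bundled_parameters("simple_nfo"), dynamics_config)
    assert out.oscillates
    cyc = out.cycle
    assert cyc.frequency * cyc.period == pytest.approx(1.0, abs=1e-15)
    assert cyc.reporter_amplitude > 0
    assert np.all(cyc.amplitude >= 0)
    assert cyc.cycle_states.shape == (dynamics_config.phase_count, 3)


def test_cycle_is_initial_condition_independent(dynamics_config):
    model = build_model("simple_nfo", 4)
    params = bundled_parameters("simple_nfo")
    periods = []
    for ic in ([1.0, 1.0, 1.0], [30.0, 5.0, 0.01]):
        out = find_limit_cycle(model, params, dynamics_config, initial_state=ic)
        assert out.oscillates
        periods.append(out.cycle.period)
    assert periods[0] == pytest.approx(periods[1], rel=5e-3)


def test_damped_linear_system_classified_absent():
    fx = make_fixture("linear_damped_3node", seed=3)
    assert np.all(fx.eigenvalues.real < 0)  # damped by construction
    out = find_limit_cycle(
        fx.model, {}, DynamicsConfig(), initial_state=np.array([1.0, 1.0, 1.0])
    )
    assert not out.oscillates
    assert out.classification in ("damped", "fixed_point")


def test_cycle_measurement_is_solver_tolerance_converged(dynamics_config):
    """Refining rtol/atol 10x moves period and amplitude by < 0.01%."""
    model = build_model("simple_nfo", 4)
    params = bundled_parameters("simple_nfo")
    coarse = find_limit_cycle(model, params, dynamics_config).cycle
    tight = find_limit_cycle(
        model,
        params,
        DynamicsConfig(rtol=dynamics_config.rtol / 10, atol=dynamics_config.atol / 10,
                       seed=dynamics_config.seed),
    ).cycle
    assert coarse.period == pytest.approx(tight.period, rel=1e-4)
    assert coarse.reporter_amplitude == pytest.approx(
        tight.reporter_amplitude, rel=1e-4
    )


# ---------------------------------------------------------------------------
# integrate_second_order


def test_zero_velocity_freezes_position():
    model = build_model("simple_nfo", 4)
    params = bundled_parameters("simple_nfo")
    x0 = np.array([1.0, 2.0, 0.3])
    start = SecondOrderState(position=x0, velocity=np.zeros(3))
    _, pos, vel = integrate_second_order(model, params, start, duration=5.0)
    np.testing.assert_allclose(pos[-1], x0, atol=1e-8)
    np.testing.assert_allclose(vel[-1], 0.0, atol=1e-10)


def test_linear_system_matches_matrix_exponential():
    fx = make_fixture("linear_oscillatory_2node")
    x0 = np.array([1.0, 0.5])
    start = SecondOrderState(position=x0, velocity=fx.matrix @ x0)
    cfg = DynamicsConfig(rtol=1e-10, atol=1e-12)
    t_eval = np.linspace(0.0, 5.0, 11)
    t, pos, _ = integrate_second_order(
        fx.model, {}, start, duration=5.0, config=cfg, t_eval=t_eval
    )
    exact = fx.exact_solution(x0, t)
    np.testing.assert_allclose(pos, exact, rtol=1e-6, atol=1e-8)


def test_negative_duration_rejected():
    model = build_model("simple_nfo", 4)
    start = SecondOrderState(position=np.ones(3), velocity=np.zeros(3))
    with pytest.raises(ValidationError):
        integrate_second_order(model, bundled_parameters("simple_nfo"), start, duration=-1.0)


@pytest.mark.parametrize("topo", ["simple_nfo", "incoherent_nfo_type1"])
def test_second_order_tracks_first_order_over_one_period(
    topo, screened_sets, dynamics_config
):
    """From a limit-cycle point with v = f(x), the reformulated system's
    position trace reproduces the first-order trajectory."""
    from scipy.integrate import solve_ivp

    model, sets, cycles = screened_sets[topo]
    ps = sets[0]
    cyc = cycles[(ps.seed, ps.id)]
    packed = model.pack(ps)
    x0 = cyc.anchor_state
    start = SecondOrderState(position=x0, velocity=model.rhs_fn(x0, packed))
    t_eval = np.linspace(0.0, cyc.period, 80)
    cfg = DynamicsConfig(rtol=1e-10, atol=1e-12)
    _, pos, _ = integrate_second_order(
        model, ps, start, duration=cyc.period, config=cfg, t_eval=t_eval
    )
    first = solve_ivp(
        lambda t, x: model.rhs_fn(x, packed),
        (0.0, cyc.period),
        x0,
        method=cfg.method,
        rtol=cfg.rtol,
        atol=cfg.atol,
        t_eval=t_eval,
    )
    scale = np.abs(first.y).max(axis=1, keepdims=True).T + 1e-12
    assert np.max(np.abs(pos - first.y.T) / scale) < 1e-3
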