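"""Integration, limit-cycle detection and oscillation measurement.

The perturbation engine works on the second-order reformulation of a model:
differentiating ``dx/dt = f(x)`` in time gives ``d2x/dt2 = J(x) dx/dt``,
which exposes every network interaction as one Jacobian element that can be
scaled independently.  This module provides

* :func:`find_limit_cycle` — multi-start integration that either returns a
  converged periodic orbit (period, per-variable amplitude, a phase-sampled
  state grid) or classifies the trajectory as fixed-point / damped /
  divergent;
* :func:`measure_frequency_amplitude` — peak-based measurement on a
  stabilized trajectory;
* :func:`integrate_second_order` — the reformulated system, optionally with
  one Jacobian element multiplied by a weakening factor along the whole
  trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

from .errors import (
    InsufficientCyclesError,
    IntegrationError,
    NoOscillationError,
    ValidationError,
)
from .models import OscillatorModel

__all__ = [
    "DynamicsConfig",
    "LimitCycle",
    "SecondOrderState",
    "CycleSearchOutcome",
    "find_limit_cycle",
    "measure_frequency_amplitude",
    "integrate_second_order",
    "steady_state_stability",
]


@dataclass(frozen=True)
class DynamicsConfig:
    """Solver and detection settings.

    The timescale-dependent quantities (transient, measurement window) are
    expressed as multiples of a crude per-model timescale estimate — for the
    Hill-template models the slowest degradation time ``1/min(kd)`` — so the
    same config works across parameter sets spanning six decades of rates.
    """

    rtol: float = 1e-8
    atol: float = 1e-8
    method: str = "LSODA"
    transient_factor: float = 50.0
    window_factor: float = 60.0
    max_window_doublings: int = 4
    convergence_tol: float = 1e-3
    n_initial_conditions: int = 3
    phase_count: int = 40
    min_relative_amplitude: float = 1e-3
    divergence_threshold: float = 1e9
    samples_per_window: int = 4000
    refine_samples_per_period: int = 250
    max_rhs_evals: int = 400_000
    seed: int = 0


@dataclass
class LimitCycle:
    """A converged periodic orbit.

    ``amplitude`` is the per-variable max-minus-min over one cycle;
    ``cycle_states`` holds ``phase_count`` states evenly spaced in time over
    one period, with phase 0 anchored at the reporter variable's maximum.
    """

    period: float
    amplitude: np.ndarray
    reporter: str
    reporter_index: int
    cycle_states: np.ndarray  # (phase_count, n_nodes)
    anchor_state: np.ndarray
    phase_count: int
    meta: dict = field(default_factory=dict)

    @property
    def frequency(self) -> float:
        return 1.0 / self.period

    @property
    def reporter_amplitude(self) -> float:
        return float(self.amplitude[self.reporter_index])

    def to_dict(self) -> dict:
        return {
            "period": self.period,
            "frequency": self.frequency,
            "amplitude": self.amplitude.tolist(),
            "reporter": self.reporter,
            "phase_count": self.phase_count,
        }


@dataclass
class CycleSearchOutcome:
    """Result of a limit-cycle search: a cycle, or a classification."""

    cycle: LimitCycle | None
    classification: str  # 'limit_cycle' | 'fixed_point' | 'damped' | 'divergent'
    detail: dict = field(default_factory=dict)

    @property
    def oscillates(self) -> bool:
        return self.cycle is not None


@dataclass
class SecondOrderState:
    """Position/velocity pair for the reformulated system (v is dx/dt)."""

    position: np.ndarray
    velocity: np.ndarray


# ---------------------------------------------------------------------------
# Helpers


def _timescale(model: OscillatorModel, packed: np.ndarray) -> float:
    kd_idx = model.metadata.get("kd_idx")
    if kd_idx is not None:
        return 1.0 / float(min(packed[k] for k in kd_idx))
    return float(model.metadata.get("timescale", 1.0))


def _clamp_state(model: OscillatorModel, x: np.ndarray) -> np.ndarray:
    """Clip a candidate initial state into the model's admissible box."""
    lo = model.metadata.get("state_min")
    hi = model.metadata.get("state_max")
    x = np.asarray(x, float)
    x = np.maximum(x, 1e-12 if lo is None else np.asarray(lo, float))
    if hi is not None:
        hi = np.asarray(hi, float)
        x = np.minimum(x, np.where(np.isfinite(hi), 0.98 * hi, hi))
    return x


def _default_initial(model: OscillatorModel, packed: np.ndarray) -> np.ndarray:
    fn = model.metadata.get("default_initial_fn")
    if fn is not None:
        return np.asarray(fn(packed), float)
    kd_idx = model.metadata.get("kd_idx")
    syn_idx = model.metadata.get("syn_idx")
    if kd_idx is not None and syn_idx is not None:
        # half the maximal steady level (sum of channel rates) / kd per node
        return np.array(
            [
                0.5 * sum(packed[v] for v in syn_idx[i]) / packed[kd_idx[i]]
                for i in range(model.n_nodes)
            ]
        )
    x0 = model.metadata.get("default_initial")
    if x0 is None:
        return np.ones(model.n_nodes)
    return np.asarray(x0, dtype=float)


def _solve(fun, t_span, y0, cfg: DynamicsConfig, t_eval=None, dense=False):
    try:
        sol = solve_ivp(
            fun,
            t_span,
            y0,
            method=cfg.method,
            rtol=cfg.rtol,
            atol=cfg.atol,
            t_eval=t_eval,
            dense_output=dense,
        )
    except (ValueError, FloatingPointError) as exc:  # solver blow-up
        raise IntegrationError(str(exc))
    if not sol.success:
        raise IntegrationError(sol.message)
    return sol


def _refine_extremum(t: np.ndarray, y: np.ndarray, idx: int) -> tuple[float, float]:
    """Parabolic interpolation of an extremum through three samples."""
    if idx <= 0 or idx >= len(y) - 1:
        return t[idx], y[idx]
    y0, y1, y2 = y[idx - 1], y[idx], y[idx + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return t[idx], y[idx]
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    dt = t[idx + 1] - t[idx]
    return t[idx] + delta * dt, y1 - 0.25 * (y0 - y2) * delta


def _peak_indices(y: np.ndarray) -> np.ndarray:
    span = float(np.max(y) - np.min(y))
    if span <= 0:
        return np.array([], dtype=int)
    idx, _ = find_peaks(y, prominence=1e-6 * span)
    return idx


# ---------------------------------------------------------------------------
# Measurement


def measure_frequency_amplitude(
    times: np.ndarray,
    states: np.ndarray,
    reporter_index: int = 0,
    min_peaks: int = 3,
    max_peaks: int = 8,
) -> tuple[float, float]:
    """Frequency and amplitude of a stabilized oscillatory trace.

    Frequency is the reciprocal of the mean inter-peak interval over the
    last ``k >= min_peaks`` reporter peaks (parabolically refined);
    amplitude is the mean per-cycle max-minus-min over the same window.

    Raises
    ------
    NoOscillationError
        if the trace is flat (relative span below 1e-9).
    InsufficientCyclesError
        if fewer than ``min_peaks`` peaks are present.
    """
    times = np.asarray(times, dtype=float)
    states = np.atleast_2d(np.asarray(states, dtype=float))
    if states.shape[0] == len(times):
        states = states.T
    y = states[reporter_index]
    span = float(np.max(y) - np.min(y))
    scale = max(float(np.max(np.abs(y))), 1e-300)
    if span <= 1e-9 * scale:
        raise NoOscillationError("trace is flat; nothing to measure")
    idx = _peak_indices(y)
    if len(idx) < min_peaks:
        raise InsufficientCyclesError(
            f"found {len(idx)} peaks, need at least {min_peaks}"
        )
    idx = idx[-max_peaks:]
    peak_times = np.array([_refine_extremum(times, y, i)[0] for i in idx])
    period = float(np.mean(np.diff(peak_times)))
    amps = []
    for a, b in zip(idx[:-1], idx[1:]):
        seg = y[a : b + 1]
        lo_i = int(np.argmin(seg)) + a
        hi = max(_refine_extremum(times, y, a)[1], _refine_extremum(times, y, b)[1])
        lo = _refine_extremum(times, y, lo_i)[1]
        amps.append(hi - lo)
    return 1.0 / period, float(np.mean(amps))


# ---------------------------------------------------------------------------
# Limit-cycle search


def _refine_extremum_local(sol, rep, i, lo=False):
    """Refine an extremum by densely re-evaluating the continuous solution.

    Falls back to grid parabolic interpolation when the solve carried no
    dense output.
    """
    t = sol.t
    y = sol.y[rep]
    if getattr(sol, "sol", None) is None:
        return _refine_extremum(t, y, i)
    a = max(i - 1, 0)
    b = min(i + 1, len(t) - 1)
    ts = np.linspace(t[a], t[b], 41)
    ys = sol.sol(ts)[rep]
    j = int(np.argmin(ys)) if lo else int(np.argmax(ys))
    return _refine_extremum(ts, ys, j)


def _window_cycle_stats(sol, rep):
    """Refined per-cycle periods and amplitudes from one measurement window."""
    y = sol.y[rep]
    idx = _peak_indices(y)
    if len(idx) < 2:
        return idx, None, None
    peak_t = []
    peak_h = []
    for i in idx:
        t_i, h_i = _refine_extremum_local(sol, rep, i)
        peak_t.append(t_i)
        peak_h.append(h_i)
    periods = np.diff(peak_t)
    amps = []
    for a, b, h1, h2 in zip(idx[:-1], idx[1:], peak_h[:-1], peak_h[1:]):
        lo_i = int(np.argmin(y[a : b + 1])) + a
        lo = _refine_extremum_local(sol, rep, lo_i, lo=True)[1]
        amps.append(max(h1, h2) - lo)
    return idx, np.asarray(periods), np.asarray(amps)


def _single_start_cycle(model, packed, x0, cfg: DynamicsConfig, want_grid: bool):
    """Integrate one initial condition to (maybe) a stabilized cycle.

    Returns ``(payload, kind, extra)`` where payload is a
    :class:`LimitCycle` (``want_grid=True``), a coarse ``(period,
    amplitude)`` tuple (``want_grid=False``), or ``None`` for
    non-oscillatory outcomes.
    """
    rhs = model.rhs_fn
    # evaluation budget: a single pathologically stiff parameter draw must
    # not stall a whole screening run
    budget = [cfg.max_rhs_evals]

    def fun(t, x):
        budget[0] -= 1
        if budget[0] <= 0:
            raise IntegrationError("rhs evaluation budget exhausted")
        return rhs(x, packed)

    tau = _timescale(model, packed)
    rep = model.node_index(model.reporter or model.nodes[0])

    # transient
    x = np.asarray(x0, float)
    sol = _solve(fun, (0.0, cfg.transient_factor * tau), x, cfg)
    x = sol.y[:, -1]
    if np.max(np.abs(x)) > cfg.divergence_threshold:
        return None, "divergent", None

    # coarse pass: find enough peaks to estimate the period at all
    window = cfg.window_factor * tau
    for _ in range(cfg.max_window_doublings + 1):
        t_eval = np.linspace(0.0, window, cfg.samples_per_window)
        sol = _solve(fun, (0.0, window), x, cfg, t_eval=t_eval)
        Y = sol.y
        if np.max(np.abs(Y)) > cfg.divergence_threshold:
            return None, "divergent", None
        y = Y[rep]
        idx = _peak_indices(y)
        if len(idx) >= 5:
            break
        x = Y[:, -1]
        window *= 2.0
    y = Y[rep]
    idx = _peak_indices(y)
    scale = max(float(np.max(np.abs(y))), 1e-300)
    span = float(np.max(y) - np.min(y))
    if len(idx) < 4 or span < cfg.min_relative_amplitude * scale:
        if len(idx) >= 2 and span >= 1e-6 * scale:
            heights = y[idx] - np.min(y)
            if heights[-1] < 0.5 * np.max(heights):
                return None, "damped", None
        return None, "fixed_point", None
    period_est = float(np.median(np.diff(sol.t[idx])))
    x = Y[:, -1]

    # convergence rounds: dense ~8-period windows, parabolic refinement
    n_per = cfg.refine_samples_per_period
    amp_history = []
    sol = None
    for round_ in range(6):
        t_end = 8.2 * period_est
        t_eval = np.linspace(0.0, t_end, int(8.2 * n_per))
        sol = _solve(fun, (0.0, t_end), x, cfg, t_eval=t_eval, dense=True)
        if np.max(np.abs(sol.y)) > cfg.divergence_threshold:
            return None, "divergent", None
        idx, periods, amps = _window_cycle_stats(sol, rep)
        if periods is None or len(periods) < 3:
            # period estimate may be stale; retry once from the coarse value
            y = sol.y[rep]
            scale = max(float(np.max(np.abs(y))), 1e-300)
            if float(np.max(y) - np.min(y)) < cfg.min_relative_amplitude * scale:
                return None, ("damped" if amp_history else "fixed_point"), None
            if len(idx) >= 2:
                period_est = float(np.median(np.diff(sol.t[idx])))
                x = sol.y[:, -1]
                continue
            return None, "fixed_point", None
        period_est = float(np.mean(periods[-5:]))
        amp_now = float(np.mean(amps[-5:]))
        amp_history.append(amp_now)
        tail_p = periods[-5:]
        tail_a = amps[-5:]
        p_spread = (tail_p.max() - tail_p.min()) / np.mean(tail_p)
        a_spread = (tail_a.max() - tail_a.min()) / max(abs(np.mean(tail_a)), 1e-300)
        if p_spread < cfg.convergence_tol and a_spread < cfg.convergence_tol:
            break
        # not settled: relax for ~25 periods and re-measure
        relax = _solve(fun, (0.0, 25.0 * period_est), sol.y[:, -1], cfg)
        x = relax.y[:, -1]
        if np.max(np.abs(x)) > cfg.divergence_threshold:
            return None, "divergent", None
    else:
        if len(amp_history) >= 3 and amp_history[-1] < 0.95 * amp_history[0]:
            return None, "damped", None
        return None, "fixed_point", None

    y = sol.y[rep]
    scale = max(float(np.max(np.abs(y))), 1e-300)
    if float(np.max(y) - np.min(y)) < cfg.min_relative_amplitude * scale:
        return None, "damped", None
    period = period_est
    if not want_grid:
        return (period, amp_now), "limit_cycle", None

    # anchor phase 0 at a refined reporter maximum with a full period after it
    idx_all = _peak_indices(y)
    peak_times = np.array([_refine_extremum_local(sol, rep, i)[0] for i in idx_all])
    anchor_t = peak_times[0]
    for pt in peak_times:
        if pt + 1.02 * period <= sol.t[-1]:
            anchor_t = pt
    grid_t = anchor_t + period * np.arange(cfg.phase_count) / cfg.phase_count
    cycle_states = sol.sol(grid_t).T
    dense_t = np.linspace(anchor_t, anchor_t + period, 8 * n_per)
    dense_states = sol.sol(dense_t)
    # per-variable amplitude with parabolic refinement at the grid extrema:
    # the raw grid max/min undershoots sharp relaxation spikes by ~0.1%
    amplitude = np.empty(len(dense_states))
    for v in range(len(dense_states)):
        yv = dense_states[v]
        hi = _refine_extremum(dense_t, yv, int(np.argmax(yv)))[1]
        lo = _refine_extremum(dense_t, yv, int(np.argmin(yv)))[1]
        amplitude[v] = hi - lo
    cyc = LimitCycle(
        period=period,
        amplitude=amplitude,
        reporter=model.reporter or model.nodes[rep],
        reporter_index=rep,
        cycle_states=cycle_states,
        anchor_state=cycle_states[0].copy(),
        phase_count=cfg.phase_count,
    )
    return cyc, "limit_cycle", (period, amp_now)


def find_limit_cycle(
    model: OscillatorModel,
    params: Mapping[str, float],
    config: DynamicsConfig | None = None,
    initial_state=None,
) -> CycleSearchOutcome:
    """Search for a stable limit cycle of ``model`` under ``params``.

    Integrates from ``n_initial_conditions`` distinct positive starting
    points; a cycle is accepted only if the tail peaks have converged in
    period and amplitude (relative spread below ``convergence_tol``) and
    the starts agree with each other within the same tolerance.
    """
    cfg = config or DynamicsConfig()
    packed = model.pack(params)

    if initial_state is not None:
        starts = [_clamp_state(model, initial_state)]
    else:
        base = np.maximum(_default_initial(model, packed), 1e-9)
        rng = np.random.default_rng(cfg.seed)
        starts = [_clamp_state(model, base)] + [
            _clamp_state(model, base * np.exp(rng.uniform(-3.0, 3.0, size=len(base))))
            for _ in range(max(cfg.n_initial_conditions - 1, 0))
        ]

    cycle = None
    classifications = []
    for x0 in starts:
        try:
            cycle, kind, _ = _single_start_cycle(model, packed, x0, cfg, want_grid=True)
        except IntegrationError as exc:
            classifications.append("divergent")
            continue
        if kind == "limit_cycle":
            break
        classifications.append(kind)
        cycle = None
    if cycle is None:
        # no start reached a cycle; report the dominant classification
        if "damped" in classifications:
            kind = "damped"
        elif classifications and all(c == "divergent" for c in classifications):
            kind = "divergent"
        else:
            kind = "fixed_point"
        return CycleSearchOutcome(None, kind)

    # attraction check: a trajectory started slightly off the orbit must
    # relax back to the same period and amplitude
    meas = None
    kind2 = "fixed_point"
    for kick in (1.005, 1.001):
        probe_start = _clamp_state(model, cycle.anchor_state * kick)
        try:
            meas, kind2, _ = _single_start_cycle(
                model, packed, probe_start, cfg, want_grid=False
            )
        except IntegrationError:
            return CycleSearchOutcome(None, "divergent")
        if kind2 == "limit_cycle":
            break
    if kind2 != "limit_cycle":
        return CycleSearchOutcome(None, kind2, {"attraction_check_failed": True})
    period2, amp2 = meas
    # agreement at a looser band: the coarse secondary measurement is
    # itself only convergence_tol-accurate
    band = 10.0 * cfg.convergence_tol
    if abs(period2 - cycle.period) / cycle.period > band:
        return CycleSearchOutcome(None, "fixed_point", {"period_mismatch": True})
    if abs(amp2 - cycle.reporter_amplitude) / max(cycle.reporter_amplitude, 1e-300) > band:
        return CycleSearchOutcome(None, "fixed_point", {"amplitude_mismatch": True})
    return CycleSearchOutcome(cycle, "limit_cycle")


# ---------------------------------------------------------------------------
# Second-order reformulation


def integrate_second_order(
    model: OscillatorModel,
    params: Mapping[str, float],
    start: SecondOrderState,
    duration: float,
    jacobian_modifier: tuple[int, int, float] | None = None,
    config: DynamicsConfig | None = None,
    t_eval: np.ndarray | None = None,
):
    """Integrate ``d2x/dt2 = J~(x) dx/dt`` for ``duration`` time units.

    ``jacobian_modifier = (row, col, factor)`` multiplies one element of
    the state-dependent Jacobian by ``factor`` along the whole trajectory;
    ``None`` integrates the unmodified reformulation.

    Returns ``(times, positions, velocities)`` with positions shaped
    ``(len(times), n_nodes)``.
    """
    if duration <= 0:
        raise ValidationError("duration must be positive")
    cfg = config or DynamicsConfig()
    packed = model.pack(params)
    n = model.n_nodes
    jac = model.jac_fn
    budget = [cfg.max_rhs_evals]

    if jacobian_modifier is None:

        def fun(t, y):
            budget[0] -= 1
            if budget[0] <= 0:
                raise IntegrationError("rhs evaluation budget exhausted")
            x, v = y[:n], y[n:]
            return np.concatenate((v, jac(x, packed) @ v))

    else:
        r, c, factor = jacobian_modifier

        def fun(t, y):
            budget[0] -= 1
            if budget[0] <= 0:
                raise IntegrationError("rhs evaluation budget exhausted")
            x, v = y[:n], y[n:]
            J = jac(x, packed)
            J[r, c] *= factor
            return np.concatenate((v, J @ v))

    y0 = np.concatenate(
        (np.asarray(start.position, float), np.asarray(start.velocity, float))
    )
    sol = _solve(fun, (0.0, duration), y0, cfg, t_eval=t_eval)
    return sol.t, sol.y[:n].T, sol.y[n:].T


# ---------------------------------------------------------------------------
# Fixed-point pre-screen (used by the ensemble sampler)


def steady_state_stability(
    model: OscillatorModel, params: Mapping[str, float] | np.ndarray, n_starts: int = 3
):
    """Locate a positive steady state and report its linear stability.

    Returns ``(x_star, max_real_eig)`` or ``(None, None)`` if no steady
    state was found.  Used as a cheap oscillation pre-screen: a parameter
    set whose only steady state is strongly stable cannot sustain a
    limit cycle born of that instability (coexisting attractors at a
    stable focus are possible but rare under this kinetic template).
    """
    from scipy.optimize import root

    packed = params if isinstance(params, np.ndarray) else model.pack(params)
    rhs = model.rhs_fn
    jac = model.jac_fn
    x0 = _default_initial(model, packed)
    best = None
    for k in range(n_starts):
        guess = x0 * (0.5 * (k + 1))
        res = root(
            lambda x: rhs(np.maximum(x, 0.0), packed),
            guess,
            jac=lambda x: jac(np.maximum(x, 0.0), packed),
            method="hybr",
        )
        if res.success and np.all(res.x > -1e-12):
            xs = np.maximum(res.x, 0.0)
            if np.max(np.abs(rhs(xs, packed))) < 1e-8 * (1 + np.max(np.abs(xs))):
                eig = np.linalg.eigvals(jac(xs, packed))
                mre = float(np.max(eig.real))
                if best is None or mre > best[1]:
                    best = (xs, mre)
    if best is None:
        return None, None
    return best
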