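"""The interaction-perturbation engine.

One perturbation run weakens a single Jacobian element during exactly one
baseline period and measures the lasting change in frequency and amplitude:

1. take the baseline limit-cycle state at one of ``phase_count`` evenly
   spaced starting phases (phase 0 anchored at the reporter maximum);
2. integrate the second-order reformulation ``d2x/dt2 = J~(x) dx/dt`` for
   one baseline period, where ``J~`` equals the state-dependent Jacobian
   with the addressed element multiplied by the weakening factor, and the
   initial velocity is ``f(x0)``;
3. continue with the unmodified reformulation until the oscillation has
   stabilized, then measure frequency and amplitude and express both as
   ratios to the baseline.

Step 3 exploits an exact reduction: along the unmodified second-order flow
the offset ``w = dx/dt - f(x)`` is conserved (``dw/dt = J(x)dx/dt -
J(x)dx/dt = 0``), so the relaxation is integrated as the first-order system
``dx/dt = f(x) + w0`` with ``w0`` fixed at its value when the perturbation
window ends.  The perturbation thus acts by displacing the vector field,
and the measured cycle is the limit cycle of the displaced field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .dynamics import (
    DynamicsConfig,
    LimitCycle,
    SecondOrderState,
    _peak_indices,
    _refine_extremum_local,
    _solve,
    integrate_second_order,
)
from .errors import IntegrationError, StructuralLinkError, ValidationError
from .models import OscillatorModel

__all__ = [
    "PerturbationSpec",
    "PerturbationResult",
    "PerturbationConfig",
    "DEFAULT_WEAKENING_FACTORS",
    "perturbed_jacobian_modifier",
    "perturb_once",
    "run_campaign",
    "resample_cycle_states",
]

DEFAULT_WEAKENING_FACTORS = (0.99, 0.98, 0.96, 0.92)

RESULT_COLUMNS = (
    "model",
    "parameter_set_id",
    "link",
    "factor",
    "phase_index",
    "frequency_ratio",
    "amplitude_ratio",
    "status",
)


@dataclass(frozen=True)
class PerturbationSpec:
    """One perturbation condition: which link, how much, starting where."""

    link: str
    weakening_factor: float
    phase_index: int
    phase_count: int = 40

    def __post_init__(self):
        if not (0.0 < self.weakening_factor <= 1.0):
            raise ValidationError("weakening_factor must be in (0, 1]")
        if not (0 <= self.phase_index < self.phase_count):
            raise ValidationError("phase_index must be in [0, phase_count)")


@dataclass(frozen=True)
class PerturbationResult:
    parameter_set_id: int
    link: str
    weakening_factor: float
    phase_index: int
    frequency_ratio: float | None
    amplitude_ratio: float | None
    status: str  # 'sustained' | 'damped' | 'diverged' | 'integration_failed'

    def __post_init__(self):
        has_ratios = self.frequency_ratio is not None and self.amplitude_ratio is not None
        if has_ratios != (self.status == "sustained"):
            raise ValidationError("ratios present iff status == 'sustained'")
        if has_ratios and (self.frequency_ratio <= 0 or self.amplitude_ratio <= 0):
            raise ValidationError("ratios must be strictly positive")


@dataclass(frozen=True)
class PerturbationConfig:
    """Stabilization and measurement settings for the relaxation stage."""

    max_relax_periods: float = 50.0
    stabilize_peaks: int = 5
    stabilize_rtol: float = 1e-3
    samples_per_period: int = 200
    dynamics: DynamicsConfig = field(default_factory=DynamicsConfig)


def perturbed_jacobian_modifier(
    model: OscillatorModel, spec: PerturbationSpec
) -> tuple[int, int, float]:
    """Resolve a link label to the (row, col, factor) element modifier.

    ``Lpq`` addresses row p, column q: weakening ``Lyx`` by 0.99 multiplies
    the element at the second row, first column by 0.99 and leaves every
    other element untouched.
    """
    row, col = model.require_structural(spec.link)
    return row, col, spec.weakening_factor


def resample_cycle_states(
    model: OscillatorModel,
    params,
    cycle: LimitCycle,
    phase_count: int,
    config: DynamicsConfig | None = None,
) -> np.ndarray:
    """States at ``phase_count`` evenly spaced phases of a known cycle.

    Integrates one period from the cycle's anchor (reporter maximum); cheap
    relative to the original cycle search.
    """
    if phase_count == cycle.phase_count:
        return cycle.cycle_states
    cfg = config or DynamicsConfig()
    packed = model.pack(params)
    fun = lambda t, x: model.rhs_fn(x, packed)
    t_eval = cycle.period * np.arange(phase_count) / phase_count
    sol = _solve(fun, (0.0, float(t_eval[-1]) + 1e-12), cycle.anchor_state, cfg,
                 t_eval=t_eval)
    return sol.y.T


def _measure_displaced_cycle(
    model: OscillatorModel,
    packed: np.ndarray,
    w0: np.ndarray,
    x0: np.ndarray,
    period_hint: float,
    cfg: PerturbationConfig,
):
    """Find frequency/amplitude of the stabilized oscillation of f + w0.

    Returns ``(frequency, amplitude, status)`` where status is 'sustained',
    'damped' or 'diverged'.
    """
    dcfg = cfg.dynamics
    rhs = model.rhs_fn
    budget = [dcfg.max_rhs_evals]

    def fun(t, x):
        budget[0] -= 1
        if budget[0] <= 0:
            raise IntegrationError("rhs evaluation budget exhausted")
        return rhs(x, packed) + w0

    rep = model.node_index(model.reporter or model.nodes[0])
    n_per = cfg.samples_per_period

    x = np.asarray(x0, float)
    spent = 0.0
    period_est = period_hint
    amp_history: list[float] = []
    while spent < cfg.max_relax_periods * period_hint:
        t_end = min(
            (cfg.stabilize_peaks + 3.2) * period_est,
            cfg.max_relax_periods * period_hint - spent + 1e-9,
        )
        if t_end <= 0:
            break
        t_eval = np.linspace(0.0, t_end, max(int(t_end / period_est * n_per), 64))
        sol = _solve(fun, (0.0, t_end), x, dcfg, t_eval=t_eval, dense=True)
        spent += t_end
        Y = sol.y
        if np.max(np.abs(Y)) > dcfg.divergence_threshold:
            return None, None, "diverged"
        y = Y[rep]
        scale = max(float(np.max(np.abs(y))), 1e-300)
        span = float(np.max(y) - np.min(y))
        idx = _peak_indices(y)
        if len(idx) < cfg.stabilize_peaks + 1:
            if span < dcfg.min_relative_amplitude * scale:
                return None, None, "damped"
            # too few peaks in the window: re-estimate the period and retry
            if len(idx) >= 2:
                period_est = float(np.median(np.diff(sol.t[idx])))
            else:
                period_est = min(2.0 * period_est, 10.0 * period_hint)
            x = Y[:, -1]
            continue
        # refined peak stats
        peak_t = []
        peak_h = []
        for i in idx:
            t_i, h_i = _refine_extremum_local(sol, rep, i)
            peak_t.append(t_i)
            peak_h.append(h_i)
        k = cfg.stabilize_peaks
        tail_h = np.array(peak_h[-k:])
        h_scale = max(abs(float(np.mean(tail_h))), span, 1e-300)
        stabilized = (tail_h.max() - tail_h.min()) <= cfg.stabilize_rtol * h_scale
        amps = []
        for a, b, h1, h2 in zip(idx[-k:-1], idx[-k + 1:], peak_h[-k:-1], peak_h[-k + 1:]):
            lo_i = int(np.argmin(y[a : b + 1])) + a
            lo = _refine_extremum_local(sol, rep, lo_i, lo=True)[1]
            amps.append(max(h1, h2) - lo)
        amp_now = float(np.mean(amps))
        periods = np.diff(peak_t[-k:])
        per_now = float(np.mean(periods))
        p_spread = (periods.max() - periods.min()) / per_now
        amp_history.append(amp_now)
        if stabilized and p_spread <= 10.0 * cfg.stabilize_rtol:
            if amp_now < dcfg.min_relative_amplitude * scale:
                return None, None, "damped"
            return 1.0 / per_now, amp_now, "sustained"
        period_est = per_now
        x = Y[:, -1]
    # never stabilized within the budget
    if len(amp_history) >= 2 and amp_history[-1] < 0.9 * amp_history[0]:
        return None, None, "damped"
    if not amp_history:
        return None, None, "damped"
    # oscillation persists but drifts slower than the budget allows;
    # report the last window's measurement
    return 1.0 / per_now, amp_now, "sustained"


def perturb_once(
    model: OscillatorModel,
    params,
    baseline: LimitCycle,
    spec: PerturbationSpec,
    config: PerturbationConfig | None = None,
    cycle_states: np.ndarray | None = None,
) -> PerturbationResult:
    """Run one weakening perturbation and report frequency/amplitude ratios.

    Never raises for numerical failures — those surface as the
    ``integration_failed`` status so campaign sweeps are not aborted.
    """
    cfg = config or PerturbationConfig()
    set_id = getattr(params, "id", -1)

    def failed():
        return PerturbationResult(
            set_id, spec.link, spec.weakening_factor, spec.phase_index,
            None, None, "integration_failed",
        )

    try:
        row, col, factor = perturbed_jacobian_modifier(model, spec)
    except StructuralLinkError:
        raise  # caller error, not a numerical failure
    states = cycle_states if cycle_states is not None else baseline.cycle_states
    if spec.phase_index >= len(states):
        raise ValidationError("phase_index outside the provided phase grid")
    anchor = np.asarray(states[spec.phase_index], float)
    packed = model.pack(params)
    try:
        v0 = model.rhs_fn(anchor, packed)
        start = SecondOrderState(position=anchor, velocity=v0)
        # the perturbation window runs at tightened tolerance: the offset
        # w0 = v - f(x) accumulated here IS the perturbation's lasting
        # effect, and solver error in it would masquerade as signal
        # (amplitude susceptibility to a field displacement is large)
        window_cfg = replace(
            cfg.dynamics,
            rtol=max(cfg.dynamics.rtol * 1e-2, 1e-12),
            atol=max(cfg.dynamics.atol * 1e-2, 1e-13),
        )
        _, pos, vel = integrate_second_order(
            model,
            params,
            start,
            duration=baseline.period,
            jacobian_modifier=(row, col, factor),
            config=window_cfg,
            t_eval=np.array([0.0, baseline.period]),
        )
        x_end, v_end = pos[-1], vel[-1]
        if not (np.all(np.isfinite(x_end)) and np.all(np.isfinite(v_end))):
            return failed()
        w0 = v_end - model.rhs_fn(x_end, packed)
        freq, amp, status = _measure_displaced_cycle(
            model, packed, w0, x_end, baseline.period, cfg
        )
    except (IntegrationError, ValidationError, FloatingPointError):
        return failed()
    if status != "sustained":
        return PerturbationResult(
            set_id, spec.link, spec.weakening_factor, spec.phase_index,
            None, None, status,
        )
    base_freq = baseline.frequency
    base_amp = baseline.reporter_amplitude
    return PerturbationResult(
        set_id,
        spec.link,
        spec.weakening_factor,
        spec.phase_index,
        freq / base_freq,
        amp / base_amp,
        "sustained",
    )


def run_campaign(
    model: OscillatorModel,
    ensemble: Sequence,
    cycles: Mapping | Iterable[LimitCycle],
    factors: Sequence[float] = DEFAULT_WEAKENING_FACTORS,
    phase_count: int = 40,
    config: PerturbationConfig | None = None,
    links: Sequence[str] | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Perturb every structurally nonzero Jacobian element of every set.

    ``cycles`` maps ``(seed, id)`` (a :class:`ScreenResult` ``cycles``
    dict) or is a parallel list of baseline :class:`LimitCycle` objects.
    The result table has exactly one row per (parameter set x element x
    factor x phase); non-sustained outcomes are retained but flagged via
    ``status`` so pattern statistics can exclude them.
    """
    if len(ensemble) == 0:
        raise ValidationError("ensemble must be nonempty")
    for f in factors:
        if not (0.0 < f <= 1.0):
            raise ValidationError("all weakening factors must be in (0, 1]")
    cfg = config or PerturbationConfig()
    labels = list(links) if links is not None else model.perturbable_labels()
    if isinstance(cycles, Mapping):
        cycle_list = [cycles[(ps.seed, ps.id)] for ps in ensemble]
    else:
        cycle_list = list(cycles)

    rows = []
    for ps, cyc in zip(ensemble, cycle_list):
        states = resample_cycle_states(model, ps, cyc, phase_count, cfg.dynamics)
        for label in labels:
            for f in factors:
                for phase in range(phase_count):
                    spec = PerturbationSpec(label, f, phase, phase_count)
                    res = perturb_once(
                        model, ps, cyc, spec, cfg, cycle_states=states
                    )
                    rows.append(
                        (
                            model.name,
                            res.parameter_set_id,
                            res.link,
                            res.weakening_factor,
                            res.phase_index,
                            res.frequency_ratio,
                            res.amplitude_ratio,
                            res.status,
                        )
                    )
        if progress:
            print(f"  perturbed set {ps.id} ({len(rows)} rows)", flush=True)
    return pd.DataFrame(rows, columns=list(RESULT_COLUMNS))
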