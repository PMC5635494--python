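"""Random parameter ensembles and oscillation screening.

Ensembles are drawn by Latin hypercube sampling: every sampled parameter is
stratified into ``n`` equal-probability bins of the sampling distribution,
with exactly one draw per bin per dimension.  The default distribution is
log-uniform on [0.001, 1000] — uniform on the exponent across the six
decades of biologically plausible rate constants.  Hill coefficients are a
fixed model property and are never sampled.

Screening retains only parameter sets that sustain a limit-cycle
oscillation.  A cheap two-window integration probe rejects the bulk of
non-oscillatory candidates; survivors are confirmed by the full multi-start
:func:`~oscperturb.dynamics.find_limit_cycle` search, whose cycle object is
kept alongside the parameter set so downstream stages need not recompute it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.stats import qmc

from .dynamics import (
    DynamicsConfig,
    LimitCycle,
    _default_initial,
    _peak_indices,
    _timescale,
    find_limit_cycle,
)
from .errors import ValidationError
from .models import OscillatorModel

__all__ = [
    "ParameterSet",
    "LogUniform",
    "TruncatedExponential",
    "sample_parameters",
    "screen_oscillatory",
    "ScreenResult",
    "DEFAULT_RANGE",
]

DEFAULT_RANGE = (0.001, 1000.0)


@dataclass(frozen=True)
class ParameterSet:
    """A named parameter assignment for one model, with sampling provenance."""

    model_name: str
    values: dict
    seed: int
    id: int

    @property
    def values_map(self) -> dict:
        return self.values

    def __getitem__(self, name: str) -> float:
        return self.values[name]


class LogUniform:
    """Log-uniform sampling distribution on [low, high]."""

    name = "log_uniform"

    def __init__(self, low: float = DEFAULT_RANGE[0], high: float = DEFAULT_RANGE[1]):
        if not (0 < low < high):
            raise ValidationError("need 0 < low < high")
        self.low, self.high = float(low), float(high)

    def ppf(self, u):
        return self.low * (self.high / self.low) ** np.asarray(u)

    def cdf(self, x):
        return np.log(np.asarray(x) / self.low) / math.log(self.high / self.low)


class TruncatedExponential:
    """Exponential distribution truncated to [low, high] (alternative reading)."""

    name = "truncated_exponential"

    def __init__(
        self,
        rate: float = 1.0,
        low: float = DEFAULT_RANGE[0],
        high: float = DEFAULT_RANGE[1],
    ):
        if rate <= 0 or not (0 <= low < high):
            raise ValidationError("need rate > 0 and 0 <= low < high")
        self.rate, self.low, self.high = float(rate), float(low), float(high)
        self._c_low = 1.0 - math.exp(-rate * low)
        self._c_high = 1.0 - math.exp(-rate * high)

    def ppf(self, u):
        c = self._c_low + np.asarray(u) * (self._c_high - self._c_low)
        return -np.log1p(-c) / self.rate

    def cdf(self, x):
        c = 1.0 - np.exp(-self.rate * np.asarray(x))
        return (c - self._c_low) / (self._c_high - self._c_low)


def sample_parameters(
    model: OscillatorModel,
    n: int,
    seed: int,
    distribution=None,
) -> list[ParameterSet]:
    """Draw ``n`` Latin-hypercube parameter sets for ``model``.

    Deterministic given ``(model, n, seed)``.  Fixed-role parameters (Hill
    coefficients) take their schema defaults in every set.
    """
    if n < 0:
        raise ValidationError("n must be >= 0")
    if n == 0:
        return []
    dist = distribution or LogUniform()
    names = model.sampled_parameter_names
    fixed = {
        p.name: p.default for p in model.parameter_schema if p.role == "hill"
    }
    u = qmc.LatinHypercube(d=len(names), seed=seed).random(n)
    vals = dist.ppf(u)
    return [
        ParameterSet(
            model_name=model.name,
            values={**dict(zip(names, map(float, row))), **fixed},
            seed=seed,
            id=i,
        )
        for i, row in enumerate(vals)
    ]


# ---------------------------------------------------------------------------
# Screening


def _probe_oscillation(model, packed, cfg: DynamicsConfig, rng=None):
    """Cheap two-window sustained-oscillation probe.

    Window 1 looks for repeated peaks after a transient; window 2, taken
    roughly 20 estimated periods later, must reproduce the period and
    amplitude within 30%.  Several initial conditions are tried because
    limit cycles of the amplified topologies often coexist with stable
    steady states.  Loose solver tolerances: this is a filter, the
    definitive check is :func:`find_limit_cycle` on survivors.

    Returns a state on the oscillating trajectory, or ``None``.
    """
    rhs = model.rhs_fn
    tau = _timescale(model, packed)
    base = np.maximum(_default_initial(model, packed), 1e-9)
    rep = model.node_index(model.reporter or model.nodes[0])

    class _Budget(Exception):
        pass

    budget = [120_000]  # rhs evaluations per candidate; guards rare
    # pathologically stiff draws from stalling a whole screen

    def fun(t, x):
        budget[0] -= 1
        if budget[0] <= 0:
            raise _Budget
        return rhs(x, packed)

    def window(x, t_skip, t_len, npts=1500):
        try:
            sol = solve_ivp(
                fun,
                (0.0, t_skip + t_len),
                x,
                method=cfg.method,
                rtol=1e-5,
                atol=1e-9,
                t_eval=np.linspace(t_skip, t_skip + t_len, npts),
            )
        except (_Budget, ValueError, FloatingPointError):
            return None
        if not sol.success or np.max(np.abs(sol.y)) > cfg.divergence_threshold:
            return None
        return sol

    from .dynamics import _clamp_state

    starts = [_clamp_state(model, base)]
    if rng is not None:
        starts += [
            _clamp_state(model, base * np.exp(rng.uniform(-3.0, 3.0, len(base))))
            for _ in range(2)
        ]

    for x0 in starts:
        # first a short window; slow relaxation oscillators that show only a
        # couple of peaks there get one retry with a much longer horizon
        for t_skip, t_len, npts in ((30.0, 30.0, 1500), (40.0, 100.0, 2500)):
            sol = window(x0, t_skip * tau, t_len * tau, npts)
            if sol is None:
                break
            y = sol.y[rep]
            span = y.max() - y.min()
            scale = max(np.abs(y).max(), 1e-300)
            if span < 0.5 * cfg.min_relative_amplitude * scale:
                break  # flat: a longer window will not help
            idx = _peak_indices(y)
            if len(idx) < 3:
                continue  # maybe just too slow; retry longer
            h = y[idx] - y.min()
            if h[-1] < 0.7 * h.max():
                continue
            period = float(np.median(np.diff(sol.t[idx])))
            amp1 = float(span)

            sol2 = window(sol.y[:, -1], 20.0 * period, 8.0 * period)
            if sol2 is None:
                break
            y2 = sol2.y[rep]
            idx2 = _peak_indices(y2)
            if len(idx2) < 4:
                continue
            period2 = float(np.median(np.diff(sol2.t[idx2])))
            amp2 = float(y2.max() - y2.min())
            if abs(period2 - period) > 0.3 * period:
                continue
            if abs(amp2 - amp1) > 0.3 * max(amp1, amp2):
                continue
            return sol2.y[:, -1]
    return None


@dataclass
class ScreenResult:
    """Outcome of an oscillation screen."""

    retained: list[ParameterSet]
    cycles: dict  # ParameterSet id -> LimitCycle (keyed by (seed, id))
    n_attempted: int
    n_probe_passed: int
    status: str  # 'ok' | 'budget_exhausted'
    acceptance_rate: float
    batches: int = 0

    def cycle_for(self, ps: ParameterSet) -> LimitCycle:
        return self.cycles[(ps.seed, ps.id)]


def screen_oscillatory(
    model: OscillatorModel,
    candidates: Sequence[ParameterSet],
    target_count: int,
    dynamics_config: DynamicsConfig | None = None,
    max_attempts: int = 200_000,
    batch_seed: int | None = None,
    distribution=None,
    use_probe: bool = True,
) -> ScreenResult:
    """Filter ``candidates`` down to limit-cycle oscillators.

    Candidates are evaluated in order; when the pool is exhausted before
    ``target_count`` oscillatory sets are found, fresh Latin-hypercube
    batches are drawn (advancing the seed per batch, batch size 10x the
    remaining target) until the goal or the ``max_attempts`` budget is
    reached.  Parameter sets are never mutated — the output is a subset of
    the inputs plus freshly sampled sets.
    """
    if target_count < 0:
        raise ValidationError("target_count must be >= 0")
    cfg = dynamics_config or DynamicsConfig()
    retained: list[ParameterSet] = []
    cycles: dict = {}
    attempts = 0
    probe_passed = 0
    batches = 0

    def consider(ps: ParameterSet) -> bool:
        nonlocal attempts, probe_passed
        attempts += 1
        packed = model.pack(ps)
        if use_probe:
            rng = np.random.default_rng((ps.seed, ps.id))
            on_cycle = _probe_oscillation(model, packed, cfg, rng=rng)
            if on_cycle is None:
                return False
            probe_passed += 1
            outcome = find_limit_cycle(model, ps, cfg, initial_state=on_cycle)
        else:
            probe_passed += 1
            outcome = find_limit_cycle(model, ps, cfg)
        if not outcome.oscillates:
            return False
        retained.append(ps)
        cycles[(ps.seed, ps.id)] = outcome.cycle
        return True

    pool: Iterable[ParameterSet] = list(candidates)
    for ps in pool:
        if len(retained) >= target_count:
            break
        if attempts >= max_attempts:
            break
        consider(ps)

    seed = batch_seed if batch_seed is not None else (candidates[0].seed + 1 if candidates else 1)
    while len(retained) < target_count and attempts < max_attempts:
        batches += 1
        batch_n = min(
            max(10 * (target_count - len(retained)), 50), max_attempts - attempts
        )
        fresh = sample_parameters(model, batch_n, seed, distribution)
        seed += 1
        for ps in fresh:
            if len(retained) >= target_count or attempts >= max_attempts:
                break
            consider(ps)

    status = "ok" if len(retained) >= target_count else "budget_exhausted"
    return ScreenResult(
        retained=retained,
        cycles=cycles,
        n_attempted=attempts,
        n_probe_passed=probe_passed,
        status=status,
        acceptance_rate=len(retained) / attempts if attempts else 0.0,
        batches=batches,
    )
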