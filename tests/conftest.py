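"""Shared fixtures.

Expensive artifacts (screened oscillatory parameter sets, campaign tables)
are session-scoped and deterministic, so every test sees identical data.
"""

from __future__ import annotations

import numpy as np
import pytest

from oscperturb.dynamics import DynamicsConfig, find_limit_cycle
from oscperturb.models import SIX_TOPOLOGIES, build_model
from oscperturb.perturbation import PerturbationConfig, run_campaign
from oscperturb.sampling import sample_parameters, screen_oscillatory

SCREEN_SEED = 11

# attempt budgets reflect the oscillatory abundance of each design: the
# amplified (class II) topologies are rare under random sampling
_ATTEMPTS = {
    "activator_amplified_nfo": 16_000,
    "inhibitor_amplified_nfo": 16_000,
}


@pytest.fixture(scope="session")
def dynamics_config():
    return DynamicsConfig(seed=SCREEN_SEED)


@pytest.fixture(scope="session")
def perturbation_config(dynamics_config):
    return PerturbationConfig(dynamics=dynamics_config)


@pytest.fixture(scope="session")
def screened_sets(dynamics_config):
    """One small oscillatory ensemble per 3-node topology.

    Returns ``{topology: (model, [ParameterSet], {key: LimitCycle})}``.
    """
    out = {}
    for topo in SIX_TOPOLOGIES:
        model = build_model(topo, 4)
        target = 8
        res = screen_oscillatory(
            model,
            sample_parameters(model, 3000, SCREEN_SEED),
            target_count=target,
            dynamics_config=dynamics_config,
            max_attempts=_ATTEMPTS.get(topo, 6000),
            batch_seed=SCREEN_SEED + 1,
        )
        assert res.retained, f"no oscillatory sets found for {topo}"
        out[topo] = (model, res.retained, res.cycles)
    return out


@pytest.fixture(scope="session")
def campaign_tables(screened_sets, perturbation_config):
    """Desk-scale 1%-weakening campaign table per topology."""
    import pandas as pd

    tables = []
    for topo, (model, sets, cycles) in screened_sets.items():
        tables.append(
            run_campaign(
                model,
                sets,
                cycles,
                factors=[0.99],
                phase_count=6,
                config=perturbation_config,
            )
        )
    return pd.concat(tables, ignore_index=True)


@pytest.fixture(scope="session")
def simple_nfo_case(screened_sets):
    """(model, params, cycle) for one oscillatory simple-NFO set."""
    model, sets, cycles = screened_sets["simple_nfo"]
    ps = sets[0]
    return model, ps, cycles[(ps.seed, ps.id)]


def random_positive_states(rng, n_states, n_dim, low=-2.0, high=2.0):
    return 10.0 ** rng.uniform(low, high, size=(n_states, n_dim))
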