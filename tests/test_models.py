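"""Structure and kinetics of the built-in oscillator models."""

import itertools

import numpy as np
import pytest

from oscperturb.errors import (
    StructuralLinkError,
    UnknownTopologyError,
    ValidationError,
)
from oscperturb.models import (
    SIX_TOPOLOGIES,
    TOPOLOGY_IDS,
    build_model,
    bundled_parameters,
    model_from_spec,
    model_to_spec,
)

RNG = np.random.default_rng(42)


def _random_params(model, rng):
    vals = {}
    for spec in model.parameter_schema:
        vals[spec.name] = (
            spec.default if spec.role == "hill" else float(10.0 ** rng.uniform(-1.5, 1.5))
        )
    return vals


def _fd_jacobian(model, x, params, h_rel=1e-6):
    n = model.n_nodes
    J = np.empty((n, n))
    for j in range(n):
        h = h_rel * max(abs(x[j]), 1e-3)
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        J[:, j] = (model.rhs(xp, params) - model.rhs(xm, params)) / (2 * h)
    return J


# ---------------------------------------------------------------------------
# Topology structure


EXPECTED_LINKS = {
    "simple_nfo": {("Y", "X", 1), ("Z", "Y", 1), ("X", "Z", -1)},
    "incoherent_nfo_type1": {
        ("Y", "X", 1),
        ("Z", "Y", 1),
        ("X", "Z", -1),
        ("X", "Y", 1),
    },
}


@pytest.mark.parametrize("topo,expected", sorted(EXPECTED_LINKS.items()))
def test_topology_link_sets(topo, expected):
    model = build_model(topo, 2)
    got = {(l.target, l.source, l.sign) for l in model.links}
    assert got == expected


def test_every_topology_has_full_degradation_diagonal():
    for topo in TOPOLOGY_IDS:
        model = build_model(topo, 4)
        pat = model.structural_pattern()
        assert {(i, i) for i in range(3)} <= pat


def test_unknown_topology_and_bad_hill_coefficient():
    with pytest.raises(UnknownTopologyError):
        build_model("bogus", 2)
    with pytest.raises(ValidationError):
        build_model("simple_nfo", -1)


def test_link_label_round_trip_is_bijective():
    model = build_model("incoherent_nfo_type2", 4)
    pat = model.structural_pattern()
    seen = set()
    for (i, j) in pat:
        label = model.indices_to_link(i, j)
        assert model.link_to_indices(label) == (i, j)
        seen.add(label)
    assert len(seen) == len(pat)


def _simple_cycles(links):
    """Signed simple cycles of a 3-node link digraph."""
    nodes = sorted({l.target for l in links} | {l.source for l in links})
    sign = {(l.target, l.source): l.sign for l in links}
    cycles = []
    for length in range(1, len(nodes) + 1):
        for perm in itertools.permutations(nodes, length):
            if perm[0] != min(perm):
                continue
            s = 1
            ok = True
            for src, tgt in zip(perm, perm[1:] + (perm[0],)):
                if (tgt, src) not in sign:
                    ok = False
                    break
                s *= sign[(tgt, src)]
            if ok:
                cycles.append((perm, s))
    return cycles


def test_loop_structure_per_class():
    """Simple NFO: single 3-node negative loop; amplified: one 2-node negative
    loop plus one positive loop; incoherent types: 3-node negative loop present."""
    cyc = _simple_cycles(build_model("simple_nfo", 4).links)
    assert [(c, s) for c, s in cyc if len(c) == 2] == []
    assert [(c, s) for c, s in cyc if len(c) == 3 and s < 0]

    for topo in ("activator_amplified_nfo", "inhibitor_amplified_nfo"):
        cyc = _simple_cycles(build_model(topo, 4).links)
        two_node = [(c, s) for c, s in cyc if len(c) == 2]
        neg_two = [c for c, s in two_node if s < 0]
        pos = [c for c, s in cyc if s > 0]
        assert len(neg_two) == 1 and set(neg_two[0]) == {"X", "Y"}
        assert pos, f"{topo} must contain an amplifying positive loop"

    for topo in ("incoherent_nfo_type1", "incoherent_nfo_type2", "incoherent_nfo_type3"):
        cyc = _simple_cycles(build_model(topo, 4).links)
        assert any(len(c) == 3 and s < 0 for c, s in cyc)
        assert len(build_model(topo, 4).links) == 4


# ---------------------------------------------------------------------------
# Kinetics


def test_pure_decay_when_synthesis_rates_vanish():
    model = build_model("simple_nfo", 2)
    params = {p.name: 0.5 for p in model.parameter_schema}
    params["hill_n"] = 2.0
    for name in params:
        if name.startswith("v_"):
            params[name] = 1e-300  # pack() requires positivity; 0 in the limit
    state = np.array([1.0, 2.0, 3.0])
    np.testing.assert_allclose(model.rhs(state, params), -0.5 * state, atol=1e-12)


def test_hill_activation_saturates_to_rate_constant():
    model = build_model("simple_nfo", 2)
    params = _random_params(model, np.random.default_rng(0))
    params["kd_y"] = 1e-300  # isolate Y's synthesis term
    huge = 1e9 * params["K_yx"]
    dy = model.rhs(np.array([huge, 0.0, 0.0]), params)[1]
    assert dy == pytest.approx(params["v_yx"], rel=1e-6)


@pytest.mark.parametrize("topo", TOPOLOGY_IDS)
def test_jacobian_matches_finite_differences(topo):
    model = build_model(topo, 4)
    rng = np.random.default_rng(7)
    for _ in range(20):
        params = _random_params(model, rng)
        x = 10.0 ** rng.uniform(-1.5, 1.5, size=3)
        if model.kinetics == "antagonist_switch":
            x[2] = rng.uniform(0.05, 0.95)
        J = model.jacobian(x, params)
        J_fd = _fd_jacobian(model, x, params)
        scale = np.abs(J).max() + 1e-12
        np.testing.assert_allclose(J, J_fd, atol=1e-5 * scale, rtol=1e-4)


@pytest.mark.parametrize("topo", SIX_TOPOLOGIES)
def test_jacobian_sign_pattern_state_independent(topo):
    """Structural zeros and off-diagonal signs are invariant over positive states."""
    model = build_model(topo, 4)
    rng = np.random.default_rng(3)
    pat = model.structural_pattern()
    link_sign = {
        (model.node_index(l.target), model.node_index(l.source)): l.sign
        for l in model.links
        if l.target != l.source
    }
    for _ in range(100):
        params = _random_params(model, rng)
        x = 10.0 ** rng.uniform(-1.0, 1.0, size=3)
        if model.kinetics == "antagonist_switch":
            x[2] = rng.uniform(0.05, 0.95)
        J = model.jacobian(x, params)
        for i in range(3):
            for j in range(3):
                if (i, j) not in pat:
                    assert J[i, j] == 0.0
                elif i == j:
                    # linear degradation (plus any antagonist flux) on the diagonal
                    assert J[i, i] < 0 or (i, i) in link_sign
        for (i, j), sign in link_sign.items():
            assert np.sign(J[i, j]) == sign


def test_simple_nfo_sign_pattern_matches_link_roles():
    model = build_model("simple_nfo", 4)
    params = bundled_parameters("simple_nfo")
    J = model.jacobian(np.array([1.0, 2.0, 0.5]), params)
    assert J[1, 0] > 0  # Lyx: X activates Y
    assert J[2, 1] > 0  # Lzy: Y activates Z
    assert J[0, 2] < 0  # Lxz: Z inhibits X
    assert all(J[i, i] < 0 for i in range(3))
    assert J[0, 1] == J[1, 2] == J[2, 0] == 0.0


def test_rhs_validation_errors():
    model = build_model("simple_nfo", 4)
    params = bundled_parameters("simple_nfo")
    with pytest.raises(ValidationError):
        model.rhs(np.array([1.0, -0.5, 1.0]), params)  # negative state
    bad = dict(params)
    del bad["v_x"]
    with pytest.raises(ValidationError):
        model.rhs(np.ones(3), bad)  # missing parameter
    bad = dict(params, v_x=np.nan)
    with pytest.raises(ValidationError):
        model.rhs(np.ones(3), bad)  # NaN parameter


def test_require_structural_rejects_absent_link():
    model = build_model("simple_nfo", 4)
    with pytest.raises(StructuralLinkError):
        model.require_structural("Lxy")  # not a link of the simple NFO
    assert model.require_structural("Lyx") == (1, 0)


def test_declarative_round_trip_preserves_dynamics(tmp_path):
    from oscperturb.models import load_model, save_model

    model = build_model("incoherent_nfo_type3", 4)
    path = tmp_path / "model.yaml"
    save_model(model, path)
    clone = load_model(path)
    assert model_to_spec(clone) == model_to_spec(model)
    params = {p.name: (0.7 if p.role != "hill" else p.default)
              for p in model.parameter_schema}
    x = np.array([0.3, 1.2, 0.8])
    np.testing.assert_allclose(clone.rhs(x, params), model.rhs(x, params))
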