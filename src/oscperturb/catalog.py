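"""A small catalog of canonical published biochemical oscillators.

Four classic models spanning the three structural classes:

* ``repressilator`` — the three-gene synthetic ring oscillator (mRNA +
  protein per gene; a pure delayed negative feedback ring, class I);
* ``hodgkin_huxley`` — the squid-axon action-potential model under
  sustained current injection (fast sodium activation provides the
  amplifying positive feedback, class II);
* ``selkov_glycolysis`` — the two-variable glycolytic oscillator
  (autocatalytic product activation, an incoherent/amplified design,
  class III);
* ``goldbeter_circadian`` — the five-variable PER protein circadian
  model (delayed negative feedback through nuclear transport, class I).

Each model ships a default parameter set in its published oscillatory
regime.  Jacobians are analytic where compact (Sel'kov, repressilator)
and central finite differences otherwise.
"""

from __future__ import annotations

import numpy as np

from .errors import UnknownModelError
from .models import Link, OscillatorModel, ParameterSpec

__all__ = ["catalog_model", "CATALOG_IDS"]


def _fd_jacobian(rhs_fn, n):
    """Central-difference Jacobian closure for an n-state rhs."""

    def jac(x, p):
        J = np.empty((n, n))
        f_scale = np.maximum(np.abs(x), 1.0)
        for j in range(n):
            h = 1e-6 * f_scale[j]
            xp = x.copy()
            xm = x.copy()
            xp[j] += h
            xm[j] -= h
            J[:, j] = (rhs_fn(xp, p) - rhs_fn(xm, p)) / (2.0 * h)
        return J

    return jac


# ---------------------------------------------------------------------------
# Sel'kov glycolysis (1968, two-variable reduction)


def _selkov() -> OscillatorModel:
    # dX/dt = -X + a*Y + X^2 Y ; dY/dt = b - a*Y - X^2 Y
    # X ~ ADP (product, autocatalytic), Y ~ F6P (substrate)
    schema = (
        ParameterSpec("a", "rate", 0.08),
        ParameterSpec("b", "rate", 0.6),
    )

    def rhs(x, p):
        X, Y = x
        flux = p[0] * Y + X * X * Y
        return np.array([-X + flux, p[1] - flux])

    def jac(x, p):
        X, Y = x
        return np.array(
            [[-1.0 + 2.0 * X * Y, p[0] + X * X], [-2.0 * X * Y, -(p[0] + X * X)]]
        )

    return OscillatorModel(
        name="selkov_glycolysis",
        nodes=("X", "Y"),
        links=(Link("X", "Y", +1), Link("Y", "X", -1)),
        parameter_schema=schema,
        rhs_fn=rhs,
        jac_fn=jac,
        reporter="X",
        kinetics="catalog",
        metadata={"timescale": 1.0, "default_initial": (1.0, 2.0)},
    )


# ---------------------------------------------------------------------------
# Repressilator (Elowitz & Leibler 2000, dimensionless form)


def _repressilator() -> OscillatorModel:
    # dm_i/dt = -m_i + alpha/(1 + p_prev^n) + alpha0 ; dp_i/dt = -beta (p_i - m_i)
    schema = (
        ParameterSpec("alpha", "rate", 216.0),
        ParameterSpec("alpha0", "rate", 0.216),
        ParameterSpec("beta", "rate", 0.2),
        ParameterSpec("hill_n", "hill", 2.0),
    )
    nodes = ("M1", "P1", "M2", "P2", "M3", "P3")
    # gene i's mRNA is repressed by the previous gene's protein
    links = (
        Link("M1", "P3", -1),
        Link("M2", "P1", -1),
        Link("M3", "P2", -1),
        Link("P1", "M1", +1),
        Link("P2", "M2", +1),
        Link("P3", "M3", +1),
    )

    def rhs(x, p):
        a, a0, b, n = p
        m = x[0::2]
        pr = x[1::2]
        rep = pr[[2, 0, 1]] ** n  # p3, p1, p2 repress m1, m2, m3
        dm = -m + a / (1.0 + rep) + a0
        dp = -b * (pr - m)
        out = np.empty(6)
        out[0::2] = dm
        out[1::2] = dp
        return out

    def jac(x, p):
        a, a0, b, n = p
        J = np.zeros((6, 6))
        pr = x[1::2]
        rep_src = [5, 1, 3]  # state index of the repressing protein per mRNA
        for g in range(3):
            mi = 2 * g
            pi = 2 * g + 1
            ps = rep_src[g]
            y = x[ps]
            J[mi, mi] = -1.0
            J[mi, ps] = -a * n * y ** (n - 1.0) / (1.0 + y ** n) ** 2
            J[pi, pi] = -b
            J[pi, mi] = b
        return J

    return OscillatorModel(
        name="repressilator",
        nodes=nodes,
        links=links,
        parameter_schema=schema,
        rhs_fn=rhs,
        jac_fn=jac,
        hill_coefficient=2.0,
        reporter="P1",
        kinetics="catalog",
        metadata={
            "timescale": 5.0,
            "default_initial": (1.0, 2.0, 3.0, 1.0, 2.0, 3.0),
        },
    )


# ---------------------------------------------------------------------------
# Hodgkin-Huxley (1952) under sustained current injection


def _hh_rates(V):
    an = 0.01 * (V + 55.0) / (1.0 - np.exp(-(V + 55.0) / 10.0))
    bn = 0.125 * np.exp(-(V + 65.0) / 80.0)
    am = 0.1 * (V + 40.0) / (1.0 - np.exp(-(V + 40.0) / 10.0))
    bm = 4.0 * np.exp(-(V + 65.0) / 18.0)
    ah = 0.07 * np.exp(-(V + 65.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(V + 35.0) / 10.0))
    return an, bn, am, bm, ah, bh


def _hodgkin_huxley() -> OscillatorModel:
    schema = (
        ParameterSpec("I_app", "rate", 10.0),
        ParameterSpec("g_Na", "rate", 120.0),
        ParameterSpec("g_K", "rate", 36.0),
        ParameterSpec("g_L", "rate", 0.3),
        ParameterSpec("C_m", "rate", 1.0),
    )
    nodes = ("V", "MGATE", "HGATE", "NGATE")
    links = (
        Link("V", "MGATE", +1),
        Link("V", "HGATE", +1),
        Link("V", "NGATE", -1),
        Link("MGATE", "V", +1),
        Link("HGATE", "V", -1),
        Link("NGATE", "V", +1),
    )
    E_Na, E_K, E_L = 50.0, -77.0, -54.4

    def rhs(x, p):
        V, m, h, n = x
        I, gNa, gK, gL, C = p
        an, bn, am, bm, ah, bh = _hh_rates(V)
        INa = gNa * m ** 3 * h * (V - E_Na)
        IK = gK * n ** 4 * (V - E_K)
        IL = gL * (V - E_L)
        return np.array(
            [
                (I - INa - IK - IL) / C,
                am * (1.0 - m) - bm * m,
                ah * (1.0 - h) - bh * h,
                an * (1.0 - n) - bn * n,
            ]
        )

    jac = _fd_jacobian(rhs, 4)

    return OscillatorModel(
        name="hodgkin_huxley",
        nodes=nodes,
        links=links,
        parameter_schema=schema,
        rhs_fn=rhs,
        jac_fn=jac,
        reporter="V",
        kinetics="catalog",
        metadata={
            "timescale": 2.0,
            "default_initial": (-65.0, 0.05, 0.6, 0.32),
            "state_min": (-150.0, 0.0, 0.0, 0.0),
            "state_max": (80.0, 1.0, 1.0, 1.0),
        },
    )


# ---------------------------------------------------------------------------
# Goldbeter circadian PER model (1995, five variables)


def _goldbeter_circadian() -> OscillatorModel:
    schema = (
        ParameterSpec("vs", "rate", 0.76),
        ParameterSpec("vm", "rate", 0.65),
        ParameterSpec("Km", "michaelis", 0.5),
        ParameterSpec("ks", "rate", 0.38),
        ParameterSpec("vd", "rate", 0.95),
        ParameterSpec("Kd", "michaelis", 0.2),
        ParameterSpec("k1", "rate", 1.9),
        ParameterSpec("k2", "rate", 1.3),
        ParameterSpec("KI", "michaelis", 1.0),
        ParameterSpec("V1", "rate", 3.2),
        ParameterSpec("K1", "michaelis", 2.0),
        ParameterSpec("V2", "rate", 1.58),
        ParameterSpec("K2", "michaelis", 2.0),
        ParameterSpec("V3", "rate", 5.0),
        ParameterSpec("K3", "michaelis", 2.0),
        ParameterSpec("V4", "rate", 2.5),
        ParameterSpec("K4", "michaelis", 2.0),
        ParameterSpec("hill_n", "hill", 4.0),
    )
    nodes = ("M", "P0", "P1", "P2", "PN")
    links = (
        Link("M", "PN", -1),
        Link("P0", "M", +1),
        Link("P1", "P0", +1),
        Link("P0", "P1", +1),
        Link("P2", "P1", +1),
        Link("P1", "P2", +1),
        Link("PN", "P2", +1),
        Link("P2", "PN", +1),
    )

    def rhs(x, p):
        M, P0, P1, P2, PN = x
        (vs, vm, Km, ks, vd, Kd, k1, k2, KI, V1, K1, V2, K2, V3, K3, V4, K4, n) = p
        kin = KI ** n / (KI ** n + PN ** n)
        f01 = V1 * P0 / (K1 + P0)
        f10 = V2 * P1 / (K2 + P1)
        f12 = V3 * P1 / (K3 + P1)
        f21 = V4 * P2 / (K4 + P2)
        return np.array(
            [
                vs * kin - vm * M / (Km + M),
                ks * M - f01 + f10,
                f01 - f10 - f12 + f21,
                f12 - f21 - k1 * P2 + k2 * PN - vd * P2 / (Kd + P2),
                k1 * P2 - k2 * PN,
            ]
        )

    jac = _fd_jacobian(rhs, 5)

    return OscillatorModel(
        name="goldbeter_circadian",
        nodes=nodes,
        links=links,
        parameter_schema=schema,
        rhs_fn=rhs,
        jac_fn=jac,
        hill_coefficient=4.0,
        reporter="M",
        kinetics="catalog",
        metadata={"timescale": 5.0, "default_initial": (0.5, 0.5, 0.5, 0.5, 0.5)},
    )


_CATALOG = {
    "repressilator": _repressilator,
    "hodgkin_huxley": _hodgkin_huxley,
    "selkov_glycolysis": _selkov,
    "goldbeter_circadian": _goldbeter_circadian,
}

CATALOG_IDS = tuple(_CATALOG)


def catalog_model(model_id: str) -> OscillatorModel:
    """Instantiate a canonical published oscillator with bundled defaults."""
    try:
        factory = _CATALOG[model_id]
    except KeyError:
        raise UnknownModelError(
            f"unknown catalog model {model_id!r}; known: {sorted(_CATALOG)}"
        )
    return factory()
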