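"""State vector, ionic currents, membrane right-hand side, and the
resting equilibrium of the pharyngeal muscle model.

The functions here are the readable reference implementation of the
model's equations; numerical integration goes through the compiled kernel
in :mod:`pharynxsim._kernels`, which is tested against this module.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
from scipy.integrate import odeint
from scipy.optimize import brentq

from . import _kernels, gating
from .parameters import ModelParameters

__all__ = ["StateVector", "channel_current", "membrane_rhs", "resting_state",
           "steady_state_current", "CHANNEL_IDS"]

CHANNEL_IDS = ("leak", "K", "CaT", "CaL", "synE", "synI")


@dataclass(frozen=True)
class StateVector:
    """Full model state at one instant.

    Gating variables are dimensionless in [0, 1]; ``gE``/``gI`` are the
    instantaneous synaptic conductances in nS.  In the ultrafast variant
    ``h`` is implicit (the K current uses ``h_inf(V)``) and the stored
    value is ignored by the dynamics.
    """

    t: float = 0.0
    V: float = -65.0
    w: float = 0.0
    h: float = 1.0
    mT: float = 0.0
    hT: float = 1.0
    mL: float = 0.0
    hL: float = 1.0
    gE: float = 0.0
    gI: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.V, self.w, self.h, self.mT, self.hT,
                         self.mL, self.hL, self.gE, self.gI], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray, t: float = 0.0) -> "StateVector":
        return cls(t=t, V=y[0], w=y[1], h=y[2], mT=y[3], hT=y[4],
                   mL=y[5], hL=y[6], gE=y[7], gI=y[8])

    def replace(self, **changes) -> "StateVector":
        return _dc_replace(self, **changes)


def _hK_effective(state: StateVector, params: ModelParameters) -> float:
    if params.is_instantaneous:
        return float(gating.steady_state("hK", state.V, params))
    return state.h


def channel_current(channel_id: str, state: StateVector,
                    params: ModelParameters) -> float:
    """Signed contribution of one channel to C dV/dt, in pA.

    Positive values are depolarizing; each term has the form
    ``-g * (gating product) * (V - Vrev)``.
    """
    V = state.V
    if channel_id == "leak":
        return -params.gL * (V - params.VL)
    if channel_id == "K":
        return -params.gK * state.w * _hK_effective(state, params) * (V - params.VK)
    if channel_id == "CaT":
        return -params.gCaT * state.mT ** 2 * state.hT * (V - params.VCa)
    if channel_id == "CaL":
        return -params.gCaL * state.mL ** 2 * state.hL * (V - params.VCa)
    if channel_id == "synE":
        return -state.gE * (V - params.VsynE)
    if channel_id == "synI":
        return -state.gI * (V - params.VsynI)
    raise ValueError(f"unknown channel {channel_id!r}; valid ids: {CHANNEL_IDS}")


def membrane_rhs(t: float, state: StateVector,
                 params: ModelParameters) -> StateVector:
    """Time derivative of the state, returned as a StateVector of rates.

    Discrete synaptic events are *not* part of the vector field; they are
    applied between integration segments (see :mod:`pharynxsim.integrator`).
    """
    y = state.as_array()
    if not np.all(np.isfinite(y)):
        raise ValueError(f"non-finite state at t={t}: {state}")
    V = state.V
    total = sum(channel_current(cid, state, params) for cid in CHANNEL_IDS)
    dV = total / params.C
    dw = params.w_rate * (gating.steady_state("w", V) - state.w) \
        / gating.time_constant("w", V)
    if params.is_instantaneous:
        dh = 0.0
    else:
        dh = (gating.steady_state("hK", V, params) - state.h) / params.tau_h
    dmT = (gating.steady_state("mT", V) - state.mT) / gating.time_constant("mT", V)
    dhT = (gating.steady_state("hT", V) - state.hT) / gating.time_constant("hT", V)
    dmL = (gating.steady_state("mL", V) - state.mL) / gating.time_constant("mL", V)
    dhL = (gating.steady_state("hL", V) - state.hL) / gating.time_constant("hL", V)
    return StateVector(t=1.0, V=dV, w=dw, h=dh, mT=dmT, hT=dhT, mL=dmL,
                       hL=dhL, gE=-state.gE / params.tauE,
                       gI=-state.gI / params.tauI)


def gating_equilibrium(V: float, params: ModelParameters,
                       t: float = 0.0) -> StateVector:
    """State with every gating variable at its steady state for ``V``
    and zero synaptic conductance."""
    return StateVector(
        t=t, V=V,
        w=float(gating.steady_state("w", V)),
        h=float(gating.steady_state("hK", V, params)),
        mT=float(gating.steady_state("mT", V)),
        hT=float(gating.steady_state("hT", V)),
        mL=float(gating.steady_state("mL", V)),
        hL=float(gating.steady_state("hL", V)),
        gE=0.0, gI=0.0,
    )


def steady_state_current(V: float, params: ModelParameters) -> float:
    """Total ionic current (pA) with all gates at steady state and no
    synaptic drive; roots of this function are the model's equilibria."""
    st = gating_equilibrium(V, params)
    return sum(channel_current(cid, st, params) for cid in CHANNEL_IDS)


def resting_state(params: ModelParameters, *, v_lo: float = -80.0,
                  v_hi: float = 0.0, relax_ms: float = 500.0) -> StateVector:
    """Stable resting equilibrium with gE = gI = 0.

    Scans the steady-state current on [v_lo, v_hi] for sign changes,
    root-finds each bracket, keeps the most hyperpolarized stable root
    (negative current slope), and polishes it with a short relaxation
    integration.  Raises if no stable equilibrium exists in the window,
    which signals pathological parameters.
    """
    vs = np.linspace(v_lo, v_hi, 641)
    fs = np.array([steady_state_current(v, params) for v in vs])
    roots = []
    for i in range(len(vs) - 1):
        if fs[i] == 0.0:
            roots.append(vs[i])
        elif fs[i] * fs[i + 1] < 0:
            roots.append(brentq(steady_state_current, vs[i], vs[i + 1],
                                args=(params,), xtol=1e-10))
    stable = [r for r in roots
              if steady_state_current(r + 1e-3, params)
              - steady_state_current(r - 1e-3, params) < 0]
    if not stable:
        raise ValueError(
            f"no stable equilibrium found in [{v_lo}, {v_hi}] mV; "
            "parameters appear pathological"
        )
    v0 = min(stable)
    # polish by relaxation so slow gates settle on the true fixed point
    y0 = gating_equilibrium(v0, params).as_array()
    p = params.as_array()
    ys = odeint(_kernels.rhs, y0, [0.0, relax_ms], args=(p,),
                rtol=1e-9, atol=1e-12)
    yf = ys[-1]
    if abs(yf[0] - v0) > 1.0:
        raise ValueError(
            f"equilibrium at {v0:.2f} mV did not hold under relaxation "
            f"(drifted to {yf[0]:.2f} mV)"
        )
    return StateVector.from_array(yf, t=0.0)
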