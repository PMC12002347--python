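"""Steady-state activation/inactivation curves and voltage-dependent
time constants of the model's gated currents.

These are the reference (vectorized numpy) implementations; the compiled
integration kernel in :mod:`pharynxsim._kernels` repeats the same algebra in
scalar form and is tested against this module.

Curve identifiers:

``w``
    activation of the EXP-2-like K current (tanh sigmoid, midpoint +12 mV).
``hK``
    inactivation of the K current; midpoint is the model's half-inactivation
    voltage ``Vhalf_inact`` with slope factor ``k_inact`` (steady state
    only -- its time constant is the constant ``tau_h`` parameter).
``mT``/``hT``
    activation/inactivation of the T-type (CCA-1-like) Ca current.
``mL``/``hL``
    activation/inactivation of the L-type (EGL-19-like) Ca current.  hL
    inactivates only partially (floor ~0.85 at plateau voltages) and slowly
    (200-300 ms), giving the slow relaxation of the plateau from its
    initial peak.
"""

from __future__ import annotations

import numpy as np

from .parameters import ModelParameters

__all__ = ["steady_state", "time_constant", "STEADY_STATE_IDS",
           "TIME_CONSTANT_IDS"]


def _w_inf(V):
    return 0.5 * (1.0 + np.tanh((V - 12.0) / 17.4))


def _tau_w(V):
    return 1.0 / np.cosh((V - 12.0) / 34.8)


def _h_inf(V, vhalf, k):
    return 0.5 * (1.0 - np.tanh((V - vhalf) / k))


def _mT_inf(V):
    return 0.5 * (1.0 + np.tanh((V + 45.0) / 6.0))


def _tau_mT(V):
    return 1.0 / (0.5 * np.cosh((V - 14.5) / 34.8))


def _hT_inf(V):
    return 0.5 * (1.0 - np.tanh((V + 40.0) / 3.0))


def _tau_hT(V):
    return 65.0 / (1.0 + np.exp((V + 40.0) / 7.0))


def _mL_inf(V):
    return 1.0 / (1.0 + np.exp(-(V + 20.0) / 6.5))


def _tau_mL(V):
    return 1.0 / (1.0 + np.exp((V + 27.0) / 10.0))


def _hL_inf(V):
    return 1.0 / (1.0 + np.exp((V - 135.0) / 55.0))


def _tau_hL(V):
    return 200.0 + 100.0 / (1.0 + np.exp((V + 40.0) / 7.0))


STEADY_STATE_IDS = ("w", "hK", "mT", "hT", "mL", "hL")
TIME_CONSTANT_IDS = ("w", "mT", "hT", "mL", "hL")


def steady_state(curve_id: str, V, params: ModelParameters | None = None):
    """Steady-state value of the named gating variable at potential ``V``.

    ``params`` is only required for ``hK`` (whose midpoint and slope are
    model parameters); it is accepted and ignored for the fixed curves.
    Values lie in [0, 1]; activation curves (w, mT, mL) are nondecreasing
    in V and inactivation curves (hK, hT, hL) nonincreasing.
    """
    V = np.asarray(V, dtype=float)
    if curve_id == "w":
        return _w_inf(V)
    if curve_id == "hK":
        p = params if params is not None else ModelParameters()
        return _h_inf(V, p.Vhalf_inact, p.k_inact)
    if curve_id == "mT":
        return _mT_inf(V)
    if curve_id == "hT":
        return _hT_inf(V)
    if curve_id == "mL":
        return _mL_inf(V)
    if curve_id == "hL":
        return _hL_inf(V)
    raise ValueError(
        f"unknown gating curve {curve_id!r}; valid ids: {STEADY_STATE_IDS}"
    )


def time_constant(curve_id: str, V, params: ModelParameters | None = None):
    """Voltage-dependent time constant (ms) of the named gating variable.

    Note the K-current activation ``w`` additionally carries the
    dimensionless rate multiplier ``w_rate`` in its kinetics,
    ``dw/dt = w_rate * (w_inf - w) / tau_w``; the value returned here is
    the bare ``tau_w``.
    """
    V = np.asarray(V, dtype=float)
    if curve_id == "w":
        return _tau_w(V)
    if curve_id == "mT":
        return _tau_mT(V)
    if curve_id == "hT":
        return _tau_hT(V)
    if curve_id == "mL":
        return _tau_mL(V)
    if curve_id == "hL":
        return _tau_hL(V)
    raise ValueError(
        f"unknown time-constant curve {curve_id!r}; "
        f"valid ids: {TIME_CONSTANT_IDS}"
    )
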