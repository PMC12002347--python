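"""Compiled right-hand side of the model ODE system.

State layout (9 components, used everywhere a flat state array appears):

    y = [V, w, h, mT, hT, mL, hL, gE, gI]

In the ultrafast variant (``tau_h`` encoded as a nonpositive number) the
``h`` slot is inert (dh/dt = 0) and the K current uses ``h_inf(V)``
pointwise.

Parameter array layout (see ``ModelParameters.as_array``):

    p = [C, gL, gK, gCaT, gCaL, VL, VK, VCa, VsynE, VsynI,
         Vhalf, k_inact, w_rate, tauE, tauI, tau_h]
"""

import math

import numpy as np
from numba import njit

# state indices
IV, IW, IH, IMT, IHT, IML, IHL, IGE, IGI = range(9)
NSTATE = 9


@njit(cache=False)
def rhs(y, t, p):
    """ODE right-hand side in the (y, t) argument order used by odeint."""
    V = y[0]
    w = y[1]
    h = y[2]
    mT = y[3]
    hT = y[4]
    mL = y[5]
    hL = y[6]
    gE = y[7]
    gI = y[8]

    C = p[0]
    gL = p[1]
    gK = p[2]
    gCaT = p[3]
    gCaL = p[4]
    VL = p[5]
    VK = p[6]
    VCa = p[7]
    VsynE = p[8]
    VsynI = p[9]
    vhalf = p[10]
    k_inact = p[11]
    w_rate = p[12]
    tauE = p[13]
    tauI = p[14]
    tau_h = p[15]

    w_inf = 0.5 * (1.0 + math.tanh((V - 12.0) / 17.4))
    tau_w = 1.0 / math.cosh((V - 12.0) / 34.8)
    h_inf = 0.5 * (1.0 - math.tanh((V - vhalf) / k_inact))
    mT_inf = 0.5 * (1.0 + math.tanh((V + 45.0) / 6.0))
    tau_mT = 1.0 / (0.5 * math.cosh((V - 14.5) / 34.8))
    hT_inf = 0.5 * (1.0 - math.tanh((V + 40.0) / 3.0))
    tau_hT = 65.0 / (1.0 + math.exp((V + 40.0) / 7.0))
    mL_inf = 1.0 / (1.0 + math.exp(-(V + 20.0) / 6.5))
    tau_mL = 1.0 / (1.0 + math.exp((V + 27.0) / 10.0))
    hL_inf = 1.0 / (1.0 + math.exp((V - 135.0) / 55.0))
    tau_hL = 200.0 + 100.0 / (1.0 + math.exp((V + 40.0) / 7.0))

    hK = h_inf if tau_h <= 0.0 else h

    current = (
        -gL * (V - VL)
        - gCaT * mT * mT * hT * (V - VCa)
        - gK * w * hK * (V - VK)
        - gCaL * mL * mL * hL * (V - VCa)
        - gE * (V - VsynE)
        - gI * (V - VsynI)
    )

    dy = np.empty(9)
    dy[0] = current / C
    dy[1] = w_rate * (w_inf - w) / tau_w
    dy[2] = 0.0 if tau_h <= 0.0 else (h_inf - h) / tau_h
    dy[3] = (mT_inf - mT) / tau_mT
    dy[4] = (hT_inf - hT) / tau_hT
    dy[5] = (mL_inf - mL) / tau_mL
    dy[6] = (hL_inf - hL) / tau_hL
    dy[7] = -gE / tauE
    dy[8] = -gI / tauI
    return dy
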