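"""Model parameters for the pharyngeal-muscle plateau model.

Units convention used throughout the package: voltages in mV, time in ms,
conductances in nS, capacitance in pF.  With these units currents come out
in pA and ``dV/dt = I/C`` is mV/ms with no conversion factors.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Union

import numpy as np
import yaml

#: Sentinel for the ultrafast model variant, in which the K-current
#: inactivation gate tracks its voltage-dependent steady state pointwise.
INSTANTANEOUS = "instantaneous"

TauH = Union[float, str]


@dataclass(frozen=True)
class ModelParameters:
    """All constants of the pharyngeal corpus muscle model.

    The default values are the reference parameter set of the model: a
    single electrically uniform muscle compartment with a leak current, a
    T-type (CCA-1-like) and an L-type (EGL-19-like) calcium current, an
    EXP-2-like potassium current with activation gate ``w`` and a very fast
    inactivation gate ``h``, and exponentially decaying excitatory and
    inhibitory synaptic conductances driven by discrete events.

    ``tau_h`` selects the model variant: the string ``"instantaneous"``
    makes the inactivation gate follow ``h_inf(V)`` pointwise (the
    ultrafast variant); a positive float gives first-order kinetics with
    that time constant in ms.
    """

    C: float = 2.0               # membrane capacitance, pF
    gL: float = 2.0              # leak conductance, nS
    gK: float = 9.0              # maximal EXP-2-like K conductance, nS
    gCaT: float = 3.0            # maximal T-type Ca conductance, nS
    gCaL: float = 3.7            # maximal L-type Ca conductance, nS
    gsynE_max: float = 3.0       # conductance assigned at each EPSP, nS
    gsynI_max: float = 2.5       # conductance assigned at each IPSP, nS
    VL: float = -65.0            # leak reversal, mV
    VK: float = -70.0            # K reversal, mV
    VCa: float = 100.0           # Ca reversal, mV
    VsynE: float = 0.0           # excitatory synaptic reversal, mV
    VsynI: float = -65.0         # inhibitory synaptic reversal, mV
    Vhalf_inact: float = 15.0    # half-inactivation voltage of IK, mV
    k_inact: float = 7.0         # inactivation slope factor, mV
    w_rate: float = 0.04         # dimensionless rate multiplier on w kinetics
    tauE: float = 1.0            # excitatory synaptic decay, ms
    tauI: float = 2.0            # inhibitory synaptic decay, ms
    tau_h: TauH = INSTANTANEOUS  # K inactivation time constant, ms, or sentinel
    noise_quantum: float = 0.15  # conductance per noise channel opening, nS

    def __post_init__(self) -> None:
        for name in ("gL", "gK", "gCaT", "gCaL", "gsynE_max", "gsynI_max",
                     "noise_quantum"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("C", "tauE", "tauI", "k_inact", "w_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not self.is_instantaneous:
            if not isinstance(self.tau_h, (int, float)) or self.tau_h <= 0:
                raise ValueError(
                    f"tau_h must be a positive time constant in ms or "
                    f"{INSTANTANEOUS!r}, got {self.tau_h!r}"
                )

    @property
    def is_instantaneous(self) -> bool:
        return self.tau_h == INSTANTANEOUS

    def replace(self, **changes) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    # -- kernel packing -------------------------------------------------

    def as_array(self) -> np.ndarray:
        """Pack into the flat float array consumed by the compiled RHS.

        ``tau_h`` is encoded as ``-1.0`` for the instantaneous variant.
        """
        tau_h = -1.0 if self.is_instantaneous else float(self.tau_h)
        return np.array(
            [self.C, self.gL, self.gK, self.gCaT, self.gCaL,
             self.VL, self.VK, self.VCa, self.VsynE, self.VsynI,
             self.Vhalf_inact, self.k_inact, self.w_rate,
             self.tauE, self.tauI, tau_h],
            dtype=np.float64,
        )

    # -- plain-text round trip ------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(
                f"unknown parameter key(s): {sorted(unknown)}; "
                f"valid keys are {sorted(known)}"
            )
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelParameters":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)
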