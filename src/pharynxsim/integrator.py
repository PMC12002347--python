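"""Event-aware numerical integration of the model.

The vector field is smooth between synaptic events; every event is a known
discontinuity of gE/gI.  Integration therefore restarts at each event time
(exact treatment of the jump) using LSODA, an adaptive solver that switches
between nonstiff and stiff methods -- the L-type activation gate has a
sub-microsecond time constant at plateau voltages, so stiffness handling is
not optional.  Output is sampled on a uniform grid by the solver's own
dense interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import odeint

from . import _kernels
from .model import StateVector, resting_state
from .parameters import ModelParameters
from .stimulus import EventSchedule, NoiseConfig, SynapticEvent, \
    apply_event_array, build_feeding_schedule, merge_schedules, \
    sample_noise_train

__all__ = ["SimulationTrace", "IntegrationError", "simulate",
           "simulate_chunked", "simulate_reference_protocol"]

_EPS = 1e-9

_COLUMNS = ("V_mV", "w", "h", "mT", "hT", "mL", "hL", "gE_nS", "gI_nS")


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails or the state leaves finite range."""


@dataclass(frozen=True)
class SimulationTrace:
    """Regularly sampled state time series.

    ``data`` has one row per time point with the kernel state layout
    [V, w, h, mT, hT, mL, hL, gE, gI].  Samples taken exactly at an event
    time are left limits (pre-event values).
    """

    times: np.ndarray
    data: np.ndarray
    params: ModelParameters
    schedule_digest: str

    @property
    def V(self) -> np.ndarray:
        return self.data[:, _kernels.IV]

    @property
    def dt_out(self) -> float:
        return float(self.times[1] - self.times[0])

    def column(self, name: str) -> np.ndarray:
        return self.data[:, _COLUMNS.index(name)]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data, columns=list(_COLUMNS))
        df.insert(0, "t_ms", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def concatenate(cls, traces: Sequence["SimulationTrace"]) -> "SimulationTrace":
        return cls(
            times=np.concatenate([tr.times for tr in traces]),
            data=np.concatenate([tr.data for tr in traces]),
            params=traces[0].params,
            schedule_digest=traces[0].schedule_digest,
        )


def _group_events(events) -> list:
    """Group already-sorted events into (t, [events]) clusters."""
    groups = []
    for ev in events:
        if groups and abs(groups[-1][0] - ev.t) <= _EPS:
            groups[-1][1].append(ev)
        else:
            groups.append((ev.t, [ev]))
    return groups


def _integrate_piecewise(p, y, groups, t0, t1, grid, out, filled,
                         rtol, atol):
    """Integrate from t0 to t1 applying grouped events, filling ``out``
    rows for grid points in (t0, t1].  Returns the final state."""
    t = t0
    boundaries = [g for g in groups] + [(t1, [])]
    for te, evs in boundaries:
        te = min(te, t1)
        if te > t + _EPS:
            i0 = int(np.searchsorted(grid, t + _EPS))
            i1 = int(np.searchsorted(grid, te - _EPS))
            ts = np.concatenate(([t], grid[i0:i1], [te]))
            with warnings.catch_warnings():
                warnings.simplefilter("error")
                try:
                    ys, info = odeint(_kernels.rhs, y, ts, args=(p,),
                                      rtol=rtol, atol=atol,
                                      mxstep=1_000_000, full_output=True)
                except Warning as exc:
                    raise IntegrationError(
                        f"solver failure in segment [{t:.6g}, {te:.6g}] ms: {exc}"
                    ) from exc
            if info["message"] != "Integration successful.":
                raise IntegrationError(
                    f"solver failure near t={t:.6g} ms: {info['message']}"
                )
            if not np.all(np.isfinite(ys[-1])):
                raise IntegrationError(f"non-finite state at t={te:.6g} ms")
            out[i0:i1] = ys[1:-1]
            filled[i0:i1] = True
            if i1 < len(grid) and abs(grid[i1] - te) <= _EPS:
                out[i1] = ys[-1]
                filled[i1] = True
            y = ys[-1].copy()
            t = te
        for ev in evs:
            apply_event_array(y, ev)
    return y


def simulate(params: ModelParameters, schedule: EventSchedule,
             t_total: float | None = None, dt_out: float = 0.5,
             rtol: float = 1e-6, atol: float = 1e-9,
             y0: StateVector | None = None) -> SimulationTrace:
    """Integrate the model under an event schedule.

    Returns the state sampled on the uniform grid ``0, dt_out, 2*dt_out,
    ...`` up to ``t_total`` (taken from the schedule when omitted).
    Identical inputs and tolerances give identical output.
    """
    if t_total is None:
        t_total = schedule.t_total
    if t_total <= 0:
        raise ValueError("t_total must be > 0")
    state0 = y0 if y0 is not None else resting_state(params)
    y = state0.as_array().copy()
    p = params.as_array()

    n_grid = int(np.floor(t_total / dt_out + _EPS)) + 1
    grid = np.arange(n_grid) * dt_out
    out = np.empty((n_grid, _kernels.NSTATE))
    filled = np.zeros(n_grid, dtype=bool)

    groups = _group_events(ev for ev in schedule.events if ev.t < t_total)
    # events at exactly t=0 apply before integration starts
    if groups and groups[0][0] <= _EPS:
        for ev in groups[0][1]:
            apply_event_array(y, ev)
        groups = groups[1:]
    out[0] = y
    filled[0] = True
    _integrate_piecewise(p, y, groups, 0.0, float(grid[-1]), grid, out,
                         filled, rtol, atol)
    assert filled.all()
    return _finalize_trace(grid, out, params, schedule.digest())


def _finalize_trace(times, data, params, digest) -> SimulationTrace:
    if params.is_instantaneous:
        # report the implicit inactivation gate as h_inf(V)
        V = data[:, _kernels.IV]
        data = data.copy()
        data[:, _kernels.IH] = 0.5 * (
            1.0 - np.tanh((V - params.Vhalf_inact) / params.k_inact))
    return SimulationTrace(times=times, data=data, params=params,
                           schedule_digest=digest)


def simulate_chunked(params: ModelParameters, schedule: EventSchedule,
                     chunk_ms: float = 50_000.0, dt_out: float = 0.5,
                     rtol: float = 1e-6, atol: float = 1e-9,
                     y0: StateVector | None = None,
                     ) -> Iterator[SimulationTrace]:
    """Yield the trace of :func:`simulate` in consecutive chunks.

    Results are identical to a single call (tested); memory stays bounded
    for very long runs.  ``chunk_ms`` must be a multiple of ``dt_out``.
    """
    t_total = schedule.t_total
    if abs(chunk_ms / dt_out - round(chunk_ms / dt_out)) > 1e-9:
        raise ValueError("chunk_ms must be a multiple of dt_out")
    state0 = y0 if y0 is not None else resting_state(params)
    y = state0.as_array().copy()
    p = params.as_array()
    digest = schedule.digest()

    n_grid = int(np.floor(t_total / dt_out + _EPS)) + 1
    t_end_grid = (n_grid - 1) * dt_out
    all_groups = _group_events(ev for ev in schedule.events if ev.t < t_total)
    if all_groups and all_groups[0][0] <= _EPS:
        for ev in all_groups[0][1]:
            apply_event_array(y, ev)
        all_groups = all_groups[1:]

    cb = 0.0
    first = True
    gi = 0
    while cb < t_end_grid - _EPS:
        cb_next = min(cb + chunk_ms, t_end_grid)
        j0 = int(round(cb / dt_out)) + (0 if first else 1)
        j1 = int(round(cb_next / dt_out))
        grid = np.arange(j0, j1 + 1) * dt_out
        out = np.empty((len(grid), _kernels.NSTATE))
        filled = np.zeros(len(grid), dtype=bool)
        if first:
            out[0] = y
            filled[0] = True
        groups = []
        while gi < len(all_groups) and all_groups[gi][0] < cb_next - _EPS:
            groups.append(all_groups[gi])
            gi += 1
        y = _integrate_piecewise(p, y, groups, cb, cb_next, grid, out,
                                 filled, rtol, atol)
        assert filled.all()
        yield _finalize_trace(grid, out, params, digest)
        cb = cb_next
        first = False


def simulate_reference_protocol(params: ModelParameters,
                                noise: NoiseConfig | None = None,
                                t_total: float = 5_000.0,
                                seed: int | None = None,
                                plateau_ms: float = 250.0,
                                isi_ms: float = 250.0,
                                t_first: float = 100.0,
                                dt_out: float = 0.5,
                                rtol: float = 1e-6, atol: float = 1e-9,
                                ) -> SimulationTrace:
    """Simulate the standard feeding protocol, optionally with noise.

    Builds the 250/250 ms EPSP/IPSP command schedule (durations
    configurable), merges in a Poisson noise train when ``noise`` has a
    positive rate, and integrates from the resting state.
    """
    schedule = reference_schedule(params, noise, t_total, seed,
                                  plateau_ms, isi_ms, t_first)
    return simulate(params, schedule, dt_out=dt_out, rtol=rtol, atol=atol)


def reference_schedule(params: ModelParameters,
                       noise: NoiseConfig | None = None,
                       t_total: float = 5_000.0,
                       seed: int | None = None,
                       plateau_ms: float = 250.0, isi_ms: float = 250.0,
                       t_first: float = 100.0) -> EventSchedule:
    """The merged command-plus-noise schedule of the reference protocol."""
    sched = build_feeding_schedule(plateau_ms, isi_ms, t_total, t_first,
                                   epsp_nS=params.gsynE_max,
                                   ipsp_nS=params.gsynI_max)
    if noise is not None and noise.lam > 0:
        cfg = noise if seed is None else NoiseConfig(noise.lam, noise.bin_ms,
                                                     seed)
        train = sample_noise_train(cfg, t_total, params.noise_quantum)
        sched = merge_schedules(sched, train)
    return sched
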