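"""Synthetic input generation: deterministic feeding-command schedules
(EPSP/IPSP event lists standing in for the MC and M3 motor neurons) and
Poisson shot-noise trains on the inhibitory synaptic conductance.

These event lists are the model's only input.  Commands *assign* the
synaptic conductance its maximal value (a spike resets the synapse);
noise events *add* quanta to the inhibitory conductance so that a small
fluctuation cannot erase a command.
"""

from __future__ import annotations

import csv
import hashlib
import io
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .parameters import ModelParameters
from .model import StateVector

__all__ = ["SynapticEvent", "EventSchedule", "NoiseConfig",
           "build_feeding_schedule", "sample_noise_train", "apply_event",
           "merge_schedules", "EPSP", "IPSP", "NOISE"]

EPSP = "EPSP"
IPSP = "IPSP"
NOISE = "NOISE"

#: Deterministic ordering of simultaneous events.
_KIND_ORDER = {EPSP: 0, IPSP: 1, NOISE: 2}


@dataclass(frozen=True)
class SynapticEvent:
    """One timed discontinuity of a synaptic conductance.

    ``magnitude`` is the assigned maximal conductance for EPSP/IPSP
    commands and the summed quantal increment (k * noise_quantum) for
    NOISE events, in nS.
    """

    t: float
    kind: str
    magnitude: float

    def __post_init__(self) -> None:
        if self.kind not in _KIND_ORDER:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.t < 0:
            raise ValueError(f"event time must be >= 0, got {self.t}")
        if self.magnitude < 0:
            raise ValueError(f"magnitude must be >= 0, got {self.magnitude}")

    @property
    def sort_key(self):
        return (self.t, _KIND_ORDER[self.kind])


@dataclass(frozen=True)
class EventSchedule:
    """Time-ordered sequence of synaptic events on [0, t_total)."""

    events: tuple
    t_total: float

    def __post_init__(self) -> None:
        keys = [ev.sort_key for ev in self.events]
        if keys != sorted(keys):
            raise ValueError("events must be ordered by (t, kind)")
        if self.events and self.events[-1].t >= self.t_total:
            raise ValueError("all event times must be < t_total")

    def __len__(self) -> int:
        return len(self.events)

    def times(self) -> np.ndarray:
        return np.array([ev.t for ev in self.events], dtype=float)

    def digest(self) -> str:
        """Checksum of the event list (used to stamp traces)."""
        h = hashlib.sha256()
        for ev in self.events:
            h.update(f"{ev.t!r},{ev.kind},{ev.magnitude!r};".encode())
        h.update(f"{self.t_total!r}".encode())
        return h.hexdigest()[:16]

    # -- CSV round trip --------------------------------------------------

    def to_csv(self, path_or_buf) -> None:
        close = False
        if isinstance(path_or_buf, (str, bytes)) or hasattr(path_or_buf, "__fspath__"):
            fh = open(path_or_buf, "w", newline="")
            close = True
        else:
            fh = path_or_buf
        try:
            wr = csv.writer(fh)
            wr.writerow(["t_ms", "kind", "magnitude_nS"])
            for ev in self.events:
                wr.writerow([repr(ev.t), ev.kind, repr(ev.magnitude)])
            wr.writerow(["#t_total", "", repr(self.t_total)])
        finally:
            if close:
                fh.close()

    @classmethod
    def from_csv(cls, path_or_buf) -> "EventSchedule":
        close = False
        if isinstance(path_or_buf, (str, bytes)) or hasattr(path_or_buf, "__fspath__"):
            fh = open(path_or_buf, newline="")
            close = True
        else:
            fh = path_or_buf
        try:
            rd = csv.reader(fh)
            header = next(rd)
            if header != ["t_ms", "kind", "magnitude_nS"]:
                raise ValueError(f"unexpected schedule CSV header: {header}")
            events = []
            t_total = None
            for row in rd:
                if not row:
                    continue
                if row[0] == "#t_total":
                    t_total = float(row[2])
                    continue
                events.append(SynapticEvent(float(row[0]), row[1], float(row[2])))
            if t_total is None:
                raise ValueError("schedule CSV missing #t_total footer")
            return cls(tuple(events), t_total)
        finally:
            if close:
                fh.close()


@dataclass(frozen=True)
class NoiseConfig:
    """Poisson shot-noise settings.

    ``lam`` is the expected number of channel openings per time bin of
    width ``bin_ms``; each opening contributes one conductance quantum to
    the inhibitory synapse.
    """

    lam: float = 0.0
    bin_ms: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError(f"lam must be >= 0, got {self.lam}")
        if self.bin_ms <= 0:
            raise ValueError(f"bin_ms must be > 0, got {self.bin_ms}")


def build_feeding_schedule(plateau_ms: float, isi_ms: float, t_total: float,
                           t_first: float = 100.0, *,
                           epsp_nS: float = 3.0,
                           ipsp_nS: float = 2.5) -> EventSchedule:
    """Regular feeding-command schedule: an EPSP initiating each plateau
    and an IPSP terminating it ``plateau_ms`` later, repeating with period
    ``plateau_ms + isi_ms`` until ``t_total``.

    The reference protocol uses 250 ms plateaus with a 250 ms ISI,
    matching the pump rate of an actively feeding animal.
    """
    if plateau_ms <= 0 or isi_ms <= 0 or t_total <= 0 or t_first < 0:
        raise ValueError("plateau_ms, isi_ms and t_total must be > 0 "
                         "and t_first >= 0")
    if t_first + plateau_ms > t_total:
        raise ValueError(
            f"first plateau does not fit: t_first + plateau_ms = "
            f"{t_first + plateau_ms} > t_total = {t_total}"
        )
    events = []
    period = plateau_ms + isi_ms
    k = 0
    while True:
        t_on = t_first + k * period
        t_off = t_on + plateau_ms
        if t_off >= t_total:
            break
        events.append(SynapticEvent(t_on, EPSP, epsp_nS))
        events.append(SynapticEvent(t_off, IPSP, ipsp_nS))
        k += 1
    return EventSchedule(tuple(events), t_total)


def sample_noise_train(cfg: NoiseConfig, t_total: float,
                       noise_quantum: float = 0.15) -> EventSchedule:
    """Poisson shot-noise train on the inhibitory conductance.

    Time is binned at ``cfg.bin_ms``; each bin draws an independent
    Poisson(``cfg.lam``) count of channel openings, and every bin with a
    nonzero count yields one NOISE event at the bin start with magnitude
    ``count * noise_quantum``.  The same (seed, lam, bin_ms, t_total)
    always reproduces the identical train.
    """
    if t_total <= 0:
        raise ValueError("t_total must be > 0")
    n_bins = int(np.ceil(t_total / cfg.bin_ms))
    if cfg.lam == 0 or n_bins == 0:
        return EventSchedule((), t_total)
    rng = np.random.default_rng(cfg.seed)
    counts = rng.poisson(cfg.lam, n_bins)
    idx = np.nonzero(counts)[0]
    events = []
    for i in idx:
        t = i * cfg.bin_ms
        if t >= t_total:
            break
        events.append(SynapticEvent(float(t), NOISE,
                                    float(counts[i]) * noise_quantum))
    return EventSchedule(tuple(events), t_total)


def merge_schedules(*schedules: EventSchedule) -> EventSchedule:
    """Merge schedules into one, ordered by time with the deterministic
    tie order EPSP < IPSP < NOISE; t_total must agree."""
    if not schedules:
        raise ValueError("need at least one schedule")
    t_total = schedules[0].t_total
    for s in schedules[1:]:
        if s.t_total != t_total:
            raise ValueError("schedules have differing t_total")
    events = sorted((ev for s in schedules for ev in s.events),
                    key=lambda ev: ev.sort_key)
    return EventSchedule(tuple(events), t_total)


def apply_event(state: StateVector, ev: SynapticEvent,
                params: ModelParameters | None = None) -> StateVector:
    """Apply one event's conductance discontinuity to the state.

    EPSP/IPSP assign the respective synaptic conductance (a presynaptic
    spike resets the synapse to its maximal value); NOISE adds its quantal
    magnitude to the inhibitory conductance, uncapped.
    """
    if ev.kind == EPSP:
        return state.replace(gE=ev.magnitude)
    if ev.kind == IPSP:
        return state.replace(gI=ev.magnitude)
    if ev.kind == NOISE:
        return state.replace(gI=state.gI + ev.magnitude)
    raise ValueError(f"unknown event kind {ev.kind!r}")


def apply_event_array(y: np.ndarray, ev: SynapticEvent) -> None:
    """In-place flat-array version of :func:`apply_event` (kernel layout)."""
    from ._kernels import IGE, IGI
    if ev.kind == EPSP:
        y[IGE] = ev.magnitude
    elif ev.kind == IPSP:
        y[IGI] = ev.magnitude
    elif ev.kind == NOISE:
        y[IGI] += ev.magnitude
    else:  # pragma: no cover - guarded by SynapticEvent
        raise ValueError(f"unknown event kind {ev.kind!r}")
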