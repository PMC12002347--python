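"""Drivers for the four computational studies.

* conductance sweep over (gK, gCaL) with regime classification,
* noise robustness of the ultrafast model across inactivation midpoints,
* noise robustness of the finite-tau_h models,
* the interaction of the inactivation timescale with the synaptic
  (noise-event) timescale.

All stochastic conditions derive their noise seeds from a single base
seed through a fixed counter scheme (`condition_seed`), so adding a
condition never reshuffles the seeds of existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .parameters import INSTANTANEOUS, ModelParameters, TauH
from .integrator import (IntegrationError, reference_schedule, simulate,
                         simulate_chunked, simulate_reference_protocol)
from .plateaus import (PlateauAccumulator, Regime, RegimeThresholds,
                       classify_regime, closed_durations, detect_plateaus,
                       mark_commanded)
from .stimulus import NoiseConfig
from .stats import compare_samples

__all__ = ["SweepGrid", "ConditionTable", "condition_seed",
           "collect_plateau_durations", "run_conductance_sweep",
           "run_noise_robustness", "run_timescale_robustness",
           "run_timescale_interaction"]

#: protocol length used per sweep cell; six commanded plateaus is enough
#: to classify the regime while keeping full-plane sweeps tractable.
DEFAULT_SWEEP_PROTOCOL_MS = 3_000.0

#: durations are compared across conditions at this resolution (ms); the
#: rank test would otherwise register sub-resolution timing jitter
#: (solver- and sub-sample-scale shifts of the threshold crossings) as
#: signal.  2 ms is <1% of the commanded plateau.
DEFAULT_DURATION_RESOLUTION_MS = 2.0


def condition_seed(base_seed: int, *indices: int) -> int:
    """Stable per-condition seed: SeedSequence([base, *coordinates])."""
    ss = np.random.SeedSequence([int(base_seed), *[int(i) for i in indices]])
    return int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)


def quantize_durations(durations: np.ndarray, resolution_ms: float) -> np.ndarray:
    if resolution_ms <= 0:
        return np.asarray(durations, dtype=float)
    return np.round(np.asarray(durations, dtype=float) / resolution_ms) \
        * resolution_ms


def collect_plateau_durations(params: ModelParameters,
                              noise: NoiseConfig | None,
                              t_total_ms: float,
                              seed: int | None = None,
                              chunk_ms: float = 50_000.0,
                              dt_out: float = 0.5,
                              threshold: float = -30.0,
                              min_duration: float = 5.0) -> np.ndarray:
    """Closed plateau durations of one reference-protocol run, computed
    chunk-by-chunk so arbitrarily long runs stay memory bounded."""
    schedule = reference_schedule(params, noise, t_total_ms, seed)
    acc = PlateauAccumulator(threshold, min_duration)
    for tr in simulate_chunked(params, schedule, chunk_ms=chunk_ms,
                               dt_out=dt_out):
        acc.feed(tr.times, tr.V)
    return closed_durations(acc.finalize())


# ---------------------------------------------------------------------------
# conductance sweep

@dataclass(frozen=True)
class SweepGrid:
    """Mean plateau duration, plateau count and regime per (gK, gCaL)."""

    gK_values: np.ndarray
    gCaL_values: np.ndarray
    mean_duration: np.ndarray   # (n_gK, n_gCaL), ms; NaN where no plateaus
    n_plateaus: np.ndarray      # (n_gK, n_gCaL)
    regime: np.ndarray          # (n_gK, n_gCaL) of regime-label strings
    tau_h: TauH
    vhalf: float

    def __post_init__(self):
        shape = (len(self.gK_values), len(self.gCaL_values))
        for name in ("mean_duration", "n_plateaus", "regime"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} shape {getattr(self, name).shape} "
                                 f"!= grid shape {shape}")

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, gk in enumerate(self.gK_values):
            for j, gcal in enumerate(self.gCaL_values):
                rows.append({
                    "gK_nS": gk, "gCaL_nS": gcal,
                    "mean_duration_ms": self.mean_duration[i, j],
                    "n_plateaus": self.n_plateaus[i, j],
                    "regime": self.regime[i, j],
                })
        return pd.DataFrame(rows)

    def regime_row(self, gK: float) -> list:
        i = int(np.argmin(np.abs(self.gK_values - gK)))
        return list(self.regime[i])

    def cells_with_regime(self, regime: Regime) -> list:
        out = []
        for i, gk in enumerate(self.gK_values):
            for j, gcal in enumerate(self.gCaL_values):
                if self.regime[i, j] == regime.value:
                    out.append((float(gk), float(gcal)))
        return out


def run_conductance_sweep(tau_h: TauH = INSTANTANEOUS,
                          gK_values: Sequence[float] | None = None,
                          gCaL_values: Sequence[float] | None = None,
                          protocol_ms: float = DEFAULT_SWEEP_PROTOCOL_MS,
                          params: ModelParameters | None = None,
                          vhalf: float = 15.0,
                          thresholds: RegimeThresholds | None = None,
                          dt_out: float = 0.5) -> SweepGrid:
    """Noiseless regime map over maximal conductances of IK and ICaL.

    Defaults cover 0-10 nS (gK) by 0-7.5 nS (gCaL) in 0.25 nS steps, the
    plane explored in the study; pass coarser grids for quick looks.
    Solver failures in a cell are recorded as the 'failure' label rather
    than aborting the sweep.
    """
    gK_values = np.asarray(gK_values if gK_values is not None
                           else np.arange(0.0, 10.01, 0.25))
    gCaL_values = np.asarray(gCaL_values if gCaL_values is not None
                             else np.arange(0.0, 7.51, 0.25))
    base = params if params is not None else ModelParameters()
    base = base.replace(tau_h=tau_h, Vhalf_inact=vhalf)
    shape = (len(gK_values), len(gCaL_values))
    mean = np.full(shape, np.nan)
    count = np.zeros(shape, dtype=int)
    regime = np.empty(shape, dtype=object)
    for i, gk in enumerate(gK_values):
        for j, gcal in enumerate(gCaL_values):
            p = base.replace(gK=float(gk), gCaL=float(gcal))
            try:
                tr = simulate_reference_protocol(p, None, t_total=protocol_ms,
                                                 dt_out=dt_out)
            except (IntegrationError, ValueError):
                regime[i, j] = Regime.FAILURE.value
                continue
            sched = reference_schedule(p, None, protocol_ms)
            regime[i, j] = classify_regime(tr, sched, thresholds).value
            d = closed_durations(detect_plateaus(tr))
            count[i, j] = d.size
            if d.size:
                mean[i, j] = d.mean()
    return SweepGrid(gK_values=gK_values, gCaL_values=gCaL_values,
                     mean_duration=mean, n_plateaus=count, regime=regime,
                     tau_h=tau_h, vhalf=vhalf)


# ---------------------------------------------------------------------------
# noise-robustness studies

@dataclass(frozen=True)
class ConditionTable:
    """Tidy per-(condition, seed) duration statistics with effect sizes.

    ``df`` has one row per condition and seed; ``pooled`` has one row per
    condition with all seeds' durations pooled and the Mann-Whitney
    z / effect size against the matching noiseless condition.
    """

    df: pd.DataFrame
    pooled: pd.DataFrame

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False, float_format="%.6g")

    def pooled_mean(self, **key) -> float:
        sel = self.pooled
        for k, v in key.items():
            sel = sel[sel[k] == v]
        if len(sel) != 1:
            raise KeyError(f"key {key} selects {len(sel)} rows")
        return float(sel["mean_ms"].iloc[0])

    def pooled_effect(self, **key) -> float:
        sel = self.pooled
        for k, v in key.items():
            sel = sel[sel[k] == v]
        if len(sel) != 1:
            raise KeyError(f"key {key} selects {len(sel)} rows")
        return float(sel["effect"].iloc[0])


def _robustness_table(variants: Sequence[tuple],
                      lam_list: Sequence[float],
                      t_total_ms: float, n_seeds: int, base_seed: int,
                      base_params: ModelParameters,
                      noise_bin_ms: float,
                      duration_resolution_ms: float,
                      chunk_ms: float, key_name: str) -> ConditionTable:
    rows = []
    pooled_rows = []
    for vi, (key_value, params) in enumerate(variants):
        noiseless = collect_plateau_durations(params, None, t_total_ms,
                                              chunk_ms=chunk_ms)
        for li, lam in enumerate(lam_list):
            samples = []
            n_runs = 1 if lam == 0 else n_seeds
            for si in range(n_runs):
                if lam == 0:
                    d = noiseless
                    seed = None
                else:
                    seed = condition_seed(base_seed, vi, li, si)
                    noise = NoiseConfig(lam=lam, bin_ms=noise_bin_ms,
                                        seed=seed)
                    d = collect_plateau_durations(params, noise, t_total_ms,
                                                  seed=seed,
                                                  chunk_ms=chunk_ms)
                samples.append(d)
                rows.append({
                    key_name: key_value, "lam": lam,
                    "seed_index": si, "seed": seed,
                    "n_plateaus": int(d.size),
                    "mean_ms": float(d.mean()) if d.size else np.nan,
                })
            pooled = (np.concatenate(samples) if samples
                      else np.empty(0))
            if lam == 0 or pooled.size == 0 or noiseless.size == 0:
                z = 0.0
                effect = 0.0
            else:
                rep = compare_samples(
                    quantize_durations(pooled, duration_resolution_ms),
                    quantize_durations(noiseless, duration_resolution_ms))
                z, effect = rep.z, rep.effect
            pooled_rows.append({
                key_name: key_value, "lam": lam,
                "n_plateaus": int(pooled.size),
                "mean_ms": float(pooled.mean()) if pooled.size else np.nan,
                "z": z, "effect": effect,
            })
    return ConditionTable(df=pd.DataFrame(rows),
                          pooled=pd.DataFrame(pooled_rows))


def run_noise_robustness(vhalf_list: Sequence[float] = (10.0, 15.0, 20.0),
                         lam_list: Sequence[float] = (0.0, 0.01, 0.05),
                         t_total_ms: float = 1_000_000.0,
                         n_seeds: int = 3, base_seed: int = 0,
                         params: ModelParameters | None = None,
                         noise_bin_ms: float = 0.1,
                         duration_resolution_ms: float =
                         DEFAULT_DURATION_RESOLUTION_MS,
                         chunk_ms: float = 50_000.0) -> ConditionTable:
    """Ultrafast-variant plateau durations across inactivation midpoints
    under increasing inhibitory shot noise."""
    base = params if params is not None else ModelParameters()
    variants = [(float(v), base.replace(Vhalf_inact=float(v),
                                        tau_h=INSTANTANEOUS))
                for v in vhalf_list]
    return _robustness_table(variants, lam_list, t_total_ms, n_seeds,
                             base_seed, base, noise_bin_ms,
                             duration_resolution_ms, chunk_ms, "vhalf")


def run_timescale_robustness(tau_list: Sequence[float] = (1.0, 5.0, 10.0,
                                                          20.0),
                             lam_list: Sequence[float] = (0.0, 0.01, 0.05),
                             t_total_ms: float = 1_000_000.0,
                             n_seeds: int = 3, base_seed: int = 0,
                             params: ModelParameters | None = None,
                             vhalf: float = 15.0,
                             noise_bin_ms: float = 0.1,
                             duration_resolution_ms: float =
                             DEFAULT_DURATION_RESOLUTION_MS,
                             chunk_ms: float = 50_000.0) -> ConditionTable:
    """Finite-tau_h variants (fixed V1/2 = 15 mV) under shot noise."""
    base = params if params is not None else ModelParameters()
    variants = [(float(t), base.replace(tau_h=float(t),
                                        Vhalf_inact=float(vhalf)))
                for t in tau_list]
    return _robustness_table(variants, lam_list, t_total_ms, n_seeds,
                             base_seed, base, noise_bin_ms,
                             duration_resolution_ms, chunk_ms, "tau_h")


def run_timescale_interaction(tau_h_values: Sequence[float] =
                              (0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0),
                              tau_syn_values: Sequence[float] =
                              (1.0, 2.0, 3.0, 4.0, 5.0),
                              lam: float = 0.05,
                              t_total_ms: float = 100_000.0,
                              n_seeds: int = 1, base_seed: int = 0,
                              params: ModelParameters | None = None,
                              vhalf: float = 15.0,
                              noise_bin_ms: float = 0.1,
                              chunk_ms: float = 50_000.0) -> pd.DataFrame:
    """Mean plateau duration over a (tau_h, tau_I) grid under noise.

    ``tau_syn`` is the inhibitory synaptic decay constant, which sets the
    temporal extent of both commanded IPSPs and noise events.  Returns a
    tidy frame with one row per (tau_h, tau_syn, seed).
    """
    base = params if params is not None else ModelParameters()
    rows = []
    for ti, th in enumerate(tau_h_values):
        for si_, ts in enumerate(tau_syn_values):
            p = base.replace(tau_h=float(th), tauI=float(ts),
                             Vhalf_inact=float(vhalf))
            for si in range(n_seeds):
                seed = condition_seed(base_seed, 100 + ti, si_, si)
                noise = NoiseConfig(lam=lam, bin_ms=noise_bin_ms, seed=seed)
                d = collect_plateau_durations(p, noise, t_total_ms,
                                              seed=seed, chunk_ms=chunk_ms)
                rows.append({
                    "tau_h": float(th), "tau_syn": float(ts),
                    "seed_index": si, "seed": seed,
                    "n_plateaus": int(d.size),
                    "mean_ms": float(d.mean()) if d.size else np.nan,
                })
    return pd.DataFrame(rows)


def find_two_level_cell(tau_h: float = 20.0, vhalf: float = 15.0,
                        params: ModelParameters | None = None,
                        gK_range=(0.0, 10.0), gCaL_range=(0.0, 7.5),
                        coarse_step: float = 0.5,
                        refine_step: float = 0.05,
                        protocol_ms: float = 5_100.0):
    """Locate a (gK, gCaL) cell producing two-level plateaus.

    Two-level cells form a thin band along the physiological/unending
    boundary of the conductance plane, narrower than any practical coarse
    grid step.  The search therefore proceeds in two deterministic
    stages: a coarse sweep brackets the boundary for each gK row, then
    gCaL is refined inside each bracket until a cell classifies as
    two_level.  Returns ``(gK, gCaL, trace, segment, (V_upper, V_lower))``
    for the first hit (row-major order), or None.
    """
    from .plateaus import plateau_levels  # local import to avoid cycle noise
    base = params if params is not None else ModelParameters()
    base = base.replace(tau_h=float(tau_h), Vhalf_inact=float(vhalf))
    gks = np.arange(gK_range[0], gK_range[1] + coarse_step / 2, coarse_step)
    gcals = np.arange(gCaL_range[0], gCaL_range[1] + coarse_step / 2,
                      coarse_step)

    def cell_regime(gk, gcal):
        p = base.replace(gK=float(gk), gCaL=float(gcal))
        try:
            tr = simulate_reference_protocol(p, None, t_total=protocol_ms)
        except (IntegrationError, ValueError):
            return Regime.FAILURE, None, None
        sched = reference_schedule(p, None, protocol_ms)
        return classify_regime(tr, sched), tr, sched

    def two_level_hit(gk, gcal):
        reg, tr, _ = cell_regime(gk, gcal)
        if reg is not Regime.TWO_LEVEL:
            return None
        for seg in detect_plateaus(tr):
            if seg.open_ended:
                continue
            levels = plateau_levels(tr, seg)
            if levels is not None:
                return float(gk), float(gcal), tr, seg, levels
        return None

    for gk in gks:
        prev = None
        for gcal in gcals:
            reg, _, _ = cell_regime(gk, gcal)
            if reg is Regime.TWO_LEVEL:
                hit = two_level_hit(gk, gcal)
                if hit:
                    return hit
            if prev is not None and \
                    prev[0] is Regime.PHYSIOLOGICAL and reg is Regime.UNENDING:
                # refine inside the bracket (prev gcal, gcal)
                for g in np.arange(prev[1] + refine_step,
                                   gcal - refine_step / 2, refine_step):
                    hit = two_level_hit(gk, round(float(g), 6))
                    if hit:
                        return hit
            prev = (reg, float(gcal))
    return None


def flat_region_width(interaction: pd.DataFrame, tau_syn: float,
                      level_ms: float = 200.0) -> int:
    """Number of tau_h grid points whose mean duration stays at or above
    ``level_ms`` for the given synaptic timescale (the 'robust region'
    width of one interaction curve)."""
    sel = interaction[interaction["tau_syn"] == tau_syn]
    curve = sel.groupby("tau_h")["mean_ms"].mean()
    return int((curve >= level_ms).sum())
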