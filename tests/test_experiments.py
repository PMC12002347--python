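"""Experiment drivers: seeds, chunked duration collection, the
conductance sweep, and the robustness tables (small problem sizes)."""

import numpy as np
import pandas as pd
import pytest

from pharynxsim import ModelParameters, NoiseConfig, simulate
from pharynxsim.experiments import (collect_plateau_durations,
                                    condition_seed, flat_region_width,
                                    quantize_durations,
                                    run_conductance_sweep,
                                    run_noise_robustness)
from pharynxsim.integrator import reference_schedule
from pharynxsim.plateaus import Regime, closed_durations, detect_plateaus


class TestSeedScheme:
    def test_stable_and_distinct(self):
        a = condition_seed(7, 1, 2, 0)
        assert a == condition_seed(7, 1, 2, 0)
        others = {condition_seed(7, 1, 2, 1), condition_seed(7, 1, 3, 0),
                  condition_seed(8, 1, 2, 0)}
        assert a not in others

    def test_fits_in_int31(self):
        for base in (0, 1, 2 ** 31 - 1):
            assert 0 <= condition_seed(base, 5, 5, 5) < 2 ** 31


def test_quantize_durations():
    d = np.array([249.4, 250.6, 100.1])
    np.testing.assert_allclose(quantize_durations(d, 2.0),
                               [250.0, 250.0, 100.0])
    np.testing.assert_allclose(quantize_durations(d, 0.0), d)


def test_chunked_collection_matches_single_trace(params):
    noise = NoiseConfig(lam=0.05, seed=3)
    d_chunked = collect_plateau_durations(params, noise, 10_000.0, seed=3,
                                          chunk_ms=2_500.0)
    sched = reference_schedule(params, noise, 10_000.0, seed=3)
    d_whole = closed_durations(detect_plateaus(simulate(params, sched)))
    assert d_chunked.size == d_whole.size
    np.testing.assert_allclose(d_chunked, d_whole, atol=0.5)


def test_noiseless_reference_durations(params):
    d = collect_plateau_durations(params, None, 10_000.0)
    assert d.size == 20  # first plateau at 100 ms, one per 500 ms
    assert d.mean() == pytest.approx(250.0, abs=2.0)


@pytest.fixture(scope="module")
def grid():
    return run_conductance_sweep(gK_values=[0.0, 9.0],
                                 gCaL_values=[0.0, 3.7, 7.5],
                                 protocol_ms=3000.0)


class TestConductanceSweep:

    def test_default_cell_is_physiological(self, grid):
        df = grid.to_dataframe()
        row = df[(df.gK_nS == 9.0) & (df.gCaL_nS == 3.7)].iloc[0]
        assert row.regime == Regime.PHYSIOLOGICAL.value
        assert row.mean_duration_ms == pytest.approx(250.0, abs=5.0)

    def test_strong_CaL_is_unending(self, grid):
        df = grid.to_dataframe()
        row = df[(df.gK_nS == 9.0) & (df.gCaL_nS == 7.5)].iloc[0]
        assert row.regime == Regime.UNENDING.value

    def test_no_CaL_cannot_sustain_plateau(self, grid):
        df = grid.to_dataframe()
        row = df[(df.gK_nS == 9.0) & (df.gCaL_nS == 0.0)].iloc[0]
        assert row.regime in (Regime.LOW_AMPLITUDE.value,
                              Regime.QUIESCENT.value)

    def test_K_loss_of_function_is_unending(self, grid):
        # gK = 0 mimics exp-2 loss of function: plateaus never terminate
        df = grid.to_dataframe()
        row = df[(df.gK_nS == 0.0) & (df.gCaL_nS == 3.7)].iloc[0]
        assert row.regime == Regime.UNENDING.value

    def test_grid_shape_and_frame(self, grid):
        assert grid.mean_duration.shape == (2, 3)
        assert len(grid.to_dataframe()) == 6


def test_noise_robustness_table_small():
    table = run_noise_robustness(vhalf_list=(20.0,), lam_list=(0.0, 0.05),
                                 t_total_ms=15_000.0, n_seeds=2,
                                 base_seed=11)
    assert set(table.df.columns) >= {"vhalf", "lam", "seed_index",
                                     "n_plateaus", "mean_ms"}
    assert len(table.df) == 3  # one noiseless row + two seeds
    noiseless = table.pooled_mean(vhalf=20.0, lam=0.0)
    noisy = table.pooled_mean(vhalf=20.0, lam=0.05)
    assert noiseless == pytest.approx(250.0, abs=5.0)
    assert noisy < 100.0      # depolarized midpoint collapses under noise
    assert table.pooled_effect(vhalf=20.0, lam=0.05) > 0.5
    assert table.pooled_effect(vhalf=20.0, lam=0.0) == 0.0


def test_midpoint_ordering_and_effect_pattern_under_high_noise():
    """Under lambda = 0.05 the mean plateau duration is ordered
    V1/2 = 10 >= 15 >= 20 with > 2 SE margins, and the rank effect size
    against the noiseless condition is negligible at 10 mV but
    pronounced at 15 and 20 mV."""
    from pharynxsim.experiments import quantize_durations
    from pharynxsim.stats import compare_samples
    seed_means, effects = {}, {}
    for vi, vhalf in enumerate((10.0, 15.0, 20.0)):
        p = ModelParameters(Vhalf_inact=vhalf)
        noiseless = collect_plateau_durations(p, None, 50_000.0)
        runs = []
        for si in range(2):
            seed = condition_seed(3, 50 + vi, si)
            runs.append(collect_plateau_durations(
                p, NoiseConfig(lam=0.05, seed=seed), 50_000.0, seed=seed))
        seed_means[vhalf] = np.array([r.mean() for r in runs])
        rep = compare_samples(
            quantize_durations(np.concatenate(runs), 2.0),
            quantize_durations(noiseless, 2.0))
        effects[vhalf] = rep.effect
    def margin_2se(a, b):
        se = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
        return (a.mean() - b.mean()) > 2 * se
    assert margin_2se(seed_means[10.0], seed_means[15.0])
    assert margin_2se(seed_means[15.0], seed_means[20.0])
    assert effects[10.0] < 0.1
    assert effects[15.0] > 0.5
    assert effects[20.0] > 0.5


def test_flat_region_width_on_synthetic_curves():
    df = pd.DataFrame({
        "tau_h": [1.0, 2.0, 3.0] * 2,
        "tau_syn": [1.0] * 3 + [5.0] * 3,
        "mean_ms": [250, 250, 210, 90, 210, 150],
    })
    assert flat_region_width(df, 1.0) == 3
    assert flat_region_width(df, 5.0) == 1
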