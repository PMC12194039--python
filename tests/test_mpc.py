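"""Receding-horizon engine tests: horizon solves, causality, tracking."""

import numpy as np
import pytest

from spikempc.metrics import bin_downsample, pearson
from spikempc.model import (
    ModelState,
    TimeSeries,
    simulate,
    steady_state,
)
from spikempc.mpc import (
    MPCConfig,
    _horizon_cost,
    infer_from_raw,
    infer_rates,
    solve_horizon,
    track_reference,
)
from spikempc.preprocess import FilterConfig


def forward_z(params, s_values, state0, dt=0.01):
    """Measurement window produced by a known control sequence."""
    traj = simulate(
        params, TimeSeries(values=np.asarray(s_values, float), dt=dt), state0
    )
    # z after each applied control (trajectory is aligned one step behind)
    full = simulate(
        params,
        TimeSeries(values=np.append(np.asarray(s_values, float), 0.0), dt=dt),
        state0,
    )
    return full.z[1:]


class TestSolveHorizon:
    def test_zero_input_window_recovers_zero(self, synth_cell):
        state0 = steady_state(synth_cell, 0.0)
        window = forward_z(synth_cell, np.zeros(6), state0)
        s, z_pred, info = solve_horizon(synth_cell, state0, window, 0.0, MPCConfig())
        assert np.all(np.abs(s) < 1e-4)
        assert info["cost"] < 1e-10

    @pytest.mark.parametrize("c", [1.0, 5.0])
    def test_constant_rate_recovery_vs_grid_oracle(self, synth_cell, c):
        """Recovered s within 5% of the true constant; cost minimum agrees
        with a dense grid search over constant controls."""
        cfg = MPCConfig()
        state0 = steady_state(synth_cell, c)
        window = forward_z(synth_cell, np.full(6, c), state0)
        s, _, info = solve_horizon(synth_cell, state0, window, c, cfg)
        assert np.all(np.abs(s - c) / c < 0.05)
        grid = np.linspace(0.5 * c, 1.5 * c, 401)
        costs = [
            _horizon_cost(np.full(6, g), state0.x, state0.z, window, c, synth_cell, cfg)
            for g in grid
        ]
        assert info["cost"] <= min(costs) + 1e-9

    def test_large_smoothness_weight_forces_constant_sequence(self, synth_cell):
        cfg = MPCConfig(r=1e6)
        state0 = steady_state(synth_cell, 0.0)
        window = forward_z(synth_cell, np.array([0, 5, 0, 5, 0, 5.0]), state0)
        s, _, _ = solve_horizon(synth_cell, state0, window, 0.0, cfg)
        assert np.max(np.abs(np.diff(s))) < 1e-3 * (1 + np.max(s))

    def test_cost_never_exceeds_zero_input_candidate(self, synth_cell):
        cfg = MPCConfig()
        rng = np.random.default_rng(5)
        state0 = steady_state(synth_cell, 1.0)
        for _ in range(5):
            window = np.abs(rng.normal(state0.z, 0.5, 6))
            warm = rng.uniform(0, 20, 6)
            s, _, info = solve_horizon(synth_cell, state0, window, 0.0, cfg, warm)
            zero_cost = _horizon_cost(
                np.zeros(6), state0.x, state0.z, window, 0.0, synth_cell, cfg
            )
            assert info["cost"] <= zero_cost + 1e-12


class TestInferRates:
    def test_constant_resting_measurement_zero_rate(self, synth_cell):
        z0 = steady_state(synth_cell, 0.0).z
        meas = TimeSeries(values=np.full(100, z0), dt=0.01)
        res = infer_rates(meas, synth_cell)
        assert np.all(res.s_hat.values >= 0)
        assert np.all(res.s_hat.values < 1e-4)

    def test_nonnegativity_hard_constraint(self, synth_cell, clean_recording):
        _, _, clean = clean_recording
        res = infer_rates(clean, synth_cell)
        assert np.all(res.s_hat.values >= 0)
        assert len(res.s_hat) == len(clean)

    def test_step_change_located_within_horizon(self, synth_cell):
        """A 0 -> c step in the true rate appears in s_hat within n steps."""
        cfg = MPCConfig()
        dt, c, t_step = 0.01, 6.0, 1.0
        t = np.arange(300) * dt
        s_true = np.where(t >= t_step, c, 0.0)
        traj = simulate(synth_cell, TimeSeries(values=s_true, dt=dt), ModelState(0, 0))
        res = infer_rates(traj.z_series(), synth_cell, cfg, init=ModelState(0, 0))
        k_true = int(t_step / dt)
        crossings = np.flatnonzero(res.s_hat.values > c / 2)
        assert len(crossings) > 0
        assert abs(crossings[0] - k_true) <= cfg.n

    def test_streaming_prefix_equals_batch(self, synth_cell, clean_recording):
        """Causality: s_hat[k] never changes once emitted (no backtracking)."""
        _, _, clean = clean_recording
        cfg = MPCConfig()
        full = infer_rates(clean, synth_cell, cfg).s_hat.values
        n_trunc = len(clean) // 2
        trunc_meas = TimeSeries(values=clean.values[:n_trunc], dt=clean.dt)
        trunc = infer_rates(trunc_meas, synth_cell, cfg).s_hat.values
        solved = n_trunc - cfg.n  # indices emitted from full windows
        assert np.array_equal(full[:solved], trunc[:solved])

    def test_too_short_measurement_rejected(self, synth_cell):
        with pytest.raises(ValueError):
            infer_rates(TimeSeries(values=np.zeros(4), dt=0.01), synth_cell)


class TestTrackReference:
    def test_feasible_reference_tracked(self, synth_cell):
        drive = TimeSeries(values=np.full(200, 3.0), dt=0.01)
        traj = simulate(synth_cell, drive, steady_state(synth_cell, 3.0))
        res = track_reference(traj.z_series(), synth_cell)
        err = np.abs(res.ci_sim.values[50:] - traj.z[50:])
        assert err.max() < 0.05 * traj.z.max()

    def test_unreachable_reference_flagged(self, synth_cell):
        desired = TimeSeries(values=np.full(60, synth_cell.L + 5.0), dt=0.01)
        with pytest.warns(UserWarning, match="plateau"):
            res = track_reference(desired, synth_cell)
        assert res.diagnostics.get("infeasible_reference")
        assert np.all(res.ci_sim.values <= synth_cell.L)

    def test_square_wave_reference_pulses_at_rising_edges(self, synth_cell):
        dt = 0.01
        z_lo, z_hi = 0.5, 5.0
        vals = np.where((np.arange(400) // 100) % 2 == 1, z_hi, z_lo)
        res = track_reference(TimeSeries(values=vals, dt=dt), synth_cell)
        s = res.s_hat.values
        edges = [100, 300]
        for e in edges:
            near = s[e - 10 : e + 10].max()
            away = s[e + 30 : e + 70].max()
            assert near > 5 * max(away, 1e-6)


class TestSaturationRestart:
    def test_fallback_shift_applied_once(self, synth_cell):
        """A trace pinned near the filter ceiling triggers the h=0.25 pass."""
        cfg = FilterConfig(normalization="none", saturation_run=25)
        raw = TimeSeries(values=np.full(120, 5.0), dt=0.01)
        res = infer_from_raw(raw, synth_cell, MPCConfig(), cfg)
        assert res.h_used == cfg.h_fallback

    def test_normal_trace_keeps_default_shift(self, synth_cell, clean_recording):
        _, _, clean = clean_recording
        res = infer_from_raw(clean, synth_cell, MPCConfig(), FilterConfig())
        assert res.h_used == 0.15


def test_noiseless_loop_recovers_spike_mass_and_timing(synth_cell, clean_recording):
    """Generate -> infer: total inferred rate mass matches the spike count
    within 10% and the binned signals are strongly correlated.  (The full
    correlation benchmark on a longer, denser recording lives in the
    acceptance suite; a 10 s, 1 Hz train has too few events for a stable
    correlation estimate.)"""
    _, train, clean = clean_recording
    res = infer_rates(clean, synth_cell)
    mass = res.s_hat.values.sum() * clean.dt
    assert mass == pytest.approx(len(train), rel=0.10)
    pred = bin_downsample(res.s_hat, 4)
    true = bin_downsample(train, 4, native_dt=0.01, n_samples=len(clean))
    m = min(len(pred), len(true))
    assert pearson(pred[:m], true[:m]) > 0.5
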