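"""Unit tests for the shift-and-search lagged GLM."""

import numpy as np
import pytest

from cvrkit.delay import (
    ShiftGrid,
    build_shifted_regressor,
    find_global_delay,
    voxelwise_lag_glm,
)
from cvrkit.errors import ValidationError
from cvrkit.physio import EtCO2Series, compute_etco2, pad_and_sample
from cvrkit.synthetic import PhantomSpec, make_bold, make_capno
from cvrkit.volume import BoldVolume


@pytest.fixture(scope="module")
def grid():
    return ShiftGrid(max_shift=15.0, step=0.5)


def test_shift_grid_contains_zero_and_is_increasing():
    g = ShiftGrid(max_shift=30.0, step=0.5).shifts
    assert 0.0 in g
    assert np.all(np.diff(g) > 0)
    assert g[0] == -30.0 and g[-1] == 30.0


class TestShiftedRegressor:
    def test_zero_shift_equals_pad_and_sample(self, small_etco2):
        frames = np.arange(120) * 2.0
        np.testing.assert_array_equal(
            build_shifted_regressor(small_etco2, 0.0, frames),
            pad_and_sample(small_etco2, frames),
        )

    def test_large_positive_shift_pads_early_frames_with_baseline(self):
        t = np.arange(0, 300.01, 0.1)
        et = EtCO2Series(40 + np.sin(t / 20), t, baseline=39.5, source_support=(0.0, 300.0))
        frames = np.arange(180) * 2.0  # to 358 s
        out = build_shifted_regressor(et, 30.0, frames)
        np.testing.assert_allclose(out[:15], 39.5)  # frames at t < 30 s
        assert out[15] != 39.5

    def test_periodic_envelope_shifted_by_one_period(self):
        period = 60.0
        t = np.arange(0, 600.01, 0.1)
        et = EtCO2Series(41 + np.cos(2 * np.pi * t / period), t, baseline=40.0,
                         source_support=(0.0, 600.0))
        frames = np.arange(60, 240, 2.0)  # interior, both shifts in-support
        np.testing.assert_allclose(
            build_shifted_regressor(et, period, frames),
            build_shifted_regressor(et, 0.0, frames),
            atol=1e-9,
        )


class TestGlobalDelay:
    def test_recovers_injected_sampling_line_lag(self, grid):
        spec = PhantomSpec(shape=(4, 4, 4), n_frames=150, global_delay_s=10.0,
                           tsnr=np.inf, noise_ic_sd=0.0, seed=21)
        bold, _, _ = make_bold(spec)
        et = compute_etco2(make_capno(spec))
        gd = find_global_delay(bold.global_signal(), et, grid, bold.frame_times)
        assert gd == pytest.approx(10.0, abs=grid.step / 2)

    def test_zero_injected_delay_returns_zero(self, grid):
        spec = PhantomSpec(shape=(4, 4, 4), n_frames=150, global_delay_s=0.0,
                           tsnr=np.inf, noise_ic_sd=0.0, seed=22)
        bold, _, _ = make_bold(spec)
        et = compute_etco2(make_capno(spec))
        gd = find_global_delay(bold.global_signal(), et, grid, bold.frame_times)
        assert gd == 0.0

    def test_matches_brute_force_argmax(self, small_etco2, grid):
        rng = np.random.default_rng(0)
        frames = np.arange(120) * 2.0
        signal = rng.standard_normal(120) + 0.3 * build_shifted_regressor(
            small_etco2, 6.0, frames
        )
        gd = find_global_delay(signal, small_etco2, grid, frames)
        rs = np.array([
            np.corrcoef(build_shifted_regressor(small_etco2, s, frames), signal)[0, 1]
            for s in grid.shifts
        ])
        assert gd == grid.shifts[np.argmax(rs)]

    def test_constant_global_signal_rejected(self, small_etco2, grid):
        with pytest.raises(ValidationError, match="degenerate global signal"):
            find_global_delay(np.full(120, 5.0), small_etco2, grid, np.arange(120) * 2.0)


class TestVoxelwiseLagGlm:
    def test_noiseless_local_shift_and_betas_recovered(self, grid):
        delay = np.zeros((3, 3, 3))
        delay[0, 0, 0] = 6.0
        spec = PhantomSpec(shape=(3, 3, 3), n_frames=150, delay_true=delay,
                           global_delay_s=4.0, tsnr=np.inf, noise_ic_sd=0.0, seed=23)
        bold, _, truth = make_bold(spec)
        et = compute_etco2(make_capno(spec))
        gd = find_global_delay(bold.global_signal(), et, grid, bold.frame_times)
        fit = voxelwise_lag_glm(bold, et, grid, gd)
        # absolute optimum equals injected total delay to grid resolution
        np.testing.assert_allclose(
            fit.delay_map + gd, truth["total_delay"], atol=grid.step / 2
        )
        b0, b1 = truth["beta0"], truth["beta0"] * truth["cvr"] / 100.0
        np.testing.assert_allclose(fit.beta1_map, b1, rtol=0.01)
        np.testing.assert_allclose(
            fit.beta0_map, b0 * (1 - truth["cvr"] / 100.0 * spec.baseline_mmhg), rtol=0.01
        )

    def test_pure_global_signal_voxel_maps_to_zero_delay(self, small_etco2, grid):
        frames = np.arange(120) * 2.0
        gs = build_shifted_regressor(small_etco2, 7.0, frames) * 2.0 + 500.0
        data = np.tile(gs, (2, 1, 1, 1))
        bold = BoldVolume(data=data, affine=np.eye(4), mask=np.ones((2, 1, 1), bool), tr=2.0)
        gd = find_global_delay(bold.global_signal(), small_etco2, grid, frames)
        fit = voxelwise_lag_glm(bold, small_etco2, grid, gd)
        np.testing.assert_array_equal(fit.delay_map, 0.0)

    def test_matches_naive_exhaustive_loop(self, grid):
        """Vectorized fit equals a per-voxel per-shift brute-force OLS loop."""
        spec = PhantomSpec(shape=(4, 4, 3), n_frames=100, tsnr=20.0, seed=24)
        bold, _, _ = make_bold(spec)
        et = compute_etco2(make_capno(spec))
        gd = find_global_delay(bold.global_signal(), et, grid, bold.frame_times)
        fit = voxelwise_lag_glm(bold, et, grid, gd)

        frames = bold.frame_times
        shifts = gd + grid.shifts
        order = sorted(range(len(shifts)), key=lambda i: (abs(grid.shifts[i]), shifts[i]))
        regs = {i: build_shifted_regressor(et, shifts[i], frames) for i in range(len(shifts))}
        for idx in np.ndindex(*spec.shape):
            y = bold.data[idx]
            best = (-1.0, None)
            for i in order:
                x = regs[i]
                r = np.corrcoef(x, y)[0, 1]
                if abs(r) > best[0]:
                    best = (abs(r), i)
            i = best[1]
            X = np.column_stack([np.ones(len(frames)), regs[i]])
            b0, b1 = np.linalg.lstsq(X, y, rcond=None)[0]
            assert fit.delay_map[idx] == shifts[i] - gd
            np.testing.assert_allclose(fit.beta0_map[idx], b0, rtol=1e-10)
            np.testing.assert_allclose(fit.beta1_map[idx], b1, rtol=1e-10)

    def test_max_abs_r_and_min_rss_select_same_shift(self, small_etco2, grid):
        """Single-regressor identity: argmax |r| == argmin RSS per voxel."""
        rng = np.random.default_rng(31)
        frames = np.arange(120) * 2.0
        shifts = grid.shifts
        regs = [build_shifted_regressor(small_etco2, s, frames) for s in shifts]
        for _ in range(10):
            y = rng.standard_normal(120) + rng.uniform(-1, 1) * regs[20]
            rvals = np.array([abs(np.corrcoef(x, y)[0, 1]) for x in regs])
            rss = []
            for x in regs:
                X = np.column_stack([np.ones(120), x])
                resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
                rss.append(resid @ resid)
            assert np.argmax(rvals) == np.argmin(rss)

    def test_zero_variance_voxel_flagged_not_fatal(self, small_etco2, grid):
        frames = np.arange(120) * 2.0
        data = np.zeros((2, 1, 1, 120))
        data[0, 0, 0] = 300.0  # constant voxel
        data[1, 0, 0] = 300.0 + build_shifted_regressor(small_etco2, 2.0, frames)
        bold = BoldVolume(data, np.eye(4), np.ones((2, 1, 1), bool), tr=2.0)
        fit = voxelwise_lag_glm(bold, small_etco2, grid, 0.0)
        assert fit.n_degenerate == 1
        assert fit.delay_map[0, 0, 0] == 0.0
        assert fit.beta1_map[0, 0, 0] == 0.0
        assert fit.rmax_map[1, 0, 0] == pytest.approx(1.0, abs=1e-9)

    def test_positive_delay_means_later_response(self, small_etco2, grid):
        """Sign convention: a voxel lagging the global signal gets delay > 0."""
        frames = np.arange(120) * 2.0
        early = build_shifted_regressor(small_etco2, 0.0, frames)
        late = build_shifted_regressor(small_etco2, 5.0, frames)
        data = np.stack([np.tile(early, (2, 1)), np.tile(late, (2, 1))]).reshape(2, 2, 1, 120)
        bold = BoldVolume(data, np.eye(4), np.ones((2, 2, 1), bool), tr=2.0)
        gd = find_global_delay(bold.global_signal(), small_etco2, grid, frames)
        fit = voxelwise_lag_glm(bold, small_etco2, grid, gd)
        assert np.all(fit.delay_map[1] > fit.delay_map[0])
        assert fit.delay_map[1, 0, 0] - fit.delay_map[0, 0, 0] == pytest.approx(5.0, abs=grid.step)
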