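import warnings

import numpy as np
import pytest

from sysphantom.relaxometry import (ROISeries, deviation, fit_relaxivity,
                                    fit_t1_ir, fit_t1_ir_arrays, fit_t1_vfa,
                                    fit_t2_se, vfa_two_point_t1,
                                    estimate_noise_floor)
from sysphantom.simulate import (IR_TI_LIST, signal_ir, signal_se, signal_vfa)

TI = np.array(IR_TI_LIST)
TE = np.arange(10.0, 321.0, 10.0)
FLIPS = np.array([2, 3, 5, 7, 9, 11, 14, 18, 24, 30], dtype=float)


class TestInversionRecovery:
    @pytest.mark.parametrize("T1", [20.0, 62.98, 200.0, 407.0, 1007.6, 2000.0])
    def test_noiseless_recovery_within_0p1pct(self, T1):
        y = signal_ir(1.0, T1, TI, 0.85, 100.0)
        f = fit_t1_ir_arrays(TI, y)
        assert abs(f.T1 - T1) / T1 < 1e-3
        assert f.delta == pytest.approx(0.85, abs=1e-3)

    def test_perfect_inversion_recovers_delta_one(self):
        y = np.abs(1.0 - 2.0 * np.exp(-TI / 500.0))
        f = fit_t1_ir_arrays(TI, y)
        assert f.delta == pytest.approx(1.0, abs=1e-6)
        assert f.T1 == pytest.approx(500.0, rel=1e-6)

    def test_scaling_invariance(self):
        """A absorbs any overall signal scaling: T1 unchanged."""
        y = signal_ir(1.0, 300.0, TI, 0.85, 1.0)
        f1 = fit_t1_ir_arrays(TI, y)
        f2 = fit_t1_ir_arrays(TI, 1234.5 * y)
        assert f2.T1 == pytest.approx(f1.T1, rel=1e-8)
        assert f2.A == pytest.approx(1234.5 * f1.A, rel=1e-6)

    def test_short_t1_with_noise_carries_enlarged_stderr(self, rng):
        """With only the first TI informative (shortest T1 sphere), the fit
        must report an enlarged relative standard error."""
        T1 = 22.3
        y0 = signal_ir(1.0, T1, TI, 0.85, 100.0)
        rel_short = []
        rel_long = []
        for _ in range(10):
            y = np.abs(y0 + rng.normal(0, 1.0, len(TI)))
            rel_short.append(fit_t1_ir_arrays(TI, y).T1_stderr / T1)
            y1 = np.abs(signal_ir(1.0, 407.0, TI, 0.85, 100.0)
                        + rng.normal(0, 1.0, len(TI)))
            rel_long.append(fit_t1_ir_arrays(TI, y1).T1_stderr / 407.0)
        assert np.median(rel_short) > 3 * np.median(rel_long)

    def test_t1_above_tr_warns(self):
        y = signal_ir(1.0, 800.0, TI, 0.85, 100.0)
        s = ROISeries(1, TI, y)
        with pytest.warns(UserWarning, match="TR >> T1"):
            fit_t1_ir(s, TR=500.0)

    def test_voxel_map_agrees_with_roi_mean(self, rng):
        """Per-voxel T1 map averaged over the ROI agrees with the ROI-mean
        fit within combined standard errors."""
        T1 = 407.0
        y0 = signal_ir(1.0, T1, TI, 0.85, 100.0)
        vox = np.abs(y0[:, None] + rng.normal(0, 1.0, (len(TI), 40)))
        s = ROISeries(1, TI, vox.mean(axis=1), voxel_signals=vox)
        f_roi = fit_t1_ir(s, mode="roi_mean")
        f_map = fit_t1_ir(s, mode="voxel_map")
        comb = np.hypot(f_roi.T1_stderr, f_map.T1_stderr) + 1e-9
        assert abs(f_roi.T1 - f_map.T1) < 3 * max(comb, 0.01 * T1)


class TestVariableFlipAngle:
    @pytest.mark.parametrize("T1", [100.0, 407.0, 1000.0, 2000.0])
    def test_noiseless_recovery_within_0p1pct(self, T1):
        y = signal_vfa(1.0, T1, 5.37, FLIPS, 100.0)
        f = fit_t1_vfa(ROISeries(1, FLIPS, y), TR=5.37)
        assert abs(f.T1 - T1) / T1 < 1e-3

    def test_two_point_closed_form_matches_fit(self):
        y = signal_vfa(1.0, 407.0, 5.37, FLIPS, 100.0)
        t1_2pt = vfa_two_point_t1(FLIPS[2], y[2], FLIPS[7], y[7], 5.37)
        f = fit_t1_vfa(ROISeries(1, FLIPS, y), TR=5.37)
        assert t1_2pt == pytest.approx(f.T1, rel=1e-6)

    def test_signal_max_at_rendered_flip_nearest_ernst(self):
        y = signal_vfa(1.0, 407.0, 5.37, FLIPS, 100.0)
        ae = np.rad2deg(np.arccos(np.exp(-5.37 / 407.0)))
        assert FLIPS[np.argmax(y)] == FLIPS[np.argmin(np.abs(FLIPS - ae))]

    def test_one_sided_flips_warn(self):
        flips = np.array([20.0, 24.0, 28.0])   # all above Ernst for long T1
        y = signal_vfa(1.0, 1500.0, 5.37, flips, 100.0)
        with pytest.warns(UserWarning, match="Ernst"):
            fit_t1_vfa(ROISeries(1, flips, y), TR=5.37)

    def test_scaling_invariance(self):
        y = signal_vfa(1.0, 300.0, 5.37, FLIPS, 1.0)
        f1 = fit_t1_vfa(ROISeries(1, FLIPS, y), TR=5.37)
        f2 = fit_t1_vfa(ROISeries(1, FLIPS, 77.7 * y), TR=5.37)
        assert f2.T1 == pytest.approx(f1.T1, rel=1e-8)


class TestSpinEcho:
    @pytest.mark.parametrize("T2", [25.0, 100.0, 400.0])
    def test_noiseless_exact(self, T2):
        y = signal_se(1.0, T2, TE, 100.0)
        f = fit_t2_se(ROISeries(1, TE, y))
        assert f.T2 == pytest.approx(T2, rel=1e-8)

    def test_floor_exclusion_reduces_rician_bias(self, rng):
        """Excluding echoes below the noise floor reduces the |bias| of T2
        relative to fitting all points, under Rician noise (paired sim)."""
        T2, sigma = 60.0, 2.0
        y0 = signal_se(1.0, T2, TE, 100.0)
        floor = sigma * np.sqrt(np.pi / 2) + 2 * sigma * np.sqrt(2 - np.pi / 2)
        err_all, err_excl = [], []
        for _ in range(100):
            y = np.hypot(y0 + rng.normal(0, sigma, len(TE)),
                         rng.normal(0, sigma, len(TE)))
            s = ROISeries(1, TE, y)
            err_all.append(fit_t2_se(s).T2 - T2)
            err_excl.append(fit_t2_se(s, noise_floor=floor).T2 - T2)
        assert abs(np.mean(err_excl)) < abs(np.mean(err_all))

    def test_first_echo_drop_recorded(self):
        y = signal_se(1.0, 100.0, TE, 100.0)
        f = fit_t2_se(ROISeries(1, TE, y), drop_first_echo=True)
        assert f.excluded_points[0][0] == 0
        assert "first echo" in f.excluded_points[0][1]
        assert f.n_points_used == len(TE) - 1

    def test_too_few_points_after_exclusion(self):
        y = signal_se(1.0, 10.0, TE, 1.0)
        with pytest.raises(ValueError, match="3 usable"):
            fit_t2_se(ROISeries(1, TE, y), noise_floor=1.0)

    def test_noise_floor_estimate(self, rng):
        bg = rng.normal(10.0, 2.0, 10000)
        floor = estimate_noise_floor(bg, multiplier=2.0)
        assert floor == pytest.approx(14.0, rel=0.03)


class TestDeviation:
    def test_basic_values(self):
        assert deviation(100.0, 100.0) == 0.0
        assert deviation(110.0, 100.0) == pytest.approx(10.0)

    def test_archival_t1_pair(self):
        # stability check of an archived short-T1 sample re-measured 4 years on
        assert round(deviation(44.67, 44.53), 1) == 0.3

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError):
            deviation(100.0, 0.0)


class TestRelaxivity:
    def test_two_exact_points(self):
        C = np.array([1.0, 2.0])
        rates = 0.6 * C + 0.33          # 1/s
        times = 1000.0 / rates
        f = fit_relaxivity(C, times, water_rate_s=0.33)
        assert f.relaxivity == pytest.approx(0.6, rel=1e-12)

    def test_zero_concentration_reads_water_rate(self):
        f = fit_relaxivity([1.0, 2.0], [1000 / 0.93, 1000 / 1.53],
                           water_rate_s=0.33)
        assert f.intercept_rate == 0.33

    def test_free_intercept_mode(self):
        C = np.array([0.5, 1.0, 2.0, 4.0])
        rates = 0.6 * C + 0.4
        f = fit_relaxivity(C, 1000.0 / rates)
        assert f.relaxivity == pytest.approx(0.6, rel=1e-9)
        assert f.intercept_rate == pytest.approx(0.4, rel=1e-9)

    def test_slope_coverage_over_200_reps(self, rng):
        """Simulated noisy rates: the stderr-based 95% interval covers the
        true relaxivity in >= 90% of 200 repetitions."""
        C = np.array([0.05, 0.1, 0.2, 0.4, 0.8, 1.6])
        r_true, w = 0.64, 0.33
        hits = 0
        for _ in range(200):
            rates = r_true * C + w + rng.normal(0, 0.01, len(C))
            f = fit_relaxivity(C, 1000.0 / rates, water_rate_s=w)
            hits += abs(f.relaxivity - r_true) <= 2.57 * f.relaxivity_stderr
        assert hits >= 180

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            fit_relaxivity([-1.0, 1.0], [100.0, 100.0], 0.33)
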