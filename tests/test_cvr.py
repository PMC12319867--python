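"""Lagged-GLM CVR mapping: PSC, alignment, voxel fits, cluster masks."""
import numpy as np
import pytest

from bhcvr.cvr import (
    CvrConfig,
    bulk_align,
    extreme_delay_mask,
    fit_voxel,
    lag_family,
    map_cvr,
    percent_signal_change,
    _legendre_basis,
)
from bhcvr.physio import Trace


def _regressor(n=6000, fs=10.0, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    x = np.sin(2 * np.pi * t / 53.0) + 0.4 * np.sin(2 * np.pi * t / 17.0)
    return Trace(x + 0.02 * rng.normal(size=n), fs=fs, units="mmHg", t0=-30.0)


class TestPsc:
    def test_constant_voxel_all_zero(self):
        bold = np.full((2, 2, 1, 50), 500.0)
        psc, mask = percent_signal_change(bold)
        assert np.all(psc == 0)
        assert mask.all()

    def test_two_point_arithmetic(self):
        bold = np.array([900.0, 1100.0]).reshape(1, 1, 1, 2)
        psc, _ = percent_signal_change(bold)
        assert np.allclose(psc.ravel(), [-10.0, 10.0])

    def test_zero_mean_voxel_excluded(self):
        bold = np.zeros((1, 2, 1, 10))
        bold[0, 0, 0] = 1000.0
        psc, mask = percent_signal_change(bold)
        assert mask[0, 0, 0] and not mask[0, 1, 0]

    def test_output_mean_zero_per_voxel(self):
        rng = np.random.default_rng(0)
        bold = 1000 + rng.normal(0, 10, size=(3, 3, 2, 40))
        psc, mask = percent_signal_change(bold)
        assert np.allclose(psc[mask].mean(axis=-1), 0.0, atol=1e-10)


class TestBulkAlign:
    def test_recovers_constructed_delay(self):
        reg = _regressor()
        t_scan = np.arange(200) * 1.5
        gm = Trace(np.interp(t_scan - 6.0, reg.times(), reg.samples), fs=1 / 1.5)
        res = bulk_align(reg, gm, bound=30.0)
        assert res.shift == pytest.approx(6.0, abs=0.1)

    def test_identical_signals_zero_shift(self):
        reg = _regressor()
        t_scan = np.arange(200) * 1.5
        gm = Trace(np.interp(t_scan, reg.times(), reg.samples), fs=1 / 1.5)
        assert bulk_align(reg, gm).shift == 0.0

    def test_anticorrelated_regressor_reports_negative_score(self):
        reg = _regressor()
        t_scan = np.arange(200) * 1.5
        gm = Trace(-np.interp(t_scan, reg.times(), reg.samples), fs=1 / 1.5)
        res = bulk_align(reg, gm)
        assert res.score < -0.9
        assert res.shift == pytest.approx(0.0, abs=0.2)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            bulk_align(Trace(np.ones(100), fs=10), Trace(np.ones(100), fs=10))


class TestLagFamily:
    def test_column_count(self):
        fam = lag_family(_regressor(), CvrConfig(max_lag=9.0, lag_step=0.3), tr=1.5, n_volumes=100)
        assert fam.shape == (100, 61)
        fam15 = lag_family(_regressor(), CvrConfig.pathology(), tr=1.5, n_volumes=100)
        assert fam15.shape == (100, 101)

    def test_zero_lag_column_is_plain_resampling(self):
        reg = _regressor()
        cfg = CvrConfig()
        fam = lag_family(reg, cfg, tr=1.5, n_volumes=150)
        t_scan = np.arange(150) * 1.5
        direct = np.interp(t_scan, reg.times(), reg.samples)
        j0 = np.flatnonzero(cfg.lags() == 0)[0]
        assert np.allclose(fam[:, j0], direct)

    def test_opposite_shifts_invert(self):
        reg = _regressor()
        t = np.arange(100) * 1.5 + 40.0
        fwd = np.interp(t - 3.0, reg.times(), reg.samples)
        back = np.interp((t - 3.0) + 3.0, reg.times(), reg.samples)
        assert np.allclose(back, np.interp(t, reg.times(), reg.samples), atol=1e-9)
        assert not np.allclose(fwd, back)


class TestFitVoxel:
    def _family(self, cfg, n_vol=200):
        reg = _regressor()
        return lag_family(reg, cfg, tr=1.5, n_volumes=n_vol), reg

    def test_recovers_noiseless_amplitude_and_delay(self):
        cfg = CvrConfig()
        fam, reg = self._family(cfg)
        t = np.arange(200) * 1.5
        x = np.interp(t - 2.1, reg.times(), reg.samples)
        drift = 0.5 * (t / t[-1]) ** 2
        y = 0.3 * x + drift
        nuis = _legendre_basis(200, 4)
        amp, delay, r2, boundary = fit_voxel(y, fam, nuis, cfg)
        assert amp == pytest.approx(0.3, abs=1e-6)
        assert delay == pytest.approx(2.1, abs=0.15)
        assert not boundary

    def test_pure_drift_gives_zero_amplitude(self):
        cfg = CvrConfig()
        fam, _ = self._family(cfg)
        t = np.arange(200) * 1.5
        y = 1.0 + 0.01 * t + 1e-5 * t**2
        nuis = _legendre_basis(200, 4)
        amp, _, _, _ = fit_voxel(y, fam, nuis, cfg)
        assert abs(amp) < 1e-8

    def test_brute_force_oracle_equivalence(self):
        """Betas and lag choice match per-lag OLS via lstsq on random voxels."""
        cfg = CvrConfig(max_lag=6.0)
        fam, _ = self._family(cfg, n_vol=120)
        nuis = _legendre_basis(120, 4)
        rng = np.random.default_rng(42)
        lags = cfg.lags()
        for _ in range(20):
            true_lag = rng.choice(lags)
            j = np.flatnonzero(np.isclose(lags, true_lag))[0]
            y = rng.uniform(0.05, 0.5) * fam[:, j] + nuis @ rng.normal(0, 0.3, 5)
            y = y + 0.01 * rng.normal(size=120)
            amp, delay, r2, _ = fit_voxel(y, fam, nuis, cfg)
            # independent oracle: full OLS per lag, argmax R2
            best = (-np.inf, None, None)
            for jj in range(fam.shape[1]):
                X = np.column_stack([fam[:, jj], nuis])
                beta, *_ = np.linalg.lstsq(X, y, rcond=None)
                resid = y - X @ beta
                ss = 1 - resid @ resid / np.sum((y - y.mean()) ** 2)
                if ss > best[0] + 1e-12:
                    best = (ss, jj, beta[0])
            assert np.isclose(lags[best[1]], delay, atol=1e-9)
            assert amp == pytest.approx(best[2], abs=1e-8)

    def test_boundary_flagging(self):
        cfg = CvrConfig(max_lag=3.0)
        fam, reg = self._family(cfg)
        t = np.arange(200) * 1.5
        y = 0.2 * np.interp(t - 3.0, reg.times(), reg.samples)
        nuis = _legendre_basis(200, 4)
        _, delay, _, boundary = fit_voxel(y, fam, nuis, cfg)
        assert boundary  # lag sits on the outermost grid points


class TestAmplitudeEquivariance:
    def test_regressor_scaling_divides_amplitude(self, processed):
        from bhcvr.synthetic import PhantomSpec, gen_phantom, phantom_regressor

        pspec = PhantomSpec(shape=(4, 4, 2), n_volumes=120, noise_sigma=0.0, seed=1)
        bold = gen_phantom(pspec, processed.petco2_uncorrected)
        reg = phantom_regressor(processed.petco2_uncorrected, pspec)
        mask = np.ones(pspec.shape, bool)
        base = map_cvr(bold, mask, pspec.gm_mask, reg, CvrConfig(), tr=1.5)
        reg2 = reg.copy(samples=2.0 * reg.samples)
        halved = map_cvr(bold, mask, pspec.gm_mask, reg2, CvrConfig(), tr=1.5)
        assert np.allclose(halved.amplitude, base.amplitude / 2.0, atol=1e-8)
        # PSC invariance: scaling BOLD leaves amplitude unchanged
        scaled = map_cvr(3.0 * bold, mask, pspec.gm_mask, reg, CvrConfig(), tr=1.5)
        assert np.allclose(scaled.amplitude, base.amplitude, atol=1e-8)


class TestMapCvr:
    def test_delay_normalized_has_zero_gm_median(self, processed):
        from bhcvr.synthetic import PhantomSpec, gen_phantom, phantom_regressor

        pspec = PhantomSpec(shape=(6, 6, 2), n_volumes=150, noise_sigma=0.02, seed=2)
        bold = gen_phantom(pspec, processed.petco2_uncorrected)
        reg = phantom_regressor(processed.petco2_uncorrected, pspec)
        maps = map_cvr(bold, np.ones(pspec.shape, bool), pspec.gm_mask, reg,
                       CvrConfig(), tr=1.5)
        med = np.nanmedian(maps.delay_normalized[pspec.gm_mask])
        assert abs(med) <= 0.3 + 1e-9

    def test_empty_gm_mask_rejected(self):
        with pytest.raises(ValueError):
            map_cvr(np.zeros((2, 2, 1, 10)), np.ones((2, 2, 1), bool),
                    np.zeros((2, 2, 1), bool), _regressor(), CvrConfig(), tr=1.5)

    def test_delays_on_lag_grid_relative_to_bulk(self, processed):
        from bhcvr.synthetic import PhantomSpec, gen_phantom, phantom_regressor

        pspec = PhantomSpec(shape=(4, 4, 2), n_volumes=120, noise_sigma=0.05, seed=3)
        bold = gen_phantom(pspec, processed.petco2_uncorrected)
        reg = phantom_regressor(processed.petco2_uncorrected, pspec)
        cfg = CvrConfig()
        maps = map_cvr(bold, np.ones(pspec.shape, bool), pspec.gm_mask, reg, cfg, tr=1.5)
        rel = (maps.delay[maps.valid_mask] - maps.bulk_shift) / cfg.lag_step
        rel = rel[np.isfinite(rel)]
        assert np.allclose(rel, np.round(rel), atol=1e-6)


class TestExtremeDelayMask:
    def test_large_cluster_retained(self):
        delay = np.zeros((10, 10, 10))
        delay[2:5, 2:5, 2:4] = 12.0  # 18 voxels
        out = extreme_delay_mask(delay)
        assert out.sum() == 18

    def test_scattered_voxels_removed(self):
        delay = np.zeros((10, 10, 10))
        for i in range(0, 10, 3):
            delay[i, i % 10, (2 * i) % 10] = 14.0
        assert extreme_delay_mask(delay).sum() == 0

    def test_touching_groups_merge_by_face_connectivity(self):
        delay = np.zeros((10, 10, 4))
        delay[1:3, 1:3, 0:2] = 11.0  # 8 voxels
        delay[3:5, 1:3, 0:2] = 11.0  # 8 voxels, face-adjacent to the first
        out = extreme_delay_mask(delay, min_cluster=15)
        assert out.sum() == 16

    def test_diagonal_contact_does_not_merge(self):
        delay = np.zeros((10, 10, 4))
        delay[1:3, 1:3, 0:2] = 11.0
        delay[3:5, 3:5, 0:2] = 11.0  # corner contact only
        assert extreme_delay_mask(delay, min_cluster=15).sum() == 0
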