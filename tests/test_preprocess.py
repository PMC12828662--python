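"""Preprocessing stages: discard, motion QC, nuisance, band-pass, lag."""

import numpy as np
import pandas as pd
import pytest

from strokeconn import preprocess as pp


def _ts(rng, t=200, m=4):
    return pd.DataFrame(rng.standard_normal((t, m)),
                        columns=[f"m{i}" for i in range(m)])


class TestDiscardInitial:
    def test_default_removes_five(self, rng):
        out = pp.discard_initial(_ts(rng, t=240), 5)
        assert len(out) == 235

    def test_zero_is_identity(self, rng):
        ts = _ts(rng)
        pd.testing.assert_frame_equal(pp.discard_initial(ts, 0), ts)

    def test_empty_output_forbidden(self, rng):
        with pytest.raises(ValueError):
            pp.discard_initial(_ts(rng, t=5), 5)


class TestMotionQC:
    def test_zero_motion_kept(self):
        qc = pp.motion_qc(pd.DataFrame(np.zeros((50, 6))))
        assert qc.keep and qc.mean_fd == 0.0

    def test_translation_step_excludes(self):
        p = np.zeros((50, 6))
        p[20:, 0] = 4.0  # 4 mm > 3 mm
        qc = pp.motion_qc(pd.DataFrame(p))
        assert not qc.keep and "translation" in qc.reason

    def test_rotation_step_excludes(self):
        p = np.zeros((50, 6))
        p[20:, 4] = 3.5  # degrees
        qc = pp.motion_qc(pd.DataFrame(p))
        assert not qc.keep and "rotation" in qc.reason

    def test_constructed_mean_fd_excludes(self):
        # alternating +-c/2 translation: every frame diff is c, max
        # displacement stays c/2; choose c so the mean FD is exactly 0.6
        t = 100
        c = 0.6 * t / (t - 1)
        p = np.zeros((t, 6))
        p[:, 0] = (np.arange(t) % 2) * c
        fd = pp.framewise_displacement(pd.DataFrame(p))
        assert fd.mean() == pytest.approx(0.6)
        qc = pp.motion_qc(pd.DataFrame(p))
        assert not qc.keep and "FD" in qc.reason

    def test_rotation_contributes_arc_length(self):
        # a 1-degree step on one rotation axis adds pi/180*50 mm of FD
        p = np.zeros((10, 6))
        p[5:, 3] = 1.0
        fd = pp.framewise_displacement(pd.DataFrame(p))
        assert fd[5] == pytest.approx(np.deg2rad(1.0) * 50.0)

    def test_malformed_table_rejected(self):
        with pytest.raises(ValueError):
            pp.motion_qc(pd.DataFrame(np.zeros((50, 4))))


class TestScrub:
    def test_censors_high_fd_frames(self, rng):
        ts = _ts(rng, t=50)
        p = np.zeros((50, 6))
        p[10, 0] = 2.0  # spike: FD at frames 10 and 11
        out, keep = pp.scrub(ts, pd.DataFrame(p), fd_threshold=0.5)
        assert keep.sum() == 48
        assert len(out) == 48


class TestNuisanceRegress:
    def test_residuals_orthogonal_to_regressors(self, rng):
        ts = _ts(rng)
        reg = pd.DataFrame(rng.standard_normal((200, 3)), columns=list("abc"))
        resid = pp.nuisance_regress(ts, reg)
        for col in reg:
            prods = resid.T @ (reg[col] - 0)
            assert np.abs(prods).max() < 1e-8

    def test_series_as_own_regressor_gives_zero(self, rng):
        ts = _ts(rng, m=1)
        resid = pp.nuisance_regress(ts, ts.rename(columns={"m0": "g"}))
        assert np.abs(resid.to_numpy()).max() < 1e-10

    def test_planted_confound_removed(self, rng):
        g = rng.standard_normal(200)
        e = rng.standard_normal(200)
        ts = pd.DataFrame({"y": 2 * g + e})
        resid = pp.nuisance_regress(ts, pd.DataFrame({"g": g}))
        assert abs(np.corrcoef(resid["y"], g)[0, 1]) < 1e-10

    def test_idempotent(self, rng):
        ts = _ts(rng)
        reg = pd.DataFrame(rng.standard_normal((200, 2)))
        once = pp.nuisance_regress(ts, reg)
        twice = pp.nuisance_regress(once, reg)
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(), atol=1e-10)

    def test_collinear_design_rejected(self, rng):
        x = rng.standard_normal(200)
        reg = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="collinear"):
            pp.nuisance_regress(_ts(rng), reg)


class TestBandpass:
    TR = 2.0

    def test_passband_sinusoid_preserved(self):
        t = np.arange(256) * self.TR
        x = pd.DataFrame({"s": np.sin(2 * np.pi * 0.04 * t)})
        y = pp.bandpass(x, self.TR)
        assert np.corrcoef(x["s"], y["s"])[0, 1] > 0.99
        assert y["s"].var() == pytest.approx(x["s"].var(), rel=0.05)

    def test_stopband_sinusoid_attenuated(self):
        t = np.arange(256) * self.TR
        x = pd.DataFrame({"s": np.sin(2 * np.pi * 0.2 * t)})
        y = pp.bandpass(x, self.TR)
        assert y["s"].var() < 0.1 * x["s"].var()

    def test_white_noise_variance_reduced(self, rng):
        x = _ts(rng, t=300, m=1)
        y = pp.bandpass(x, self.TR)
        assert y.to_numpy().var() < x.to_numpy().var()

    def test_linearity(self, rng):
        x = _ts(rng, t=128, m=1)
        y = _ts(rng, t=128, m=1)
        lhs = pp.bandpass(2 * x + 3 * y, self.TR)
        rhs = 2 * pp.bandpass(x, self.TR) + 3 * pp.bandpass(y, self.TR)
        np.testing.assert_allclose(lhs.to_numpy(), rhs.to_numpy(), atol=1e-10)

    def test_high_cut_above_nyquist_rejected(self, rng):
        with pytest.raises(ValueError):
            pp.bandpass(_ts(rng), self.TR, 0.01, 0.3)


def _smooth_signal(rng, t=300, tr=2.0):
    """Temporally smooth reference: band-limited noise."""
    x = pd.DataFrame({"s": rng.standard_normal(t)})
    return pp.bandpass(x, tr, 0.01, 0.08)["s"].to_numpy()


class TestLagEstimation:
    TR = 2.0

    def test_self_lag_zero(self, rng):
        x = _smooth_signal(rng)
        assert pp.estimate_lag(x, x, self.TR) == 0.0

    def test_planted_integer_lag_recovered(self, rng):
        ref = _smooth_signal(rng)
        lagged = np.roll(ref, 2)  # delayed by 2 samples = 2 TR
        tau = pp.estimate_lag(lagged[5:-5], ref[5:-5], self.TR)
        assert round(tau / self.TR) == 2

    def test_antisymmetric_at_integer_resolution(self, rng):
        ref = _smooth_signal(rng)
        lagged = np.roll(ref, 3)[5:-5]
        a = pp.estimate_lag(lagged, ref[5:-5], self.TR)
        b = pp.estimate_lag(ref[5:-5], lagged, self.TR)
        assert round(a / self.TR) == -round(b / self.TR)

    def test_subsample_lag_within_quarter_tr(self, rng):
        ref = _smooth_signal(rng, t=500)
        t = np.arange(500) * self.TR
        lagged = np.interp(t - 0.5 * self.TR, t, ref)
        tau = pp.estimate_lag(lagged[10:-10], ref[10:-10], self.TR)
        assert abs(tau - 0.5 * self.TR) <= 0.25 * self.TR

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pp.estimate_lag(np.ones(100), np.arange(100.0), self.TR)


class TestLagCorrection:
    TR = 2.0

    def test_zero_lags_identity(self, rng):
        ts = _ts(rng)
        lags = pp.LagMap(lags=pd.Series(0.0, index=ts.columns), search_range=8.0)
        pd.testing.assert_frame_equal(
            pp.apply_lag_correction(ts, lags, self.TR), ts
        )

    def test_round_trip_lag_re_estimate_zero(self, rng):
        ref = _smooth_signal(rng, t=400)
        t = np.arange(400) * self.TR
        ts = pd.DataFrame({
            "ref": ref,
            "lagged": np.interp(t - 2 * self.TR, t, ref),
        })
        lag_map = pp.estimate_lag_map(ts, self.TR, reference=ref)
        assert round(lag_map.lags["lagged"] / self.TR) == 2
        fixed = pp.apply_lag_correction(ts, lag_map, self.TR)
        re_lag = pp.estimate_lag(
            fixed["lagged"].to_numpy(), ref, self.TR
        )
        assert round(re_lag / self.TR) == 0

    def test_correction_restores_anti_lagged_correlation(self, rng):
        ref = _smooth_signal(rng, t=400)
        t = np.arange(400) * self.TR
        ts = pd.DataFrame({
            "plus": np.interp(t - self.TR, t, ref),
            "minus": np.interp(t + self.TR, t, ref),
        })
        before = np.corrcoef(ts["plus"], ts["minus"])[0, 1]
        lag_map = pp.estimate_lag_map(ts, self.TR, reference=ref)
        fixed = pp.apply_lag_correction(ts, lag_map, self.TR)
        after = np.corrcoef(fixed["plus"], fixed["minus"])[0, 1]
        assert after > before
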