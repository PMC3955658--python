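"""Preprocessing chain: each step's contract, oracles, and the full chain."""

import numpy as np
import pytest

import surfreho as sr
from surfreho.preprocess import (PreprocessParams, RegressorMatrix, SurfaceBold,
                                 VolumeBold, bandpass, compute_rmsfd, detrend,
                                 drop_initial_volumes, friston24,
                                 intensity_normalize, nuisance_regress,
                                 preprocess_surface, vol_to_surf)

from helpers import ols_residuals


def make_bold(rng, v=8, t=212, tr=2.0):
    return SurfaceBold(100.0 + rng.standard_normal((v, t)), tr)


class TestDropAndNormalize:
    def test_drop_five_of_212(self, rng):
        out = drop_initial_volumes(make_bold(rng), 5)
        assert out.n_frames == 207
        assert out.frames_dropped == 5

    def test_drop_zero_is_identity(self, rng):
        b = make_bold(rng)
        np.testing.assert_array_equal(drop_initial_volumes(b, 0).data, b.data)

    def test_drop_all_frames_rejected(self, rng):
        with pytest.raises(ValueError):
            drop_initial_volumes(make_bold(rng, t=5), 5)

    def test_normalized_grand_mean_exact(self, rng):
        out = intensity_normalize(make_bold(rng))
        assert out.data.mean() == pytest.approx(10000.0, abs=1e-9)

    def test_normalize_idempotent_and_scale_invariant(self, rng):
        b = make_bold(rng)
        once = intensity_normalize(b)
        twice = intensity_normalize(once)
        np.testing.assert_allclose(twice.data, once.data, rtol=1e-12)
        prescaled = intensity_normalize(SurfaceBold(3.3 * b.data, b.tr))
        np.testing.assert_allclose(prescaled.data, once.data, rtol=1e-12)

    def test_nonpositive_mean_rejected(self, rng):
        b = SurfaceBold(-np.abs(rng.standard_normal((3, 10))) - 1, 2.0)
        with pytest.raises(ValueError):
            intensity_normalize(b)


class TestFriston24:
    def test_column_count_and_lag_structure(self, rng):
        mo = rng.standard_normal((30, 6))
        f = friston24(mo)
        assert f.values.shape == (30, 24)
        # independently constructed lag matrix
        lag = np.zeros_like(mo)
        lag[1:] = mo[:-1]
        np.testing.assert_array_equal(f.values[:, 6:12], lag)
        np.testing.assert_array_equal(f.values[:, 12:18], mo**2)
        np.testing.assert_array_equal(f.values[:, 18:24], lag**2)

    def test_zero_trace_gives_zero_matrix(self):
        assert not friston24(np.zeros((10, 6))).values.any()


class TestNuisanceRegression:
    def test_residuals_match_normal_equations_oracle(self, rng):
        b = make_bold(rng, v=5, t=60)
        R = RegressorMatrix(rng.standard_normal((60, 4)))
        out = nuisance_regress(b, R)
        X = np.column_stack([np.ones(60), R.values])
        for v in range(5):
            ref = ols_residuals(b.data[v], X) + b.data[v].mean()
            np.testing.assert_allclose(out.data[v], ref, atol=1e-9)

    def test_residuals_orthogonal_to_regressors(self, rng):
        b = make_bold(rng, v=6, t=100)
        R = RegressorMatrix(rng.standard_normal((100, 5)))
        out = nuisance_regress(b, R)
        centered = out.data - out.data.mean(axis=1, keepdims=True)
        inner = centered @ R.values
        scale = np.linalg.norm(centered) * np.linalg.norm(R.values)
        assert np.abs(inner).max() / scale < 1e-10

    def test_perfect_fit_leaves_constant(self, rng):
        series = rng.standard_normal(50)
        b = SurfaceBold(np.tile(series, (2, 1)) + 100, 2.0)
        out = nuisance_regress(b, RegressorMatrix(series[:, None]))
        assert np.ptp(out.data, axis=1).max() < 1e-9

    def test_empty_regressors_identity(self, rng):
        b = make_bold(rng)
        np.testing.assert_array_equal(nuisance_regress(b, None).data, b.data)

    def test_collinear_columns_named(self, rng):
        x = rng.standard_normal(40)
        R = RegressorMatrix(np.column_stack([x, 2 * x]), ["a", "b"])
        with pytest.raises(ValueError, match="collinear"):
            nuisance_regress(make_bold(rng, t=40), R)


class TestBandpass:
    @pytest.mark.parametrize("method", ["butterworth", "fft"])
    def test_passband_and_stopband_ratios(self, method):
        tr, n = 2.0, 250
        t = np.arange(n) * tr

        def ratio(freq):
            sig = np.sin(2 * np.pi * freq * t)[None, :]
            out = bandpass(SurfaceBold(sig, tr), method=method).data[0]
            fr = np.fft.rfftfreq(n, tr)
            i = np.argmin(np.abs(fr - freq))
            return np.abs(np.fft.rfft(out))[i] / np.abs(np.fft.rfft(sig[0]))[i]

        assert ratio(0.05) >= 0.9
        assert ratio(0.2) <= 0.1

    def test_constant_series_zero_mean_output(self):
        out = bandpass(SurfaceBold(np.full((2, 200), 7.0), 2.0))
        assert np.abs(out.data.mean()) < 1e-6

    def test_high_edge_at_nyquist_rejected(self, rng):
        with pytest.raises(ValueError):
            bandpass(make_bold(rng), high=0.25)


class TestDetrend:
    def test_quadratic_input_removed(self):
        t = np.arange(100, dtype=float)
        sig = (3 + 0.5 * t - 0.01 * t**2)[None, :]
        out = detrend(SurfaceBold(sig, 2.0))
        assert np.abs(out.data).max() < 1e-8

    def test_idempotent_and_matches_polyfit_oracle(self, rng):
        b = make_bold(rng, v=4, t=80)
        out = detrend(b)
        t = np.arange(80, dtype=float)
        X = np.column_stack([np.ones(80), t, t**2])
        for v in range(4):
            np.testing.assert_allclose(out.data[v], ols_residuals(b.data[v], X), atol=1e-8)
        again = detrend(out)
        np.testing.assert_allclose(again.data, out.data, atol=1e-8)

    def test_too_few_frames_rejected(self, rng):
        with pytest.raises(ValueError):
            detrend(make_bold(rng, t=3), order=2)


class TestFramewiseDisplacement:
    def test_zero_motion(self):
        assert compute_rmsfd(np.zeros((10, 6))) == 0.0

    def test_single_translation_step(self):
        m = np.zeros((2, 6))
        m[1, 0] = 1.0
        assert compute_rmsfd(m) == pytest.approx(1.0)

    def test_matches_two_pass_oracle(self, rng):
        m = rng.standard_normal((50, 6)) * 0.1
        fd = []
        for t in range(1, 50):
            d = m[t] - m[t - 1]
            fd.append(abs(d[0]) + abs(d[1]) + abs(d[2])
                      + 50 * (abs(d[3]) + abs(d[4]) + abs(d[5])))
        ref = float(np.sqrt(np.mean(np.square(fd))))
        assert compute_rmsfd(m) == pytest.approx(ref, rel=1e-12)


def _centered_affine():
    aff = np.eye(4)
    aff[:3, 3] = -2.0  # 5^3 grid spanning world [-2, 2]^3
    return aff


class TestVolToSurf:
    def test_constant_volume(self, rng):
        mesh = sr.build_icosphere(1, 1.0)
        vol = VolumeBold(np.full((5, 5, 5, 3), 4.2), _centered_affine())
        np.testing.assert_allclose(vol_to_surf(vol, mesh).data, 4.2)

    def test_exact_on_affine_field(self):
        mesh = sr.build_icosphere(1, 1.5)
        aff = _centered_affine()
        ijk = np.stack(np.meshgrid(*[np.arange(5)] * 3, indexing="ij"))
        world = np.einsum("ab,bxyz->axyz", aff[:3, :3], ijk) + aff[:3, 3, None, None, None]
        field = 2 * world[0] + 3 * world[1] - world[2] + 5
        out = vol_to_surf(VolumeBold(field[..., None], aff), mesh)
        expect = 2 * mesh.vertices[:, 0] + 3 * mesh.vertices[:, 1] - mesh.vertices[:, 2] + 5
        np.testing.assert_allclose(out.data[:, 0], expect, atol=1e-12)

    def test_vertex_outside_fov_listed(self):
        mesh = sr.build_icosphere(0, 10.0)
        vol = VolumeBold(np.zeros((3, 3, 3, 2)), np.eye(4))
        with pytest.raises(ValueError, match="field of view"):
            vol_to_surf(vol, mesh)


class TestChain:
    def test_chain_is_deterministic_and_logs_order(self, rng):
        b = make_bold(rng, v=12)
        motion = rng.standard_normal((212, 6)) * 0.05
        wm, csf = rng.standard_normal((2, 212))
        out1, info1 = preprocess_surface(b, motion, wm, csf)
        out2, info2 = preprocess_surface(b, motion, wm, csf)
        np.testing.assert_array_equal(out1.data, out2.data)
        assert info1["order"] == list(PreprocessParams().order)
        assert out1.n_frames == 207

    def test_full_chain_output_uncorrelated_with_regressors(self, rng):
        b = make_bold(rng, v=30, t=212)
        motion = np.cumsum(rng.standard_normal((212, 6)) * 0.02, axis=0)
        wm, csf = rng.standard_normal((2, 212))
        out, _ = preprocess_surface(b, motion, wm, csf)
        reg = np.column_stack([wm[5:], csf[5:], friston24(motion[5:]).values])
        reg = reg - reg.mean(axis=0)
        keep = reg.std(axis=0) > 0
        d = out.data - out.data.mean(axis=1, keepdims=True)
        corr = (d / d.std(axis=1, keepdims=True)) @ (reg[:, keep] / reg[:, keep].std(axis=0)) / 207
        assert np.abs(corr).max() < 0.05
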