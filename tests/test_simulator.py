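"""Speckle simulator: phantoms, static/dynamic speckle, sensor noise."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import speckleflow as sf
from speckleflow.lsci import LABEL_CODES, LABEL_WELL


class TestMakePhantom:
    def test_no_regions_gives_constant_background(self):
        ph = sf.make_phantom(sf.SceneParams(height_px=16, width_px=16,
                                            background_tau_c_ms=5.0))
        assert np.all(ph.tau_c_map == 5.0)
        assert np.all(ph.label_map == LABEL_WELL)

    def test_half_frame_rectangle_pixel_count(self):
        reg = sf.Region("poor", "rect", (0, 10, 0, 5), 50.0)
        ph = sf.make_phantom(sf.SceneParams(height_px=10, width_px=10,
                                            regions=(reg,),
                                            background_tau_c_ms=2.0))
        assert np.count_nonzero(ph.label_map == LABEL_CODES["poor"]) == 50
        assert set(np.unique(ph.tau_c_map)) == {2.0, 50.0}

    def test_zero_falloff_means_flat_illumination(self):
        ph = sf.make_phantom(sf.SceneParams(height_px=12, width_px=20,
                                            illumination_falloff=0.0))
        assert np.all(ph.illumination_map == 1.0)

    def test_corner_illumination_equals_one_minus_falloff(self):
        ph = sf.make_phantom(sf.SceneParams(height_px=33, width_px=33,
                                            illumination_falloff=0.4))
        assert ph.illumination_map[0, 0] == pytest.approx(0.6)
        assert ph.illumination_map[16, 16] == pytest.approx(1.0)
        assert ph.illumination_map.min() >= 0.6 - 1e-12

    def test_region_outside_frame_rejected_by_index(self):
        reg = sf.Region("poor", "rect", (0, 40, 0, 5), 50.0)
        with pytest.raises(ValueError, match="region 0"):
            sf.make_phantom(sf.SceneParams(height_px=10, width_px=10,
                                           regions=(reg,)))

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValueError):
            sf.Region("poor", "rect", (0, 5, 0, 5), 0.0)
        with pytest.raises(ValueError):
            sf.SceneParams(background_tau_c_ms=-1.0)

    def test_later_regions_overwrite_earlier(self):
        regs = (sf.Region("poor", "rect", (0, 8, 0, 8), 50.0),
                sf.Region("marginal", "rect", (0, 4, 0, 8), 5.0))
        ph = sf.make_phantom(sf.SceneParams(height_px=8, width_px=8,
                                            regions=regs))
        assert np.all(ph.label_map[:4] == LABEL_CODES["marginal"])
        assert np.all(ph.label_map[4:] == LABEL_CODES["poor"])

    @given(r0=st.integers(0, 20), dr=st.integers(1, 20),
           c0=st.integers(0, 20), dc=st.integers(1, 20))
    def test_rectangle_label_count_matches_analytic_area(self, r0, dr, c0, dc):
        reg = sf.Region("poor", "rect", (r0, r0 + dr, c0, c0 + dc), 9.0)
        ph = sf.make_phantom(sf.SceneParams(height_px=40, width_px=40,
                                            regions=(reg,)))
        assert np.count_nonzero(ph.label_map == LABEL_CODES["poor"]) == dr * dc

    def test_ellipse_label_count_matches_area_within_boundary_band(self):
        reg = sf.Region("marginal", "ellipse", (20.0, 20.0, 12.0, 8.0), 5.0)
        ph = sf.make_phantom(sf.SceneParams(height_px=41, width_px=41,
                                            regions=(reg,)))
        count = np.count_nonzero(ph.label_map == LABEL_CODES["marginal"])
        area = np.pi * 12.0 * 8.0
        assert abs(count - area) <= 2 * np.pi * 12.0 + 8  # ~1-px boundary band


class TestStaticSpeckle:
    def test_deterministic_given_seed(self):
        a = sf.generate_static_speckle(64, 64, 2.0, seed=42)
        b = sf.generate_static_speckle(64, 64, 2.0, seed=42)
        assert np.array_equal(a.intensity, b.intensity)
        c = sf.generate_static_speckle(64, 64, 2.0, seed=43)
        assert not np.array_equal(a.intensity, c.intensity)

    def test_fully_developed_contrast_near_unity(self):
        f = sf.generate_static_speckle(512, 512, 4.0, beta=1.0, seed=1)
        k = f.intensity.std() / f.intensity.mean()
        assert 0.85 <= k <= 1.05

    def test_beta_scales_global_contrast(self):
        f1 = sf.generate_static_speckle(256, 256, 2.0, beta=1.0, seed=5)
        f2 = sf.generate_static_speckle(256, 256, 2.0, beta=0.25, seed=5)
        k1 = f1.intensity.std() / f1.intensity.mean()
        k2 = f2.intensity.std() / f2.intensity.mean()
        assert k2 == pytest.approx(0.5 * k1, rel=0.05)

    @pytest.mark.parametrize("size", [2.0, 4.0])
    def test_speckle_size_round_trip(self, size):
        f = sf.generate_static_speckle(256, 256, size, seed=3)
        est = sf.estimate_speckle_size(f)
        assert est == pytest.approx(size, rel=0.25)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            sf.generate_static_speckle(0, 64)
        with pytest.raises(ValueError):
            sf.generate_static_speckle(64, 64, speckle_size_px=0.2)


class TestDynamicStack:
    def test_static_limit_frames_identical(self):
        ph = sf.make_phantom(sf.SceneParams(height_px=128, width_px=128,
                                            background_tau_c_ms=1e9, seed=2))
        stack = sf.generate_dynamic_stack(ph, sf.AcquisitionParams(n_frames=3))
        arr = stack.as_array().astype(float)
        assert np.array_equal(arr[0], arr[1]) and np.array_equal(arr[1], arr[2])
        k = arr[0].std() / arr[0].mean()
        assert 0.85 <= k <= 1.05   # sqrt(beta_effective) for beta=1, size 2

    def test_deterministic_given_seeds(self):
        ph = sf.make_phantom(sf.SceneParams(height_px=64, width_px=64,
                                            background_tau_c_ms=5.0, seed=9))
        acq = sf.AcquisitionParams(n_frames=2)
        a = sf.generate_dynamic_stack(ph, acq, sf.NoiseParams(shot_noise=True, seed=4))
        b = sf.generate_dynamic_stack(ph, acq, sf.NoiseParams(shot_noise=True, seed=4))
        assert np.array_equal(a.as_array(), b.as_array())

    def test_slower_decorrelation_gives_higher_contrast(self):
        reg = sf.Region("poor", "rect", (0, 96, 48, 96), 50.0)
        ph = sf.make_phantom(sf.SceneParams(height_px=96, width_px=96,
                                            regions=(reg,),
                                            background_tau_c_ms=0.5, seed=6))
        stack = sf.generate_dynamic_stack(ph, sf.AcquisitionParams(n_frames=2))
        cmap = sf.spatial_contrast(stack.frames[0])
        well = np.mean(cmap.k[8:88, 8:40])
        poor = np.mean(cmap.k[8:88, 56:88])
        assert poor > well

    def test_mean_intensity_matches_mean_counts(self):
        ph = sf.make_phantom(sf.SceneParams(height_px=512, width_px=512,
                                            background_tau_c_ms=5.0, seed=8))
        acq = sf.AcquisitionParams(n_frames=1, mean_counts=8000.0)
        stack = sf.generate_dynamic_stack(ph, acq)
        mean = stack.frames[0].intensity.mean()
        assert mean == pytest.approx(8000.0, rel=0.02)

    def test_field_decorrelation_follows_exponential(self):
        tau = 4.0
        dt = 1.0
        rng = np.random.default_rng(13)
        tau_map = np.full((128, 128), tau)
        fields = list(sf.iter_field_steps(tau_map, dt, 9, 2.0, rng))
        f0 = fields[0]
        denom = np.mean(np.abs(f0) ** 2)
        for k in (1, 2, 4, 8):
            corr = np.abs(np.mean(fields[k] * np.conj(f0))) / denom
            assert corr == pytest.approx(np.exp(-k * dt / tau), abs=0.05)

    def test_exposure_longer_than_frame_interval_rejected(self):
        with pytest.raises(ValueError, match="frame interval"):
            sf.AcquisitionParams(exposure_ms=60.0, frame_rate_fps=20.0)

    def test_coarse_explicit_subframes_warn(self):
        ph = sf.make_phantom(sf.SceneParams(height_px=64, width_px=64,
                                            background_tau_c_ms=1.0, seed=1))
        acq = sf.AcquisitionParams(n_frames=1, n_subframes=8)
        with pytest.warns(UserWarning, match="coarse"):
            sf.generate_dynamic_stack(ph, acq)


class TestSensorNoise:
    def test_all_noise_off_is_identity(self):
        f = sf.generate_static_speckle(64, 64, 2.0, seed=1)
        out = sf.add_sensor_noise(f, sf.NoiseParams())
        assert np.array_equal(out.intensity, f.intensity)

    def test_dark_offset_shifts_every_pixel(self):
        f = sf.SpeckleFrame(np.full((32, 32), 100.0))
        out = sf.add_sensor_noise(f, sf.NoiseParams(dark_offset_dn=10.0))
        assert np.allclose(out.intensity, 110.0)

    def test_shot_noise_variance_matches_poisson(self):
        f = sf.SpeckleFrame(np.full((350, 350), 1000.0))
        out = sf.add_sensor_noise(f, sf.NoiseParams(shot_noise=True, seed=2))
        assert out.intensity.var() == pytest.approx(1000.0, rel=0.1)
        assert out.intensity.mean() == pytest.approx(1000.0, rel=0.01)

    def test_deterministic_given_seed(self):
        f = sf.SpeckleFrame(np.full((64, 64), 500.0))
        noise = sf.NoiseParams(shot_noise=True, read_noise_dn=3.0, seed=7)
        a = sf.add_sensor_noise(f, noise)
        b = sf.add_sensor_noise(f, noise)
        assert np.array_equal(a.intensity, b.intensity)

    def test_negative_noise_magnitude_rejected(self):
        with pytest.raises(ValueError):
            sf.NoiseParams(read_noise_dn=-1.0)
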