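import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ctdose as cd
from ctdose.projection import MU_WATER_MM, hu_to_mu, mu_to_hu, projection_angles


class TestForwardProject:
    def test_central_ray_matches_chord_length(self, water_disc_256):
        sino = cd.forward_project(water_disc_256, 1.0)
        center_bin = sino.values.shape[0] // 2
        expected = MU_WATER_MM * 2 * 120.0
        assert sino.values[center_bin, 0] == pytest.approx(expected, rel=0.01)

    def test_all_air_gives_zero_sinogram(self):
        img = cd.ImageGrid(np.full((64, 64), -1000.0), 1.0)
        sino = cd.forward_project(img, 1.0)
        assert np.all(sino.values == 0)

    @pytest.mark.parametrize(
        "interval,n_angles", [(0.6, 300), (1.0, 180), (0.7, 258)]
    )
    def test_angle_count_is_ceil(self, interval, n_angles):
        assert projection_angles(interval).size == n_angles

    def test_hu_mu_round_trip(self):
        hu = np.linspace(-1000, 3000, 101)
        assert np.allclose(mu_to_hu(hu_to_mu(hu)), hu, atol=1e-9)


class TestScaleFlux:
    def test_relative_dose_of_20_of_300_mas(self):
        f = cd.scale_flux(cd.FluxParameter(1.0), 20 / 300)
        assert round(f.i0, 2) == 0.07

    def test_identity_and_multiplication(self):
        assert cd.scale_flux(cd.FluxParameter(1e5), 1.0).i0 == 1e5
        assert cd.scale_flux(cd.FluxParameter(1e5), 0.05).i0 == pytest.approx(5e3)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            cd.scale_flux(cd.FluxParameter(1e5), 0.0)


class TestPoissonNoise:
    def _uniform_sino(self, value=1.0, shape=(400, 300)):
        return cd.Sinogram(
            values=np.full(shape, value),
            angles_deg=np.linspace(0, 180, shape[1], endpoint=False),
            detector_spacing_mm=1.0,
            n_pixels=256,
        )

    def test_infinite_flux_limit(self):
        sino = self._uniform_sino(2.0, (64, 45))
        out = cd.insert_poisson_noise(sino, cd.FluxParameter(1e12), seed=0)
        assert np.max(np.abs(out.values - sino.values)) < 1e-3

    def test_seeded_reproducibility(self):
        sino = self._uniform_sino()
        a = cd.insert_poisson_noise(sino, cd.FluxParameter(1e5), seed=11)
        b = cd.insert_poisson_noise(sino, cd.FluxParameter(1e5), seed=11)
        assert np.array_equal(a.values, b.values)

    def test_log_count_variance_matches_delta_method(self):
        # Var(ln N) ~ 1/E[N] = e^p / i0 for N ~ Poisson(i0 e^-p)
        sino = self._uniform_sino(1.0, (500, 300))
        out = cd.insert_poisson_noise(sino, cd.FluxParameter(1e5), seed=3)
        expected_sd = np.sqrt(np.e / 1e5)
        assert np.std(out.values) == pytest.approx(expected_sd, rel=0.05)

    def test_nonfinite_rejected(self):
        sino = self._uniform_sino()
        sino.values[0, 0] = np.inf
        with pytest.raises(ValueError):
            cd.insert_poisson_noise(sino, cd.FluxParameter(1e5), seed=0)


class TestFBP:
    def test_chest_round_trip_error(self, chest_slice_256, tissue):
        sino = cd.forward_project(chest_slice_256, 0.5)
        rec = cd.fbp_reconstruct(sino, cd.ReconParams("ram-lak", 1.0, 0.5))
        body = chest_slice_256.pixels != tissue.air_hu
        mae = np.abs(rec.pixels - chest_slice_256.pixels)[body].mean()
        assert mae < 30.0

    def test_uniform_disc_roi_mean(self, water_disc_256):
        sino = cd.forward_project(water_disc_256, 0.5)
        rec = cd.fbp_reconstruct(sino, cd.ReconParams("ram-lak", 1.0, 0.5))
        stats = cd.roi_stats(rec, cd.ROI.circle((0, 0), 40))
        assert abs(stats.mean_hu - 0.0) < 20.0

    def test_lower_cutoff_reduces_noise(self, water_disc_256):
        sino = cd.forward_project(water_disc_256, 1.0)
        noisy = cd.insert_poisson_noise(sino, cd.FluxParameter(1e4), seed=1)
        roi = cd.ROI.circle((0, 0), 40)
        sds = {}
        for cutoff in (0.4, 1.0):
            rec = cd.fbp_reconstruct(noisy, cd.ReconParams("hann", cutoff, 1.0))
            sds[cutoff] = cd.roi_stats(rec, roi).sd_hu
        assert sds[0.4] < sds[1.0]

    def test_unknown_filter_lists_valid_names(self):
        with pytest.raises(ValueError, match="ram-lak"):
            cd.ReconParams("butterworth", 0.8, 1.0)

    @pytest.mark.parametrize("filter_name", cd.projection.FILTER_NAMES)
    def test_all_filters_reconstruct_disc_mean(self, water_disc_256, filter_name):
        sino = cd.forward_project(water_disc_256, 1.0)
        rec = cd.fbp_reconstruct(sino, cd.ReconParams(filter_name, 1.0, 1.0))
        stats = cd.roi_stats(rec, cd.ROI.circle((0, 0), 40))
        assert abs(stats.mean_hu) < 25.0


class TestSimulateDoseLevel:
    def test_infinite_flux_matches_noise_free_round_trip(self, water_disc_256):
        params = cd.ReconParams("hamming", 0.8, 1.0)
        clean = cd.fbp_reconstruct(cd.forward_project(water_disc_256, 1.0), params)
        sim = cd.simulate_dose_level(
            water_disc_256, cd.FluxParameter(1e12), 1.0, params, seed=0
        )
        assert np.max(np.abs(sim.pixels - clean.pixels)) < 1.0

    def test_roi_sd_monotone_in_dose(self, tissue_disc_128):
        params = cd.ReconParams("hamming", 0.8, 1.0)
        roi = cd.ROI.circle((0, 0), 40)
        sds = [
            cd.roi_stats(
                cd.simulate_dose_level(
                    tissue_disc_128, cd.FluxParameter(1e5), d, params, seed=2
                ),
                roi,
            ).sd_hu
            for d in (1.0, 0.25, 0.10, 0.05, 0.02)
        ]
        assert all(np.diff(sds) > 0)  # SD grows as dose falls

    def test_determinism(self, tissue_disc_128):
        params = cd.ReconParams("hann", 0.6, 1.0)
        a = cd.simulate_dose_level(
            tissue_disc_128, cd.FluxParameter(1e4), 0.1, params, seed=9
        )
        b = cd.simulate_dose_level(
            tissue_disc_128, cd.FluxParameter(1e4), 0.1, params, seed=9
        )
        assert np.array_equal(a.pixels, b.pixels)


class TestDoseSimulatorEstimator:
    def test_sklearn_params_round_trip(self):
        from sklearn.base import clone

        est = cd.DoseSimulator(i0=5e4, relative_dose=0.25, seed=7)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_transform_matches_function(self, tissue_disc_128):
        from ctdose._utils import derive_seed

        est = cd.DoseSimulator(
            i0=1e4, relative_dose=0.5, sampling_interval_deg=1.0, seed=3
        )
        out = est.fit().transform(tissue_disc_128)
        ref = cd.simulate_dose_level(
            tissue_disc_128,
            cd.FluxParameter(1e4),
            0.5,
            cd.ReconParams("hamming", 0.8, 1.0),
            derive_seed(3, "dose_sim", 0),
        )
        assert np.array_equal(out.pixels, ref.pixels)


@settings(max_examples=25, deadline=None)
@given(
    hu=st.floats(min_value=-1000, max_value=4000, allow_nan=False),
)
def test_hu_mu_bijection_property(hu):
    assert mu_to_hu(hu_to_mu(np.array([hu])))[0] == pytest.approx(hu, abs=1e-6)
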