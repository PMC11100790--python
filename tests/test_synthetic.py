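import numpy as np
import pytest

from ecmfluor.flim import phasor_from_decay, DecayHistogram, phasor_of_lifetime
from ecmfluor.kinetics import binding_model
from ecmfluor.synthetic import (
    SceneSpec,
    make_default_dye,
    simulate_array,
    simulate_flim,
    simulate_hyperspectral,
    simulate_photostability,
    simulate_timelapse,
)


class TestDeterminism:
    def test_timelapse_same_seed_identical(self):
        a, _ = simulate_timelapse(seed=42)
        b, _ = simulate_timelapse(seed=42)
        c, _ = simulate_timelapse(seed=43)
        assert np.array_equal(a.intensities, b.intensities)
        assert not np.array_equal(a.intensities, c.intensities)

    def test_flim_same_seed_identical(self):
        frac = np.zeros((8, 8))
        frac[:, 4:] = 1.0
        s1, _, _ = simulate_flim(frac, photons_per_pixel=200, n_bins=64, seed=9)
        s2, _, _ = simulate_flim(frac, photons_per_pixel=200, n_bins=64, seed=9)
        assert np.array_equal(s1, s2)

    def test_array_same_seed_identical(self):
        i1, _, _ = simulate_array(seed=3)
        i2, _, _ = simulate_array(seed=3)
        assert np.array_equal(i1, i2)


class TestTimelapseGenerator:
    def test_noiseless_equals_model(self):
        tl, truth = simulate_timelapse(noise_sd_frac=0.0)
        expected = binding_model(
            tl.times_s, truth["imax"], truth["kobs"], truth["t0"], truth["b"]
        )
        assert np.array_equal(tl.intensities, expected)

    def test_half_rise_at_t0_plus_934s(self):
        """At 5 uM with the reference rate constants, half of the amplitude is
        reached ln2/kobs ~ 935.5 s after the delay t0."""
        tl, truth = simulate_timelapse(noise_sd_frac=0.0)
        t_half = truth["t0"] + np.log(2.0) / truth["kobs"]
        half_level = truth["b"] + truth["imax"] / 2.0
        crossing = np.interp(half_level, tl.intensities, tl.times_s)
        assert crossing == pytest.approx(t_half, rel=0.01)
        assert np.log(2.0) / truth["kobs"] == pytest.approx(935.5, rel=1e-3)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            simulate_timelapse(kon=-1.0)
        with pytest.raises(ValueError):
            simulate_timelapse(koff=-1e-5)
        with pytest.raises(ValueError):
            simulate_timelapse(concentration_M=0.0)


class TestSceneSpec:
    def test_overlapping_masks_rejected(self):
        m = np.ones((4, 4), bool)
        with pytest.raises(ValueError, match="overlap"):
            SceneSpec(
                shape=(4, 4),
                region_masks={"a": m, "b": m},
                fraction_bound={"a": 0.0, "b": 1.0},
                brightness={"a": 1.0, "b": 1.0},
            )

    def test_fraction_outside_unit_interval_rejected(self):
        m = np.ones((4, 4), bool)
        with pytest.raises(ValueError):
            SceneSpec(
                shape=(4, 4),
                region_masks={"a": m},
                fraction_bound={"a": 1.2},
                brightness={"a": 1.0},
            )


class TestHyperspectralGenerator:
    def test_unbound_scene_has_single_shared_peak(self):
        scene = SceneSpec.two_region(
            shape=(8, 8), fraction_bound_gel=0.0, fraction_bound_buffer=0.0,
            noise_sd_frac=0.0,
        )
        stack, truth = simulate_hyperspectral(scene)
        assert len(set(truth["region_peaks_nm"].values())) == 1
        assert truth["region_peaks_nm"]["gel"] == 548.0

    def test_two_region_scene_has_distinct_grid_peaks(self):
        scene = SceneSpec.two_region(shape=(8, 8), noise_sd_frac=0.0)
        _, truth = simulate_hyperspectral(scene)
        peaks = truth["region_peaks_nm"]
        assert peaks["gel"] > peaks["buffer"]
        grid = np.arange(500.0, 567.0, 2.0)
        assert peaks["gel"] in grid and peaks["buffer"] in grid


class TestFlimGenerator:
    def test_pure_unbound_pixels_cluster_at_2ns_phasor(self):
        stack, edges, truth = simulate_flim(
            np.zeros((6, 6)), photons_per_pixel=20000, seed=1
        )
        omega = 2 * np.pi * truth["rep_rate_hz"]
        ref = phasor_of_lifetime(truth["tau_unbound_ns"], omega)
        total = stack.sum(axis=(1, 2)).astype(float)
        p = phasor_from_decay(DecayHistogram(edges, total, truth["rep_rate_hz"]))
        assert p.g == pytest.approx(ref.g, abs=5e-3)
        assert p.s == pytest.approx(ref.s, abs=5e-3)

    def test_expected_count_limit_matches_mixture_phasor(self):
        """Replacing draws by expected counts (infinite-photon limit), the
        stack phasor equals the count-weighted mixture of the pure phasors."""
        from ecmfluor.synthetic import _wrapped_exponential_bin_probs

        period_ns = 1e9 / 8.0e7
        edges = np.linspace(0.0, period_ns, 4097)
        f = 0.5
        p_mix = f * _wrapped_exponential_bin_probs(3.5, edges) + (
            1 - f
        ) * _wrapped_exponential_bin_probs(2.0, edges)
        p = phasor_from_decay(DecayHistogram(edges, p_mix * 1e6, 8.0e7))
        omega = 2 * np.pi * 8.0e7
        pa, pb = phasor_of_lifetime(2.0, omega), phasor_of_lifetime(3.5, omega)
        assert p.g == pytest.approx(0.5 * (pa.g + pb.g), abs=1e-3)
        assert p.s == pytest.approx(0.5 * (pa.s + pb.s), abs=1e-3)

    def test_long_lifetime_warns_about_wraparound(self):
        with pytest.warns(RuntimeWarning, match="wraps"):
            simulate_flim(np.zeros((2, 2)), tau_bound_ns=20.0, photons_per_pixel=10, n_bins=32)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            simulate_flim(np.full((2, 2), 1.5))
        with pytest.raises(ValueError):
            simulate_flim(np.zeros((2, 2)), tau_unbound_ns=-1.0)
        with pytest.raises(ValueError):
            simulate_flim(np.zeros((2, 2)), photons_per_pixel=0)


class TestArrayGenerator:
    def test_truth_table_marks_binders(self):
        _, layout, truth = simulate_array(seed=0)
        assert truth["is_binder"].sum() == 98
        assert len(truth) == len(layout.glycans) == 100
        assert layout.n_replicates == 4
        assert layout.control_positions.shape == (8, 2)

    def test_single_strong_spot_detected(self):
        from ecmfluor.arrayquant import detection_call, quantify_array

        amplitudes = np.zeros(100)
        amplitudes[17] = 20.0  # 10x the default noise sd
        image, layout, _ = simulate_array(amplitudes=amplitudes, seed=6)
        spots = quantify_array(image, layout)
        sel = spots[spots.glycan == layout.glycans[17]]
        assert detection_call(sel["corrected"].mean(), sel["background_sd"].mean())


class TestPhotostabilityGenerator:
    def test_exchange_model_loss_shrinks_with_pool_excess(self):
        lo, _ = simulate_photostability(free_pool_excess=10.0, noise_sd_frac=0.0)
        hi, _ = simulate_photostability(free_pool_excess=1000.0, noise_sd_frac=0.0)
        loss_lo = 1.0 - lo.intensities[-1] / lo.intensities[0]
        loss_hi = 1.0 - hi.intensities[-1] / hi.intensities[0]
        assert loss_hi < loss_lo

    def test_truth_records_expected_final_fraction(self):
        _, truth = simulate_photostability(noise_sd_frac=0.0, seed=0)
        assert 0.99 <= truth["expected_final_over_initial"] <= 1.0
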