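"""Background subtraction, lock-mass correction, QC, binning and the
per-sample representative."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reimsdx.preprocessing import (
    BinnedSpectrum,
    PreprocessConfig,
    bin_spectrum,
    estimate_and_correct_lockmass,
    quality_filter,
    sample_representative,
    subtract_background,
    tic_normalize,
)
from reimsdx.spectra_io import RawSpectrum
from reimsdx.synthetic_data import SimulationConfig, simulate_burn_spectrum, simulate_cohort


class TestBackgroundSubtraction:
    def test_constant_background_goes_to_zero(self):
        s = RawSpectrum(600 + np.arange(100) * 0.1, np.full(100, 5.0))
        out = subtract_background(s, 0.10)
        assert np.all(out.intensity == 0.0)

    def test_peak_on_baseline(self):
        intensity = np.full(100, 1.0)
        intensity[50] = 11.0
        s = RawSpectrum(600 + np.arange(100) * 0.1, intensity)
        out = subtract_background(s, 0.10)
        assert out.intensity[50] == pytest.approx(10.0)
        assert np.all(out.intensity[:50] == 0.0)
        np.testing.assert_array_equal(out.mz, s.mz)

    def test_empty_spectrum_unchanged(self):
        s = RawSpectrum([], [])
        assert len(subtract_background(s)) == 0


class TestLockmass:
    def test_zero_drift_identity(self, panel):
        s = simulate_burn_spectrum(panel, "normal", 0.0, 1.0, np.random.default_rng(1),
                                   baseline_noise_sd=0.0)
        corrected, drift = estimate_and_correct_lockmass(s)
        assert drift == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(corrected.mz, s.mz, atol=1e-12)

    @pytest.mark.parametrize("injected", [-0.05, -0.02, 0.02, 0.05])
    def test_rigid_drift_recovery_noise_free(self, panel, injected):
        s = simulate_burn_spectrum(panel, "normal", injected, 1.0,
                                   np.random.default_rng(2), baseline_noise_sd=0.0)
        corrected, drift = estimate_and_correct_lockmass(s)
        assert drift == pytest.approx(injected, abs=1e-3)
        # the lock-mass peak really lands back on 699.497
        near = np.abs(corrected.mz - 699.497) < 0.3
        apex = corrected.mz[near][np.argmax(corrected.intensity[near])]
        assert apex == pytest.approx(699.497, abs=0.01)

    def test_spectrum_without_lockmass_region_is_flagged(self):
        s = RawSpectrum(800 + np.arange(100) * 0.1, np.random.default_rng(0).random(100))
        corrected, drift = estimate_and_correct_lockmass(s)
        assert drift is None
        np.testing.assert_array_equal(corrected.mz, s.mz)

    def test_two_point_linear_correction(self, panel):
        """A spectrum covering both lock masses gets a slope+offset fit that
        recovers both reference positions."""
        lock = [p for p in panel if p.lipid_name == "PA(36:2)"]
        s = simulate_burn_spectrum(lock, "normal", 0.0, 1.0, np.random.default_rng(3),
                                   baseline_noise_sd=0.0, mz_min=540.0, mz_max=1005.0)
        # add an external lock-mass peak, then distort linearly: mz' = a·mz + b
        ext = 300.0 * np.exp(-0.5 * ((s.mz - 554.262) / 0.02) ** 2)
        s = RawSpectrum(s.mz, s.intensity + ext)
        a, b = 1.00003, -0.005
        distorted = RawSpectrum(a * s.mz + b, s.intensity)
        corrected, drift = estimate_and_correct_lockmass(distorted)
        assert drift is not None
        for ref in (554.262, 699.497):
            near = np.abs(corrected.mz - ref) < 0.3
            apex = corrected.mz[near][np.argmax(corrected.intensity[near])]
            assert apex == pytest.approx(ref, abs=0.01)


class TestQualityFilter:
    def test_flat_noise_excluded(self):
        s = RawSpectrum(600 + np.arange(1000) * 0.1, np.full(1000, 3.0), spectrum_id="flat")
        kept, excluded, reports = quality_filter([s])
        assert not kept and excluded
        assert reports[0].snr_estimate == pytest.approx(1.0)

    def test_clean_peak_kept_unless_tic_too_low(self):
        intensity = np.zeros(10)
        intensity[5] = 10.0
        s = RawSpectrum(600 + np.arange(10) * 0.1, intensity)
        kept, _, reports = quality_filter([s])
        assert kept and reports[0].snr_estimate > 100
        tiny = RawSpectrum(s.mz, intensity * 1e-9)
        kept2, excluded2, reports2 = quality_filter([tiny])
        assert not kept2 and "tic" in reports2[0].reason

    def test_empty_input_and_empty_spectrum(self):
        assert quality_filter([]) == ([], [], [])
        kept, excluded, _ = quality_filter([RawSpectrum([], [])])
        assert not kept and excluded

    def test_degraded_fraction_matches_generator_flag(self):
        cfg = SimulationConfig(n_normal_patients=12, n_cancer_patients=12,
                               poor_quality_fraction=0.15, seed=9)
        spectra, _ = simulate_cohort(cfg)
        kept, excluded, _ = quality_filter(spectra)
        frac = len(excluded) / len(spectra)
        assert 0.05 <= frac <= 0.30


class TestBinning:
    def test_hand_binning_oracle(self):
        s = RawSpectrum([600.05, 600.14], [10.0, 5.0])
        b = bin_spectrum(s)
        assert b.values[0] == 10.0 and b.values[1] == 5.0
        assert b.values.sum() == 15.0

    @pytest.mark.parametrize("mz", [599.99, 1000.0, 1050.0])
    def test_out_of_range_points_dropped(self, mz):
        b = bin_spectrum(RawSpectrum([mz], [7.0]))
        assert b.values.sum() == 0.0

    def test_bin_edge_points_land_in_upper_bin(self):
        # 600.1 is the lower edge of bin 1 in the half-open convention
        b = bin_spectrum(RawSpectrum([600.1], [1.0]))
        assert b.values[1] == 1.0 and b.values[0] == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_intensity_conservation(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 300))
        mz = rng.uniform(550, 1050, n)
        intensity = rng.exponential(10.0, n)
        s = RawSpectrum(np.sort(mz), intensity[np.argsort(mz)])
        in_range = (s.mz >= 600.0) & (s.mz < 1000.0)
        b = bin_spectrum(s)
        assert b.values.sum() == pytest.approx(s.intensity[in_range].sum(), rel=1e-12)
        assert b.values.shape == (4000,)

    def test_order_robustness(self):
        rng = np.random.default_rng(4)
        mz = rng.uniform(600, 1000, 200)
        intensity = rng.exponential(5.0, 200)
        sorted_spec = RawSpectrum(np.sort(mz), intensity[np.argsort(mz)])
        perm = rng.permutation(200)
        permuted_spec = RawSpectrum(mz[perm], intensity[perm])
        a = bin_spectrum(subtract_background(sorted_spec))
        b = bin_spectrum(subtract_background(permuted_spec))
        np.testing.assert_allclose(a.values, b.values, rtol=1e-12)


class TestNormalisationAndRepresentative:
    def test_tic_normalize(self):
        b = BinnedSpectrum(np.array([2.0, 2.0, 4.0, 0.0]))
        out = tic_normalize(b)
        assert out.normalised
        np.testing.assert_allclose(out.values, [0.25, 0.25, 0.5, 0.0])
        zero = tic_normalize(BinnedSpectrum(np.zeros(4)))
        assert not zero.normalised
        np.testing.assert_array_equal(zero.values, np.zeros(4))

    def test_simulated_spectrum_normalises_to_unit_sum(self, panel):
        s = simulate_burn_spectrum(panel, "cancer", 0.0, 2.0, np.random.default_rng(6))
        out = tic_normalize(bin_spectrum(s))
        assert out.values.sum() == pytest.approx(1.0, abs=1e-9)

    def test_representative_mean_and_idempotence(self):
        a = tic_normalize(BinnedSpectrum(np.array([1.0, 0.0])))
        b = tic_normalize(BinnedSpectrum(np.array([0.0, 1.0])))
        rep = sample_representative([a, b])
        np.testing.assert_allclose(rep.values, [0.5, 0.5])
        np.testing.assert_allclose(sample_representative([a]).values, a.values)
        np.testing.assert_allclose(sample_representative([a, a, a]).values, a.values)

    def test_representative_contract(self):
        with pytest.raises(ValueError):
            sample_representative([])
        with pytest.raises(ValueError):
            sample_representative([BinnedSpectrum(np.array([1.0, 2.0]))])  # not normalised


def test_config_validation():
    with pytest.raises(ValueError):
        PreprocessConfig(bin_lo=700, bin_hi=600)
    with pytest.raises(ValueError):
        PreprocessConfig(bin_width=0.3)
    assert PreprocessConfig().n_bins == 4000
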