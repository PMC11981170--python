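"""Simulator: concentration sampling, augmentation operators, datasets."""

import warnings

import numpy as np
import pytest

import mrsinet as M
from mrsinet import simulate as S
from mrsinet.basis import make_grid
from mrsinet.errors import (ConfigurationError, DataError,
                            InvalidArgumentError, UnknownMetaboliteError)
from mrsinet.records import FidRecord

from conftest import brute_force_dft


@pytest.fixture(scope="module")
def clean_fid(basis3t):
    basis, grid, fids = basis3t
    rng = np.random.default_rng(7)
    conc = S.sample_concentrations(S.ConcentrationRanges(), rng)
    return S.compose_fid(conc, fids, grid), grid


class TestConcentrations:
    def test_defaults_match_literature_table(self):
        r = S.ConcentrationRanges()
        assert r.ranges["NAA"] == (7.0, 10.0)
        assert r.ranges["Cr"] == (5.5, 7.0)
        assert r.ranges["Lac"] == (0.2, 1.0)
        assert len(r.ranges) == 21

    def test_samples_stay_within_ranges(self):
        rng = np.random.default_rng(0)
        r = S.ConcentrationRanges()
        for _ in range(50):
            for m, v in S.sample_concentrations(r, rng).items():
                lo, hi = r.ranges[m]
                assert lo <= v <= hi

    def test_degenerate_range_is_constant(self):
        r = S.ConcentrationRanges(ranges={"Cr": (5.5, 5.5)})
        rng = np.random.default_rng(1)
        assert S.sample_concentrations(r, rng)["Cr"] == 5.5

    def test_deterministic_given_rng_state(self):
        a = S.sample_concentrations(S.ConcentrationRanges(),
                                    np.random.default_rng(3))
        b = S.sample_concentrations(S.ConcentrationRanges(),
                                    np.random.default_rng(3))
        assert a == b

    def test_invalid_range_rejected(self):
        with pytest.raises(InvalidArgumentError):
            S.ConcentrationRanges(ranges={"NAA": (2.0, 1.0)})


class TestCompose:
    def test_zero_concentrations_give_zero_fid(self, basis3t):
        _, grid, fids = basis3t
        out = S.compose_fid({m: 0.0 for m in fids}, fids, grid)
        np.testing.assert_array_equal(out.samples, 0)

    def test_single_metabolite_identity_and_linearity(self, basis3t):
        _, grid, fids = basis3t
        one = S.compose_fid({"NAA": 1.0}, fids, grid)
        np.testing.assert_allclose(one.samples, fids["NAA"].samples)
        conc = {"NAA": 2.0, "Cr": 3.0}
        a = S.compose_fid(conc, fids, grid)
        b = S.compose_fid({m: 2 * c for m, c in conc.items()}, fids, grid)
        np.testing.assert_allclose(b.samples, 2 * a.samples, rtol=1e-12)

    def test_unknown_metabolite_rejected(self, basis3t):
        _, grid, fids = basis3t
        with pytest.raises(UnknownMetaboliteError):
            S.compose_fid({"Unobtainium": 1.0}, fids, grid)


class TestAugmentationOperators:
    def test_phase_identity_and_unitarity(self, clean_fid):
        fid, grid = clean_fid
        np.testing.assert_array_equal(S.apply_phase(fid, 0.0).samples,
                                      fid.samples)
        rotated = S.apply_phase(fid, np.pi / 4)
        np.testing.assert_allclose(np.abs(rotated.samples),
                                   np.abs(fid.samples), rtol=1e-12)

    def test_phase_quarter_pi_hand_value(self, grid3t):
        fid = FidRecord(samples=np.ones(1024, dtype=complex), grid=grid3t,
                        field_strength=3.0)
        out = S.apply_phase(fid, np.pi / 4)
        expected = np.sqrt(2) / 2 * (1 + 1j)
        np.testing.assert_allclose(out.samples, expected, rtol=1e-12)

    def test_phase_warns_outside_augmentation_range(self, clean_fid):
        fid, _ = clean_fid
        with pytest.warns(UserWarning):
            S.apply_phase(fid, np.pi / 2)
        with pytest.raises(InvalidArgumentError):
            S.apply_phase(fid, 3.5)

    def test_broadening_identity_envelope_and_rejection(self, clean_fid):
        fid, grid = clean_fid
        np.testing.assert_array_equal(
            S.apply_broadening(fid, 0.0, grid).samples, fid.samples)
        out = S.apply_broadening(fid, 40.0, grid)
        t_idx = np.argmin(np.abs(grid.time_axis - 0.01))  # t = 10 ms
        factor = out.samples[t_idx] / fid.samples[t_idx]
        assert abs(factor) == pytest.approx(
            np.exp(-np.pi * 40 * grid.time_axis[t_idx]), rel=1e-9)
        assert np.exp(-np.pi * 40 * 0.01) == pytest.approx(0.2846, abs=2e-4)
        with pytest.raises(InvalidArgumentError):
            S.apply_broadening(fid, -1.0, grid)

    def test_broadening_adds_to_fwhm(self):
        # single line, fine grid; FWHM should grow by lb Hz
        from mrsinet import basis as B
        grid = make_grid(3.0, spectral_width=2000.0, n_points=8192)
        t2 = 0.15
        shift = B.REFERENCE_PPM + 200.0 / grid.larmor_frequency
        res = {"X": [B.MetaboliteResonance("X", shift, 1.0)]}
        custom = B.BasisSet(resonances=res, field_strength=3.0,
                            spectral_width=2000.0, n_points=8192)
        fid = B.metabolite_fid("X", custom, grid, intrinsic_t2=t2)
        freq = (grid.ppm_axis - B.REFERENCE_PPM) * grid.larmor_frequency
        def fwhm(x):
            spec = np.fft.fftshift(np.fft.fft(x)).real
            half = spec.max() / 2
            above = np.nonzero(spec >= half)[0]
            lo, hi = above[0], above[-1]
            def cross(i, j):
                return freq[i] + (half - spec[i]) * (freq[j] - freq[i]) \
                    / (spec[j] - spec[i])
            return cross(hi, hi + 1) - cross(lo, lo - 1)
        f0 = fwhm(fid.samples)
        f20 = fwhm(S.apply_broadening(fid, 20.0, grid).samples)
        assert f20 - f0 == pytest.approx(20.0, rel=0.05)

    def test_noise_sd_and_identity(self, clean_fid):
        fid, _ = clean_fid
        rng = np.random.default_rng(5)
        np.testing.assert_array_equal(S.add_noise(fid, 0.0, rng).samples,
                                      fid.samples)
        noisy = S.add_noise(fid, 1.0, np.random.default_rng(6))
        resid = (noisy.samples - fid.samples).real
        # chi-square bound for n = 1024 at ~3 sigma
        assert 0.91 <= resid.std() <= 1.09

    def test_noise_deterministic_given_rng(self, clean_fid):
        fid, _ = clean_fid
        a = S.add_noise(fid, 0.5, np.random.default_rng(9))
        b = S.add_noise(fid, 0.5, np.random.default_rng(9))
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_water_peak_position_and_ratio(self, clean_fid):
        fid, grid = clean_fid
        np.testing.assert_array_equal(S.add_water(fid, 0.0, grid).samples,
                                      fid.samples)
        out = S.add_water(fid, 10.0, grid)
        spec = np.abs(np.fft.fftshift(np.fft.fft(out.samples)))
        assert grid.ppm_axis[spec.argmax()] == pytest.approx(4.7, abs=0.1)
        cr = spec[grid.ppm_window(2.9, 3.1)].max()
        water = spec[grid.ppm_window(4.6, 4.8)].max()
        assert 9.0 <= water / cr <= 11.0


class TestTargetSpectrum:
    def test_zero_fid_degenerate(self, grid3t):
        fid = FidRecord(samples=np.zeros(1024, dtype=complex), grid=grid3t,
                        field_strength=3.0)
        spec = S.target_spectrum(fid)
        assert spec.degenerate
        np.testing.assert_array_equal(spec.real_part, 0)
        np.testing.assert_array_equal(spec.imag_part, 0)

    def test_normalization_contract(self, clean_fid):
        fid, _ = clean_fid
        spec = S.target_spectrum(fid)
        for ch in (spec.real_part, spec.imag_part):
            assert ch.min() == 0.0
            assert ch.max() == 1.0

    def test_matches_brute_force_dft_before_normalization(self, grid3t):
        t = grid3t.time_axis
        fid = FidRecord(samples=np.exp(2j * np.pi * 100.0 * t - t / 0.1),
                        grid=grid3t, field_strength=3.0)
        oracle = brute_force_dft(fid.samples)
        fast = np.fft.fftshift(np.fft.fft(fid.samples))
        assert np.abs(fast - oracle).max() / np.abs(oracle).max() < 1e-9
        spec = S.target_spectrum(fid)
        # normalization is monotone, so argmaxes agree with the oracle
        assert spec.real_part.argmax() == oracle.real.argmax()


class TestGenerateDataset:
    def test_small_split_arithmetic(self):
        ds = M.generate_dataset(10, master_seed=0)
        assert (len(ds.train), len(ds.validation), len(ds.test)) == (8, 1, 1)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ConfigurationError):
            M.generate_dataset(100, split_fractions=(0.7, 0.2, 0.2))

    def test_determinism_and_shapes(self):
        a = M.generate_dataset(60, master_seed=42)
        b = M.generate_dataset(60, master_seed=42)
        np.testing.assert_array_equal(a.train.fids, b.train.fids)
        np.testing.assert_array_equal(a.test.targets, b.test.targets)
        assert a.train.fids.shape == (48, 1024, 2)
        assert np.all(np.isfinite(a.train.fids))
        c = M.generate_dataset(60, master_seed=43)
        assert not np.array_equal(a.train.fids, c.train.fids)

    def test_targets_normalized_per_channel(self):
        ds = M.generate_dataset(40, master_seed=3)
        t = ds.train.targets
        np.testing.assert_allclose(t.min(axis=1), 0.0, atol=1e-6)
        np.testing.assert_allclose(t.max(axis=1), 1.0, atol=1e-6)

    def test_identity_augmentation_is_noop(self):
        """phi=0, lb=0, sigma=0 must reproduce the scaled clean FID."""
        aug = S.AugmentParams(phase_range=(0.0, 0.0),
                              broadening_range=(0.0, 0.0),
                              noise_range=(0.0, 0.0))
        ds = M.generate_dataset(20, aug=aug, master_seed=5,
                                field_range=(3.0, 3.0),
                                split_fractions=(1.0, 0.0, 0.0))
        fids = ds.train.fids[..., 0] + 1j * ds.train.fids[..., 1]
        spec = np.fft.fftshift(np.fft.fft(fids, axis=1), axes=1)
        ch = np.stack([spec.real, spec.imag], axis=-1)
        lo = ch.min(axis=1, keepdims=True)
        hi = ch.max(axis=1, keepdims=True)
        np.testing.assert_allclose((ch - lo) / (hi - lo), ds.train.targets,
                                   atol=5e-5)

    def test_phase_broadening_commute_in_magnitude(self, clean_fid):
        fid, grid = clean_fid
        a = S.apply_broadening(S.apply_phase(fid, 0.3), 15.0, grid)
        b = S.apply_phase(S.apply_broadening(fid, 15.0, grid), 0.3)
        sa = np.abs(np.fft.fft(a.samples))
        sb = np.abs(np.fft.fft(b.samples))
        np.testing.assert_allclose(sa, sb, rtol=1e-9)

    def test_simulation_snr_spans_one_to_three(self):
        lo = S.simulation_snr(S.AugmentParams().noise_range[1])
        hi = S.simulation_snr(S.AugmentParams().noise_range[0])
        assert lo <= 1.0 and hi >= 3.0


class TestLabeledDataset:
    def test_balance_and_labels(self):
        ds = M.generate_labeled_dataset(50, master_seed=8)
        labels = np.concatenate([ds.train.labels, ds.validation.labels,
                                 ds.test.labels])
        assert len(labels) == 100
        assert labels.sum() == 50

    def test_requires_two_distinct_profiles(self):
        with pytest.raises(DataError):
            M.generate_labeled_dataset(10, profiles=[S.healthy_profile()],
                                       master_seed=0)

    def test_class_profiles_separate_tcho_and_naa(self):
        """Glioma spectra carry more 3.2 ppm signal, healthy more NAA."""
        aug = S.AugmentParams(noise_range=(0.0, 0.0),
                              broadening_range=(0.0, 0.0),
                              phase_range=(0.0, 0.0))
        ds = M.generate_labeled_dataset(60, aug=aug, master_seed=12,
                                        split_fractions=(1.0, 0.0, 0.0))
        axis = ds.train.ppm_axis
        tcho = (axis >= 3.1) & (axis <= 3.3)
        naa_bin = np.argmin(np.abs(axis - 2.01))  # the NAA CH3 resonance
        fids = ds.train.fids[..., 0] + 1j * ds.train.fids[..., 1]
        mag = np.abs(np.fft.fftshift(np.fft.fft(fids, axis=1), axes=1))
        glioma = ds.train.labels == 1
        assert mag[glioma][:, tcho].max(axis=1).mean() > \
            mag[~glioma][:, tcho].max(axis=1).mean()
        assert mag[~glioma][:, naa_bin].mean() > mag[glioma][:, naa_bin].mean()


class TestPhantomPreset:
    def test_composition_as_printed(self):
        metabolites, ranges = S.phantom_preset()
        assert ranges.ranges["NAA"] == (6.0, 6.0)
        assert ranges.ranges["Cr"] == (4.0, 4.0)
        assert ranges.ranges["Cho"] == (5.0, 5.0)
        assert len(metabolites) == 7

    def test_sampling_is_degenerate(self):
        _, ranges = S.phantom_preset()
        a = S.sample_concentrations(ranges, np.random.default_rng(1))
        b = S.sample_concentrations(ranges, np.random.default_rng(99))
        assert a == b

    def test_phantom_dataset_generates(self):
        metabolites, ranges = S.phantom_preset()
        ds = M.generate_dataset(20, ranges=ranges, master_seed=4,
                                metabolites=metabolites,
                                split_fractions=(1.0, 0.0, 0.0))
        assert len(ds.train) == 20
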