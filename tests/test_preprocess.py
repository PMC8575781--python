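"""Demodulation, calibration, CT conversion and masking contracts."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from optomics.channels import CHANNEL_SPECS
from optomics.phantom import (
    PhantomConfig,
    generate_raw_ct,
    generate_raw_sfdi,
    generate_specimen,
)
from optomics.preprocess import (
    AmplitudeMap,
    CTCalibration,
    apply_coupling_mask,
    calibrate_reflectance,
    ct_to_attenuation,
    demodulate,
    demodulate_dc,
    reconstruct_specimen,
)
from optomics.sampling import ROIRecord, tile_roi


class TestDemodulate:
    def test_constant_frames_give_zero_amplitude(self):
        c = np.full((5, 5), 7.0)
        assert np.allclose(demodulate(c, c, c).values, 0.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(phi=st.floats(0, 2 * np.pi), amp=st.floats(0.1, 10),
           offset=st.floats(0.0, 20))
    def test_recovers_sinusoid_amplitude_at_any_phase(self, phi, amp, offset):
        """M_AC equals the AC amplitude regardless of global phase offset."""
        phases = (0.0, 2 * np.pi / 3, 4 * np.pi / 3)
        frames = [np.full((3, 3), offset + amp * np.cos(phi + pk))
                  for pk in phases]
        out = demodulate(*frames).values
        assert np.allclose(out, amp, rtol=1e-9, atol=1e-9)

    def test_homogeneity_scaling(self):
        rng = np.random.default_rng(0)
        frames = [rng.uniform(1, 5, (4, 4)) for _ in range(3)]
        base = demodulate(*frames).values
        scaled = demodulate(*(3.5 * f for f in frames)).values
        assert np.allclose(scaled, 3.5 * base)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            demodulate(np.zeros((3, 3)), np.zeros((3, 3)), np.zeros((4, 4)))


class TestCalibrate:
    def test_self_calibration_returns_reference_reflectance(self):
        amp = AmplitudeMap(np.full((4, 4), 2.0), 490, 0.15)
        out = calibrate_reflectance(amp, amp, 0.8)
        assert np.allclose(out.values, 0.8)

    def test_double_amplitude_doubles_reflectance(self):
        ref = AmplitudeMap(np.full((4, 4), 1.5), 550, 0.61)
        sam = AmplitudeMap(np.full((4, 4), 3.0), 550, 0.61)
        assert np.allclose(calibrate_reflectance(sam, ref, 0.4).values, 0.8)

    def test_above_one_flagged_not_clipped(self):
        ref = AmplitudeMap(np.ones((2, 2)), 600, 1.37)
        sam = AmplitudeMap(np.full((2, 2), 3.0), 600, 1.37)
        out = calibrate_reflectance(sam, ref, 0.5)
        assert np.allclose(out.values, 1.5)
        assert out.n_above_one == 4

    def test_zero_reference_pixels_counted_invalid(self):
        ref_vals = np.ones((2, 2))
        ref_vals[0, 0] = 0.0
        out = calibrate_reflectance(
            AmplitudeMap(np.ones((2, 2)), 490, 0.15),
            AmplitudeMap(ref_vals, 490, 0.15), 0.8)
        assert out.invalid.sum() == 1

    def test_channel_mismatch_rejected(self):
        a = AmplitudeMap(np.ones((2, 2)), 490, 0.15)
        b = AmplitudeMap(np.ones((2, 2)), 550, 0.15)
        with pytest.raises(ValueError):
            calibrate_reflectance(a, b, 0.8)


class TestCTConversion:
    CAL = CTCalibration(raw_air=100.0, raw_water=1100.0, mu_water=0.0227)

    @pytest.mark.parametrize("raw,expected", [
        (1100.0, 0.0227), (100.0, 0.0), (600.0, 0.0227 / 2)])
    def test_affine_anchors_and_midpoint(self, raw, expected):
        out = ct_to_attenuation(np.full((2, 2), raw), self.CAL)
        assert np.allclose(out.values, expected)

    def test_negative_values_clamped_and_counted(self):
        out = ct_to_attenuation(np.array([[50.0, 200.0]]), self.CAL)
        assert out.values[0, 0] == 0.0
        assert out.n_clamped == 1

    def test_degenerate_calibration_rejected(self):
        with pytest.raises(ValueError):
            CTCalibration(raw_air=5.0, raw_water=5.0)


class TestCouplingMask:
    def test_full_mask_is_identity(self):
        stack = np.arange(2 * 3 * 3, dtype=float).reshape(2, 3, 3)
        out = apply_coupling_mask(stack, np.ones((3, 3), bool))
        assert np.array_equal(out, stack)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            apply_coupling_mask(np.ones((2, 3, 3)), np.zeros((3, 3), bool))

    def test_windows_overlapping_masked_half_rejected_by_sampling(self):
        mask = np.ones((40, 40), bool)
        roi = ROIRecord(1, "S", "P", "Adipose", mask, mask.sum() * 0.15**2)
        coupling = np.ones((40, 40), bool)
        coupling[:, :20] = False  # left half unusable
        wins = tile_roi(roi, 3.0, 0.15, coupling)  # 20 px windows
        assert wins and all(c >= 20 for _, c, _ in wins)

    def test_single_hole_excludes_exactly_covering_windows(self):
        """Window rejections equal the number of windows covering the hole."""
        mask = np.ones((8, 8), bool)
        roi = ROIRecord(1, "S", "P", "Adipose", mask, mask.sum())
        full = tile_roi(roi, 4.0, 1.0, np.ones((8, 8), bool))  # 4px windows
        holey = np.ones((8, 8), bool)
        holey[1, 1] = False
        wins = tile_roi(roi, 4.0, 1.0, holey)
        covering = [w for w in full
                    if w[0] <= 1 < w[0] + 4 and w[1] <= 1 < w[1] + 4]
        assert len(full) - len(wins) == len(covering) == 1


class TestRoundTrip:
    def test_forward_then_inverse_reproduces_truth_channels(self):
        """Noise-free raw simulation -> demodulate -> calibrate -> attenuate
        reproduces every truth channel to <= 1e-9 relative error."""
        sp = generate_specimen(PhantomConfig(seed=21), seed=21)
        truth = {
            (s.wavelength, s.spatial_frequency):
                np.clip(sp.channels[i], 0.0, 1.0)
            for i, s in enumerate(CHANNEL_SPECS) if s.modality == "SFDI"
        }
        raw_sfdi = generate_raw_sfdi(truth, noise_sd=0.0, seed=0)
        raw_ct = generate_raw_ct(sp.channel("CT"), seed=0)
        rec = reconstruct_specimen(sp, raw_sfdi, raw_ct)
        for i, spec in enumerate(CHANNEL_SPECS):
            if spec.modality == "microCT":
                ok = ~(raw_ct.air_mask | raw_ct.water_mask)
                num = np.abs(rec.channels[i][ok] - sp.channels[i][ok])
                den = np.maximum(np.abs(sp.channels[i][ok]), 1e-12)
            else:
                num = np.abs(rec.channels[i] - truth[(spec.wavelength,
                                                      spec.spatial_frequency)])
                den = np.maximum(truth[(spec.wavelength,
                                        spec.spatial_frequency)], 1e-12)
            assert (num / den).max() <= 1e-9

    def test_noisy_recovery_unbiased_over_seeds(self):
        """1% frame noise: recovered uniform R = 0.5 mean within 3 SE."""
        truth = {(700, 0.61): np.full((24, 24), 0.5)}
        means = []
        for seed in range(10):
            raw = generate_raw_sfdi(truth, noise_sd=0.01, seed=seed)
            amp = demodulate(*raw.frames[(700, 0.61)], wavelength=700,
                             spatial_frequency=0.61)
            ref = demodulate(*raw.reference_frames[(700, 0.61)],
                             wavelength=700, spatial_frequency=0.61)
            rec = calibrate_reflectance(amp, ref,
                                        raw.reference_reflectance[(700, 0.61)])
            means.append(rec.values.mean())
        means = np.asarray(means)
        se = means.std(ddof=1) / np.sqrt(means.size)
        assert abs(means.mean() - 0.5) <= 3 * max(se, 1e-6)
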