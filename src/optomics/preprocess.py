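"""Raw-acquisition normalization: SFDI demodulation and reflectance
calibration, micro-CT conversion to linear attenuation, coupling-mask
application.

Three-phase amplitude demodulation uses the standard form

    M_AC = (sqrt(2)/3) * sqrt((I1-I2)^2 + (I2-I3)^2 + (I3-I1)^2),

which is invariant to a global phase offset of the sinusoidal pattern. The
planar (f = 0) channel carries no AC component; its amplitude is the
three-frame mean (``demodulate_dc``). Calibration is a single-ratio
normalization against a standard of known reflectance. Micro-CT scanner
units are mapped affinely to attenuation using air/water anchors.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .channels import CHANNEL_SPECS, N_CHANNELS, ChannelSpec
from .phantom import RawCTSlice, RawFrameSet, SpecimenImage


@dataclass
class AmplitudeMap:
    """Demodulated AC (or DC) amplitude, intensity units."""

    values: np.ndarray
    wavelength: int | None = None
    spatial_frequency: float | None = None


@dataclass
class ReflectanceMap:
    """Calibrated diffuse reflectance, unitless.

    ``invalid`` flags pixels where calibration failed (zero reference);
    ``n_above_one`` counts physically suspect pixels (> 1, specular/noise).
    """

    values: np.ndarray
    wavelength: int | None = None
    spatial_frequency: float | None = None
    invalid: np.ndarray | None = None
    n_above_one: int = 0


@dataclass
class AttenuationMap:
    """Linear attenuation coefficient, mm^-1, at the stated tube energy."""

    values: np.ndarray
    energy_setting: float = 50.0
    n_clamped: int = 0


@dataclass
class CTCalibration:
    """Two-point scanner-unit calibration: air -> 0, water -> mu_water."""

    raw_air: float
    raw_water: float
    mu_water: float = 0.0227  # mm^-1, configurable placeholder at 50 kVp

    def __post_init__(self) -> None:
        if self.raw_air == self.raw_water:
            raise ValueError("raw_air and raw_water must differ")
        if self.mu_water <= 0:
            raise ValueError("mu_water must be positive")


def demodulate(i1: np.ndarray, i2: np.ndarray, i3: np.ndarray,
               wavelength: int | None = None,
               spatial_frequency: float | None = None) -> AmplitudeMap:
    """Three-phase AC amplitude demodulation (phases 0, 2pi/3, 4pi/3)."""
    arrs = [np.asarray(a, dtype=np.float64) for a in (i1, i2, i3)]
    shapes = {a.shape for a in arrs}
    if len(shapes) != 1:
        raise ValueError(
            f"phase-frame shape mismatch: {[a.shape for a in arrs]}")
    if not all(np.isfinite(a).all() for a in arrs):
        raise ValueError("phase frames contain non-finite values")
    a, b, c = arrs
    m_ac = (np.sqrt(2.0) / 3.0) * np.sqrt(
        (a - b) ** 2 + (b - c) ** 2 + (c - a) ** 2)
    return AmplitudeMap(m_ac, wavelength, spatial_frequency)


def demodulate_dc(i1: np.ndarray, i2: np.ndarray, i3: np.ndarray,
                  wavelength: int | None = None) -> AmplitudeMap:
    """DC amplitude for planar (f = 0) illumination: the three-frame mean."""
    arrs = [np.asarray(a, dtype=np.float64) for a in (i1, i2, i3)]
    if len({a.shape for a in arrs}) != 1:
        raise ValueError(
            f"phase-frame shape mismatch: {[a.shape for a in arrs]}")
    return AmplitudeMap((arrs[0] + arrs[1] + arrs[2]) / 3.0, wavelength, 0.0)


def demodulate_frames(frames: np.ndarray, spatial_frequency: float,
                      wavelength: int | None = None) -> AmplitudeMap:
    """Dispatch on frequency: AC demodulation for f > 0, frame mean for f = 0."""
    if frames.shape[0] != 3:
        raise ValueError("expected a (3, H, W) phase-frame stack")
    if spatial_frequency > 0:
        amp = demodulate(*frames, wavelength=wavelength,
                         spatial_frequency=spatial_frequency)
    else:
        amp = demodulate_dc(*frames, wavelength=wavelength)
    return amp


def calibrate_reflectance(sample: AmplitudeMap, reference: AmplitudeMap,
                          reference_reflectance: float) -> ReflectanceMap:
    """Single-ratio calibration: R_d = (M_sample / M_reference) * R_reference.

    Pixels with zero reference amplitude are flagged invalid and counted.
    """
    if (sample.wavelength, sample.spatial_frequency) != (
            reference.wavelength, reference.spatial_frequency):
        raise ValueError("sample/reference channel mismatch")
    if sample.values.shape != reference.values.shape:
        raise ValueError("sample/reference shape mismatch")
    ref = reference.values
    invalid = ref == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r_d = sample.values / ref * reference_reflectance
    r_d = np.where(invalid, 0.0, r_d)
    return ReflectanceMap(
        values=r_d, wavelength=sample.wavelength,
        spatial_frequency=sample.spatial_frequency,
        invalid=invalid, n_above_one=int((r_d > 1.0).sum()),
    )


def ct_to_attenuation(raw_ct: np.ndarray, cal: CTCalibration,
                      energy_setting: float = 50.0) -> AttenuationMap:
    """Affine scanner-unit -> attenuation map; negatives clamped and counted."""
    raw = np.asarray(raw_ct, dtype=np.float64)
    mu = (raw - cal.raw_air) / (cal.raw_water - cal.raw_air) * cal.mu_water
    n_clamped = int((mu < 0).sum())
    return AttenuationMap(np.clip(mu, 0.0, None), energy_setting, n_clamped)


def apply_coupling_mask(stack: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Mark pixels outside the coupling mask invalid (NaN) in every channel.

    The sampling stage independently enforces that no window contains an
    invalid pixel; NaN marking here makes accidental use loud downstream.
    """
    stack = np.asarray(stack, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if stack.shape[-2:] != mask.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match stack {stack.shape[-2:]}")
    if not mask.any():
        raise ValueError("empty coupling mask: no analyzable tissue")
    out = stack.copy()
    out[..., ~mask] = np.nan
    return out


def reconstruct_specimen(
    truth: SpecimenImage,
    raw_sfdi: RawFrameSet,
    raw_ct: RawCTSlice,
    cal: CTCalibration | None = None,
) -> SpecimenImage:
    """Rebuild a physical-unit 17-channel stack from raw acquisitions.

    Calibration anchors default to the scanner-unit means over the raw
    slice's air/water target disks. ROI/masks/ids are carried over from the
    truth specimen (co-registration is assumed; the modalities are generated
    on a common grid).
    """
    if cal is None:
        cal = CTCalibration(
            raw_air=float(raw_ct.image[raw_ct.air_mask].mean()),
            raw_water=float(raw_ct.image[raw_ct.water_mask].mean()),
            mu_water=raw_ct.mu_water,
        )
    channels = np.empty_like(truth.channels)
    for ci, spec in enumerate(truth.channel_specs):
        if spec.modality == "microCT":
            channels[ci] = ct_to_attenuation(raw_ct.image, cal).values
        else:
            key = (spec.wavelength, spec.spatial_frequency)
            amp = demodulate_frames(
                raw_sfdi.frames[key], spec.spatial_frequency, spec.wavelength)
            ref = demodulate_frames(
                raw_sfdi.reference_frames[key], spec.spatial_frequency,
                spec.wavelength)
            channels[ci] = calibrate_reflectance(
                amp, ref, raw_sfdi.reference_reflectance[key]).values
    valid = truth.valid_mask & ~(raw_ct.air_mask | raw_ct.water_mask)
    return SpecimenImage(
        specimen_id=truth.specimen_id, patient_id=truth.patient_id,
        pixel_pitch=truth.pixel_pitch, channel_specs=truth.channel_specs,
        channels=channels, valid_mask=valid,
        roi_label_map=truth.roi_label_map, rois=truth.rois,
    )
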