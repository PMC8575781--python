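"""Synthetic co-registered multimodal tissue phantoms.

Generates specimen image stacks (1 micro-CT attenuation channel + 16
SFDI calibrated-reflectance channels, pre-registered on a common 0.15 mm
pixel grid), raw three-phase SFDI frame sets with reference-standard frames,
raw micro-CT slices with air/water calibration targets, and whole cohorts
with a configurable mix of benign-only / malignant-only / mixed specimens.

The texture model is a per-ROI Gaussian random field multiplied onto the
channel means — it gives texture-matrix features genuine spatial signal
without claiming biological fidelity. A per-specimen multiplicative random
effect (one factor per modality) induces patient-level correlation, which is
what makes patient-level cross-validation splitting consequential.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .channels import (
    CHANNEL_SPECS,
    N_CHANNELS,
    SPATIAL_FREQUENCIES_MM,
    WAVELENGTHS_NM,
    ChannelSpec,
)
from .subtypes import (
    BENIGN_SUBTYPES,
    DEFAULT_PREVALENCE,
    MALIGNANT_SUBTYPES,
    SUBTYPES,
    SubtypeAppearance,
    default_appearances,
    is_malignant,
)

DEFAULT_PIXEL_PITCH_MM = 0.15

THREE_PHASES: tuple[float, ...] = (0.0, 2 * np.pi / 3, 4 * np.pi / 3)


class PlacementError(RuntimeError):
    """Raised when the requested ROIs cannot be placed without overlap."""


@dataclass
class PhantomConfig:
    """Geometry and composition of one synthetic specimen."""

    image_size: int = 256
    pixel_pitch: float = DEFAULT_PIXEL_PITCH_MM
    n_rois_per_specimen: int = 4
    roi_shape: str = "ellipse"  # "ellipse" or "blob"
    roi_area_range_mm2: tuple[float, float] = (55.0, 130.0)
    subtype_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE)
    )
    #: SD of the per-specimen lognormal intensity factor, one per modality.
    specimen_effect_sd: float = 0.08
    #: When > 0, punch this many random holes in the coupling mask.
    n_coupling_holes: int = 0
    coupling_hole_radius_px: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if self.image_size < 16:
            raise ValueError("image_size too small")
        if self.roi_shape not in ("ellipse", "blob"):
            raise ValueError(f"unknown roi_shape: {self.roi_shape!r}")
        weights = self.subtype_prevalence
        if any(w < 0 for w in weights.values()) or sum(weights.values()) <= 0:
            raise ValueError("prevalence weights must be nonnegative, not all zero")
        unknown = set(weights) - set(SUBTYPES)
        if unknown:
            raise ValueError(f"unknown subtypes in prevalence: {sorted(unknown)}")


@dataclass
class ROIRecord:
    """One histologically labelled region of interest."""

    roi_id: int
    specimen_id: str
    patient_id: str
    subtype: str
    mask: np.ndarray  # boolean image
    area_mm2: float

    @property
    def malignant(self) -> bool:
        return is_malignant(self.subtype)


@dataclass
class SpecimenImage:
    """Co-registered 17-channel stack for one tumour slice.

    channels : float array, shape (17, H, W), physical units (attenuation in
        mm^-1 for micro-CT; unitless calibrated reflectance for SFDI).
    valid_mask : boolean coupling mask; sampling never draws windows that
        touch invalid pixels.
    roi_label_map : int image, 0 = unlabelled, k = rois[k-1].
    """

    specimen_id: str
    patient_id: str
    pixel_pitch: float
    channel_specs: tuple[ChannelSpec, ...]
    channels: np.ndarray
    valid_mask: np.ndarray
    roi_label_map: np.ndarray
    rois: list[ROIRecord]

    def channel(self, spec_or_tag: ChannelSpec | str) -> np.ndarray:
        tag = spec_or_tag.tag if isinstance(spec_or_tag, ChannelSpec) else spec_or_tag
        for i, s in enumerate(self.channel_specs):
            if s.tag == tag:
                return self.channels[i]
        raise KeyError(f"channel {tag!r} not in stack")


@dataclass
class RawFrameSet:
    """Raw three-phase SFDI frames plus matched reference-standard frames.

    frames / reference_frames : dict keyed by (wavelength, frequency) holding
    a (3, H, W) intensity array, one frame per phase in THREE_PHASES.
    """

    phases: tuple[float, ...]
    frames: dict[tuple[int, float], np.ndarray]
    reference_frames: dict[tuple[int, float], np.ndarray]
    reference_reflectance: dict[tuple[int, float], float]


@dataclass
class RawCTSlice:
    """Raw micro-CT slice in scanner units with air/water calibration disks."""

    image: np.ndarray
    air_mask: np.ndarray
    water_mask: np.ndarray
    raw_air: float
    raw_water: float
    mu_water: float
    energy_kvp: float = 50.0


# ---------------------------------------------------------------------------
# ROI geometry
# ---------------------------------------------------------------------------

def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                  axes: tuple[float, float], angle: float) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = dr * ca + dc * sa
    v = -dr * sa + dc * ca
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def _blob_mask(shape: tuple[int, int], center: tuple[float, float],
               mean_radius: float, rng: np.random.Generator) -> np.ndarray:
    """Star-convex blob: ellipse-like region with a lumpy radial boundary."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    theta = np.arctan2(dc, dr)
    n_harm = 4
    amps = rng.uniform(-0.18, 0.18, size=n_harm)
    phases = rng.uniform(0, 2 * np.pi, size=n_harm)
    radius = mean_radius * (
        1.0 + sum(a * np.cos((k + 2) * theta + p)
                  for k, (a, p) in enumerate(zip(amps, phases)))
    )
    return dr**2 + dc**2 <= radius**2


def _place_rois(config: PhantomConfig, subtype_draws: list[str],
                rng: np.random.Generator, max_retries: int = 400
                ) -> list[tuple[str, np.ndarray]]:
    """Place non-overlapping ROI masks; raises PlacementError when stuck."""
    n = config.image_size
    shape = (n, n)
    occupied = np.zeros(shape, dtype=bool)
    margin = 3
    placed: list[tuple[str, np.ndarray]] = []
    for subtype in subtype_draws:
        area_mm2 = rng.uniform(*config.roi_area_range_mm2)
        area_px = area_mm2 / config.pixel_pitch**2
        ok = False
        for _ in range(max_retries):
            if config.roi_shape == "ellipse":
                ratio = rng.uniform(0.75, 1.0)
                b = np.sqrt(area_px / (np.pi * ratio))
                a = ratio * b
                angle = rng.uniform(0, np.pi)
                lim = max(a, b) + margin
                if n - 2 * lim <= 1:
                    continue
                center = tuple(rng.uniform(lim, n - lim, size=2))
                mask = _ellipse_mask(shape, center, (a, b), angle)
            else:
                radius = np.sqrt(area_px / np.pi)
                lim = 1.25 * radius + margin
                if n - 2 * lim <= 1:
                    continue
                center = tuple(rng.uniform(lim, n - lim, size=2))
                mask = _blob_mask(shape, center, radius, rng)
            if not (mask & occupied).any():
                occupied |= mask
                placed.append((subtype, mask))
                ok = True
                break
        if not ok:
            raise PlacementError(
                f"could not place ROI {len(placed) + 1}/{len(subtype_draws)} "
                f"({subtype}) without overlap after {max_retries} retries"
            )
    return placed


# ---------------------------------------------------------------------------
# Specimen generation
# ---------------------------------------------------------------------------

def _texture_field(shape: tuple[int, int], corr_len_px: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Unit-SD Gaussian random field with the given correlation length."""
    white = rng.standard_normal(shape)
    if corr_len_px <= 0:
        return white
    smooth = gaussian_filter(white, sigma=corr_len_px, mode="reflect")
    sd = smooth.std()
    if sd == 0:
        return np.zeros(shape)
    return smooth / sd


def _channel_mean(app: SubtypeAppearance, spec: ChannelSpec) -> float:
    if spec.modality == "microCT":
        return app.mean_attenuation
    return app.mean_reflectance(spec.wavelength, spec.spatial_frequency)


#: Background (unlabelled tissue) rendered as mild connective-like matrix.
_BACKGROUND_SUBTYPE = "NormalConnective"

#: Texture of the micro-CT channel is subtype-independent: X-ray attenuation
#: of dense (fibrous and malignant) tissue is spatially similar, so the
#: fibrous-vs-malignant texture contrast lives in the optical channels only
#: and the modalities stay complementary. (Adipose remains separable on CT
#: through its mean attenuation.)
CT_TEXTURE_CORR_MM = 0.6
CT_TEXTURE_AMPLITUDE = 0.09


def generate_specimen(
    config: PhantomConfig,
    appearances: dict[str, SubtypeAppearance] | None = None,
    seed: int | None = None,
    specimen_id: str = "S000",
    patient_id: str = "P000",
    subtypes: list[str] | None = None,
) -> SpecimenImage:
    """Generate one co-registered 17-channel specimen with labelled ROIs.

    ``subtypes`` fixes the ROI subtypes explicitly; otherwise they are drawn
    from ``config.subtype_prevalence``. Identical (config, seed) gives
    bit-identical output.
    """
    if appearances is None:
        appearances = default_appearances()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.image_size
    shape = (n, n)

    if subtypes is None:
        names = [s for s in SUBTYPES if config.subtype_prevalence.get(s, 0) > 0]
        weights = np.array([config.subtype_prevalence[s] for s in names], float)
        weights /= weights.sum()
        subtypes = list(rng.choice(names, size=config.n_rois_per_specimen,
                                   p=weights))
    else:
        for s in subtypes:
            if s not in SUBTYPES:
                raise ValueError(f"unknown subtype {s!r}")

    placed = _place_rois(config, subtypes, rng)

    # Per-specimen multiplicative random effect, one factor per modality.
    ct_factor = float(np.exp(rng.normal(0.0, config.specimen_effect_sd)))
    sfdi_factor = float(np.exp(rng.normal(0.0, config.specimen_effect_sd)))

    bg_app = appearances[_BACKGROUND_SUBTYPE]
    channels = np.empty((N_CHANNELS, n, n), dtype=np.float64)
    ct_corr_px = CT_TEXTURE_CORR_MM / config.pixel_pitch
    bg_field = _texture_field(
        shape, bg_app.texture_correlation_length / config.pixel_pitch, rng)
    bg_ct_field = _texture_field(shape, ct_corr_px, rng)
    bg_ct_amp = CT_TEXTURE_AMPLITUDE if bg_app.texture_amplitude > 0 else 0.0
    for ci, spec in enumerate(CHANNEL_SPECS):
        if spec.modality == "microCT":
            mean = _channel_mean(bg_app, spec) * ct_factor
            channels[ci] = mean * (1.0 + bg_ct_amp * bg_ct_field)
        else:
            mean = _channel_mean(bg_app, spec) * sfdi_factor
            channels[ci] = mean * (1.0 + bg_app.texture_amplitude * bg_field)

    roi_label_map = np.zeros(shape, dtype=np.int32)
    rois: list[ROIRecord] = []
    for k, (subtype, mask) in enumerate(placed, start=1):
        app = appearances[subtype]
        field_ = _texture_field(
            shape, app.texture_correlation_length / config.pixel_pitch, rng)
        ct_field = _texture_field(shape, ct_corr_px, rng)
        texture = 1.0 + app.texture_amplitude * field_
        # texture_amplitude == 0 disables texture in every channel (the
        # noise-free degenerate contract); otherwise CT texture strength is
        # the subtype-independent constant
        ct_amp = CT_TEXTURE_AMPLITUDE if app.texture_amplitude > 0 else 0.0
        ct_texture = 1.0 + ct_amp * ct_field
        for ci, spec in enumerate(CHANNEL_SPECS):
            if spec.modality == "microCT":
                mean = _channel_mean(app, spec) * ct_factor
                channels[ci][mask] = mean * ct_texture[mask]
            else:
                mean = _channel_mean(app, spec) * sfdi_factor
                channels[ci][mask] = mean * texture[mask]
        roi_label_map[mask] = k
        rois.append(ROIRecord(
            roi_id=k, specimen_id=specimen_id, patient_id=patient_id,
            subtype=subtype, mask=mask,
            area_mm2=float(mask.sum()) * config.pixel_pitch**2,
        ))

    # Additive measurement noise, per ROI appearance (fraction of the mean).
    for ci, spec in enumerate(CHANNEL_SPECS):
        noise = rng.standard_normal(shape)
        sd_map = np.full(shape, bg_app.noise_sd * _channel_mean(bg_app, spec))
        for roi in rois:
            app = appearances[roi.subtype]
            sd_map[roi.mask] = app.noise_sd * _channel_mean(app, spec)
        channels[ci] += sd_map * noise

    np.clip(channels, 0.0, None, out=channels)

    valid_mask = np.ones(shape, dtype=bool)
    for _ in range(config.n_coupling_holes):
        r = config.coupling_hole_radius_px
        cr, cc = rng.integers(0, n, size=2)
        hole = _ellipse_mask(shape, (float(cr), float(cc)), (r, r), 0.0)
        valid_mask &= ~hole

    return SpecimenImage(
        specimen_id=specimen_id, patient_id=patient_id,
        pixel_pitch=config.pixel_pitch, channel_specs=CHANNEL_SPECS,
        channels=channels, valid_mask=valid_mask,
        roi_label_map=roi_label_map, rois=rois,
    )


# ---------------------------------------------------------------------------
# Raw-acquisition forward models
# ---------------------------------------------------------------------------

def generate_raw_sfdi(
    truth_reflectance: dict[tuple[int, float], np.ndarray],
    pixel_pitch: float = DEFAULT_PIXEL_PITCH_MM,
    source_intensity: float = 1000.0,
    reference_reflectance: float | dict[tuple[int, float], float] = 0.8,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> RawFrameSet:
    """Forward-simulate raw three-phase SFDI frames from truth reflectance.

    For AC frequencies f > 0 each frame is
    ``I_k = S * R(x) * (1 + cos(2 pi f x + phi_k)) / 2`` with x in mm along
    image columns; the f = 0 channel is planar illumination ``I_k = S * R``.
    Matched frames over a reflectance standard of known reflectance are
    simulated with the same illumination. ``noise_sd`` is additive Gaussian
    noise expressed as a fraction of the source intensity scale ``S * R``.
    """
    if source_intensity <= 0:
        raise ValueError("source intensity must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    frames: dict[tuple[int, float], np.ndarray] = {}
    ref_frames: dict[tuple[int, float], np.ndarray] = {}
    ref_refl: dict[tuple[int, float], float] = {}
    for key, truth in truth_reflectance.items():
        wavelength, frequency = key
        truth = np.asarray(truth, dtype=np.float64)
        if truth.min() < 0 or truth.max() > 1:
            raise ValueError(f"truth reflectance for {key} outside [0, 1]")
        r_ref = (reference_reflectance[key]
                 if isinstance(reference_reflectance, dict)
                 else float(reference_reflectance))
        x_mm = np.arange(truth.shape[1]) * pixel_pitch
        ref_map = np.full_like(truth, r_ref)
        stack, ref_stack = [], []
        for phase in THREE_PHASES:
            if frequency > 0:
                pattern = (1.0 + np.cos(2 * np.pi * frequency * x_mm + phase)) / 2.0
            else:
                pattern = np.ones_like(x_mm)
            for target, out in ((truth, stack), (ref_map, ref_stack)):
                frame = source_intensity * target * pattern[None, :]
                if noise_sd > 0:
                    frame = frame + rng.normal(
                        0.0, noise_sd * source_intensity * target.mean(),
                        size=frame.shape)
                out.append(np.clip(frame, 0.0, None))
        frames[key] = np.stack(stack)
        ref_frames[key] = np.stack(ref_stack)
        ref_refl[key] = r_ref
    return RawFrameSet(
        phases=THREE_PHASES, frames=frames,
        reference_frames=ref_frames, reference_reflectance=ref_refl,
    )


def generate_raw_ct(
    truth_attenuation: np.ndarray,
    raw_air: float = 100.0,
    raw_water: float = 1100.0,
    mu_water: float = 0.0227,
    noise_sd_raw: float = 0.0,
    seed: int = 0,
) -> RawCTSlice:
    """Forward-simulate a raw micro-CT slice in scanner units.

    The scanner scale maps attenuation affinely: mu = 0 -> raw_air,
    mu = mu_water -> raw_water. Two calibration disks (air and water) are
    stamped into opposite corners so preprocessing can recover the scale.
    """
    if raw_air == raw_water:
        raise ValueError("raw_air and raw_water must differ")
    rng = np.random.default_rng(seed)
    mu = np.asarray(truth_attenuation, dtype=np.float64)
    raw = raw_air + (raw_water - raw_air) * (mu / mu_water)

    shape = mu.shape
    r = max(3, min(shape) // 24)
    air_mask = _ellipse_mask(shape, (r + 1.0, r + 1.0), (r, r), 0.0)
    water_mask = _ellipse_mask(
        shape, (r + 1.0, shape[1] - r - 2.0), (r, r), 0.0)
    raw[air_mask] = raw_air
    raw[water_mask] = raw_water
    if noise_sd_raw > 0:
        raw = raw + rng.normal(0.0, noise_sd_raw, size=shape)
    return RawCTSlice(
        image=raw, air_mask=air_mask, water_mask=water_mask,
        raw_air=raw_air, raw_water=raw_water, mu_water=mu_water,
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

#: Default benign-only : malignant-only : mixed specimen proportions.
DEFAULT_COHORT_PROPORTIONS: tuple[int, int, int] = (14, 3, 37)


def _cohort_class_counts(n_specimens: int,
                         proportions: tuple[float, float, float]
                         ) -> tuple[int, int, int]:
    """Largest-remainder apportionment of specimens to the three classes."""
    p = np.asarray(proportions, dtype=float)
    if p.min() < 0 or p.sum() <= 0:
        raise ValueError("proportions must be nonnegative and not all zero")
    quota = n_specimens * p / p.sum()
    counts = np.floor(quota).astype(int)
    rem = n_specimens - counts.sum()
    order = np.argsort(-(quota - counts))
    for i in range(rem):
        counts[order[i]] += 1
    return tuple(int(c) for c in counts)


def _draw_subtypes_for_class(cls: str, n_rois: int,
                             prevalence: dict[str, float],
                             rng: np.random.Generator) -> list[str]:
    benign = [s for s in BENIGN_SUBTYPES if prevalence.get(s, 0) > 0]
    malignant = [s for s in sorted(MALIGNANT_SUBTYPES) if prevalence.get(s, 0) > 0]

    def draw(pool: list[str], k: int) -> list[str]:
        w = np.array([prevalence[s] for s in pool], float)
        w /= w.sum()
        return list(rng.choice(pool, size=k, p=w))

    if cls == "benign":
        return draw(benign, n_rois)
    if cls == "malignant":
        return draw(malignant, n_rois)
    # mixed: guarantee at least one of each class, fill the rest freely
    n_b = 1 + int(rng.integers(0, n_rois - 1))
    picks = draw(benign, n_b) + draw(malignant, n_rois - n_b)
    return list(rng.permutation(picks))


def generate_cohort(
    n_specimens: int,
    config: PhantomConfig | None = None,
    seed: int = 0,
    proportions: tuple[float, float, float] = DEFAULT_COHORT_PROPORTIONS,
    appearances: dict[str, SubtypeAppearance] | None = None,
) -> tuple[list[SpecimenImage], pd.DataFrame]:
    """Generate a cohort of specimens, one patient per specimen.

    Specimens are split into benign-only / malignant-only / mixed classes in
    the given ``proportions`` (largest-remainder apportionment). Returns the
    specimen list plus an ROI table (specimen_id, patient_id, roi_id,
    subtype, malignant, area_mm2).
    """
    if n_specimens < 2:
        raise ValueError("need at least 2 specimens")
    if config is None:
        config = PhantomConfig()
    counts = _cohort_class_counts(n_specimens, proportions)
    classes = (["benign"] * counts[0] + ["malignant"] * counts[1]
               + ["mixed"] * counts[2])
    if any(c == "mixed" for c in classes) and config.n_rois_per_specimen < 2:
        raise ValueError("mixed specimens need n_rois_per_specimen >= 2")

    root = np.random.SeedSequence(seed)
    class_rng = np.random.default_rng(root.spawn(1)[0])
    order = class_rng.permutation(len(classes))
    specimen_seeds = root.spawn(n_specimens)

    specimens: list[SpecimenImage] = []
    rows = []
    for i in range(n_specimens):
        cls = classes[order[i]]
        sseq = specimen_seeds[i]
        rng = np.random.default_rng(sseq)
        subtypes = _draw_subtypes_for_class(
            cls, config.n_rois_per_specimen, config.subtype_prevalence, rng)
        spec_seed = int(sseq.generate_state(1)[0] % (2**31))
        sid, pid = f"S{i:03d}", f"P{i:03d}"
        specimen = generate_specimen(
            config, appearances=appearances, seed=spec_seed,
            specimen_id=sid, patient_id=pid, subtypes=subtypes)
        specimens.append(specimen)
        for roi in specimen.rois:
            rows.append({
                "specimen_id": sid, "patient_id": pid, "roi_id": roi.roi_id,
                "subtype": roi.subtype, "malignant": roi.malignant,
                "area_mm2": roi.area_mm2,
            })
    roi_table = pd.DataFrame(rows)
    return specimens, roi_table


def cohort_class_of(specimen: SpecimenImage) -> str:
    """Classify a specimen as benign-only / malignant-only / mixed."""
    flags = {roi.malignant for roi in specimen.rois}
    if flags == {False}:
        return "benign"
    if flags == {True}:
        return "malignant"
    return "mixed"
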