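"""Square sub-image sampling from labelled ROIs.

Windows are tiled on a non-overlapping grid (stride = window side) anchored
at the ROI mask's bounding box, keeping only windows entirely inside both
the ROI and the coupling mask. The number of samples drawn per ROI is
proportional to its physical area, capped at the available windows, so all
ROIs are approximately equally sampled per unit area.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantom import ROIRecord, SpecimenImage
from .subtypes import is_malignant

SUB_IMAGE_SIZES_MM: tuple[float, ...] = (2.0, 3.0, 4.0, 5.0)
DEFAULT_SIZE_MM = 5.0  # best-performing size; others remain configurable


@dataclass
class SubImageSample:
    """One square multi-channel sub-image with its labels."""

    sample_id: str
    specimen_id: str
    patient_id: str
    subtype: str
    malignant: bool
    size_mm: float
    window: tuple[int, int, int]  # (row0, col0, side_px)
    channels: np.ndarray  # (17, side, side)


def window_side_px(size_mm: float, pitch: float) -> int:
    """Window side in pixels: round(size_mm / pitch)."""
    if size_mm <= 0 or pitch <= 0:
        raise ValueError("size_mm and pitch must be positive")
    return int(round(size_mm / pitch))


def tile_roi(roi: ROIRecord, size_mm: float, pitch: float,
             coupling_mask: np.ndarray | None = None
             ) -> list[tuple[int, int, int]]:
    """Candidate windows tiling the ROI, row-major from its bounding box.

    Only windows whose every pixel lies inside ``roi.mask`` (and the coupling
    mask, when given) are returned. An ROI smaller than one window yields an
    empty list.
    """
    side = window_side_px(size_mm, pitch)
    mask = roi.mask
    if coupling_mask is not None:
        mask = mask & coupling_mask
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        return []
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    box = mask[r0:r1, c0:c1]
    h, w = box.shape
    if h < side or w < side:
        return []
    # full-coverage indicator for every window position via an area table
    integral = np.pad(np.cumsum(np.cumsum(box, axis=0), axis=1),
                      ((1, 0), (1, 0)))
    cover = (integral[side:, side:] - integral[:-side, side:]
             - integral[side:, :-side] + integral[:-side, :-side])
    full = cover == side * side  # (h - side + 1, w - side + 1)
    # grid anchored in the bounding box at the offset admitting the most
    # windows (deterministic; ties -> smallest offset, which is plain
    # bounding-box anchoring for rectangular ROIs)
    best, best_off = -1, (0, 0)
    for dr in range(min(side, full.shape[0])):
        for dc in range(min(side, full.shape[1])):
            count = int(full[dr::side, dc::side].sum())
            if count > best:
                best, best_off = count, (dr, dc)
    if best <= 0:
        return []
    dr, dc = best_off
    return [(r0 + dr + i * side, c0 + dc + j * side, side)
            for i, j in zip(*np.nonzero(full[dr::side, dc::side]))]


def proportional_counts(roi_areas_mm2: list[float],
                        available_windows: list[int],
                        density: float) -> list[int]:
    """Per-ROI sample counts: min(floor(density * area), available windows)."""
    if density <= 0:
        raise ValueError("density must be positive")
    if len(roi_areas_mm2) != len(available_windows):
        raise ValueError("areas and window counts must align")
    return [min(int(np.floor(density * a)), int(n))
            for a, n in zip(roi_areas_mm2, available_windows)]


def draw_samples(specimen: SpecimenImage, roi: ROIRecord,
                 windows: list[tuple[int, int, int]], count: int,
                 size_mm: float, seed: int = 0) -> list[SubImageSample]:
    """Uniform seeded draw without replacement of ``count`` windows."""
    if count > len(windows):
        raise ValueError(
            f"requested {count} samples but only {len(windows)} windows "
            f"available in ROI {roi.roi_id} of {roi.specimen_id}")
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(len(windows), size=count, replace=False))
    samples = []
    for j, wi in enumerate(chosen):
        r, c, side = windows[wi]
        sub = specimen.channels[:, r : r + side, c : c + side].copy()
        if np.isnan(sub).any():
            raise ValueError(
                f"window ({r}, {c}) in ROI {roi.roi_id} contains invalid pixels")
        samples.append(SubImageSample(
            sample_id=f"{roi.specimen_id}_R{roi.roi_id}_{size_mm:g}mm_{j:03d}",
            specimen_id=roi.specimen_id, patient_id=roi.patient_id,
            subtype=roi.subtype, malignant=is_malignant(roi.subtype),
            size_mm=size_mm, window=(r, c, side), channels=sub,
        ))
    return samples


def sample_specimen(specimen: SpecimenImage, size_mm: float = DEFAULT_SIZE_MM,
                    density: float = 0.05, seed: int = 0
                    ) -> list[SubImageSample]:
    """Tile, count and draw sub-image samples for every ROI of a specimen.

    ``density`` is samples per mm^2 of ROI area (before the availability cap).
    """
    root = np.random.SeedSequence(seed)
    per_roi = [tile_roi(roi, size_mm, specimen.pixel_pitch,
                        specimen.valid_mask) for roi in specimen.rois]
    counts = proportional_counts(
        [roi.area_mm2 for roi in specimen.rois],
        [len(w) for w in per_roi], density)
    samples: list[SubImageSample] = []
    for roi, windows, count, seq in zip(
            specimen.rois, per_roi, counts, root.spawn(len(specimen.rois))):
        roi_seed = int(seq.generate_state(1)[0] % (2**31))
        samples.extend(draw_samples(
            specimen, roi, windows, count, size_mm, seed=roi_seed))
    return samples


def sample_cohort(specimens: list[SpecimenImage],
                  size_mm: float = DEFAULT_SIZE_MM, density: float = 0.05,
                  seed: int = 0) -> list[SubImageSample]:
    """Sample every specimen of a cohort with independent per-specimen seeds."""
    root = np.random.SeedSequence(seed)
    samples: list[SubImageSample] = []
    for specimen, seq in zip(specimens, root.spawn(len(specimens))):
        s = int(seq.generate_state(1)[0] % (2**31))
        samples.extend(sample_specimen(specimen, size_mm, density, seed=s))
    return samples


def filter_adipose(samples: list[SubImageSample],
                   include_adipose: bool) -> list[SubImageSample]:
    """Drop adipose samples when ``include_adipose`` is false."""
    if include_adipose:
        return list(samples)
    return [s for s in samples if s.subtype != "Adipose"]


def sample_manifest(samples: list[SubImageSample]) -> pd.DataFrame:
    """Tabular manifest of the drawn samples."""
    return pd.DataFrame([
        {"sample_id": s.sample_id, "specimen_id": s.specimen_id,
         "patient_id": s.patient_id, "subtype": s.subtype,
         "malignant": s.malignant, "size_mm": s.size_mm,
         "row": s.window[0], "col": s.window[1], "side_px": s.window[2]}
        for s in samples
    ])
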