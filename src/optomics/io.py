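"""On-disk formats: multi-page TIFF stacks with JSON channel manifests,
integer-label ROI TIFFs, and CSV feature/manifest tables.

A specimen is stored as ``<id>_stack.tif`` (one page per channel, float32),
``<id>_labels.tif`` (ROI label map + validity mask), and ``<id>.json``
(channel specs, pitch, ids, ROI metadata). The round trip is lossless up to
float32 storage of channel values; masks and labels are exact.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .channels import ChannelSpec, N_CHANNELS
from .phantom import ROIRecord, SpecimenImage
from .subtypes import SUBTYPES
from .features.extract import META_COLUMNS


def write_stack(specimen: SpecimenImage, out_dir: str | Path) -> Path:
    """Write one specimen; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sid = specimen.specimen_id
    tifffile.imwrite(out_dir / f"{sid}_stack.tif",
                     specimen.channels.astype(np.float32))
    labels = np.stack([
        specimen.roi_label_map.astype(np.int32),
        specimen.valid_mask.astype(np.int32),
    ])
    tifffile.imwrite(out_dir / f"{sid}_labels.tif", labels)
    manifest = {
        "specimen_id": sid,
        "patient_id": specimen.patient_id,
        "pixel_pitch_mm": specimen.pixel_pitch,
        "channels": [
            {"modality": s.modality, "wavelength": s.wavelength,
             "spatial_frequency": s.spatial_frequency, "tag": s.tag}
            for s in specimen.channel_specs
        ],
        "rois": [
            {"roi_id": r.roi_id, "subtype": r.subtype,
             "area_mm2": r.area_mm2} for r in specimen.rois
        ],
    }
    path = out_dir / f"{sid}.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def read_stack(manifest_path: str | Path) -> SpecimenImage:
    """Read a specimen written by :func:`write_stack`."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    sid = manifest["specimen_id"]
    specs = tuple(
        ChannelSpec(c["modality"], c["wavelength"], c["spatial_frequency"])
        for c in manifest["channels"]
    )
    if len(specs) != N_CHANNELS:
        raise ValueError(
            f"manifest lists {len(specs)} channels, expected {N_CHANNELS}")
    if not any(s.modality == "microCT" for s in specs):
        raise ValueError("manifest is missing the microCT channel spec")
    channels = tifffile.imread(
        manifest_path.parent / f"{sid}_stack.tif").astype(np.float64)
    labels = tifffile.imread(manifest_path.parent / f"{sid}_labels.tif")
    roi_label_map = labels[0].astype(np.int32)
    valid_mask = labels[1].astype(bool)
    rois = [
        ROIRecord(
            roi_id=r["roi_id"], specimen_id=sid,
            patient_id=manifest["patient_id"], subtype=r["subtype"],
            mask=roi_label_map == r["roi_id"], area_mm2=r["area_mm2"])
        for r in manifest["rois"]
    ]
    return SpecimenImage(
        specimen_id=sid, patient_id=manifest["patient_id"],
        pixel_pitch=manifest["pixel_pitch_mm"], channel_specs=specs,
        channels=channels, valid_mask=valid_mask,
        roi_label_map=roi_label_map, rois=rois,
    )


def write_feature_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Feature table CSV: metadata columns first, then feature columns."""
    missing = [c for c in META_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing metadata columns: {missing}")
    cols = list(META_COLUMNS) + [c for c in table.columns
                                 if c not in META_COLUMNS]
    if len(set(cols)) != len(cols):
        raise ValueError("duplicate feature column names")
    table[cols].to_csv(path, index=False)


def read_feature_csv(path: str | Path) -> pd.DataFrame:
    """Read a feature CSV, validating schema and subtype values."""
    table = pd.read_csv(path)
    missing = [c for c in META_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature CSV missing metadata columns: {missing}")
    if table.columns.duplicated().any():
        dupes = list(table.columns[table.columns.duplicated()])
        raise ValueError(f"duplicate feature columns: {dupes}")
    bad = ~table["subtype"].isin(SUBTYPES)
    if bad.any():
        row = int(np.nonzero(bad.to_numpy())[0][0])
        raise ValueError(
            f"unknown subtype {table.loc[row, 'subtype']!r} at row {row}")
    table["malignant"] = table["malignant"].astype(bool)
    return table
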