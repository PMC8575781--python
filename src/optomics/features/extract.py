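"""Per-channel and per-sample feature extraction into the feature table."""
from __future__ import annotations

import numpy as np
import pandas as pd

from ..channels import CHANNEL_SPECS, ChannelSpec, arm_indices
from ..sampling import SubImageSample
from .catalog import FeatureCatalog, default_catalog
from .discretize import discretize_fbw
from .firstorder import first_order_features
from .matrices import compute_texture_matrices
from .texture import (
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

#: Metadata columns preceding the feature columns in every feature table.
META_COLUMNS: tuple[str, ...] = (
    "sample_id", "specimen_id", "patient_id", "subtype", "malignant",
    "size_mm",
)


def extract_channel_features(channel_image: np.ndarray, spec: ChannelSpec,
                             catalog: FeatureCatalog | None = None
                             ) -> dict[str, float]:
    """All enabled features for one channel sub-image, in catalog order."""
    if catalog is None:
        catalog = default_catalog()
    image = np.asarray(channel_image, dtype=np.float64)
    if not np.isfinite(image).all():
        raise ValueError(f"channel {spec.tag}: non-finite pixels in sub-image")
    discrete = discretize_fbw(image, catalog.bin_width_for(spec.modality))

    values: dict[str, dict[str, float]] = {}
    if "firstorder" in catalog.enabled_classes:
        values["firstorder"] = first_order_features(image, discrete)
    texture_classes = [c for c in catalog.enabled_classes if c != "firstorder"]
    if texture_classes:
        mats = compute_texture_matrices(discrete, gldm_alpha=catalog.gldm_alpha)
        computers = {
            "glcm": lambda: glcm_features(mats.glcm),
            "glrlm": lambda: glrlm_features(mats.glrlm),
            "glszm": lambda: glszm_features(mats.glszm),
            "gldm": lambda: gldm_features(mats.gldm),
            "ngtdm": lambda: ngtdm_features(mats.ngtdm),
        }
        for cls in texture_classes:
            values[cls] = computers[cls]()

    out: dict[str, float] = {}
    for cls, name in catalog.entries():
        v = values[cls][name]
        if not np.isfinite(v):
            raise ValueError(
                f"non-finite feature {cls}.{name} on channel {spec.tag}")
        out[f"{spec.tag}__{cls}__{name}"] = float(v)
    return out


def extract_sample_features(sample: SubImageSample,
                            catalog: FeatureCatalog | None = None,
                            modality_set: str = "combined") -> dict[str, float]:
    """Concatenated feature row for one sample over the requested arm.

    combined -> 17 x 92 = 1564 values; CT -> 92; SFDI -> 1472 (defaults).
    """
    if catalog is None:
        catalog = default_catalog()
    if sample.channels.shape[0] != len(CHANNEL_SPECS):
        raise ValueError(
            f"sample {sample.sample_id}: expected {len(CHANNEL_SPECS)} "
            f"channels, got {sample.channels.shape[0]}")
    row: dict[str, float] = {}
    for ci in arm_indices(modality_set):
        row.update(extract_channel_features(
            sample.channels[ci], CHANNEL_SPECS[ci], catalog))
    return row


def build_feature_table(samples: list[SubImageSample],
                        catalog: FeatureCatalog | None = None,
                        modality_set: str = "combined") -> pd.DataFrame:
    """FeatureTable: metadata columns then feature columns, one row/sample."""
    if catalog is None:
        catalog = default_catalog()
    rows = []
    for s in samples:
        meta = {
            "sample_id": s.sample_id, "specimen_id": s.specimen_id,
            "patient_id": s.patient_id, "subtype": s.subtype,
            "malignant": s.malignant, "size_mm": s.size_mm,
        }
        meta.update(extract_sample_features(s, catalog, modality_set))
        rows.append(meta)
    table = pd.DataFrame(rows)
    feature_cols = [c for c in table.columns if c not in META_COLUMNS]
    if table[feature_cols].isna().any().any():
        bad = table[feature_cols].isna().any()
        raise ValueError(
            f"missing feature values in columns: "
            f"{list(bad[bad].index[:5])} ...")
    return table


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


def arm_columns(table: pd.DataFrame, modality_set: str) -> list[str]:
    """Feature columns of one modality arm from a combined table."""
    tags = {CHANNEL_SPECS[i].tag for i in arm_indices(modality_set)}
    return [c for c in feature_columns(table)
            if c.split("__", 1)[0] in tags]
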