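"""The per-channel feature catalog and per-modality discretization widths.

The default catalog enables 18 first-order + 23 GLCM + 16 GLRLM + 16 GLSZM
+ 14 GLDM + 5 NGTDM = 92 features per channel, giving 92 x 17 = 1564
features for the combined modality set. The catalog is an editable manifest
(YAML-serializable) so the enabled classes and bin widths can be adjusted
without touching code.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .firstorder import FIRSTORDER_FEATURE_NAMES
from .texture import (
    GLCM_FEATURE_NAMES,
    GLDM_FEATURE_NAMES,
    GLRLM_FEATURE_NAMES,
    GLSZM_FEATURE_NAMES,
    NGTDM_FEATURE_NAMES,
)

FEATURE_CLASSES: tuple[str, ...] = (
    "firstorder", "glcm", "glrlm", "glszm", "gldm", "ngtdm",
)

CLASS_FEATURE_NAMES: dict[str, tuple[str, ...]] = {
    "firstorder": FIRSTORDER_FEATURE_NAMES,
    "glcm": GLCM_FEATURE_NAMES,
    "glrlm": GLRLM_FEATURE_NAMES,
    "glszm": GLSZM_FEATURE_NAMES,
    "gldm": GLDM_FEATURE_NAMES,
    "ngtdm": NGTDM_FEATURE_NAMES,
}

#: Fixed bin widths per modality, in the channel's physical units
#: (attenuation mm^-1 for micro-CT, unitless reflectance for SFDI). Chosen so
#: typical synthetic sub-images discretize to roughly 16-128 gray levels;
#: a tuning default, not a measured value.
DEFAULT_BIN_WIDTHS: dict[str, float] = {"microCT": 0.002, "SFDI": 0.01}


@dataclass
class FeatureCatalog:
    """Ordered per-channel feature manifest with per-modality bin widths."""

    enabled_classes: tuple[str, ...] = FEATURE_CLASSES
    bin_widths: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BIN_WIDTHS))
    gldm_alpha: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.enabled_classes) - set(FEATURE_CLASSES)
        if unknown:
            raise ValueError(f"unknown feature classes: {sorted(unknown)}")
        if any(w <= 0 for w in self.bin_widths.values()):
            raise ValueError("bin widths must be positive")

    def entries(self) -> list[tuple[str, str]]:
        """Ordered (class, feature_name) pairs for one channel."""
        out: list[tuple[str, str]] = []
        for cls in FEATURE_CLASSES:
            if cls in self.enabled_classes:
                out.extend((cls, name) for name in CLASS_FEATURE_NAMES[cls])
        return out

    @property
    def n_per_channel(self) -> int:
        return len(self.entries())

    def column_names(self, channel_tag: str) -> list[str]:
        """Feature column names for one channel, e.g. ``CT__glcm__Contrast``."""
        return [f"{channel_tag}__{cls}__{name}"
                for cls, name in self.entries()]

    def bin_width_for(self, modality: str) -> float:
        try:
            return self.bin_widths[modality]
        except KeyError:
            raise KeyError(f"no bin width configured for modality {modality!r}")

    # -- manifest serialization --------------------------------------------

    def to_dict(self) -> dict:
        return {
            "enabled_classes": list(self.enabled_classes),
            "bin_widths": dict(self.bin_widths),
            "gldm_alpha": self.gldm_alpha,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureCatalog":
        return cls(
            enabled_classes=tuple(d.get("enabled_classes", FEATURE_CLASSES)),
            bin_widths=dict(d.get("bin_widths", DEFAULT_BIN_WIDTHS)),
            gldm_alpha=int(d.get("gldm_alpha", 0)),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "FeatureCatalog":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_catalog() -> FeatureCatalog:
    return FeatureCatalog()
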