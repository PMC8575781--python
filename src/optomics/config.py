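"""Run configuration: one serializable object covering every stage.

A saved run manifest (config + seeds + package version) is sufficient to
reproduce a run bit-for-bit with the same code version.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .features.catalog import FeatureCatalog


@dataclass
class RunConfig:
    """Parameters for the full simulate -> preprocess -> sample -> extract ->
    evaluate pipeline."""

    seed: int = 0
    out_dir: str = "results"

    # simulate
    n_specimens: int = 12
    image_size: int = 256
    pixel_pitch: float = 0.15
    n_rois_per_specimen: int = 4
    cohort_proportions: tuple[float, float, float] = (14, 3, 37)
    simulate_raw: bool = True        # run the raw-acquisition round trip
    sfdi_noise_sd: float = 0.01
    ct_noise_sd_raw: float = 2.0

    # sample
    size_mm: float = 5.0
    density: float = 0.05            # samples per mm^2 of ROI area
    include_adipose: bool = True

    # extract
    catalog: FeatureCatalog = field(default_factory=FeatureCatalog)

    # evaluate
    arms: tuple[str, ...] = ("ct", "sfdi", "combined")
    n_splits: int = 1000
    mrmr_k: int = 6
    test_fraction: float = 0.3
    rf_n_estimators: int = 500

    def to_dict(self) -> dict:
        d = asdict(self)
        d["catalog"] = self.catalog.to_dict()
        d["cohort_proportions"] = list(self.cohort_proportions)
        d["arms"] = list(self.arms)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "catalog" in d:
            d["catalog"] = FeatureCatalog.from_dict(d["catalog"])
        if "cohort_proportions" in d:
            d["cohort_proportions"] = tuple(d["cohort_proportions"])
        if "arms" in d:
            d["arms"] = tuple(d["arms"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        return cls.from_dict(yaml.safe_load(text))
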