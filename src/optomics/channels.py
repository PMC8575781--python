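"""Channel specifications for the co-registered 17-channel specimen stack.

One micro-CT slice (linear attenuation, mm^-1) plus 16 calibrated-reflectance
SFDI channels: 4 optical wavelengths x 4 illumination spatial frequencies.
"""
from __future__ import annotations

from dataclasses import dataclass

WAVELENGTHS_NM: tuple[int, ...] = (490, 550, 600, 700)
SPATIAL_FREQUENCIES_MM: tuple[float, ...] = (0.00, 0.15, 0.61, 1.37)

#: Frequencies treated as "high spatial frequency" in feature reporting.
HIGH_FREQUENCIES_MM: tuple[float, ...] = (0.61, 1.37)


@dataclass(frozen=True)
class ChannelSpec:
    """One channel of the specimen stack.

    ``modality`` is ``"microCT"`` or ``"SFDI"``; wavelength (nm) and spatial
    frequency (mm^-1) are set for SFDI channels only.
    """

    modality: str
    wavelength: int | None = None
    spatial_frequency: float | None = None

    def __post_init__(self) -> None:
        if self.modality == "microCT":
            if self.wavelength is not None or self.spatial_frequency is not None:
                raise ValueError("microCT channel carries no wavelength/frequency")
        elif self.modality == "SFDI":
            if self.wavelength not in WAVELENGTHS_NM:
                raise ValueError(f"unknown SFDI wavelength: {self.wavelength}")
            if self.spatial_frequency not in SPATIAL_FREQUENCIES_MM:
                raise ValueError(
                    f"unknown SFDI spatial frequency: {self.spatial_frequency}"
                )
        else:
            raise ValueError(f"unknown modality: {self.modality}")

    @property
    def tag(self) -> str:
        """Short channel tag used in feature column names, e.g. ``w490_f1.37``."""
        if self.modality == "microCT":
            return "CT"
        return f"w{self.wavelength}_f{self.spatial_frequency:.2f}"

    @classmethod
    def from_tag(cls, tag: str) -> "ChannelSpec":
        if tag == "CT":
            return cls("microCT")
        if not tag.startswith("w") or "_f" not in tag:
            raise ValueError(f"unrecognized channel tag: {tag!r}")
        w_part, f_part = tag[1:].split("_f")
        return cls("SFDI", wavelength=int(w_part), spatial_frequency=float(f_part))


def default_channel_specs() -> tuple[ChannelSpec, ...]:
    """The canonical 17-channel ordering: micro-CT first, then SFDI sorted by
    (wavelength, frequency)."""
    specs = [ChannelSpec("microCT")]
    for w in WAVELENGTHS_NM:
        for f in SPATIAL_FREQUENCIES_MM:
            specs.append(ChannelSpec("SFDI", wavelength=w, spatial_frequency=f))
    return tuple(specs)


CHANNEL_SPECS: tuple[ChannelSpec, ...] = default_channel_specs()
CHANNEL_TAGS: tuple[str, ...] = tuple(s.tag for s in CHANNEL_SPECS)
N_CHANNELS: int = len(CHANNEL_SPECS)

#: Channel indices per modality arm.
CT_INDICES: tuple[int, ...] = tuple(
    i for i, s in enumerate(CHANNEL_SPECS) if s.modality == "microCT"
)
SFDI_INDICES: tuple[int, ...] = tuple(
    i for i, s in enumerate(CHANNEL_SPECS) if s.modality == "SFDI"
)


def arm_indices(modality_set: str) -> tuple[int, ...]:
    """Channel indices for a modality arm: ``ct``, ``sfdi`` or ``combined``."""
    key = modality_set.lower()
    if key in ("ct", "microct"):
        return CT_INDICES
    if key == "sfdi":
        return SFDI_INDICES
    if key == "combined":
        return tuple(range(N_CHANNELS))
    raise ValueError(f"unknown modality set: {modality_set!r}")
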