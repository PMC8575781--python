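"""Breast tissue subtypes, the malignancy dichotomy, and synthetic appearances.

Seven histologic subtypes are modelled: three non-malignant (adipose, normal
connective tissue, fibrocystic disease) and four invasive cancers (invasive
ductal carcinoma at three grades, plus invasive lobular carcinoma).

The appearance table is synthetic: values are package constants chosen to be
ordering-faithful to the qualitative multimodal contrast of these tissues —
adipose has distinctly low X-ray attenuation; collagen-rich connective and
fibrocystic tissue backscatter strongly at high illumination spatial
frequency; adipose and high-grade IDCa (large Mie-regime scatterers) have low
high-frequency reflectance; invasive cancers attenuate X-rays like fibrous
tissue. No number here is a measured tissue property.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .channels import SPATIAL_FREQUENCIES_MM, WAVELENGTHS_NM

SUBTYPES: tuple[str, ...] = (
    "Adipose",
    "NormalConnective",
    "FibrocysticDisease",
    "IDCaLow",
    "IDCaIntermediate",
    "IDCaHigh",
    "ILCa",
)

MALIGNANT_SUBTYPES: frozenset[str] = frozenset(
    {"IDCaLow", "IDCaIntermediate", "IDCaHigh", "ILCa"}
)
BENIGN_SUBTYPES: tuple[str, ...] = tuple(
    s for s in SUBTYPES if s not in MALIGNANT_SUBTYPES
)


def is_malignant(subtype: str) -> bool:
    if subtype not in SUBTYPES:
        raise ValueError(f"unknown tissue subtype: {subtype!r}")
    return subtype in MALIGNANT_SUBTYPES


#: Specimen-count weights used as subtype prevalence defaults (cohort-like
#: composition in which adipose is by far the most frequent subtype).
DEFAULT_PREVALENCE: dict[str, int] = {
    "Adipose": 49,
    "NormalConnective": 13,
    "FibrocysticDisease": 14,
    "IDCaLow": 10,
    "IDCaIntermediate": 13,
    "IDCaHigh": 10,
    "ILCa": 9,
}


@dataclass(frozen=True)
class SubtypeAppearance:
    """Synthetic per-subtype image appearance.

    mean_attenuation : mm^-1, micro-CT channel mean.
    dc_reflectance : unitless diffuse reflectance at f = 0 (before the
        wavelength gain).
    frequency_profile : multiplicative fall-off per spatial frequency,
        ordered as SPATIAL_FREQUENCIES_MM.
    texture_correlation_length : mm, Gaussian-random-field correlation length.
    texture_amplitude : multiplicative texture SD as a fraction of the mean.
    noise_sd : additive noise SD as a fraction of the mean.
    """

    name: str
    mean_attenuation: float
    dc_reflectance: float
    frequency_profile: tuple[float, float, float, float]
    texture_correlation_length: float = 0.6
    texture_amplitude: float = 0.08
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.mean_attenuation <= 0 or self.dc_reflectance <= 0:
            raise ValueError("appearance means must be positive")
        if any(p <= 0 for p in self.frequency_profile):
            raise ValueError("frequency profile must be positive")
        if self.noise_sd < 0 or self.texture_amplitude < 0:
            raise ValueError("noise/texture fractions must be nonnegative")

    def mean_reflectance(self, wavelength: int, frequency: float) -> float:
        """Channel-mean calibrated reflectance for one (wavelength, frequency)."""
        gain = WAVELENGTH_GAIN[wavelength]
        idx = SPATIAL_FREQUENCIES_MM.index(frequency)
        return self.dc_reflectance * gain * self.frequency_profile[idx]


#: Mild spectral slope across the four wavelengths (relative gain).
WAVELENGTH_GAIN: dict[int, float] = {490: 0.80, 550: 0.90, 600: 1.00, 700: 1.05}


def default_appearances() -> dict[str, SubtypeAppearance]:
    """Synthetic appearance table (see module docstring for the ordering it
    encodes)."""
    table = {
        # Adipose: distinctly low attenuation (trivial for CT); on optics its
        # large Mie-regime vacuoles mimic high-grade carcinoma (same low
        # high-frequency reflectance and fine texture), so the optical arm
        # cannot separate it from IDCa high-grade — the modalities are
        # complementary by construction.
        "Adipose": SubtypeAppearance(
            "Adipose", 0.050, 0.46, (1.00, 0.76, 0.33, 0.13),
            texture_correlation_length=0.35, texture_amplitude=0.14),
        "NormalConnective": SubtypeAppearance(
            "NormalConnective", 0.088, 0.50, (1.00, 0.85, 0.55, 0.38),
            texture_correlation_length=0.6, texture_amplitude=0.08),
        "FibrocysticDisease": SubtypeAppearance(
            "FibrocysticDisease", 0.091, 0.52, (1.00, 0.87, 0.58, 0.42),
            texture_correlation_length=0.7, texture_amplitude=0.10),
        # Invasive cancers: attenuation similar to (slightly above) fibrous
        # tissue, low high-frequency backscatter, fine-grained texture.
        "IDCaLow": SubtypeAppearance(
            "IDCaLow", 0.094, 0.48, (1.00, 0.80, 0.42, 0.22),
            texture_correlation_length=0.45, texture_amplitude=0.10),
        "IDCaIntermediate": SubtypeAppearance(
            "IDCaIntermediate", 0.097, 0.47, (1.00, 0.78, 0.38, 0.18),
            texture_correlation_length=0.40, texture_amplitude=0.12),
        "IDCaHigh": SubtypeAppearance(
            "IDCaHigh", 0.101, 0.46, (1.00, 0.76, 0.33, 0.13),
            texture_correlation_length=0.35, texture_amplitude=0.14),
        "ILCa": SubtypeAppearance(
            "ILCa", 0.095, 0.48, (1.00, 0.79, 0.40, 0.20),
            texture_correlation_length=0.40, texture_amplitude=0.12),
    }
    _validate_contrast_ordering(table)
    return table


def _validate_contrast_ordering(table: dict[str, SubtypeAppearance]) -> None:
    """Enforce the qualitative contrast structure the classifier relies on."""
    adipose = table["Adipose"].mean_attenuation
    for name, app in table.items():
        if name != "Adipose" and app.mean_attenuation <= adipose:
            raise ValueError("adipose attenuation must be strictly lowest")
    f_hi = SPATIAL_FREQUENCIES_MM[-1]
    for w in WAVELENGTHS_NM:
        lo = max(table[s].mean_reflectance(w, f_hi) for s in ("Adipose", "IDCaHigh"))
        hi = min(
            table[s].mean_reflectance(w, f_hi)
            for s in ("NormalConnective", "FibrocysticDisease")
        )
        if lo >= hi:
            raise ValueError(
                "adipose/IDCaHigh must sit below fibrous subtypes at the "
                "highest spatial frequency"
            )
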