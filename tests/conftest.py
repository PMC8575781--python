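"""Shared fixtures: small seeded phantoms and feature tables.

Everything is generated at test time; session scope amortizes the expensive
image-to-feature computations across test modules.
"""
from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from optomics.features import build_feature_table
from optomics.phantom import PhantomConfig, generate_cohort, generate_specimen
from optomics.sampling import sample_cohort

SMALL_RF = {"n_estimators": 100, "max_features": "sqrt"}


@pytest.fixture(scope="session")
def specimen():
    """One deterministic 4-ROI specimen."""
    return generate_specimen(PhantomConfig(seed=11), seed=11,
                             specimen_id="S011", patient_id="P011")


@pytest.fixture(scope="session")
def cohort():
    """A 12-specimen cohort with the default class proportions."""
    specimens, roi_table = generate_cohort(12, PhantomConfig(), seed=0)
    return specimens, roi_table


@pytest.fixture(scope="session")
def cohort_features(cohort):
    """Combined-modality feature table for the 12-specimen cohort."""
    specimens, _ = cohort
    samples = sample_cohort(specimens, size_mm=5.0, density=0.05, seed=1)
    return build_feature_table(samples)


def synthetic_feature_table(n_patients: int = 40, samples_per_patient: int = 4,
                            n_features: int = 25, signal: float = 1.5,
                            patient_sd: float = 0.8, seed: int = 0
                            ) -> pd.DataFrame:
    """Direct (non-image) feature table with patient effects and label signal.

    The first five features carry the label signal; the rest are noise.
    Patient-level random effects make patient-level splitting consequential.
    """
    rng = np.random.default_rng(seed)
    rows = []
    half = n_patients // 2
    for p in range(n_patients):
        label = p < half
        effect = rng.normal(0, patient_sd, size=n_features)
        for s in range(samples_per_patient):
            x = rng.normal(0, 1, size=n_features) + effect
            if label:
                x[:5] += signal
            row = {"sample_id": f"P{p:02d}_{s}", "specimen_id": f"S{p:02d}",
                   "patient_id": f"P{p:02d}", "subtype":
                       "IDCaLow" if label else "NormalConnective",
                   "malignant": bool(label), "size_mm": 5.0}
            row.update({f"CT__firstorder__f{j}": x[j]
                        for j in range(n_features)})
            rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture()
def plain_table():
    return synthetic_feature_table(seed=3)
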