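"""First-order (histogram) statistics: 18 named features.

Entropy and uniformity are computed on the fixed-bin-width discretized
histogram; all other statistics act on the raw intensities. Variance and
standard deviation are population (n-denominator) moments; skewness is
m3 / m2^1.5 and kurtosis m4 / m2^2 (not excess), both defined as 0 on a
constant image.
"""
from __future__ import annotations

import numpy as np

from .discretize import DiscreteImage

FIRSTORDER_FEATURE_NAMES: tuple[str, ...] = (
    "Energy", "Entropy", "Minimum", "Percentile10", "Percentile90",
    "Maximum", "Mean", "Median", "InterquartileRange", "Range",
    "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "StandardDeviation", "Skewness", "Kurtosis",
    "Variance", "Uniformity",
)


def first_order_features(image: np.ndarray,
                         discrete: DiscreteImage) -> dict[str, float]:
    x = np.asarray(image, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty sample")
    mean = float(x.mean())
    m2 = float(((x - mean) ** 2).mean())
    if m2 > 0:
        skew = float(((x - mean) ** 3).mean() / m2**1.5)
        kurt = float(((x - mean) ** 4).mean() / m2**2)
    else:
        skew = kurt = 0.0
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0

    counts = np.bincount(discrete.levels.ravel())[1:]
    p = counts[counts > 0] / counts.sum()
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p**2).sum())

    return {
        "Energy": float((x**2).sum()),
        "Entropy": entropy,
        "Minimum": float(x.min()),
        "Percentile10": float(p10),
        "Percentile90": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(np.median(x)),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "StandardDeviation": float(np.sqrt(m2)),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": m2,
        "Uniformity": uniformity,
    }
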