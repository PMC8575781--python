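"""Feature formulas for the five texture matrix families.

All formulas operate on the matrices built in ``matrices.py`` and follow the
standardized (IBSI-style) definitions; entropies are base 2. Degenerate
conventions are explicit: correlation and MCC on a zero-variance image are 1,
NGTDM coarseness is capped at 1e6, undefined ratios fall back to 0.
"""
from __future__ import annotations

import numpy as np

from .matrices import NGTDMData

COARSENESS_CAP = 1e6


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum()) if p.size else 0.0


# ---------------------------------------------------------------------------
# GLCM (23 features)
# ---------------------------------------------------------------------------

GLCM_FEATURE_NAMES: tuple[str, ...] = (
    "Autocorrelation", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "Id", "Idm", "Idmn", "Idn",
    "Imc1", "Imc2", "InverseVariance", "JointAverage", "JointEnergy",
    "JointEntropy", "MCC", "MaximumProbability", "SumEntropy", "SumSquares",
)


def _glcm_mcc(p: np.ndarray, px: np.ndarray) -> float:
    occ = px > 0
    if occ.sum() <= 1:
        return 1.0
    sub = p[np.ix_(occ, occ)]
    pxo = px[occ]
    a = sub / pxo[:, None]          # P(i,k) / px(i)
    c = sub / pxo[None, :]          # P(j,k) / py(k), symmetric matrix
    q = a @ c.T
    eigs = np.sort(np.real(np.linalg.eigvals(q)))[::-1]
    second = max(float(eigs[1]), 0.0)
    return float(np.sqrt(min(second, 1.0)))


def glcm_features(p: np.ndarray) -> dict[str, float]:
    """All 23 co-occurrence features on a normalized symmetric matrix."""
    n = p.shape[0]
    iv = np.arange(1, n + 1, dtype=np.float64)
    ii, jj = np.meshgrid(iv, iv, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((iv * px).sum())
    mu_y = float((iv * py).sum())
    var_x = float(((iv - mu_x) ** 2 * px).sum())
    var_y = float(((iv - mu_y) ** 2 * py).sum())

    k_diff = np.arange(0, n, dtype=np.float64)
    p_diff = np.zeros(n)
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), p.ravel())
    k_sum = np.arange(2, 2 * n + 1, dtype=np.float64)
    p_sum = np.zeros(2 * n - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel() - 2, p.ravel())

    autocorr = float((ii * jj * p).sum())
    diff_avg = float((k_diff * p_diff).sum())
    hxy = _entropy(p.ravel())
    hx = _entropy(px)
    hy = _entropy(py)
    with np.errstate(divide="ignore"):
        log_pxpy = np.where(px[:, None] * py[None, :] > 0,
                            np.log2(np.maximum(px[:, None] * py[None, :],
                                               np.finfo(float).tiny)), 0.0)
    hxy1 = float(-(p * log_pxpy).sum())
    hxy2 = float(-((px[:, None] * py[None, :]) * log_pxpy).sum())

    if var_x > 0 and var_y > 0:
        correlation = (autocorr - mu_x * mu_y) / np.sqrt(var_x * var_y)
    else:
        correlation = 1.0  # zero-variance convention
    imc1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    inv_var = float((p_diff[1:] / k_diff[1:] ** 2).sum())

    return {
        "Autocorrelation": autocorr,
        "ClusterProminence": float(((ii + jj - mu_x - mu_y) ** 4 * p).sum()),
        "ClusterShade": float(((ii + jj - mu_x - mu_y) ** 3 * p).sum()),
        "ClusterTendency": float(((ii + jj - mu_x - mu_y) ** 2 * p).sum()),
        "Contrast": float(((ii - jj) ** 2 * p).sum()),
        "Correlation": float(correlation),
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": _entropy(p_diff),
        "DifferenceVariance": float(((k_diff - diff_avg) ** 2 * p_diff).sum()),
        "Id": float((p_diff / (1.0 + k_diff)).sum()),
        "Idm": float((p_diff / (1.0 + k_diff**2)).sum()),
        "Idmn": float((p_diff / (1.0 + (k_diff / n) ** 2)).sum()),
        "Idn": float((p_diff / (1.0 + k_diff / n)).sum()),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointAverage": mu_x,
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "MCC": _glcm_mcc(p, px),
        "MaximumProbability": float(p.max()),
        "SumEntropy": _entropy(p_sum),
        "SumSquares": var_x,
    }


# ---------------------------------------------------------------------------
# GLRLM (16) and GLSZM (16) share their algebra: a count matrix over
# (gray level, run length | zone size).
# ---------------------------------------------------------------------------

def _level_size_features(mat: np.ndarray) -> dict[str, float]:
    """Common gray-level x size features on a count matrix P(i, s)."""
    n_lev, n_size = mat.shape
    iv = np.arange(1, n_lev + 1, dtype=np.float64)
    sv = np.arange(1, n_size + 1, dtype=np.float64)
    ns = mat.sum()
    if ns == 0:
        raise ValueError("empty count matrix")
    n_pix = float((mat * sv[None, :]).sum())
    p = mat / ns
    level_sums = mat.sum(axis=1)
    size_sums = mat.sum(axis=0)
    mu_i = float((iv * level_sums / ns).sum())
    mu_s = float((sv * size_sums / ns).sum())
    return {
        "SmallEmphasis": float((size_sums / sv**2).sum() / ns),
        "LargeEmphasis": float((size_sums * sv**2).sum() / ns),
        "GrayLevelNonUniformity": float((level_sums**2).sum() / ns),
        "GrayLevelNonUniformityNormalized": float((level_sums**2).sum() / ns**2),
        "SizeNonUniformity": float((size_sums**2).sum() / ns),
        "SizeNonUniformityNormalized": float((size_sums**2).sum() / ns**2),
        "Percentage": float(ns / n_pix),
        "GrayLevelVariance": float((((iv - mu_i) ** 2)[:, None] * p).sum()),
        "SizeVariance": float((((sv - mu_s) ** 2)[None, :] * p).sum()),
        "Entropy": _entropy(p.ravel()),
        "LowGrayLevelEmphasis": float((level_sums / iv**2).sum() / ns),
        "HighGrayLevelEmphasis": float((level_sums * iv**2).sum() / ns),
        "SmallLowGrayLevelEmphasis": float(
            (mat / (iv[:, None] ** 2 * sv[None, :] ** 2)).sum() / ns),
        "SmallHighGrayLevelEmphasis": float(
            (mat * iv[:, None] ** 2 / sv[None, :] ** 2).sum() / ns),
        "LargeLowGrayLevelEmphasis": float(
            (mat * sv[None, :] ** 2 / iv[:, None] ** 2).sum() / ns),
        "LargeHighGrayLevelEmphasis": float(
            (mat * iv[:, None] ** 2 * sv[None, :] ** 2).sum() / ns),
    }


_GLRLM_RENAME = {
    "SmallEmphasis": "ShortRunEmphasis",
    "LargeEmphasis": "LongRunEmphasis",
    "SizeNonUniformity": "RunLengthNonUniformity",
    "SizeNonUniformityNormalized": "RunLengthNonUniformityNormalized",
    "Percentage": "RunPercentage",
    "SizeVariance": "RunVariance",
    "Entropy": "RunEntropy",
    "LowGrayLevelEmphasis": "LowGrayLevelRunEmphasis",
    "HighGrayLevelEmphasis": "HighGrayLevelRunEmphasis",
    "SmallLowGrayLevelEmphasis": "ShortRunLowGrayLevelEmphasis",
    "SmallHighGrayLevelEmphasis": "ShortRunHighGrayLevelEmphasis",
    "LargeLowGrayLevelEmphasis": "LongRunLowGrayLevelEmphasis",
    "LargeHighGrayLevelEmphasis": "LongRunHighGrayLevelEmphasis",
}

_GLSZM_RENAME = {
    "SmallEmphasis": "SmallAreaEmphasis",
    "LargeEmphasis": "LargeAreaEmphasis",
    "SizeNonUniformity": "SizeZoneNonUniformity",
    "SizeNonUniformityNormalized": "SizeZoneNonUniformityNormalized",
    "Percentage": "ZonePercentage",
    "SizeVariance": "ZoneVariance",
    "Entropy": "ZoneEntropy",
    "LowGrayLevelEmphasis": "LowGrayLevelZoneEmphasis",
    "HighGrayLevelEmphasis": "HighGrayLevelZoneEmphasis",
    "SmallLowGrayLevelEmphasis": "SmallAreaLowGrayLevelEmphasis",
    "SmallHighGrayLevelEmphasis": "SmallAreaHighGrayLevelEmphasis",
    "LargeLowGrayLevelEmphasis": "LargeAreaLowGrayLevelEmphasis",
    "LargeHighGrayLevelEmphasis": "LargeAreaHighGrayLevelEmphasis",
}


def glrlm_features(mat: np.ndarray) -> dict[str, float]:
    base = _level_size_features(mat)
    return {_GLRLM_RENAME.get(k, k): v for k, v in base.items()}


def glszm_features(mat: np.ndarray) -> dict[str, float]:
    base = _level_size_features(mat)
    return {_GLSZM_RENAME.get(k, k): v for k, v in base.items()}


GLRLM_FEATURE_NAMES: tuple[str, ...] = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)

GLSZM_FEATURE_NAMES: tuple[str, ...] = (
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)


# ---------------------------------------------------------------------------
# GLDM (14)
# ---------------------------------------------------------------------------

GLDM_FEATURE_NAMES: tuple[str, ...] = (
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)


def gldm_features(mat: np.ndarray) -> dict[str, float]:
    n_lev, n_dep = mat.shape
    iv = np.arange(1, n_lev + 1, dtype=np.float64)
    jv = np.arange(1, n_dep + 1, dtype=np.float64)
    nz = mat.sum()
    if nz == 0:
        raise ValueError("empty dependence matrix")
    p = mat / nz
    level_sums = mat.sum(axis=1)
    dep_sums = mat.sum(axis=0)
    mu_i = float((iv * level_sums / nz).sum())
    mu_j = float((jv * dep_sums / nz).sum())
    return {
        "SmallDependenceEmphasis": float((dep_sums / jv**2).sum() / nz),
        "LargeDependenceEmphasis": float((dep_sums * jv**2).sum() / nz),
        "GrayLevelNonUniformity": float((level_sums**2).sum() / nz),
        "DependenceNonUniformity": float((dep_sums**2).sum() / nz),
        "DependenceNonUniformityNormalized": float((dep_sums**2).sum() / nz**2),
        "GrayLevelVariance": float((((iv - mu_i) ** 2)[:, None] * p).sum()),
        "DependenceVariance": float((((jv - mu_j) ** 2)[None, :] * p).sum()),
        "DependenceEntropy": _entropy(p.ravel()),
        "LowGrayLevelEmphasis": float((level_sums / iv**2).sum() / nz),
        "HighGrayLevelEmphasis": float((level_sums * iv**2).sum() / nz),
        "SmallDependenceLowGrayLevelEmphasis": float(
            (mat / (iv[:, None] ** 2 * jv[None, :] ** 2)).sum() / nz),
        "SmallDependenceHighGrayLevelEmphasis": float(
            (mat * iv[:, None] ** 2 / jv[None, :] ** 2).sum() / nz),
        "LargeDependenceLowGrayLevelEmphasis": float(
            (mat * jv[None, :] ** 2 / iv[:, None] ** 2).sum() / nz),
        "LargeDependenceHighGrayLevelEmphasis": float(
            (mat * iv[:, None] ** 2 * jv[None, :] ** 2).sum() / nz),
    }


# ---------------------------------------------------------------------------
# NGTDM (5)
# ---------------------------------------------------------------------------

NGTDM_FEATURE_NAMES: tuple[str, ...] = (
    "Coarseness", "Contrast", "Busyness", "Complexity", "Strength",
)


def ngtdm_features(data: NGTDMData) -> dict[str, float]:
    occ = data.p > 0
    iv = data.levels[occ].astype(np.float64)
    p = data.p[occ]
    s = data.s[occ]
    n_vp = float(data.n.sum())
    ngp = int(occ.sum())

    ps = float((p * s).sum())
    coarseness = min(1.0 / ps, COARSENESS_CAP) if ps > 0 else COARSENESS_CAP

    if ngp > 1:
        di = iv[:, None] - iv[None, :]
        pp = p[:, None] * p[None, :]
        contrast = float((pp * di**2).sum() / (ngp * (ngp - 1))
                         * s.sum() / n_vp)
        ipi = iv * p
        busy_den = float(np.abs(ipi[:, None] - ipi[None, :]).sum())
        busyness = ps / busy_den if busy_den > 0 else 0.0
        complexity = float((np.abs(di)
                            * (p[:, None] * s[:, None] + p[None, :] * s[None, :])
                            / (p[:, None] + p[None, :])).sum() / n_vp)
        strength_num = float(((p[:, None] + p[None, :]) * di**2).sum())
        strength = strength_num / s.sum() if s.sum() > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "Coarseness": float(coarseness),
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }
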