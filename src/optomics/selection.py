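"""Minimum-redundancy-maximum-relevance feature ranking.

Relevance and redundancy are plug-in mutual information estimates (base 2)
on equal-frequency-binned features. The greedy MID (difference) scheme is
used: at each step the candidate maximizing

    relevance(f) - mean_{s in selected} MI(f, s)

is added, ties broken by table (catalog) column order. Binning is always
computed on the data handed in — inside cross-validation that is the
training split only, which avoids test leakage.

The 1%-change rule selects how many top-ranked features a classifier needs:
the smallest k >= 2 at which mean accuracy changes by less than 1% relative
to k - 1.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_N_BINS = 10


@dataclass
class MRMRRanking:
    """Greedy MRMR selection result."""

    features: list[str]          # selected names, in selection order
    relevance: list[float]       # MI(feature; label), bits, per selected
    redundancy: list[float]      # mean MI to previously selected, bits
    score: list[float]           # relevance - redundancy at selection time


def equal_frequency_bins(x: np.ndarray, n_bins: int = DEFAULT_N_BINS
                         ) -> np.ndarray:
    """Integer bin codes from equal-frequency (quantile) binning.

    Duplicate quantile edges collapse, so low-cardinality or constant
    features get fewer (possibly one) bins.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("expected 1D feature values")
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.searchsorted(edges, x, side="right").astype(np.int64)


def _mi_from_codes(cx: np.ndarray, cy: np.ndarray) -> float:
    """Plug-in MI (bits) between two integer code arrays."""
    nx = int(cx.max()) + 1
    ny = int(cy.max()) + 1
    joint = np.bincount(cx * ny + cy, minlength=nx * ny).astype(np.float64)
    joint = joint.reshape(nx, ny) / cx.size
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    outer = px[:, None] * py[None, :]
    return float((joint[nz] * np.log2(joint[nz] / outer[nz])).sum())


def mutual_information(x: np.ndarray, y: np.ndarray,
                       n_bins: int = DEFAULT_N_BINS) -> float:
    """MI (bits) of equal-frequency-binned x against discrete labels y."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.size != y.size or x.size < 2:
        raise ValueError("need >= 2 aligned samples")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    cx = equal_frequency_bins(x, n_bins)
    _, cy = np.unique(y, return_inverse=True)
    return _mi_from_codes(cx, cy)


def _bin_matrix(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Column-wise equal-frequency bin codes, shape (n, p)."""
    return np.column_stack([
        equal_frequency_bins(values[:, j], n_bins)
        for j in range(values.shape[1])
    ])


def _mi_vector(codes: np.ndarray, ref: np.ndarray, n_bins: int) -> np.ndarray:
    """MI (bits) of each column of ``codes`` against code vector ``ref``."""
    n, p = codes.shape
    n_ref = int(ref.max()) + 1
    cells = n_bins * n_ref
    combined = codes * n_ref + ref[:, None]  # (n, p)
    flat = (np.arange(p)[:, None] * cells + combined.T).ravel()
    counts = np.bincount(flat, minlength=p * cells).astype(np.float64)
    joint = counts.reshape(p, n_bins, n_ref) / n
    px = joint.sum(axis=2)
    py = joint.sum(axis=1)
    outer = px[:, :, None] * py[:, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log2(joint / outer)
    return np.nansum(terms, axis=(1, 2))


def mrmr_rank(table: pd.DataFrame | np.ndarray, labels: np.ndarray,
              k: int, feature_names: list[str] | None = None,
              n_bins: int = DEFAULT_N_BINS) -> MRMRRanking:
    """Greedy forward MID selection of ``k`` features.

    ``table`` holds feature columns only (metadata already stripped); column
    order is the tie-break order.
    """
    if isinstance(table, pd.DataFrame):
        feature_names = list(table.columns)
        values = table.to_numpy(dtype=np.float64)
    else:
        values = np.asarray(table, dtype=np.float64)
        if feature_names is None:
            feature_names = [f"f{j}" for j in range(values.shape[1])]
    n, p = values.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > p:
        raise ValueError(f"k = {k} exceeds feature count {p}")

    codes = _bin_matrix(values, n_bins)
    _, y_codes = np.unique(np.asarray(labels), return_inverse=True)
    relevance = _mi_vector(codes, y_codes.astype(np.int64), n_bins)

    selected: list[int] = []
    red_sum = np.zeros(p)
    ranking = MRMRRanking([], [], [], [])
    available = np.ones(p, dtype=bool)
    for step in range(k):
        if step == 0:
            scores = relevance.copy()
            red = np.zeros(p)
        else:
            red = red_sum / step
            scores = relevance - red
        scores_masked = np.where(available, scores, -np.inf)
        # argmax with first-index (catalog-order) tie break
        best = int(np.argmax(scores_masked))
        selected.append(best)
        available[best] = False
        ranking.features.append(feature_names[best])
        ranking.relevance.append(float(relevance[best]))
        ranking.redundancy.append(float(red[best]))
        ranking.score.append(float(scores[best]))
        if step < k - 1:
            red_sum += _mi_vector(codes, codes[:, best], n_bins)
    return ranking


def selection_frequency(rankings: list[MRMRRanking]) -> pd.DataFrame:
    """Fraction of splits in which each feature was selected (descending)."""
    counts: dict[str, int] = {}
    for r in rankings:
        for f in r.features:
            counts[f] = counts.get(f, 0) + 1
    n = len(rankings)
    rows = [{"feature": f, "count": c, "fraction": c / n}
            for f, c in sorted(counts.items(), key=lambda kv: -kv[1])]
    return pd.DataFrame(rows)


def choose_feature_count(mean_accuracy: np.ndarray | list[float],
                         threshold_pct: float = 1.0) -> int:
    """Smallest k >= 2 whose relative accuracy change from k-1 is below the
    threshold (percent); K_max when no such k exists.

    ``mean_accuracy[i]`` is the mean accuracy using i+1 features.
    """
    acc = np.asarray(mean_accuracy, dtype=np.float64)
    if acc.size == 0:
        raise ValueError("empty accuracy curve")
    for k in range(2, acc.size + 1):
        prev, cur = acc[k - 2], acc[k - 1]
        change = 100.0 * abs(cur - prev) / prev if prev != 0 else np.inf
        if change < threshold_pct:
            return k
    return int(acc.size)
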