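"""Brute-force reference implementations used only by the test suite.

Every oracle here is written as a direct, slow enumeration of the defining
construction (pixel pairs, runs, flood-filled zones, neighbour loops,
concordant score pairs, exhaustive greedy search) and shares no code with
the package implementations it checks.
"""
from __future__ import annotations

import numpy as np

# Offsets matching the four 2D texture directions at distance 1.
OFFSETS = ((0, 1), (1, 1), (1, 0), (1, -1))


def naive_glcm(levels: np.ndarray) -> np.ndarray:
    """Symmetric, per-angle-normalized, angle-averaged co-occurrence matrix."""
    levels = np.asarray(levels)
    n = int(levels.max())
    h, w = levels.shape
    per_angle = []
    for dr, dc in OFFSETS:
        counts = np.zeros((n, n))
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w:
                    i, j = levels[r, c] - 1, levels[r2, c2] - 1
                    counts[i, j] += 1
                    counts[j, i] += 1  # symmetric
        if counts.sum() > 0:
            per_angle.append(counts / counts.sum())
    return np.mean(per_angle, axis=0)


def _lines_for_direction(levels: np.ndarray, dr: int, dc: int) -> list[list[int]]:
    """All maximal lattice lines through the image along (dr, dc)."""
    h, w = levels.shape
    starts = set()
    for r in range(h):
        for c in range(w):
            pr, pc = r - dr, c - dc
            if not (0 <= pr < h and 0 <= pc < w):
                starts.add((r, c))
    lines = []
    for r0, c0 in sorted(starts):
        line, r, c = [], r0, c0
        while 0 <= r < h and 0 <= c < w:
            line.append(int(levels[r, c]))
            r, c = r + dr, c + dc
        lines.append(line)
    return lines


def naive_glrlm(levels: np.ndarray) -> np.ndarray:
    """Run-length counts merged over the four directions."""
    levels = np.asarray(levels)
    n = int(levels.max())
    mat = np.zeros((n, max(levels.shape)))
    for dr, dc in OFFSETS:
        for line in _lines_for_direction(levels, dr, dc):
            i = 0
            while i < len(line):
                j = i
                while j < len(line) and line[j] == line[i]:
                    j += 1
                mat[line[i] - 1, j - i - 1] += 1
                i = j
    return mat


def naive_glszm(levels: np.ndarray) -> np.ndarray:
    """Zone sizes by BFS flood fill with 8-connectivity."""
    levels = np.asarray(levels)
    n = int(levels.max())
    h, w = levels.shape
    seen = np.zeros((h, w), dtype=bool)
    sizes: list[tuple[int, int]] = []
    for r in range(h):
        for c in range(w):
            if seen[r, c]:
                continue
            val = levels[r, c]
            queue, seen[r, c] = [(r, c)], True
            size = 0
            while queue:
                cr, cc = queue.pop()
                size += 1
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        nr, nc = cr + dr, cc + dc
                        if (0 <= nr < h and 0 <= nc < w and not seen[nr, nc]
                                and levels[nr, nc] == val):
                            seen[nr, nc] = True
                            queue.append((nr, nc))
            sizes.append((int(val), size))
    max_size = max(s for _, s in sizes)
    mat = np.zeros((n, max_size))
    for val, size in sizes:
        mat[val - 1, size - 1] += 1
    return mat


def naive_gldm(levels: np.ndarray, alpha: int = 0) -> np.ndarray:
    """Dependence counts; column = dependent neighbours + 1."""
    levels = np.asarray(levels)
    n = int(levels.max())
    h, w = levels.shape
    mat = np.zeros((n, 9))
    for r in range(h):
        for c in range(w):
            dep = 0
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    nr, nc = r + dr, c + dc
                    if (0 <= nr < h and 0 <= nc < w
                            and abs(int(levels[nr, nc]) - int(levels[r, c]))
                            <= alpha):
                        dep += 1
            mat[levels[r, c] - 1, dep] += 1
    return mat


def naive_ngtdm(levels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n_i, p_i, s_i) per gray level, border-aware neighbourhood means."""
    levels = np.asarray(levels)
    n = int(levels.max())
    h, w = levels.shape
    n_i = np.zeros(n)
    s_i = np.zeros(n)
    for r in range(h):
        for c in range(w):
            neigh = []
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    nr, nc = r + dr, c + dc
                    if 0 <= nr < h and 0 <= nc < w:
                        neigh.append(int(levels[nr, nc]))
            i = levels[r, c] - 1
            n_i[i] += 1
            s_i[i] += abs(levels[r, c] - np.mean(neigh))
    return n_i, n_i / levels.size, s_i


def naive_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """All-pairs concordance count with ties scored 1/2."""
    pos = np.asarray(scores)[np.asarray(labels, dtype=bool)]
    neg = np.asarray(scores)[~np.asarray(labels, dtype=bool)]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def oracle_mi_bits(x_codes: np.ndarray, y_codes: np.ndarray) -> float:
    """Plug-in MI in bits from a contingency table (independent route)."""
    from sklearn.metrics import mutual_info_score

    return float(mutual_info_score(x_codes, y_codes)) / np.log(2)


def exhaustive_mrmr(values: np.ndarray, labels: np.ndarray, k: int,
                    n_bins: int = 10) -> list[int]:
    """Greedy MID selection evaluated by direct per-candidate scoring."""
    n, p = values.shape

    def bins(col: np.ndarray) -> np.ndarray:
        edges = np.unique(np.quantile(col, np.linspace(0, 1, n_bins + 1)[1:-1]))
        return np.searchsorted(edges, col, side="right")

    codes = [bins(values[:, j]) for j in range(p)]
    _, y = np.unique(labels, return_inverse=True)
    relevance = [oracle_mi_bits(codes[j], y) for j in range(p)]
    selected: list[int] = []
    while len(selected) < k:
        best_j, best_score = None, -np.inf
        for j in range(p):
            if j in selected:
                continue
            if selected:
                red = np.mean([oracle_mi_bits(codes[j], codes[s])
                               for s in selected])
            else:
                red = 0.0
            score = relevance[j] - red
            if score > best_score:  # strict: first index wins ties
                best_j, best_score = j, score
        selected.append(best_j)
    return selected


def paired_permutation_auc_pvalue(scores_a: np.ndarray, scores_b: np.ndarray,
                                  labels: np.ndarray, n_perm: int = 10_000,
                                  seed: int = 0) -> float:
    """Two-sided sign-flip permutation test for AUC_a - AUC_b (paired)."""
    rng = np.random.default_rng(seed)
    obs = abs(naive_auc(scores_a, labels) - naive_auc(scores_b, labels))
    n = len(labels)
    hits = 0
    for _ in range(n_perm):
        flip = rng.random(n) < 0.5
        a = np.where(flip, scores_b, scores_a)
        b = np.where(flip, scores_a, scores_b)
        if abs(naive_auc(a, labels) - naive_auc(b, labels)) >= obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)
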