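"""Patient-level Monte Carlo cross-validated malignancy classification.

Each split holds out a random subset of patients (never splitting one
patient's samples across sides), refits MRMR feature selection on the
training samples only, trains a random forest on the top-k features, and
scores the held-out samples. ROC curves are averaged by interpolating TPR
onto a common FPR grid; AUC pairs are compared with DeLong's
placement-value test (paired and unpaired variants).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve

from .features.extract import META_COLUMNS, arm_columns, feature_columns
from .selection import MRMRRanking, mrmr_rank, selection_frequency

DEFAULT_N_SPLITS = 1000
DEFAULT_TEST_FRACTION = 0.3
DEFAULT_RF_PARAMS: dict = {"n_estimators": 500, "max_features": "sqrt"}
ROC_GRID_POINTS = 101


@dataclass
class MCSplit:
    """One patient-level train/test partition."""

    split_id: int
    train_patients: tuple[str, ...]
    test_patients: tuple[str, ...]
    seed: int


@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class AveragedROC:
    """Mean ROC over splits with SD and a 95% closest-curves band."""

    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    sd_tpr: np.ndarray
    band_lower: np.ndarray
    band_upper: np.ndarray
    mean_auc: float
    auc_sd: float
    n_curves: int
    n_in_band: int


@dataclass
class SplitResult:
    split_id: int
    scores: np.ndarray
    y_true: np.ndarray
    metrics: dict[str, float]
    ranking: MRMRRanking
    roc: ROCCurve


@dataclass
class ExperimentSummary:
    """Per-arm results across all Monte Carlo splits."""

    modality_set: str
    adipose_included: bool
    n_splits: int
    per_split: pd.DataFrame               # split_id x metric
    mean_metrics: dict[str, float]
    sd_metrics: dict[str, float]
    averaged_roc: AveragedROC
    selection_frequency: pd.DataFrame
    pooled_scores: np.ndarray = field(repr=False, default=None)
    pooled_labels: np.ndarray = field(repr=False, default=None)


@dataclass
class DeLongResult:
    auc_a: float
    auc_b: float
    var_a: float
    var_b: float
    covariance: float
    z: float
    p_value: float
    paired: bool


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

def make_mc_splits(patients: np.ndarray, labels: np.ndarray,
                   n_splits: int = DEFAULT_N_SPLITS,
                   test_fraction: float = DEFAULT_TEST_FRACTION,
                   seed: int = 0, max_retries: int = 1000) -> list[MCSplit]:
    """Seeded independent patient-level splits with both classes on both
    sides (resampled otherwise)."""
    patients = np.asarray(patients)
    labels = np.asarray(labels, dtype=bool)
    unique_patients = np.unique(patients)
    n_pat = unique_patients.size
    pos_patients = set(patients[labels])
    neg_patients = set(patients[~labels])
    if (sum(1 for p in unique_patients if p in pos_patients) < 2
            or sum(1 for p in unique_patients if p in neg_patients) < 2):
        raise ValueError(
            "cohort too small: need >= 2 patients contributing each class")
    n_test = max(1, int(round(test_fraction * n_pat)))
    if n_test >= n_pat:
        raise ValueError("test fraction leaves no training patients")

    root = np.random.SeedSequence(seed)
    splits: list[MCSplit] = []
    for split_id, seq in enumerate(root.spawn(n_splits)):
        rng = np.random.default_rng(seq)
        split_seed = int(seq.generate_state(1)[0] % (2**31))
        for _ in range(max_retries):
            perm = rng.permutation(unique_patients)
            test = set(perm[:n_test])
            train = set(perm[n_test:])
            if (test & pos_patients and test & neg_patients
                    and train & pos_patients and train & neg_patients):
                splits.append(MCSplit(
                    split_id=split_id,
                    train_patients=tuple(sorted(train)),
                    test_patients=tuple(sorted(test)),
                    seed=split_seed))
                break
        else:
            raise ValueError(
                "could not draw a class-balanced patient split after "
                f"{max_retries} retries")
    return splits


# ---------------------------------------------------------------------------
# ROC and AUC
# ---------------------------------------------------------------------------

def roc_and_auc(scores: np.ndarray, labels: np.ndarray) -> ROCCurve:
    """Empirical ROC; AUC is the tie-corrected Mann-Whitney statistic."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes required for a ROC curve")
    fpr, tpr, _ = roc_curve(labels.astype(int), scores)
    return ROCCurve(fpr=fpr, tpr=tpr,
                    auc=float(roc_auc_score(labels.astype(int), scores)))


def average_roc(curves: list[ROCCurve],
                n_grid: int = ROC_GRID_POINTS) -> AveragedROC:
    """Interpolate member TPRs onto a common FPR grid; average pointwise.

    The 95% band is the pointwise envelope of the floor(0.95 n) member
    curves with the smallest mean absolute vertical distance to the mean.
    """
    if not curves:
        raise ValueError("no ROC curves to average")
    grid = np.linspace(0.0, 1.0, n_grid)
    tprs = np.stack([np.interp(grid, c.fpr, c.tpr) for c in curves])
    tprs[:, 0] = 0.0
    tprs[:, -1] = 1.0
    mean_tpr = tprs.mean(axis=0)
    sd_tpr = tprs.std(axis=0)
    aucs = np.array([c.auc for c in curves])

    n_keep = max(1, int(np.floor(0.95 * len(curves))))
    dist = np.abs(tprs - mean_tpr[None, :]).mean(axis=1)
    keep = np.argsort(dist, kind="stable")[:n_keep]
    band_lower = tprs[keep].min(axis=0)
    band_upper = tprs[keep].max(axis=0)
    return AveragedROC(
        fpr_grid=grid, mean_tpr=mean_tpr, sd_tpr=sd_tpr,
        band_lower=band_lower, band_upper=band_upper,
        mean_auc=float(aucs.mean()), auc_sd=float(aucs.std()),
        n_curves=len(curves), n_in_band=n_keep,
    )


# ---------------------------------------------------------------------------
# DeLong's test
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = x.size
    ranks = np.empty(n, dtype=np.float64)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        ranks[i:j] = 0.5 * (i + j - 1) + 1.0
        i = j
    out = np.empty(n, dtype=np.float64)
    out[order] = ranks
    return out


def _placements(scores: np.ndarray, labels: np.ndarray
                ) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus placement values (V10 over positives, V01 over negatives)."""
    pos = scores[labels]
    neg = scores[~labels]
    m, n = pos.size, neg.size
    tz = _midrank(np.concatenate([pos, neg]))
    tx = _midrank(pos)
    ty = _midrank(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return float(auc), v10, v01


def delong_test(scores_a: np.ndarray, scores_b: np.ndarray,
                labels: np.ndarray, paired: bool = True) -> DeLongResult:
    """DeLong comparison of two empirical AUCs on a shared label vector.

    ``paired=True`` assumes sample-aligned score vectors (same test samples
    scored by two classifiers) and uses the placement-value covariance;
    ``paired=False`` treats the two score sets as independent.
    """
    scores_a = np.asarray(scores_a, dtype=np.float64)
    scores_b = np.asarray(scores_b, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes required")
    if paired and not (scores_a.shape == scores_b.shape == labels.shape):
        raise ValueError("paired test requires aligned score/label vectors")

    auc_a, v10_a, v01_a = _placements(scores_a, labels)
    auc_b, v10_b, v01_b = _placements(scores_b, labels)
    m, n = v10_a.size, v01_a.size

    def _var(v10: np.ndarray, v01: np.ndarray) -> float:
        s10 = v10.var(ddof=1) if m > 1 else 0.0
        s01 = v01.var(ddof=1) if n > 1 else 0.0
        return float(s10 / m + s01 / n)

    var_a = _var(v10_a, v01_a)
    var_b = _var(v10_b, v01_b)
    if paired:
        c10 = float(np.cov(v10_a, v10_b, ddof=1)[0, 1]) if m > 1 else 0.0
        c01 = float(np.cov(v01_a, v01_b, ddof=1)[0, 1]) if n > 1 else 0.0
        cov = c10 / m + c01 / n
    else:
        cov = 0.0
    var_diff = var_a + var_b - 2.0 * cov
    if var_diff <= 0:
        if np.isclose(auc_a, auc_b):
            z, p = 0.0, 1.0
        else:
            raise ValueError(
                f"zero variance of the AUC difference with unequal AUCs "
                f"({auc_a:.4f} vs {auc_b:.4f})")
    else:
        z = (auc_a - auc_b) / np.sqrt(var_diff)
        p = float(2.0 * norm.sf(abs(z)))
    return DeLongResult(auc_a=auc_a, auc_b=auc_b, var_a=var_a, var_b=var_b,
                        covariance=cov, z=float(z), p_value=max(p, 1e-300),
                        paired=paired)


# ---------------------------------------------------------------------------
# Split training and the experiment driver
# ---------------------------------------------------------------------------

def _binary_metrics(y_true: np.ndarray, scores: np.ndarray,
                    threshold: float = 0.5) -> dict[str, float]:
    pred = scores >= threshold
    tp = int((pred & y_true).sum())
    fp = int((pred & ~y_true).sum())
    fn = int((~pred & y_true).sum())
    acc = float((pred == y_true).mean())
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    return {"accuracy": acc, "recall": recall, "precision": precision}


def train_eval_split(table: pd.DataFrame, split: MCSplit, mrmr_k: int,
                     columns: list[str] | None = None,
                     rf_params: dict | None = None) -> SplitResult:
    """Fit MRMR + random forest on the training patients, score the rest.

    ``columns`` restricts the candidate feature columns (one modality arm);
    selection and model fitting see training samples only.
    """
    if rf_params is None:
        rf_params = dict(DEFAULT_RF_PARAMS)
    if columns is None:
        columns = feature_columns(table)
    in_train = table["patient_id"].isin(split.train_patients).to_numpy()
    in_test = table["patient_id"].isin(split.test_patients).to_numpy()
    y = table["malignant"].to_numpy(dtype=bool)
    if y[in_train].all() or not y[in_train].any():
        raise ValueError(f"split {split.split_id}: degenerate training classes")

    x_train = table.loc[in_train, columns]
    ranking = mrmr_rank(x_train, y[in_train], k=mrmr_k)
    top = ranking.features
    rf = RandomForestClassifier(random_state=split.seed, **rf_params)
    rf.fit(x_train[top].to_numpy(), y[in_train])
    pos_col = int(np.nonzero(rf.classes_)[0][0])
    scores = rf.predict_proba(table.loc[in_test, top].to_numpy())[:, pos_col]
    y_test = y[in_test]
    metrics = _binary_metrics(y_test, scores)
    roc = roc_and_auc(scores, y_test)
    metrics["auc"] = roc.auc
    return SplitResult(split_id=split.split_id, scores=scores, y_true=y_test,
                       metrics=metrics, ranking=ranking, roc=roc)


def run_arm(table: pd.DataFrame, splits: list[MCSplit], modality_set: str,
            mrmr_k: int, rf_params: dict | None = None,
            adipose_included: bool = True) -> ExperimentSummary:
    """All Monte Carlo splits for one modality arm on a prepared table."""
    columns = arm_columns(table, modality_set)
    results = [train_eval_split(table, s, mrmr_k, columns, rf_params)
               for s in splits]
    per_split = pd.DataFrame(
        [{"split_id": r.split_id, **r.metrics} for r in results])
    metric_names = ["accuracy", "recall", "precision", "auc"]
    avg = average_roc([r.roc for r in results])
    return ExperimentSummary(
        modality_set=modality_set, adipose_included=adipose_included,
        n_splits=len(splits), per_split=per_split,
        mean_metrics={m: float(per_split[m].mean()) for m in metric_names},
        sd_metrics={m: float(per_split[m].std()) for m in metric_names},
        averaged_roc=avg,
        selection_frequency=selection_frequency([r.ranking for r in results]),
        pooled_scores=np.concatenate([r.scores for r in results]),
        pooled_labels=np.concatenate([r.y_true for r in results]),
    )


@dataclass
class ExperimentResult:
    summaries: dict[str, ExperimentSummary]
    delong: pd.DataFrame
    splits: list[MCSplit]


def run_experiment(table: pd.DataFrame,
                   arms: tuple[str, ...] = ("ct", "sfdi", "combined"),
                   include_adipose: bool = True,
                   n_splits: int = DEFAULT_N_SPLITS,
                   mrmr_k: int = 6,
                   test_fraction: float = DEFAULT_TEST_FRACTION,
                   rf_params: dict | None = None,
                   seed: int = 0) -> ExperimentResult:
    """Run the modality arms on identical patient-level splits.

    ``table`` is a combined-modality feature table; arm columns are selected
    per arm, so every arm sees exactly the same samples and splits. DeLong
    comparisons are made on the pooled out-of-test scores concatenated
    across splits (paired and unpaired variants).
    """
    if not include_adipose:
        table = table[table["subtype"] != "Adipose"].reset_index(drop=True)
    if table.empty:
        raise ValueError("no samples after filtering")
    splits = make_mc_splits(
        table["patient_id"].to_numpy(), table["malignant"].to_numpy(),
        n_splits=n_splits, test_fraction=test_fraction, seed=seed)
    summaries = {
        arm: run_arm(table, splits, arm, mrmr_k, rf_params,
                     adipose_included=include_adipose)
        for arm in arms
    }
    rows = []
    arm_list = list(arms)
    for i, a in enumerate(arm_list):
        for b in arm_list[i + 1 :]:
            sa, sb = summaries[a], summaries[b]
            for paired in (True, False):
                res = delong_test(sa.pooled_scores, sb.pooled_scores,
                                  sa.pooled_labels, paired=paired)
                rows.append({
                    "arm_a": a, "arm_b": b, "paired": paired,
                    "auc_a": res.auc_a, "auc_b": res.auc_b,
                    "z": res.z, "p_value": res.p_value,
                })
    return ExperimentResult(summaries=summaries,
                            delong=pd.DataFrame(rows), splits=splits)


def accuracy_vs_k(table: pd.DataFrame, modality_set: str,
                  k_values: list[int] | None = None,
                  include_adipose: bool = True, n_splits: int = 50,
                  test_fraction: float = DEFAULT_TEST_FRACTION,
                  rf_params: dict | None = None,
                  seed: int = 0) -> pd.DataFrame:
    """Mean accuracy as a function of the number of MRMR features.

    Feeds ``selection.choose_feature_count`` (the 1%-change rule).
    """
    if k_values is None:
        k_values = list(range(1, 11))
    if not include_adipose:
        table = table[table["subtype"] != "Adipose"].reset_index(drop=True)
    splits = make_mc_splits(
        table["patient_id"].to_numpy(), table["malignant"].to_numpy(),
        n_splits=n_splits, test_fraction=test_fraction, seed=seed)
    columns = arm_columns(table, modality_set)
    rows = []
    for k in k_values:
        accs = [train_eval_split(table, s, k, columns, rf_params)
                .metrics["accuracy"] for s in splits]
        rows.append({"k": k, "mean_accuracy": float(np.mean(accs)),
                     "sd_accuracy": float(np.std(accs))})
    return pd.DataFrame(rows)
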