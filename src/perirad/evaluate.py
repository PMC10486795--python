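"""Internal validation: stratified k-fold CV, the metric panel, paired
one-sided permutation comparison of models, and the cohort summary.

The splitter is written in-package because fold counts larger than the
minority class are an explicit use case here (k = 50 on ~244 patients means
~5-patient folds); folds containing a single outcome class have their
threshold/rank metrics flagged undefined and excluded from the mean, with
the count reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .models import select_model
from .selection import prune_correlated

METRICS = ("roc_auc", "pr_auc", "sensitivity", "specificity", "accuracy", "precision")


def stratified_folds(y: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """Deterministic stratified partition into k folds (round-robin per class).

    Classes smaller than k are allowed; such folds simply receive no member
    of that class.
    """
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    offset = 0
    for cls in np.unique(y):
        idx = np.where(y == cls)[0]
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[(offset + j) % k].append(int(i))
        offset += len(idx)
    out = [np.sort(np.array(f, dtype=int)) for f in folds]
    assert sum(len(f) for f in out) == len(y)
    return out


def metric_panel(scores, labels, threshold: float = 0.5) -> dict[str, float]:
    """ROC AUC (rank statistic), PR AUC (precision-recall step integration)
    and threshold metrics at the given probability cut-off.

    Raises on one-class input (AUC undefined).  Precision with no predicted
    positives, and sensitivity/specificity with no actual positives/negatives,
    are NaN.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("metric panel needs both classes in the labels")
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    return {
        "roc_auc": float(roc_auc_score(labels, scores)),
        "pr_auc": float(average_precision_score(labels, scores)),
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "accuracy": (tp + tn) / len(labels),
        "precision": tp / (tp + fp) if tp + fp else float("nan"),
    }


@dataclass
class CvResult:
    per_fold: pd.DataFrame         # k rows, one column per metric (NaN = undefined)
    mean: dict[str, float]
    sd: dict[str, float]
    k: int
    seed: int
    n_undefined_folds: int
    outcome: str = ""
    label: str = ""


def stratified_cv(
    table: pd.DataFrame,
    outcome: str,
    clinical_cols,
    feature_cols=(),
    k: int = 50,
    seed: int = 0,
    family: str = "backward",
    select_per_fold: bool = True,
    prune_threshold: float = 0.85,
    threshold: float = 0.5,
    label: str = "",
) -> CvResult:
    """Stratified k-fold CV of one model block, refitting inside each fold.

    With ``select_per_fold`` (default) feature pruning and subset selection
    are re-run on each training split, so the held-out fold never informs
    selection.  ``select_per_fold=False`` fits a plain ML logistic model on
    all listed columns per training split (the pre-selected-model mode).
    """
    y = table[outcome].to_numpy(int)
    folds = stratified_folds(y, k, seed)
    clinical_cols = list(clinical_cols)
    feature_cols = list(feature_cols)
    rows = []
    n_undefined = 0
    for test_idx in folds:
        if len(test_idx) == 0:
            rows.append({m: np.nan for m in METRICS})
            n_undefined += 1
            continue
        train = table.drop(index=table.index[test_idx])
        test = table.iloc[test_idx]
        train, test, cols = _fold_prepare(train, test, clinical_cols + feature_cols)
        if select_per_fold:
            kept_features = [c for c in cols if c in feature_cols]
            if len(kept_features) > 1:
                report = prune_correlated(train[kept_features], prune_threshold)
                kept_features = report.kept
            candidates = [c for c in cols if c in clinical_cols] + kept_features
            fit = select_model(train, outcome, candidates, family=family)
        else:
            fit = select_model(train, outcome, cols, family="logistic")
        scores = fit.predict_proba(test)
        try:
            rows.append(metric_panel(scores, test[outcome].to_numpy(int), threshold))
        except ValueError:  # single-class fold: panel undefined
            rows.append({m: np.nan for m in METRICS})
            n_undefined += 1
    per_fold = pd.DataFrame(rows)
    mean = {m: float(np.nanmean(per_fold[m])) for m in METRICS}
    sd = {m: float(np.nanstd(per_fold[m], ddof=1)) for m in METRICS}
    return CvResult(per_fold=per_fold, mean=mean, sd=sd, k=k, seed=seed,
                    n_undefined_folds=n_undefined, outcome=outcome, label=label)


def _fold_prepare(train: pd.DataFrame, test: pd.DataFrame, cols):
    """Standardize continuous columns with training-fold statistics; drop
    columns constant on the training fold."""
    train = train.copy()
    test = test.copy()
    kept = []
    for col in cols:
        mu = train[col].mean()
        sd = train[col].std(ddof=0)
        if sd == 0:
            continue
        if train[col].nunique() > 2:
            train[col] = (train[col] - mu) / sd
            test[col] = (test[col] - mu) / sd
        kept.append(col)
    return train, test, kept


@dataclass
class PermutationResult:
    p_values: dict[str, float]
    observed_diff: dict[str, float]
    n_permutations: int
    seed: int
    direction: str = "b_greater"


def permutation_compare(
    cv_a: CvResult, cv_b: CvResult, n_perm: int = 10_000, seed: int = 0,
    metrics=METRICS,
) -> PermutationResult:
    """Paired one-sided sign-flip permutation test per metric.

    Null: per-fold performance of the two models is exchangeable.
    Alternative: model ``b``'s mean exceeds model ``a``'s.
    p = (1 + #{permuted mean >= observed mean}) / (1 + n_perm).
    """
    if cv_a.k != cv_b.k or cv_a.seed != cv_b.seed:
        raise ValueError(
            "cv results are not paired: fold count/seed differ "
            f"({cv_a.k}/{cv_a.seed} vs {cv_b.k}/{cv_b.seed})"
        )
    rng = np.random.default_rng(seed)
    p_values, observed = {}, {}
    for m in metrics:
        d = (cv_b.per_fold[m] - cv_a.per_fold[m]).to_numpy(float)
        d = d[np.isfinite(d)]
        if d.size == 0:
            p_values[m] = float("nan")
            observed[m] = float("nan")
            continue
        obs = d.mean()
        signs = rng.choice((-1.0, 1.0), size=(n_perm, d.size))
        perm_means = (signs * d).mean(axis=1)
        p_values[m] = float((1 + np.sum(perm_means >= obs)) / (1 + n_perm))
        observed[m] = float(obs)
    return PermutationResult(p_values=p_values, observed_diff=observed,
                             n_permutations=n_perm, seed=seed)


def sign_flip_pvalue(diffs: np.ndarray, n_perm: int = 10_000, seed: int = 0) -> float:
    """One-sided sign-flip permutation p-value that mean(diffs) > 0."""
    d = np.asarray(diffs, dtype=float)
    d = d[np.isfinite(d)]
    rng = np.random.default_rng(seed)
    obs = d.mean()
    signs = rng.choice((-1.0, 1.0), size=(n_perm, d.size))
    return float((1 + np.sum((signs * d).mean(axis=1) >= obs)) / (1 + n_perm))


# ---------------------------------------------------------------------------
# Cohort summary
# ---------------------------------------------------------------------------

def percentage(count: int, total: int) -> float:
    """Percentage over the retained cohort, one decimal."""
    if total == 0:
        return 0.0
    return round(100.0 * count / total, 1)


def cohort_summary(table: pd.DataFrame, binary_cols=(), continuous_cols=(),
                   categorical_cols=()) -> pd.DataFrame:
    """Characteristics table: count (percent) for binary/categorical rows,
    median (range) for continuous rows, plus missing counts."""
    n = len(table)
    rows = []
    for col in binary_cols:
        x = table[col]
        count = int((x == 1).sum())
        rows.append({
            "characteristic": col,
            "value": f"{count} ({percentage(count, n)}%)",
            "count": count, "percent": percentage(count, n),
            "missing": int(x.isna().sum()),
        })
    for col in categorical_cols:
        x = table[col]
        for lev in sorted(x.dropna().unique()):
            count = int((x == lev).sum())
            rows.append({
                "characteristic": f"{col}={lev}",
                "value": f"{count} ({percentage(count, n)}%)",
                "count": count, "percent": percentage(count, n),
                "missing": int(x.isna().sum()),
            })
    for col in continuous_cols:
        x = table[col].dropna()
        rows.append({
            "characteristic": col,
            "value": f"{x.median():g} ({x.min():g}-{x.max():g})",
            "count": len(x), "percent": float("nan"),
            "missing": int(table[col].isna().sum()),
        })
    return pd.DataFrame(rows)
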