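"""Modeling-table assembly: missing-data policy, chained-equation imputation,
and pairwise-correlation pruning of the radiomic feature blocks.

Policy: patients with a missing outcome or any missing radiomic feature are
excluded; clinical covariates missing in >= 15% of rows are excluded from the
model matrix; the remaining incomplete covariates are imputed by chained
equations.  Feature blocks (Tumor-VOI vs Margin-VOI) are pruned independently
with an absolute-Pearson-correlation threshold of 0.85.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class MissingnessReport:
    n_rows_in: int
    n_rows_kept: int
    dropped_rows: int
    excluded_covariates: dict[str, float]  # name -> missing fraction
    imputable_covariates: dict[str, float]


def apply_missingness_policy(
    table: pd.DataFrame,
    outcome_cols,
    feature_cols,
    covariate_cols,
    max_missing_frac: float = 0.15,
) -> tuple[pd.DataFrame, MissingnessReport]:
    """Drop rows missing outcomes/features; triage covariates by missingness.

    Covariates with a missing fraction >= ``max_missing_frac`` are excluded
    from modeling (reported); those below the cut are routed to imputation.
    """
    n_in = len(table)
    keep = table[list(outcome_cols) + list(feature_cols)].notna().all(axis=1)
    out = table.loc[keep].reset_index(drop=True)
    if out.empty:
        raise ValueError("missingness policy dropped every row")
    excluded, imputable = {}, {}
    for col in covariate_cols:
        frac = float(out[col].isna().mean())
        if frac >= max_missing_frac:
            excluded[col] = frac
        elif frac > 0:
            imputable[col] = frac
    report = MissingnessReport(
        n_rows_in=n_in,
        n_rows_kept=len(out),
        dropped_rows=n_in - len(out),
        excluded_covariates=excluded,
        imputable_covariates=imputable,
    )
    return out, report


def impute_chained(
    table: pd.DataFrame,
    columns=None,
    n_iterations: int = 5,
    seed: int = 0,
    n_imputations: int = 1,
) -> pd.DataFrame | list[pd.DataFrame]:
    """Chained-equation imputation of numeric columns.

    Each incomplete column is iteratively regressed (OLS) on all other
    numeric columns; missing cells are replaced by the prediction plus a
    Gaussian residual draw.  Observed cells are never altered; the result is
    deterministic under a fixed seed.  ``n_imputations > 1`` returns a list
    of independently completed datasets.
    """
    rng = np.random.default_rng(seed)
    numeric = table.select_dtypes(include=[np.number]).columns
    if columns is None:
        columns = [c for c in numeric if table[c].isna().any()]
    for col in columns:
        if col not in numeric:
            raise ValueError(f"column {col!r} is not numeric; declare an encoding first")
    completed = [
        _impute_once(table, columns, numeric, n_iterations, rng)
        for _ in range(n_imputations)
    ]
    return completed[0] if n_imputations == 1 else completed


def _impute_once(table, columns, numeric, n_iterations, rng) -> pd.DataFrame:
    out = table.copy()
    masks = {c: table[c].isna().to_numpy() for c in columns}
    for col in columns:  # mean initialisation
        out.loc[masks[col], col] = table[col].mean()
    predictors = [c for c in numeric if not table[c].isna().all()]
    for _ in range(n_iterations):
        for col in columns:
            miss = masks[col]
            if not miss.any():
                continue
            others = [c for c in predictors if c != col]
            X = out[others].to_numpy(float)
            X = np.column_stack([np.ones(len(X)), X])
            y = out[col].to_numpy(float)
            beta, _, _, _ = np.linalg.lstsq(X[~miss], y[~miss], rcond=None)
            resid = y[~miss] - X[~miss] @ beta
            dof = max((~miss).sum() - X.shape[1], 1)
            sd = float(np.sqrt((resid**2).sum() / dof))
            out.loc[miss, col] = X[miss] @ beta + rng.normal(0.0, sd, miss.sum())
    return out


@dataclass
class PruneReport:
    kept: list[str]
    dropped: list[tuple[str, str, float]] = field(default_factory=list)
    threshold: float = 0.85


def prune_correlated(
    features: pd.DataFrame, threshold: float = 0.85
) -> PruneReport:
    """Remove one member of every feature pair with |Pearson r| > threshold.

    Deterministic greedy scan: repeatedly take the most-correlated offending
    pair and drop the member with the larger mean absolute correlation to all
    remaining features (column order breaks exact ties).  Constant columns
    have undefined correlation, treated as 0 with a warning.
    """
    cols = list(features.columns)
    if len(cols) < 2:
        raise ValueError("need at least two feature columns to prune")
    X = features.to_numpy(float)
    if not np.isfinite(X).all():
        raise ValueError("feature table contains non-finite values")
    sd = X.std(axis=0)
    if (sd == 0).any():
        constant = [c for c, s in zip(cols, sd) if s == 0]
        warnings.warn(
            f"constant feature columns {constant}: correlation undefined, treated as 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 0.0)
    corr = np.abs(corr)

    alive = np.ones(len(cols), dtype=bool)
    dropped: list[tuple[str, str, float]] = []
    while True:
        sub = np.where(alive)[0]
        c = corr[np.ix_(sub, sub)]
        if c.size == 0 or c.max() <= threshold:
            break
        a, b = np.unravel_index(np.argmax(c), c.shape)
        ia, ib = sub[a], sub[b]
        mean_a = corr[ia, alive].mean()
        mean_b = corr[ib, alive].mean()
        # drop the member more entangled with the rest; column order on ties
        drop, keep = (ia, ib) if (mean_a, ia) >= (mean_b, ib) else (ib, ia)
        alive[drop] = False
        dropped.append((cols[drop], cols[keep], float(corr[ia, ib])))
    report = PruneReport(
        kept=[c for c, a in zip(cols, alive) if a],
        dropped=dropped,
        threshold=threshold,
    )
    kept_idx = np.where(alive)[0]
    if len(kept_idx) > 1:
        final = corr[np.ix_(kept_idx, kept_idx)]
        assert final.max() <= threshold + 1e-12
    return report


def standardize_columns(table: pd.DataFrame, columns) -> pd.DataFrame:
    """Z-score the given columns (coefficients become per-SD log-odds)."""
    out = table.copy()
    for col in columns:
        sd = out[col].std(ddof=0)
        if sd > 0:
            out[col] = (out[col] - out[col].mean()) / sd
    return out
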