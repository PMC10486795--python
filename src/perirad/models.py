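"""Candidate model families and the center-effect mixed model.

Families: unpenalized maximum-likelihood logistic regression (with Wald
intervals and odds ratios), lasso/ridge with internally cross-validated
penalty, and AIC-driven backward / forward / stepwise subset selection.

The center effect is a random-intercept logistic model fitted by maximum
likelihood with Gauss-Hermite quadrature; the Variance Partition Coefficient
uses the latent-threshold residual variance pi^2/3:

    VPC = sigma_u^2 / (sigma_u^2 + pi^2 / 3)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.special import expit, log_expit
from sklearn.linear_model import LogisticRegressionCV

LOGISTIC_RESIDUAL_VAR = np.pi**2 / 3


def _group_index(starts: np.ndarray, n: int) -> np.ndarray:
    """Map each (group-sorted) observation to its group ordinal."""
    idx = np.zeros(n, dtype=int)
    idx[starts[1:]] = 1
    return np.cumsum(idx)

FAMILIES = ("logistic", "lasso", "ridge", "backward", "forward", "stepwise")


@dataclass
class FittedModel:
    terms: pd.DataFrame          # index=term; coef, odds_ratio, ci_low, ci_high, p_value
    family: str
    predictors: list[str]        # retained predictor columns (no intercept)
    intercept: float
    llf: float | None = None
    aic: float | None = None
    separation: bool = False
    trace: list[str] = field(default_factory=list)

    @property
    def coef(self) -> pd.Series:
        return self.terms["coef"]

    def linear_predictor(self, table: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(table), self.intercept)
        for term in self.predictors:
            eta += self.terms.loc[term, "coef"] * table[term].to_numpy(float)
        return eta

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        return expit(self.linear_predictor(table))


def _terms_frame(params, bse, pvalues, names) -> pd.DataFrame:
    params = np.asarray(params, dtype=float)
    bse = np.asarray(bse, dtype=float)
    z = stats.norm.ppf(0.975)
    with np.errstate(over="ignore"):
        return _terms_frame_inner(params, bse, pvalues, names, z)


def _terms_frame_inner(params, bse, pvalues, names, z) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "coef": params,
            "odds_ratio": np.exp(params),
            "ci_low": np.exp(params - z * bse),
            "ci_high": np.exp(params + z * bse),
            "p_value": np.asarray(pvalues, dtype=float),
        },
        index=list(names),
    )


def fit_logistic(table: pd.DataFrame, outcome: str, predictors, family: str = "logistic",
                 seed: int = 0) -> FittedModel:
    """Fit one logistic model; ``family`` selects the estimator."""
    predictors = list(predictors)
    y = table[outcome].to_numpy(float)
    if len(np.unique(y)) < 2:
        raise ValueError(f"outcome {outcome!r} has a single class")
    X = table[predictors].to_numpy(float)
    if family in ("lasso", "ridge"):
        return _fit_penalized(y, X, predictors, family, seed)
    if family in ("backward", "forward", "stepwise"):
        raise ValueError(f"use the dedicated selection entry point for {family!r}")
    return _fit_ml(y, X, predictors)


def _fit_ml(y, X, names) -> FittedModel:
    exog = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, exog).fit(disp=0, maxiter=200)
        separation = bool(np.abs(res.params).max() > 15) or not res.mle_retvals.get(
            "converged", True
        )
    except np.linalg.LinAlgError:
        res = None
        separation = True
    if separation:
        warnings.warn(
            "possible separation: falling back to a weakly ridge-penalized fit; "
            "consider the lasso/ridge families",
            stacklevel=3,
        )
    if res is None:
        from sklearn.linear_model import LogisticRegression

        est = LogisticRegression(penalty="l2", C=1e4, max_iter=5000).fit(X, y)
        params = np.concatenate([est.intercept_, est.coef_.ravel()])
        nan = np.full(len(names) + 1, np.nan)
        terms = _terms_frame(params[1:], nan[1:], nan[1:], names)
        return FittedModel(
            terms=terms, family="logistic", predictors=list(names),
            intercept=float(params[0]), llf=None, aic=np.inf, separation=True,
        )
    terms = _terms_frame(res.params[1:], res.bse[1:], res.pvalues[1:], names)
    return FittedModel(
        terms=terms,
        family="logistic",
        predictors=list(names),
        intercept=float(res.params[0]),
        llf=float(res.llf),
        aic=float(res.aic),
        separation=separation,
    )


def _fit_penalized(y, X, names, family, seed) -> FittedModel:
    penalty = "l1" if family == "lasso" else "l2"
    solver = "liblinear" if family == "lasso" else "lbfgs"
    est = LogisticRegressionCV(
        Cs=10, cv=5, penalty=penalty, solver=solver, max_iter=5000,
        random_state=seed, scoring="neg_log_loss",
    ).fit(X, y)
    coef = est.coef_.ravel()
    nan = np.full(len(names), np.nan)
    terms = _terms_frame(coef, nan, nan, names)
    retained = [n for n, c in zip(names, coef) if c != 0.0]
    return FittedModel(
        terms=terms,
        family=family,
        predictors=list(names),
        intercept=float(est.intercept_[0]),
    )


# ---------------------------------------------------------------------------
# Subset selection
# ---------------------------------------------------------------------------

def _aic_of(table, outcome, preds) -> float:
    if not preds:
        y = table[outcome].to_numpy(float)
        res = sm.Logit(y, np.ones((len(y), 1))).fit(disp=0)
        return float(res.aic)
    return _fit_ml(table[outcome].to_numpy(float), table[list(preds)].to_numpy(float),
                   list(preds)).aic


def backward_select(table: pd.DataFrame, outcome: str, candidates,
                    criterion: str = "aic", alpha: float = 0.05) -> FittedModel:
    """Backward elimination from the full candidate set.

    ``criterion='aic'`` (default) removes the term whose deletion most
    improves AIC until no deletion improves it; ``criterion='alpha'`` removes
    the largest Wald p-value above ``alpha``.  An intercept-only final model
    is permitted and reported.
    """
    current = list(candidates)
    trace: list[str] = []
    while current:
        fit = _fit_ml(table[outcome].to_numpy(float),
                      table[current].to_numpy(float), current)
        if criterion == "aic":
            best_aic, drop = fit.aic, None
            for term in current:
                reduced = [t for t in current if t != term]
                aic = _aic_of(table, outcome, reduced)
                if aic < best_aic - 1e-10:
                    best_aic, drop = aic, term
            if drop is None:
                break
        elif criterion == "alpha":
            worst = fit.terms["p_value"].idxmax()
            if fit.terms.loc[worst, "p_value"] <= alpha:
                break
            drop = worst
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
        current.remove(drop)
        trace.append(f"drop {drop}")
    if current:
        final = _fit_ml(table[outcome].to_numpy(float),
                        table[current].to_numpy(float), current)
    else:
        y = table[outcome].to_numpy(float)
        res = sm.Logit(y, np.ones((len(y), 1))).fit(disp=0)
        final = FittedModel(
            terms=_terms_frame([], [], [], []), family="logistic",
            predictors=[], intercept=float(res.params[0]),
            llf=float(res.llf), aic=float(res.aic),
        )
    final.family = "backward"
    final.trace = trace
    return final


def forward_select(table: pd.DataFrame, outcome: str, candidates,
                   criterion: str = "aic") -> FittedModel:
    """Forward inclusion by AIC until no addition improves it."""
    remaining = list(candidates)
    current: list[str] = []
    trace: list[str] = []
    best_aic = _aic_of(table, outcome, current)
    while remaining:
        aics = [(_aic_of(table, outcome, current + [t]), t) for t in remaining]
        aic, term = min(aics)
        if aic >= best_aic - 1e-10:
            break
        best_aic = aic
        current.append(term)
        remaining.remove(term)
        trace.append(f"add {term}")
    if not current:
        fit = backward_select(table, outcome, [])  # intercept-only path
    else:
        fit = _fit_ml(table[outcome].to_numpy(float),
                      table[current].to_numpy(float), current)
    fit.family = "forward"
    fit.trace = trace
    return fit


def stepwise_select(table: pd.DataFrame, outcome: str, candidates,
                    max_sweeps: int = 20) -> FittedModel:
    """Alternating forward/backward sweeps by AIC."""
    current: list[str] = []
    trace: list[str] = []
    pool = list(candidates)
    for _ in range(max_sweeps):
        changed = False
        best_aic = _aic_of(table, outcome, current)
        adds = [(_aic_of(table, outcome, current + [t]), t)
                for t in pool if t not in current]
        if adds:
            aic, term = min(adds)
            if aic < best_aic - 1e-10:
                current.append(term)
                trace.append(f"add {term}")
                best_aic = aic
                changed = True
        drops = [(_aic_of(table, outcome, [t for t in current if t != d]), d)
                 for d in current]
        if drops:
            aic, term = min(drops)
            if aic < best_aic - 1e-10:
                current.remove(term)
                trace.append(f"drop {term}")
                changed = True
        if not changed:
            break
    fit = backward_select(table, outcome, current) if not current else _fit_ml(
        table[outcome].to_numpy(float), table[current].to_numpy(float), current
    )
    fit.family = "stepwise"
    fit.trace = trace
    return fit


def select_model(table, outcome, candidates, family="backward", **kwargs) -> FittedModel:
    if family == "backward":
        return backward_select(table, outcome, candidates, **kwargs)
    if family == "forward":
        return forward_select(table, outcome, candidates, **kwargs)
    if family == "stepwise":
        return stepwise_select(table, outcome, candidates, **kwargs)
    return fit_logistic(table, outcome, candidates, family=family, **kwargs)


# ---------------------------------------------------------------------------
# Univariate screening of clinical candidates
# ---------------------------------------------------------------------------

def univariate_screen(table: pd.DataFrame, outcome: str, covariates,
                      alpha: float = 0.1) -> dict[str, float]:
    """Per-covariate association p-values with the binary outcome.

    Binary/categorical covariates: chi-square, or Fisher's exact for 2x2
    tables with small expected counts.  Continuous covariates: t-test when a
    skew/kurtosis heuristic accepts normality (|skew| < 1 and |excess
    kurtosis| < 2 in both groups), otherwise Mann-Whitney U.
    """
    y = table[outcome].to_numpy()
    out: dict[str, float] = {}
    for col in covariates:
        x = table[col]
        if x.nunique(dropna=True) <= 5:
            ct = pd.crosstab(x, table[outcome])
            if ct.shape == (2, 2) and (stats.contingency.expected_freq(ct) < 5).any():
                p = stats.fisher_exact(ct)[1]
            else:
                p = stats.chi2_contingency(ct)[1]
        else:
            a = x[y == 1].dropna().to_numpy(float)
            b = x[y == 0].dropna().to_numpy(float)
            normal = all(
                abs(stats.skew(g)) < 1 and abs(stats.kurtosis(g)) < 2
                for g in (a, b) if len(g) > 7
            )
            p = (stats.ttest_ind(a, b).pvalue if normal
                 else stats.mannwhitneyu(a, b).pvalue)
        out[col] = float(p)
    return out


def screen_clinical(table, outcome, covariates, a_priori=(), alpha: float = 0.1) -> list[str]:
    """A-priori clinical variables plus those passing univariate p < alpha."""
    pvals = univariate_screen(table, outcome, covariates, alpha)
    keep = [c for c in covariates if pvals[c] < alpha or c in a_priori]
    return keep


# ---------------------------------------------------------------------------
# Mixed-effect logistic model (random intercept per center)
# ---------------------------------------------------------------------------

@dataclass
class MemFit:
    fe_params: pd.Series
    sigma2_u: float
    vpc: float
    llf: float
    converged: bool


def vpc_from_sigma2(sigma2_u: float) -> float:
    """Latent-threshold VPC for a random-intercept logistic model."""
    if sigma2_u < 0:
        raise ValueError("sigma2_u must be >= 0")
    return sigma2_u / (sigma2_u + LOGISTIC_RESIDUAL_VAR)


def fit_mem(table: pd.DataFrame, outcome: str, predictors, group: str = "center",
            n_quad: int = 15) -> MemFit:
    """Maximum-likelihood random-intercept logistic fit.

    The per-group likelihood is integrated over the Gaussian random intercept
    with adaptive Gauss-Hermite quadrature: each group's integrand is
    re-centered at its Laplace mode and rescaled by the local curvature
    before applying the ``n_quad``-node rule, which keeps the quadrature
    accurate for large clusters whose integrand is much narrower than the
    random-effect scale.
    """
    groups = table[group].to_numpy()
    if len(np.unique(groups)) < 2:
        raise ValueError("mixed model requires >= 2 groups (centers)")
    predictors = list(predictors)
    y = table[outcome].to_numpy(float)
    X = sm.add_constant(table[predictors].to_numpy(float), has_constant="add")

    order = np.argsort(groups, kind="stable")
    y, X, groups = y[order], X[order], groups[order]
    _, starts = np.unique(groups, return_index=True)
    n_groups = len(starts)

    nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
    log_w = np.log(weights)

    sign = 2 * y - 1  # log P(y|eta) = log_expit(sign * eta)

    def negll(theta):
        beta, sigma = theta[:-1], max(abs(theta[-1]), 1e-6)
        eta = X @ beta
        # Laplace mode per group by Newton on
        # h(u) = -u^2/(2 s^2) + sum_i log P(y_i | eta_i + u)
        u = np.zeros(n_groups)
        for _ in range(30):
            p = expit(eta + u[_group_index(starts, len(y))])
            grad = np.add.reduceat(y - p, starts) - u / sigma**2
            curv = np.add.reduceat(p * (1 - p), starts) + 1.0 / sigma**2
            step = grad / curv
            u += step
            if np.abs(step).max() < 1e-10:
                break
        tau = 1.0 / np.sqrt(curv)
        # adaptive nodes u_gk = mode_g + tau_g * x_k
        ug = u[:, None] + tau[:, None] * nodes[None, :]
        gidx = _group_index(starts, len(y))
        lp = log_expit(sign[:, None] * (eta[:, None] + ug[gidx]))
        data_lp = np.add.reduceat(lp, starts, axis=0)
        h = data_lp - ug**2 / (2 * sigma**2)
        log_int = h + log_w[None, :] + nodes[None, :] ** 2 / 2.0
        m = log_int.max(axis=1, keepdims=True)
        ll = (
            np.log(tau) - 0.5 * np.log(2 * np.pi * sigma**2)
            + m.ravel() + np.log(np.exp(log_int - m).sum(axis=1))
        ).sum()
        return -ll

    start_fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    theta0 = np.append(start_fit.params, 0.5)
    res = optimize.minimize(negll, theta0, method="Nelder-Mead",
                            options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-8})
    res = optimize.minimize(negll, res.x, method="BFGS",
                            options={"maxiter": 500})
    beta = res.x[:-1]
    sigma2 = float(res.x[-1] ** 2)
    return MemFit(
        fe_params=pd.Series(beta, index=["intercept"] + predictors),
        sigma2_u=sigma2,
        vpc=vpc_from_sigma2(sigma2),
        llf=float(-res.fun),
        converged=bool(res.success or np.isfinite(res.fun)),
    )
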