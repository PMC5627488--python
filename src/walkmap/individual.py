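"""Stage 1: individual-level logistic adjustment.

Each binary activity outcome is regressed on the 13 individual covariates by
maximum-likelihood logistic regression (IRLS).  The fitted probabilities are
summed within areas to give indirectly standardised expected counts
``e_j = sum_i Yhat_ij`` — the offsets of the stage-2 spatial model adjusted
for each area's respondent mix.  The unadjusted alternative is
``e_j = p * n_j`` with ``p`` the overall prevalence.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm, rankdata

from .covariates import CovariateSpec

logger = logging.getLogger(__name__)


class SeparationError(RuntimeError):
    """Logistic fit diverged (quasi-complete separation)."""


class RankDeficientError(ValueError):
    """Design matrix is rank deficient."""


def build_design(cohort: pd.DataFrame, spec: CovariateSpec = None):
    """Reference-coded design matrix (intercept + one dummy per non-reference
    level), with deterministic column order given by the spec.

    Returns ``(X, columns)`` with X an (n, p) float array.  Raises on
    categories outside the declared level sets.
    """
    spec = spec or CovariateSpec()
    spec.validate(cohort)
    n = len(cohort)
    cols = spec.column_names()
    X = np.empty((n, len(cols)))
    X[:, 0] = 1.0
    j = 1
    for covname in spec.covariates:
        vals = cohort[covname].astype(str).to_numpy()
        for lvl in spec.levels[covname]:
            if lvl == spec.reference[covname]:
                continue
            X[:, j] = vals == lvl
            j += 1
    return X, cols


def _check_rank(X, columns):
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # name the offending columns via pivoted QR on the gram matrix
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [columns[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise RankDeficientError(
            f"design rank {r} < {X.shape[1]}; collinear columns: {bad}")


class LogisticFit:
    """Converged logistic fit with Wald summaries and predictions."""

    def __init__(self, coef, se, columns, llf):
        self.coef = np.asarray(coef)
        self.se = np.asarray(se)
        self.columns = list(columns)
        self.llf = llf

    def predict(self, X) -> np.ndarray:
        eta = np.asarray(X) @ self.coef
        return 1.0 / (1.0 + np.exp(-eta))

    def odds_ratios(self, alpha: float = 0.05) -> pd.DataFrame:
        """Term, OR and exponentiated Wald interval (reference coding)."""
        z = norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"term": self.columns,
             "coef": self.coef, "se": self.se,
             "or": np.exp(self.coef),
             "or_low": np.exp(self.coef - z * self.se),
             "or_high": np.exp(self.coef + z * self.se)}
        )


def fit_logistic(X, y, columns=None) -> LogisticFit:
    """Maximum-likelihood logistic regression via IRLS.

    Raises :class:`RankDeficientError` for collinear designs and
    :class:`SeparationError` when any coefficient diverges beyond |15|
    (quasi-complete separation).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if columns is None:
        columns = [f"x{j}" for j in range(X.shape[1])]
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    _check_rank(X, columns)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    res = model.fit(maxiter=100, tol=1e-10)
    coef = res.params
    if np.any(np.abs(coef) > 15):
        bad = [columns[i] for i in np.where(np.abs(coef) > 15)[0]]
        raise SeparationError(f"diverging coefficients (|b|>15): {bad}")
    return LogisticFit(coef, res.bse, columns, res.llf)


def auc_mann_whitney(y, scores) -> float:
    """AUC by the tie-corrected Mann-Whitney rank estimator."""
    y = np.asarray(y, bool)
    scores = np.asarray(scores, float)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes required for AUC")
    ranks = rankdata(scores)  # mid-ranks handle ties
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2) / (n0 * n1))


def expected_counts(cohort: pd.DataFrame, y, mode: str = "adjusted",
                    fit: LogisticFit = None, X=None,
                    weights=None) -> pd.DataFrame:
    """Per-area observed counts and expected-count offsets.

    ``mode='adjusted'``: e_j = sum of fitted probabilities within the area
    (requires ``fit`` and the design ``X``); by the logistic score equation
    the e_j then sum to the total observed events.  ``mode='unadjusted'``:
    e_j = p * n_j with p the overall (weighted) prevalence.  Optional
    ``weights`` multiply both observed events and expectations (used by the
    post-stratification check).  Areas with no respondents are absent from
    the output; an area with events but zero expectation is an error.
    """
    y = np.asarray(y, float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, float)
    df = pd.DataFrame({"area_id": cohort["area_id"].to_numpy(),
                       "obs": w * y, "n": w})
    if mode == "adjusted":
        if fit is None or X is None:
            raise ValueError("adjusted mode requires a fitted model and design")
        df["e"] = w * fit.predict(X)
    elif mode == "unadjusted":
        p = float(np.sum(w * y) / np.sum(w))
        df["e"] = w * p
    else:
        raise ValueError(f"unknown mode {mode!r}")
    agg = df.groupby("area_id", sort=True).sum().reset_index()
    agg = agg.rename(columns={"obs": "observed", "n": "n_j", "e": "e_j"})
    bad = (agg["e_j"] <= 0) & (agg["observed"] > 0)
    if bad.any():
        raise ValueError(
            f"areas with events but zero expectation: "
            f"{agg.loc[bad, 'area_id'].tolist()}")
    agg["mode"] = mode
    return agg


def stage1(cohort: pd.DataFrame, outcome: str, spec: CovariateSpec = None,
           mode: str = "adjusted") -> dict:
    """Fit the individual model for one outcome and aggregate offsets.

    Returns a dict with the fit, its odds-ratio table, the in-sample AUC and
    the per-area expected counts.
    """
    spec = spec or CovariateSpec()
    y = cohort[outcome].to_numpy().astype(float)
    X, columns = build_design(cohort, spec)
    fit = fit_logistic(X, y, columns)
    probs = fit.predict(X)
    return {
        "fit": fit,
        "odds_ratios": fit.odds_ratios(),
        "auc": auc_mann_whitney(y.astype(bool), probs),
        "expected": expected_counts(cohort, y, mode=mode, fit=fit, X=X),
        "design": (X, columns),
    }
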