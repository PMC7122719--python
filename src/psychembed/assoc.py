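"""Associations between derived scores and neurocognitive outcomes.

Rank-correlation heatmaps relate per-survey PCs and RDoC scores to
individual neurocognitive measures; L1-penalized (LASSO) regressions with
the penalty chosen by the Akaike information criterion summarize how the
pooled 18-PC feature block jointly predicts each outcome, with predictive
power assessed as the cross-validated Spearman correlation between
out-of-fold predictions and observations over bootstrap replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import lasso_path
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationMatrix",
    "spearman_matrix",
    "log_transform_skewed",
    "LassoAIC",
    "lasso_aic_fit",
    "cv_rank_correlation",
    "coefficient_heatmap_export",
]

_STAR_LEVELS = ((0.01, "***"), (0.05, "**"), (0.1, "*"))


def _stars(p: float) -> str:
    for alpha, s in _STAR_LEVELS:
        if p < alpha:
            return s
    return ""


@dataclass
class CorrelationMatrix:
    """Predictor x outcome Spearman correlations with p-values and n."""

    rho: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame

    def stars(self) -> pd.DataFrame:
        return self.p.map(lambda v: "" if np.isnan(v) else _stars(v))

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for pred in self.rho.index:
            for out in self.rho.columns:
                rows.append(
                    {
                        "predictor": pred,
                        "outcome": out,
                        "rho": self.rho.loc[pred, out],
                        "p": self.p.loc[pred, out],
                        "n": self.n.loc[pred, out],
                        "stars": ""
                        if np.isnan(self.p.loc[pred, out])
                        else _stars(self.p.loc[pred, out]),
                    }
                )
        return pd.DataFrame(rows)


def spearman_matrix(
    predictors: pd.DataFrame, outcomes: pd.DataFrame, min_n: int = 3
) -> CorrelationMatrix:
    """Spearman rank correlation of every predictor against every outcome.

    Missing values are removed pairwise per cell; cells with fewer than
    ``min_n`` complete pairs, or with a constant column, are marked missing
    (NaN).  Ties are handled by midranks; p-values are two-sided.
    """
    if not predictors.index.equals(outcomes.index):
        raise ValueError("predictors and outcomes must share the patient roster")
    rho = pd.DataFrame(index=predictors.columns, columns=outcomes.columns, dtype=float)
    p = rho.copy()
    n = rho.copy()
    for pc in predictors.columns:
        x_all = predictors[pc].to_numpy(dtype=float)
        for oc in outcomes.columns:
            y_all = outcomes[oc].to_numpy(dtype=float)
            mask = ~(np.isnan(x_all) | np.isnan(y_all))
            x, y = x_all[mask], y_all[mask]
            n.loc[pc, oc] = float(mask.sum())
            if mask.sum() < min_n or np.ptp(x) == 0 or np.ptp(y) == 0:
                rho.loc[pc, oc] = np.nan
                p.loc[pc, oc] = np.nan
                continue
            r, pv = stats.spearmanr(x, y)
            rho.loc[pc, oc] = r
            p.loc[pc, oc] = pv
    return CorrelationMatrix(rho=rho, p=p, n=n)


def log_transform_skewed(
    outcomes: pd.DataFrame, skew_threshold: float = 1.0
) -> tuple[pd.DataFrame, list[str]]:
    """Log-transform outcome columns with skewed distributions.

    A column with sample skewness |g1| > ``skew_threshold`` is replaced by
    ``ln(x - min(x) + 1)`` (the shift guards nonpositive values); constant
    columns have skewness defined as 0 and stay untouched.  Returns the
    transformed table and the list of transformed column names.
    """
    out = outcomes.copy()
    transformed: list[str] = []
    for col in out.columns:
        x = out[col].to_numpy(dtype=float)
        obs = x[~np.isnan(x)]
        if obs.size < 3 or np.ptp(obs) == 0:
            continue
        if abs(stats.skew(obs)) > skew_threshold:
            out[col] = np.log(x - np.nanmin(x) + 1.0)
            transformed.append(col)
    return out, transformed


class LassoAIC(BaseEstimator, RegressorMixin):
    """LASSO linear regression with the penalty chosen by AIC.

    A path of ``n_alphas`` log-spaced penalties from the smallest penalty
    that zeroes all coefficients down to ``eps`` times that value is fit
    with coordinate descent; the chosen model minimizes
    ``AIC = n * ln(RSS / n) + 2 * df`` with ``df`` the number of nonzero
    coefficients (the standard LARS-style degrees-of-freedom estimate).
    Features are z-scored and the response centered internally; the fit is
    deterministic given the data.

    Fitted attributes: ``coef_`` (on the z-scored feature scale),
    ``alpha_``, ``intercept_``, ``aic_path_``, ``alphas_``.
    """

    def __init__(self, n_alphas: int = 100, eps: float = 1e-4, alphas=None):
        self.n_alphas = n_alphas
        self.eps = eps
        self.alphas = alphas

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LassoAIC":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).ravel()
        n, _ = X.shape
        if n <= 2:
            raise ValueError("need more than 2 observations")
        self.x_mean_, self.x_std_ = X.mean(0), X.std(0)
        xs = np.where(self.x_std_ > 0, self.x_std_, 1.0)
        Xz = (X - self.x_mean_) / xs
        self.y_mean_ = y.mean()
        yc = y - self.y_mean_

        if self.alphas is not None:
            alphas = np.sort(np.asarray(self.alphas, dtype=float))[::-1]
        else:
            alpha_max = np.max(np.abs(Xz.T @ yc)) / n
            if alpha_max <= 0:
                alpha_max = 1.0
            alphas = np.logspace(
                np.log10(alpha_max), np.log10(alpha_max * self.eps), self.n_alphas
            )
        alphas_out, coefs, _ = lasso_path(Xz, yc, alphas=alphas)
        resid = yc[:, None] - Xz @ coefs
        rss = np.maximum(np.sum(resid**2, axis=0), 1e-12)
        df = np.count_nonzero(coefs, axis=0)
        aic = n * np.log(rss / n) + 2 * df
        # ties broken toward the larger penalty (sparser model)
        best = int(np.argmin(aic))
        self.alphas_ = alphas_out
        self.aic_path_ = aic
        self.alpha_ = float(alphas_out[best])
        self.coef_ = coefs[:, best].copy()
        self.intercept_ = float(self.y_mean_)
        self._xs = xs
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xz = (np.asarray(X, dtype=np.float64) - self.x_mean_) / self._xs
        return Xz @ self.coef_ + self.intercept_


def lasso_aic_fit(
    X: np.ndarray, y: np.ndarray, n_alphas: int = 100
) -> tuple[np.ndarray, float]:
    """Coefficients (z-scored feature scale) and chosen penalty."""
    model = LassoAIC(n_alphas=n_alphas).fit(X, y)
    return model.coef_, model.alpha_


def cv_rank_correlation(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 10,
    B: int = 500,
    seed: int = 0,
    n_alphas: int = 50,
) -> dict[str, object]:
    """Cross-validated Spearman correlation of LASSO-AIC predictions.

    Per bootstrap replicate: resample patients with replacement, run
    ``folds``-fold CV refitting the LASSO-AIC model in each training fold,
    pool out-of-fold predictions, and record Spearman rho(predicted,
    observed).  A replicate with constant predictions is recorded as rho=0
    and flagged.  Returns mean, percentile 95% CI, the replicate rhos and
    the degenerate-replicate count.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    mask = ~np.isnan(y)
    X, y = X[mask], y[mask]
    rng = np.random.default_rng(seed)
    rhos = np.empty(B)
    n_degenerate = 0
    n = len(y)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        Xb, yb = X[idx], y[idx]
        kf = KFold(n_splits=folds, shuffle=True,
                   random_state=int(rng.integers(0, 2**31 - 1)))
        pred = np.empty(n)
        for train, test in kf.split(Xb):
            model = LassoAIC(n_alphas=n_alphas).fit(Xb[train], yb[train])
            pred[test] = model.predict(Xb[test])
        if np.ptp(pred) == 0 or np.ptp(yb) == 0:
            n_degenerate += 1
            rhos[b] = 0.0
            continue
        rhos[b] = stats.spearmanr(pred, yb)[0]
    lo, hi = np.percentile(rhos, [2.5, 97.5])
    if n_degenerate:
        logger.warning("cv_rank_correlation: %d degenerate replicates", n_degenerate)
    return {
        "mean": float(rhos.mean()),
        "lo": float(lo),
        "hi": float(hi),
        "replicates": rhos,
        "n_degenerate": n_degenerate,
    }


def coefficient_heatmap_export(
    fits: Mapping[str, LassoAIC | np.ndarray], feature_names: Sequence[str]
) -> pd.DataFrame:
    """Long-format (outcome, feature, coefficient) table for heatmaps.

    Zero coefficients are kept as explicit rows so the export has exactly
    ``n_outcomes * n_features`` rows.
    """
    rows = []
    for outcome, fit in fits.items():
        coef = fit.coef_ if isinstance(fit, LassoAIC) else np.asarray(fit)
        if len(coef) != len(feature_names):
            raise ValueError(
                f"outcome {outcome!r}: {len(coef)} coefficients for "
                f"{len(feature_names)} features"
            )
        for name, c in zip(feature_names, coef):
            rows.append({"outcome": outcome, "feature": name, "coefficient": float(c)})
    return pd.DataFrame(rows)
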