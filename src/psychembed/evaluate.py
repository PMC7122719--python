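"""Diagnostic-contrast evaluation of derived scores.

Given per-patient feature sets (survey CCVs, leading PCs, or raw ordinal
responses) and the three a-priori diagnostic groups (case / control /
supercontrol), this module measures how well the features separate two
binary contrasts:

* ``C_vs_CS``  — cases vs controls + supercontrols,
* ``CC_vs_S``  — cases + controls vs supercontrols,

using unsupervised two-component Gaussian-mixture clustering and supervised
10-fold cross-validated logistic regression, each repeated over bootstrap
resamples.  Accuracy, AUC, false positive rate and false negative rate are
reported as bootstrap means with percentile 95% confidence intervals; all
threshold metrics use a class-probability cutoff of 0.5.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.manifold import TSNE
from sklearn.mixture import GaussianMixture
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)

__all__ = [
    "CONTRASTS",
    "contrast_labels",
    "fit_gmm_binary",
    "align_clusters",
    "classification_metrics",
    "bootstrap_evaluate",
    "MetricReport",
    "permutation_test_means",
    "tsne_project",
]

GROUPS = ("case", "control", "supercontrol")

# contrast name -> set of groups forming the positive class
CONTRASTS: dict[str, frozenset[str]] = {
    "C_vs_CS": frozenset({"case"}),
    "CC_vs_S": frozenset({"case", "control"}),
}

METRICS = ("ACC", "AUC", "FPR", "FNR")


def contrast_labels(groups: Sequence[str], contrast: str) -> np.ndarray:
    """Binary 0/1 labels for a named contrast over the three groups."""
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; use {sorted(CONTRASTS)}")
    bad = sorted(set(groups) - set(GROUPS))
    if bad:
        raise ValueError(f"unknown group labels: {bad}")
    pos = CONTRASTS[contrast]
    return np.array([1 if g in pos else 0 for g in groups], dtype=np.int64)


def fit_gmm_binary(
    features: np.ndarray,
    seed: int = 0,
    n_init: int = 5,
    tol: float = 1e-6,
    max_iter: int = 500,
    on_nonconvergence: str = "raise",
) -> np.ndarray:
    """Two-component full-covariance GMM posterior membership probabilities.

    Returns an (n, 2) matrix of posteriors summing to 1 per patient; both
    columns are kept at full floating-point resolution (posteriors saturate
    toward 0/1, and ``1 - p`` would destroy the resolution of the small
    column).  Features are z-scored per column before fitting.
    Initialization is k-means++ with ``n_init`` restarts.  Non-convergence
    raises; a degenerate fit (near-coincident components) logs a warning.
    """
    _, gmm, Xz = _fit_gmm_model(
        features,
        seed=seed,
        n_init=n_init,
        tol=tol,
        max_iter=max_iter,
        on_nonconvergence=on_nonconvergence,
    )
    return gmm.predict_proba(Xz)


def _fit_gmm_model(
    features: np.ndarray,
    seed: int = 0,
    n_init: int = 5,
    tol: float = 1e-6,
    max_iter: int = 500,
    on_nonconvergence: str = "raise",
) -> tuple[StandardScaler, GaussianMixture, np.ndarray]:
    X = np.asarray(features, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 4:
        raise ValueError("need at least 4 observations for a 2-cluster GMM")
    spread = X.std(axis=0)
    if np.all(spread < 1e-6 * (np.abs(X.mean(axis=0)) + 1.0)):
        logger.warning(
            "fit_gmm_binary: input is a single tight cluster; "
            "2-component posteriors are unstable"
        )
    scaler = StandardScaler().fit(X)
    Xz = scaler.transform(X)
    gmm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        n_init=n_init,
        tol=tol,
        max_iter=max_iter,
        init_params="k-means++",
        random_state=seed,
        reg_covar=1e-6,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gmm.fit(Xz)
    if not gmm.converged_:
        msg = (
            f"GMM EM failed to converge after {n_init} restarts "
            f"(lower bound {gmm.lower_bound_:.4g})"
        )
        if on_nonconvergence == "raise":
            raise RuntimeError(msg)
        logger.warning("%s; using best fit", msg)
    sep = np.linalg.norm(gmm.means_[0] - gmm.means_[1])
    if sep < 1e-3:
        logger.warning(
            "fit_gmm_binary: near-coincident component means (|mu0-mu1|=%.2g); "
            "posteriors are unstable",
            sep,
        )
    return scaler, gmm, Xz


def align_clusters(
    posteriors: np.ndarray, labels: np.ndarray
) -> np.ndarray:
    """Orient cluster posteriors so the in-sample AUC vs labels is >= 0.5.

    Cluster identities from a mixture model are arbitrary; P(cluster 1) is
    flipped to ``1 - p`` whenever that raises the AUC against the labels.
    At exactly 0.5 the orientation is left unchanged (cluster 1 =
    positive).  Posteriors are first quantized to a 1e-12 grid: mixture
    posteriors saturate toward 0/1, and without a common grid the float
    map ``p -> 1 - p`` is not exactly order-reversing (it collapses
    distinct near-1 values into ties), which would break the guarantee
    that the oriented AUC is >= 0.5.  A 2-D (n, 2) posterior matrix is
    accepted and reduced to its cluster-1 column.
    """
    posteriors = np.asarray(posteriors, dtype=np.float64)
    labels = np.asarray(labels)
    if posteriors.ndim == 2:
        posteriors = posteriors[:, 1]
    p = np.round(posteriors * 1e12) / 1e12
    if _rank_auc(p, labels) < 0.5:
        return 1.0 - p
    return p


def _rank_auc(probs: np.ndarray, labels: np.ndarray) -> float:
    """AUC by the Mann-Whitney rank statistic with ties averaged."""
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: only one class present")
    ranks = rankdata(probs)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def classification_metrics(
    case_prob: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> dict[str, float]:
    """ACC/AUC/FPR/FNR from case probabilities and binary labels.

    ACC, FPR and FNR come from the confusion matrix at the probability
    ``threshold`` (predictions are ``prob >= threshold``); AUC is the
    tie-averaged rank statistic and does not depend on the threshold.
    """
    p = np.asarray(case_prob, dtype=np.float64)
    y = np.asarray(labels)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities outside [0, 1]")
    auc = _rank_auc(p, y)
    pred = (p >= threshold).astype(np.int64)
    pos, neg = y == 1, y == 0
    fn = int(np.sum(pos & (pred == 0)))
    fp = int(np.sum(neg & (pred == 1)))
    fpr = fp / int(neg.sum())
    fnr = fn / int(pos.sum())
    acc = float(np.mean(pred == y))
    return {"ACC": acc, "AUC": auc, "FPR": fpr, "FNR": fnr}


@dataclass
class MetricReport:
    """Bootstrap summary of classification metrics for one evaluation cell."""

    method: str
    contrast: str
    feature_set: str
    n_bootstrap: int
    summary: dict[str, tuple[float, float, float]]  # metric -> (mean, lo, hi)
    replicates: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "method": self.method,
                "contrast": self.contrast,
                "feature_set": self.feature_set,
                "metric": m,
                "mean": mean,
                "lo": lo,
                "hi": hi,
            }
            for m, (mean, lo, hi) in self.summary.items()
        ]
        return pd.DataFrame(rows)


def _stratified_bootstrap(
    rng: np.random.Generator, labels: np.ndarray
) -> np.ndarray:
    """Resample indices with replacement within each class (both classes kept)."""
    idx = []
    for cls in np.unique(labels):
        members = np.flatnonzero(labels == cls)
        idx.append(rng.choice(members, size=members.size, replace=True))
    return np.concatenate(idx)


def _stratified_fold_ids(
    X: np.ndarray, y: np.ndarray, n_folds: int, seed: int
) -> np.ndarray:
    """Deterministic stratified fold assignment, invariant to row order.

    Rows are put into a canonical order (lexicographic by label then feature
    values) before folds are dealt out, so permuting patients with the same
    fold seed yields the identical pooled out-of-fold metrics (identical
    rows are exchangeable).
    """
    keys = np.column_stack([np.asarray(X, dtype=np.float64), y])
    order = np.lexsort(keys.T[::-1])
    rng = np.random.default_rng(seed)
    fold = np.empty(len(y), dtype=np.int64)
    for cls in np.unique(y):
        members = order[y[order] == cls]
        ids = np.arange(len(members)) % n_folds
        rng.shuffle(ids)
        fold[members] = ids
    return fold


def _logistic_oof_probs(
    X: np.ndarray, y: np.ndarray, seed: int, n_folds: int = 10
) -> np.ndarray:
    """Pooled out-of-fold case probabilities from stratified k-fold logistic.

    Features are z-scored using statistics of the training folds only; the
    logistic model is near-unpenalized (large C) for numerical stability.
    """
    fold = _stratified_fold_ids(X, y, n_folds, seed)
    probs = np.empty(len(y))
    for k in range(n_folds):
        train, test = fold != k, fold == k
        if not test.any():
            continue
        scaler = StandardScaler().fit(X[train])
        clf = LogisticRegression(C=1e6, max_iter=2000)
        clf.fit(scaler.transform(X[train]), y[train])
        probs[test] = clf.predict_proba(scaler.transform(X[test]))[:, 1]
    return probs


def bootstrap_evaluate(
    features: np.ndarray,
    groups: Sequence[str],
    contrast: str,
    method: str = "logistic",
    B: int = 500,
    seed: int = 0,
    n_folds: int = 10,
    feature_set: str = "features",
    out_of_bag: bool = False,
) -> MetricReport:
    """Bootstrap evaluation of one (method, contrast, feature set) cell.

    Each of ``B`` replicates resamples patients with replacement (stratified
    by group so both classes are always present) and computes ACC/AUC/FPR/FNR:

    * ``method="gmm"``: a 2-component GMM is fit on the replicate, its
      posteriors oriented against the replicate labels, metrics in-sample by
      default; with ``out_of_bag=True`` the replicate-fitted, replicate-
      oriented model is instead scored on the patients left out of the
      resample (the oriented AUC is then not bounded below by 0.5);
    * ``method="logistic"``: stratified ``n_folds``-fold CV inside the
      replicate, metrics from pooled out-of-fold probabilities.

    Returns bootstrap means with percentile (2.5, 97.5) confidence
    intervals, retaining per-replicate metric values for permutation tests.
    """
    if method not in ("gmm", "logistic"):
        raise ValueError(f"unknown method {method!r}")
    X = np.asarray(features, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    y = contrast_labels(groups, contrast)
    if y.min() == y.max():
        raise ValueError(f"contrast {contrast!r} yields a single class")
    rng = np.random.default_rng(seed)
    reps: dict[str, list[float]] = {m: [] for m in METRICS}
    for b in range(B):
        idx = _stratified_bootstrap(rng, y)
        Xb, yb = X[idx], y[idx]
        rep_seed = int(rng.integers(0, 2**31 - 1))
        if method == "gmm":
            scaler, gmm, Xz = _fit_gmm_model(
                Xb, seed=rep_seed, on_nonconvergence="warn"
            )
            post = gmm.predict_proba(Xz)
            if out_of_bag:
                oob = np.setdiff1d(np.arange(len(y)), idx)
                if oob.size < 2 or len(np.unique(y[oob])) < 2:
                    continue  # logged implicitly by the shorter replicate list
                flip = _rank_auc(
                    np.round(post[:, 1] * 1e12) / 1e12, yb
                ) < 0.5
                col = 0 if flip else 1
                p_oob = np.round(
                    gmm.predict_proba(scaler.transform(X[oob]))[:, col] * 1e12
                ) / 1e12
                m = classification_metrics(p_oob, y[oob])
            else:
                prob = align_clusters(post, yb)
                m = classification_metrics(prob, yb)
        else:
            prob = _logistic_oof_probs(Xb, yb, seed=rep_seed, n_folds=n_folds)
            m = classification_metrics(prob, yb)
        for k in METRICS:
            reps[k].append(m[k])
    summary = {}
    replicates = {}
    for k in METRICS:
        vals = np.asarray(reps[k])
        lo, hi = np.percentile(vals, [2.5, 97.5])
        summary[k] = (float(vals.mean()), float(lo), float(hi))
        replicates[k] = vals
    return MetricReport(
        method=method,
        contrast=contrast,
        feature_set=feature_set,
        n_bootstrap=B,
        summary=summary,
        replicates=replicates,
    )


def permutation_test_means(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> float:
    """Two-sided permutation test for a difference in means.

    Replicate-level metric values from two feature sets are pooled and
    reassigned at random ``n_perm`` times;
    ``p = (1 + #{|d_perm| >= |d_obs|}) / (n_perm + 1)``.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    if n_perm < 999:
        raise ValueError("n_perm must be >= 999")
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    n_a = a.size
    d_obs = abs(a.mean() - b.mean())
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        d = abs(perm[:n_a].mean() - perm[n_a:].mean())
        if d >= d_obs - 1e-15:
            count += 1
    return (1 + count) / (n_perm + 1)


def tsne_project(
    features: np.ndarray, seed: int = 0, perplexity: float = 30.0
) -> np.ndarray:
    """2-D t-SNE projection of the feature matrix (for Gaussian-contour plots)."""
    X = np.asarray(features, dtype=np.float64)
    n = X.shape[0]
    if perplexity >= n / 3:
        raise ValueError(f"perplexity {perplexity} too large for n={n} (< n/3 required)")
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
        max_iter=1000,
    )
    return tsne.fit_transform(X)
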