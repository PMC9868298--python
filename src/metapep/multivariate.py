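"""Preprocessing and PLS-DA with leave-one-out cross-validated Q².

The preprocessing chain follows the MetaboAnalyst convention for
intensity matrices: remove features quantified in fewer than half of the
samples, impute remaining missing values with one fifth of the feature's
minimum positive value, normalize each sample to its total signal,
log10-transform and auto-scale (unit variance per feature).

PLS-DA regresses the one-hot class-indicator matrix on the processed
intensities (PLS2); its predictive ability is summarized by Q², the
cross-validated analogue of R², computed by leave-one-out with the
centering/scaling statistics re-estimated inside every fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

logger = logging.getLogger(__name__)


# -- preprocessing ------------------------------------------------------------


def filter_impute(
    matrix: pd.DataFrame, missing_frac: float = 0.5
) -> pd.DataFrame:
    """Steps 1-2: drop features with too many missing values, impute rest.

    ``matrix`` is features x samples with NaN for missing; non-positive
    intensities are treated as missing (they carry no usable signal on a
    log scale).  A feature is dropped when missing in strictly more than
    ``missing_frac`` of the samples; surviving missing entries are set to
    one fifth of the feature's minimum positive value.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least 2 features and 2 samples")
    values = matrix.where(matrix > 0)
    frac_missing = values.isna().mean(axis=1)
    kept = values.loc[frac_missing <= missing_frac].copy()
    fill = kept.min(axis=1, skipna=True) / 5.0
    return kept.apply(lambda row: row.fillna(fill[row.name]), axis=1)


def normalize_log_scale(
    matrix: pd.DataFrame,
    scale: bool = True,
    log_base: float = 10.0,
) -> pd.DataFrame:
    """Steps 3-5: sum-normalize per sample, log-transform, auto-scale.

    Constant features (zero variance after the log step) are dropped
    before scaling.  Variance uses n-1 degrees of freedom.
    """
    sums = matrix.sum(axis=0)
    if (sums <= 0).any():
        bad = list(sums.index[sums <= 0])
        raise ValueError(f"samples with non-positive total signal: {bad}")
    rel = matrix.divide(sums, axis=1)
    logged = np.log(rel) / np.log(log_base)
    if not scale:
        return logged
    sd = logged.std(axis=1, ddof=1)
    kept = logged.loc[sd > 0]
    dropped = len(logged) - len(kept)
    if dropped:
        logger.info("dropped %d constant features before auto-scaling", dropped)
    centered = kept.sub(kept.mean(axis=1), axis=0)
    return centered.div(sd[kept.index], axis=0)


def preprocess(
    matrix: pd.DataFrame,
    missing_frac: float = 0.5,
    log_base: float = 10.0,
) -> pd.DataFrame:
    """Full preprocessing chain (filter, impute, normalize, log, scale)."""
    return normalize_log_scale(
        filter_impute(matrix, missing_frac), log_base=log_base
    )


# -- PLS-DA -------------------------------------------------------------------


@dataclass
class PlsdaModel:
    """Fitted PLS-DA: scores, weights/loadings and explained variation."""

    scores: pd.DataFrame  # samples x components
    weights: pd.DataFrame  # features x components
    x_loadings: pd.DataFrame
    y_loadings: pd.DataFrame  # classes x components
    r2x: np.ndarray  # per-component fraction of X variation
    r2y: np.ndarray  # per-component fraction of Y variation
    classes: list[str]
    rank_deficient: bool = False


def _one_hot(y, classes: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    labels = list(y)
    if classes is None:
        classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("PLS-DA needs at least 2 classes")
    indicator = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        indicator[i, classes.index(lab)] = 1.0
    return indicator, classes


def plsda_fit(
    X: pd.DataFrame, y, n_components: int = 3
) -> PlsdaModel:
    """Fit PLS2 on the one-hot class indicator.

    ``X`` is features x samples (the output of :func:`preprocess`); ``y``
    gives one class label per sample in column order.  Scores are
    orthogonal; for reproducibility the first nonzero element of each
    weight vector is forced positive.
    """
    Xmat = X.to_numpy(dtype=float).T  # samples x features
    n, p = Xmat.shape
    if n < n_components + 1:
        raise ValueError(
            f"need at least n_components+1={n_components + 1} samples, got {n}"
        )
    Y, classes = _one_hot(y)
    if Y.shape[0] != n:
        raise ValueError("y length must match the number of samples")
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(Xmat, Y)

    weights = pls.x_weights_.copy()
    scores = pls.x_scores_.copy()
    x_load = pls.x_loadings_.copy()
    y_load = pls.y_loadings_.copy()
    for j in range(n_components):
        nz = np.flatnonzero(np.abs(weights[:, j]) > 1e-12)
        if nz.size and weights[nz[0], j] < 0:
            weights[:, j] *= -1
            scores[:, j] *= -1
            x_load[:, j] *= -1
            y_load[:, j] *= -1

    Xc = Xmat - Xmat.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    ssx, ssy = (Xc**2).sum(), (Yc**2).sum()
    r2x = np.array(
        [
            (np.outer(scores[:, j], x_load[:, j]) ** 2).sum() / ssx
            for j in range(n_components)
        ]
    )
    r2y = np.array(
        [
            (np.outer(scores[:, j], y_load[:, j]) ** 2).sum() / ssy
            for j in range(n_components)
        ]
    )
    score_norms = np.linalg.norm(scores, axis=0)
    rank_deficient = bool(np.any(score_norms < 1e-10 * max(score_norms.max(), 1)))
    if rank_deficient:
        logger.warning(
            "PLS-DA model is rank-deficient: some components carry no signal"
        )
    samples = list(X.columns)
    comp_index = [f"comp{j + 1}" for j in range(n_components)]
    return PlsdaModel(
        scores=pd.DataFrame(scores, index=samples, columns=comp_index),
        weights=pd.DataFrame(weights, index=X.index, columns=comp_index),
        x_loadings=pd.DataFrame(x_load, index=X.index, columns=comp_index),
        y_loadings=pd.DataFrame(y_load, index=classes, columns=comp_index),
        r2x=r2x,
        r2y=r2y,
        classes=classes,
        rank_deficient=rank_deficient,
    )


def q2_loocv(
    matrix: pd.DataFrame,
    y,
    n_components: int = 3,
    log_base: float = 10.0,
) -> pd.Series:
    """Cumulative Q² per component count by leave-one-out cross-validation.

    ``matrix`` is the filtered and imputed intensity matrix (features x
    samples, all positive).  Sum-normalization and the log transform are
    per-sample and applied once; centering and scaling are re-estimated
    from each training fold and applied to the held-out sample.  Q²(k) =
    1 - PRESS(k)/TSS on the one-hot response, with the training-fold class
    mean as the zero-component baseline, so Q²(0) = 0 by construction.
    """
    labels = list(y)
    n = matrix.shape[1]
    if len(labels) != n:
        raise ValueError("y length must match the number of samples")
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 samples")
    Y, classes = _one_hot(labels)
    logged = normalize_log_scale(matrix, scale=False, log_base=log_base)
    X = logged.to_numpy(dtype=float).T  # samples x features

    press = np.zeros(n_components)
    tss = 0.0
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        Xtr, Xte = X[train], X[i]
        mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0, ddof=1)
        keep = sd > 0
        Xtr = (Xtr[:, keep] - mu[keep]) / sd[keep]
        Xte = (Xte[keep] - mu[keep]) / sd[keep]
        Ytr = Y[train]
        y_mean = Ytr.mean(axis=0)
        k_max = min(n_components, Xtr.shape[0] - 1, Xtr.shape[1])
        pls = PLSRegression(n_components=k_max, scale=False)
        pls.fit(Xtr, Ytr - y_mean)
        rot, yl = pls.x_rotations_, pls.y_loadings_
        resid = Y[i] - y_mean
        tss += float(resid @ resid)
        for k in range(1, n_components + 1):
            kk = min(k, k_max)
            pred = y_mean + Xte @ rot[:, :kk] @ yl[:, :kk].T
            err = Y[i] - pred
            press[k - 1] += float(err @ err)
    q2 = np.concatenate([[0.0], 1.0 - press / tss])
    return pd.Series(q2, index=range(n_components + 1), name="Q2")
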