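"""Scaled-subprofile-model PCA: covariance disease patterns from BP_ND profiles.

The subjects x regions profile is double-centered (subject and region means
removed) to a residual matrix; PCA of the subject-by-subject covariance of
these residuals yields principal components in region space.  The leading
components covering half the variance enter a forward stepwise search: at
each step the component whose inclusion minimises the AIC of a logistic
regression of group on the subjects' component scores is added, and the
combination with the lowest AIC is the disease pattern.  Each subject
expresses the pattern as the inner product of the pattern weights with the
subject's residual profile.  Discrimination is assessed by leave-one-out
cross-validation (the pattern is re-derived on every fold and the held-out
subject scored prospectively) and an ROC curve.

No log transform is applied by default; the classic SSM log step is
available via ``log_transform`` with a configurable positive offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

__all__ = [
    "ResidualMatrix",
    "PCSet",
    "DiseasePattern",
    "ScoreSet",
    "ROCResult",
    "double_center",
    "decompose",
    "select_components",
    "stepwise_pattern",
    "score_subjects",
    "derive_pattern",
    "loocv_patterns",
    "roc",
]


@dataclass
class ResidualMatrix:
    """Doubly centered subjects x features residuals with the removed means."""

    residuals: np.ndarray
    subject_ids: list[str]
    features: list[str]
    feature_means: np.ndarray  # column means removed (pattern-space centering)
    subject_means: np.ndarray
    grand_mean: float
    log_transform: bool = False
    log_offset: float = 0.0


@dataclass
class PCSet:
    """Principal components in feature space (rows, unit norm)."""

    components: np.ndarray  # (n_pc, n_features)
    eigenvalues: np.ndarray  # non-increasing
    variance_fractions: np.ndarray
    features: list[str]

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


@dataclass
class DiseasePattern:
    """Unit-norm feature-weight vector with derivation metadata."""

    weights: pd.Series  # indexed by feature
    included_pcs: tuple[int, ...]
    aic: float
    disease_label: str
    other_label: str
    feature_means: np.ndarray  # derivation-set means, for prospective scoring
    log_transform: bool = False
    log_offset: float = 0.0
    separation_fallback: bool = False


@dataclass
class ScoreSet:
    """Per-subject pattern-expression scores."""

    scores: pd.Series  # indexed by subject id
    labels: pd.Series
    tag: str = "derivation"  # "derivation" | "loocv"

    def zscored(self) -> pd.Series:
        s = self.scores
        return (s - s.mean()) / s.std(ddof=1)


@dataclass
class ROCResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


# ---------------------------------------------------------------------------

def double_center(
    profile: pd.DataFrame,
    log_transform: bool = False,
    log_offset: float = 0.0,
    mask_floor: float | None = None,
    mask_zero_variance: bool = True,
) -> ResidualMatrix:
    """Remove subject and region means: r_ij = x_ij - rowmean_i - colmean_j + grand.

    Features with zero variance (unless ``mask_zero_variance`` is off), or
    with mean value below ``mask_floor``, are masked out before centering.
    """
    if profile.shape[0] < 2 or profile.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 features")
    X = profile.to_numpy(dtype=float)
    features = list(profile.columns)
    keep = np.std(X, axis=0) > 0 if mask_zero_variance else np.ones(X.shape[1], bool)
    if mask_floor is not None:
        keep &= X.mean(axis=0) >= mask_floor
    if keep.sum() < 2:
        raise ValueError("fewer than 2 features remain after masking")
    X = X[:, keep]
    features = [f for f, k in zip(features, keep) if k]
    if log_transform:
        shifted = X + log_offset
        if np.any(shifted <= 0):
            i, j = np.argwhere(shifted <= 0)[0]
            raise ValueError(
                f"non-positive value at subject {profile.index[i]!r}, "
                f"feature {features[j]!r} with log transform on"
            )
        X = np.log(shifted)
    col = X.mean(axis=0)
    row = X.mean(axis=1)
    grand = X.mean()
    R = X - row[:, None] - col[None, :] + grand
    return ResidualMatrix(
        residuals=R,
        subject_ids=[str(s) for s in profile.index],
        features=features,
        feature_means=col,
        subject_means=row,
        grand_mean=float(grand),
        log_transform=log_transform,
        log_offset=log_offset,
    )


def decompose(res: ResidualMatrix) -> PCSet:
    """PCA via the subject-by-subject covariance of the residuals.

    Eigenvectors of R R^T / (n-1) are projected back to feature space and
    unit-normalised; eigenvalues below 1e-10 of the largest are dropped
    (double centering leaves at most min(n, p) - 1 nonzero components).
    """
    R = res.residuals
    n = R.shape[0]
    S = R @ R.T / (n - 1)
    if not np.any(S):
        raise ValueError("residual matrix has rank 0 (constant profile?)")
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > max(evals.max() * 1e-10, 0.0)
    evals, evecs = evals[keep], evecs[:, keep]
    comps = evecs.T @ R  # (n_pc, n_features)
    norms = np.linalg.norm(comps, axis=1)
    comps = comps / norms[:, None]
    return PCSet(
        components=comps,
        eigenvalues=evals,
        variance_fractions=evals / evals.sum(),
        features=list(res.features),
    )


def select_components(pcs: PCSet, cumulative_fraction: float = 0.5) -> PCSet:
    """Smallest leading prefix whose cumulative variance reaches the threshold."""
    if not 0 < cumulative_fraction <= 1:
        raise ValueError("cumulative_fraction must be in (0, 1]")
    cum = np.cumsum(pcs.variance_fractions)
    k = int(np.searchsorted(cum, cumulative_fraction - 1e-12) + 1)
    k = min(k, pcs.n_components)
    return PCSet(
        components=pcs.components[:k],
        eigenvalues=pcs.eigenvalues[:k],
        variance_fractions=pcs.variance_fractions[:k],
        features=list(pcs.features),
    )


# ---------------------------------------------------------------------------
# logistic AIC machinery
# ---------------------------------------------------------------------------

def _firth_logit(X: np.ndarray, y: np.ndarray, max_iter: int = 50) -> tuple[np.ndarray, float]:
    """Bias-reduced (Jeffreys-penalised) logistic fit; returns (beta, loglik).

    Used as fallback when the MLE does not exist (perfect separation)."""
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        W = p * (1 - p)
        XtW = X.T * W
        info = XtW @ X
        try:
            cov = np.linalg.inv(info + 1e-10 * np.eye(k))
        except np.linalg.LinAlgError:
            break
        h = np.einsum("ij,jk,ik->i", X, cov, X) * W  # hat diagonal
        score = X.T @ (y - p + h * (0.5 - p))
        step = cov @ score
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    eta = np.clip(X @ beta, -30, 30)
    p = 1.0 / (1.0 + np.exp(-eta))
    eps = 1e-12
    ll = float(np.sum(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
    return beta, ll


def _logit_mle(X: np.ndarray, y: np.ndarray, max_iter: int = 60) -> tuple[np.ndarray, float, bool]:
    """Maximum-likelihood logistic fit by damped Newton iterations.

    Returns (beta, loglik, converged); non-convergence or runaway
    coefficients signal a non-existent MLE (perfect separation)."""
    n, k = X.shape
    beta = np.zeros(k)

    def loglik(b: np.ndarray) -> float:
        eta = X @ b
        return float(y @ eta - np.logaddexp(0.0, eta).sum())

    ll = loglik(beta)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        W = p * (1 - p)
        grad = X.T @ (y - p)
        hess = (X.T * W) @ X
        try:
            step = np.linalg.solve(hess + 1e-12 * np.eye(k), grad)
        except np.linalg.LinAlgError:
            return beta, ll, False
        # step-halving line search
        for _ in range(20):
            cand = beta + step
            ll_new = loglik(cand)
            if ll_new >= ll - 1e-13:
                break
            step = step / 2
        moved = np.max(np.abs(cand - beta))
        beta, ll = cand, ll_new
        if moved < 1e-9:
            break
    converged = moved < 1e-6 and np.all(np.abs(beta) < 50)
    return beta, ll, converged


def _logit_aic(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """Fit class ~ 1 + X by logistic regression; return (coef_without_intercept,
    AIC, separation_fallback)."""
    Xd = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    beta, ll, ok = _logit_mle(Xd, y)
    fallback = False
    if not ok:
        beta, ll = _firth_logit(Xd, y)
        fallback = True
    aic = 2 * Xd.shape[1] - 2 * ll
    return beta[1:], aic, fallback


def _stepwise_core(
    residuals: np.ndarray, components: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, list[int], float, bool]:
    """Forward-AIC search; returns (unit weights oriented disease-high,
    included PC indices, AIC, separation_fallback)."""
    scores_all = residuals @ components.T  # (n, n_pc)
    n_pc = components.shape[0]
    included: list[int] = []
    fallback_any = False
    _, best_aic, _ = _logit_aic(np.empty((len(y), 0)), y)  # intercept-only baseline
    first = True
    while True:
        cand_best: tuple[float, int] | None = None
        for j in range(n_pc):
            if j in included:
                continue
            _, aic, fb = _logit_aic(scores_all[:, included + [j]], y)
            fallback_any = fallback_any or fb
            if cand_best is None or aic < cand_best[0] - 1e-12:
                cand_best = (aic, j)
        if cand_best is None:
            break
        aic, j = cand_best
        if first or aic < best_aic - 1e-12:
            included.append(j)
            best_aic = aic
            first = False
        else:
            break

    coef, _, fb = _logit_aic(scores_all[:, included], y)
    fallback_any = fallback_any or fb
    w = coef @ components[included]
    norm = np.linalg.norm(w)
    if norm == 0:
        w = components[included[0]].copy()
    w = w / np.linalg.norm(w)
    subj_scores = residuals @ w
    if subj_scores[y == 1].mean() < subj_scores[y == 0].mean():
        w = -w
    return w, included, float(best_aic), fallback_any


def stepwise_pattern(
    pcs: PCSet,
    res: ResidualMatrix,
    labels: pd.Series,
    disease_label: str,
) -> DiseasePattern:
    """Forward AIC search over principal components.

    The best single component is always included; further components are
    added only while they strictly lower the AIC of the logistic regression
    of class on subject scores (ties break toward the smaller model).  The
    final pattern is the unit-normalised linear combination of the included
    components with the fitted coefficients, signed so the disease class
    has the higher mean score.
    """
    labels = pd.Series(labels)
    if len(labels) != len(res.subject_ids):
        raise ValueError("labels must be aligned with the residual matrix subjects")
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValueError(f"derivation set must contain exactly 2 classes, got {classes}")
    if disease_label not in classes:
        raise ValueError(f"disease label {disease_label!r} not among {classes}")
    other = next(c for c in classes if c != disease_label)
    y = (np.asarray(labels) == disease_label).astype(float)
    w, included, aic, fallback = _stepwise_core(res.residuals, pcs.components, y)
    return DiseasePattern(
        weights=pd.Series(w, index=res.features),
        included_pcs=tuple(included),
        aic=aic,
        disease_label=disease_label,
        other_label=other,
        feature_means=res.feature_means.copy(),
        log_transform=res.log_transform,
        log_offset=res.log_offset,
        separation_fallback=fallback,
    )


def score_subjects(
    pattern: DiseasePattern, profile: pd.DataFrame, labels: pd.Series | None = None,
    tag: str = "derivation",
) -> ScoreSet:
    """Prospective expression scores: inner product of the pattern with each
    subject's residual profile, centered against the derivation-set feature
    means (the subject's own mean is removed afterwards, reproducing double
    centering for derivation subjects)."""
    missing = [f for f in pattern.weights.index if f not in profile.columns]
    if missing:
        raise ValueError(f"profile lacks pattern features: {missing}")
    X = profile[list(pattern.weights.index)].to_numpy(dtype=float)
    if pattern.log_transform:
        shifted = X + pattern.log_offset
        if np.any(shifted <= 0):
            raise ValueError("non-positive value under log transform while scoring")
        X = np.log(shifted)
    R = X - pattern.feature_means[None, :]
    R = R - R.mean(axis=1, keepdims=True)
    scores = R @ pattern.weights.to_numpy()
    idx = profile.index
    lab = labels.loc[idx] if labels is not None else pd.Series(index=idx, dtype=object)
    return ScoreSet(scores=pd.Series(scores, index=idx), labels=lab, tag=tag)


def _derive_core(
    X: np.ndarray,
    y: np.ndarray,
    *,
    cumulative_fraction: float = 0.5,
    log_transform: bool = False,
    log_offset: float = 0.0,
    mask_floor: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[int], float, bool]:
    """Numpy-only derivation chain (centering -> PCA -> selection ->
    stepwise), shared by :func:`derive_pattern` and :func:`loocv_patterns`.

    Returns (weights over kept features, kept feature indices, kept-feature
    column means, included PCs, AIC, separation_fallback).
    """
    keep = np.std(X, axis=0) > 0
    if mask_floor is not None:
        keep &= X.mean(axis=0) >= mask_floor
    if keep.sum() < 2:
        raise ValueError("fewer than 2 features remain after masking")
    Xk = X[:, keep]
    if log_transform:
        shifted = Xk + log_offset
        if np.any(shifted <= 0):
            raise ValueError("non-positive value with log transform on")
        Xk = np.log(shifted)
    col = Xk.mean(axis=0)
    R = Xk - Xk.mean(axis=1, keepdims=True) - col[None, :] + Xk.mean()
    n = R.shape[0]
    S = R @ R.T / (n - 1)
    if not np.any(S):
        raise ValueError("residual matrix has rank 0 (constant profile?)")
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    nz = evals > max(evals.max() * 1e-10, 0.0)
    evals, evecs = evals[nz], evecs[:, nz]
    comps = evecs.T @ R
    comps = comps / np.linalg.norm(comps, axis=1)[:, None]
    fracs = evals / evals.sum()
    k = int(np.searchsorted(np.cumsum(fracs), cumulative_fraction - 1e-12) + 1)
    k = min(k, comps.shape[0])
    w, included, aic, fallback = _stepwise_core(R, comps[:k], y)
    return w, np.flatnonzero(keep), col, included, aic, fallback


def derive_pattern(
    profile: pd.DataFrame,
    labels: pd.Series,
    disease_label: str,
    *,
    cumulative_fraction: float = 0.5,
    log_transform: bool = False,
    log_offset: float = 0.0,
    mask_floor: float | None = None,
) -> DiseasePattern:
    """Full derivation chain: double-center -> PCA -> 50%-variance selection
    -> forward-AIC stepwise combination."""
    res = double_center(profile, log_transform=log_transform, log_offset=log_offset,
                        mask_floor=mask_floor)
    pcs = select_components(decompose(res), cumulative_fraction)
    return stepwise_pattern(pcs, res, pd.Series(labels).loc[profile.index], disease_label)


def loocv_patterns(
    profile: pd.DataFrame,
    labels: pd.Series,
    disease_label: str,
    **derive_opts,
) -> ScoreSet:
    """Leave-one-out cross-validated expression scores.

    Each fold re-derives the pattern on the remaining n-1 subjects (both
    classes must remain represented), aligns its sign to the full-data
    pattern (positive correlation), and scores the held-out subject
    prospectively against the fold's feature means.
    """
    labels = pd.Series(labels).loc[profile.index]
    counts = labels.value_counts()
    if (counts < 3).any():
        raise ValueError("need at least 3 subjects per class for LOOCV")
    full = derive_pattern(profile, labels, disease_label, **derive_opts)
    full_w = np.zeros(profile.shape[1])
    full_idx = [profile.columns.get_loc(f) for f in full.weights.index]
    full_w[full_idx] = full.weights.to_numpy()

    X = profile.to_numpy(dtype=float)
    y_all = (labels.to_numpy() == disease_label).astype(float)
    n = X.shape[0]
    held = np.empty(n)
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        y_fold = y_all[mask]
        if y_fold.min() == y_fold.max():
            raise ValueError(
                f"fold without both classes when holding out {profile.index[i]!r}"
            )
        w, kept, col, _, _, _ = _derive_core(X[mask], y_fold, **derive_opts)
        if float(w @ full_w[kept]) < 0:
            w = -w
        x = X[i, kept]
        if full.log_transform:
            if np.any(x + full.log_offset <= 0):
                raise ValueError("non-positive value under log transform while scoring")
            x = np.log(x + full.log_offset)
        resid = x - col
        resid = resid - resid.mean()
        held[i] = float(resid @ w)
    scores = pd.Series(held, index=profile.index)
    return ScoreSet(scores=scores, labels=labels, tag="loocv")


def roc(score_set: ScoreSet, positive_label: str | None = None) -> ROCResult:
    """ROC curve and trapezoidal AUC of the expression scores.

    Equals the Mann-Whitney statistic U/(n1*n2) on the same scores, with
    ties contributing one half.
    """
    labels = score_set.labels
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValueError(f"ROC needs exactly 2 classes, got {classes}")
    pos = positive_label or classes[0]
    y = (np.asarray(labels) == pos).astype(int)
    if y.sum() in (0, len(y)):
        raise ValueError("both classes must be present")
    fpr, tpr, thr = roc_curve(y, score_set.scores.to_numpy(), drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc)
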