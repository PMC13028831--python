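"""NIPALS PLS with LDA on latent scores, VIP, CV and Monte Carlo CV.

The classifier follows the classical chemometrics construction: partial
least squares (PLS1, NIPALS with per-component deflation) projects the
scaled spectral matrix onto a small number of latent variables (LVs), and
a two-class linear discriminant with pooled within-class covariance and
empirical priors draws the boundary in score space.  Class labels are
coded -1 (male) / +1 (female); the LDA threshold depends on this coding.

Model quality is summarised by per-LV R²X / R²Y (fractions of scaled-X
and y variance captured by each component), VIP scores, and validated
misclassification error, sensitivity, specificity and rank-statistic AUC
under stratified k-fold CV or Monte Carlo CV (repeated random stratified
splits).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

NEG_LABEL, POS_LABEL = -1, 1  # male, female


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Samples x variables intensity table with class labels.

    ``X`` is a dense real matrix; ``var_labels`` are ppm values or peak
    identifiers; ``y`` holds -1/+1 class labels (or None for unlabelled
    data); ``sample_ids`` identify rows.
    """

    X: np.ndarray
    var_labels: np.ndarray
    y: Optional[np.ndarray] = None
    sample_ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (samples x variables)")
        self.var_labels = np.asarray(self.var_labels)
        if len(self.var_labels) != self.X.shape[1]:
            raise ValueError("var_labels length must match number of columns")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains missing or non-finite values")
        if self.y is not None:
            self.y = np.asarray(self.y)
            if len(self.y) != self.X.shape[0]:
                raise ValueError("y length must match number of rows")
        if self.sample_ids is None:
            self.sample_ids = np.array([f"s{i}" for i in range(self.X.shape[0])])
        else:
            self.sample_ids = np.asarray(self.sample_ids)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_vars(self) -> int:
        return self.X.shape[1]

    def select_vars(self, keep) -> "FeatureMatrix":
        keep = np.asarray(keep)
        return FeatureMatrix(self.X[:, keep], self.var_labels[keep], self.y, self.sample_ids)


@dataclass(frozen=True)
class ScalingSpec:
    """Column scaling: always mean-centred, optionally pareto/auto scaled."""

    scale: str = "none"

    def __post_init__(self) -> None:
        if self.scale not in ("none", "pareto", "auto"):
            raise ValueError(f"unknown scale {self.scale!r}")


@dataclass
class ScalingStats:
    """Training-set column statistics, reusable on held-out data."""

    mean: np.ndarray
    divisor: np.ndarray
    kept: np.ndarray  # boolean: columns retained (zero-variance dropped)


@dataclass
class LDABoundary:
    """Two-class linear discriminant in latent-score space."""

    direction: np.ndarray
    threshold: float
    priors: tuple

    def decision(self, scores: np.ndarray) -> np.ndarray:
        """Signed decision values; positive means the +1 (female) class."""
        return scores @ self.direction - self.threshold

    def predict(self, scores: np.ndarray) -> np.ndarray:
        return np.where(self.decision(scores) > 0, POS_LABEL, NEG_LABEL)


@dataclass
class PLSLDAModel:
    """Fitted NIPALS PLS components with an LDA boundary in score space."""

    A: int
    W: np.ndarray          # variables x A, unit-norm weight vectors
    P: np.ndarray          # variables x A, X loadings
    q: np.ndarray          # A, y loadings
    T: np.ndarray          # samples x A, training scores
    r2x: np.ndarray
    r2y: np.ndarray
    lda: LDABoundary
    y_mean: float = 0.0

    @property
    def R(self) -> np.ndarray:
        """Projection weights W (P'W)^-1 mapping scaled X to scores."""
        return self.W @ np.linalg.inv(self.P.T @ self.W)

    def transform(self, X: np.ndarray, a: Optional[int] = None) -> np.ndarray:
        a = self.A if a is None else a
        return np.asarray(X, dtype=float) @ self.R[:, :a]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.lda.predict(self.transform(X))

    def decision(self, X: np.ndarray) -> np.ndarray:
        return self.lda.decision(self.transform(X))

    def regression_vector(self) -> np.ndarray:
        """PLS1 regression coefficients for scaled X -> centred y."""
        return self.R @ self.q


@dataclass
class CVResult:
    """Validated performance: per-LV error curve and metrics at optLV."""

    scheme: str
    error_curve: np.ndarray
    optLV: int
    error_min: float
    sensitivity: Optional[float]
    specificity: Optional[float]
    auc: Optional[float]
    n_used: int = 0


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------

def scale_matrix(X: np.ndarray, spec: ScalingSpec,
                 train_stats: Optional[ScalingStats] = None):
    """Mean-centre and scale columns; returns ``(scaled X, stats)``.

    Pareto scaling divides by the square root of the column standard
    deviation, autoscaling by the standard deviation itself.  When
    ``train_stats`` is given, its means/divisors (from a training set)
    are applied instead, so held-out rows never contribute statistics.
    Zero-variance columns under pareto/auto are dropped with a warning
    rather than divided by zero.
    """
    X = np.asarray(X, dtype=float)
    if train_stats is not None:
        Xs = (X[:, train_stats.kept] - train_stats.mean) / train_stats.divisor
        return Xs, train_stats
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    if spec.scale == "none":
        divisor = np.ones_like(sd)
        kept = np.ones(X.shape[1], dtype=bool)
    else:
        kept = sd > 0
        if not kept.all():
            warnings.warn(
                f"{int((~kept).sum())} zero-variance column(s) dropped under "
                f"{spec.scale} scaling", RuntimeWarning, stacklevel=2)
        sd = sd[kept]
        divisor = np.sqrt(sd) if spec.scale == "pareto" else sd
        mean = mean[kept]
    stats = ScalingStats(mean=mean, divisor=divisor, kept=kept)
    Xs = (X[:, kept] - mean) / divisor
    return Xs, stats


# ---------------------------------------------------------------------------
# NIPALS PLS1 + LDA
# ---------------------------------------------------------------------------

def _fit_lda(T: np.ndarray, y: np.ndarray) -> LDABoundary:
    """Pooled-covariance two-class LDA on latent scores."""
    pos, neg = T[y == POS_LABEL], T[y == NEG_LABEL]
    mu_p, mu_n = pos.mean(axis=0), neg.mean(axis=0)
    n_p, n_n = len(pos), len(neg)
    S = np.zeros((T.shape[1], T.shape[1]))
    for grp, mu in ((pos, mu_p), (neg, mu_n)):
        d = grp - mu
        S += d.T @ d
    dof = max(n_p + n_n - 2, 1)
    S /= dof
    # regularise degenerate directions (e.g. single LV with tiny spread)
    S += np.eye(S.shape[0]) * 1e-12 * max(np.trace(S), 1.0)
    direction = np.linalg.solve(S, mu_p - mu_n)
    priors = (n_n / (n_p + n_n), n_p / (n_p + n_n))
    # decision > 0 -> positive class, with empirical log-prior offset
    threshold = direction @ (mu_p + mu_n) / 2.0 - np.log(priors[1] / priors[0])
    return LDABoundary(direction=direction, threshold=float(threshold), priors=priors)


def fit_pls_nipals(X: np.ndarray, y: np.ndarray, A: int) -> PLSLDAModel:
    """Fit a PLS1 model by NIPALS with per-component deflation.

    ``X`` must already be scaled (see :func:`scale_matrix`); ``y`` is a
    -1/+1 (or 0/1) class vector, centred internally.  ``A`` components are
    extracted unless the residual rank is exhausted first, in which case
    the model is truncated with a warning.  An LDA boundary is fitted on
    the full A-dimensional training scores.
    """
    X = np.asarray(X, dtype=float).copy()
    y = np.asarray(y, dtype=float).copy()
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"y must be binary, got classes {classes}")
    y_cls = np.where(y == classes.max(), POS_LABEL, NEG_LABEL)
    y = y_cls.astype(float)
    y_mean = y.mean()
    y = y - y_mean

    n, V = X.shape
    ssx_total = float((X ** 2).sum())
    ssy_total = float((y ** 2).sum())
    if ssx_total == 0 or ssy_total == 0:
        raise ValueError("X or y has zero variance; nothing to model")

    W = np.zeros((V, A))
    P = np.zeros((V, A))
    q = np.zeros(A)
    T = np.zeros((n, A))
    r2x = np.zeros(A)
    r2y = np.zeros(A)

    a_eff = 0
    for a in range(A):
        w = X.T @ y
        wnorm = np.linalg.norm(w)
        if wnorm < 1e-12 * max(ssx_total, 1.0):
            break
        w /= wnorm
        t = X @ w
        tt = float(t @ t)
        if tt < 1e-14:
            break
        p = X.T @ t / tt
        qa = float(y @ t / tt)
        X -= np.outer(t, p)
        y -= t * qa
        W[:, a], P[:, a], q[a], T[:, a] = w, p, qa, t
        r2x[a] = tt * float(p @ p) / ssx_total
        r2y[a] = tt * qa * qa / ssy_total
        a_eff += 1

    if a_eff < A:
        warnings.warn(
            f"rank exhausted: truncated to {a_eff} of {A} requested LVs",
            RuntimeWarning, stacklevel=2)
    if a_eff == 0:
        raise ValueError("could not extract any latent variable")

    W, P, q, T = W[:, :a_eff], P[:, :a_eff], q[:a_eff], T[:, :a_eff]
    lda = _fit_lda(T, y_cls)
    return PLSLDAModel(A=a_eff, W=W, P=P, q=q, T=T,
                       r2x=r2x[:a_eff], r2y=r2y[:a_eff], lda=lda, y_mean=y_mean)


def vip_scores(model: PLSLDAModel) -> np.ndarray:
    """Variable importance in projection.

    ``VIP_j = sqrt( V * sum_a SSY_a (w_ja/||w_a||)^2 / sum_a SSY_a )``
    where SSY_a is the y-variance captured by component a.  The mean of
    the squared VIPs is 1 by construction.
    """
    W = model.W
    V = W.shape[0]
    ssy = model.r2y
    wn2 = (W / np.linalg.norm(W, axis=0, keepdims=True)) ** 2
    return np.sqrt(V * (wn2 @ ssy) / ssy.sum())


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _rank_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUC via the Mann–Whitney rank statistic; ties contribute 1/2."""
    from scipy.stats import rankdata

    pos = y_true == POS_LABEL
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def classification_metrics(y_true, y_pred, scores=None):
    """Misclassification error, sensitivity, specificity and AUC.

    The +1 (female) class is "positive".  With a single-class ``y_true``
    the undefined rate(s) and AUC are reported as None, not 0.
    Returns ``(error, sensitivity, specificity, auc)``.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    error = float(np.mean(y_true != y_pred))
    pos = y_true == POS_LABEL
    neg = y_true == NEG_LABEL
    sens = float(np.mean(y_pred[pos] == POS_LABEL)) if pos.any() else None
    spec = float(np.mean(y_pred[neg] == NEG_LABEL)) if neg.any() else None
    auc = None
    if scores is not None and pos.any() and neg.any():
        auc = _rank_auc(y_true, np.asarray(scores, dtype=float))
    return error, sens, spec, auc


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _as_labels(y) -> np.ndarray:
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("binary labels required")
    return np.where(y == classes.max(), POS_LABEL, NEG_LABEL)


def _stratified_folds(y: np.ndarray, k: int, rng: Optional[np.random.Generator] = None):
    """Round-robin stratified fold assignment (deterministic without rng)."""
    fold = np.empty(len(y), dtype=int)
    for cls in (NEG_LABEL, POS_LABEL):
        idx = np.flatnonzero(y == cls)
        if rng is not None:
            idx = rng.permutation(idx)
        fold[idx] = np.arange(len(idx)) % k
    return fold

def _eval_split(X, y, train, test, spec, A_max):
    """Fit on the training rows only and return per-LV test predictions.

    Scaling statistics and the per-LV LDA boundaries are computed from the
    training partition alone.  Returns (errors[A_max], decisions at optLV
    computed later by the caller via the returned per-LV arrays).
    """
    Xtr_s, stats = scale_matrix(X[train], spec)
    Xte_s, _ = scale_matrix(X[test], spec, train_stats=stats)
    a_fit = min(A_max, len(train) - 1, Xtr_s.shape[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        model = fit_pls_nipals(Xtr_s, y[train], a_fit)
    Ttr = model.T
    Tte = model.transform(Xte_s)
    preds = np.empty((A_max, len(test)), dtype=int)
    decs = np.empty((A_max, len(test)), dtype=float)
    for a in range(A_max):
        a_use = min(a + 1, model.A)
        lda = _fit_lda(Ttr[:, :a_use], y[train])
        preds[a] = lda.predict(Tte[:, :a_use])
        decs[a] = lda.decision(Tte[:, :a_use])
    return preds, decs


def _summarise(scheme, err_curve, y_pool, pred_pool, dec_pool, n_used):
    optLV = int(np.argmin(err_curve)) + 1  # smallest A at the minimum
    error_min = float(err_curve[optLV - 1])
    _, sens, spec_, auc = classification_metrics(
        y_pool, pred_pool[optLV - 1], dec_pool[optLV - 1])
    return CVResult(scheme=scheme, error_curve=err_curve, optLV=optLV,
                    error_min=error_min, sensitivity=sens, specificity=spec_,
                    auc=auc, n_used=n_used)


def cross_validate(X, y, spec: ScalingSpec, A_max: int = 6, k: int = 5) -> CVResult:
    """Stratified k-fold CV with in-fold scaling; per-LV pooled error.

    ``optLV`` is the smallest component count attaining the minimum of the
    pooled error curve.  ``k = n`` gives leave-one-out.  Raises if a fold's
    training partition would lose a class entirely.
    """
    X = np.asarray(X, dtype=float)
    y = _as_labels(y)
    n = len(y)
    n_min = min((y == POS_LABEL).sum(), (y == NEG_LABEL).sum())
    if n_min < 2:
        raise ValueError("need at least 2 samples per class")
    k = min(k, n)
    fold = _stratified_folds(y, k)
    preds = np.empty((A_max, n), dtype=int)
    decs = np.empty((A_max, n), dtype=float)
    for f in range(k):
        test = np.flatnonzero(fold == f)
        train = np.flatnonzero(fold != f)
        if len(np.unique(y[train])) < 2:
            raise ValueError(f"fold {f}: training partition lost a class")
        preds[:, test], decs[:, test] = _eval_split(X, y, train, test, spec, A_max)
    err_curve = (preds != y).mean(axis=1)
    logger.info("cross_validate: n=%d, k=%d, error curve %s", n, k,
                np.round(err_curve, 4))
    return _summarise("kfold", err_curve, y, preds, decs, n)


def mccv(X, y, spec: ScalingSpec, A_max: int = 6, split_fraction: float = 0.8,
         n_reps: int = 500, seed: int = 0) -> CVResult:
    """Monte Carlo CV: repeated random stratified train/test splits.

    Per-LV error is the mean test error over replicates; metrics at optLV
    pool all replicate test predictions.  Deterministic under ``seed``.
    """
    if not 0 < split_fraction < 1:
        raise ValueError("split_fraction must be in (0, 1)")
    X = np.asarray(X, dtype=float)
    y = _as_labels(y)
    rng = np.random.default_rng(seed)
    idx_pos = np.flatnonzero(y == POS_LABEL)
    idx_neg = np.flatnonzero(y == NEG_LABEL)
    n_tr_pos = max(int(round(split_fraction * len(idx_pos))), 2)
    n_tr_neg = max(int(round(split_fraction * len(idx_neg))), 2)
    if n_tr_pos >= len(idx_pos) or n_tr_neg >= len(idx_neg):
        raise ValueError("split_fraction leaves an empty test class")
    err_sum = np.zeros(A_max)
    y_pool, pred_pool, dec_pool = [], [], []
    for _ in range(n_reps):
        tr_pos = rng.permutation(idx_pos)
        tr_neg = rng.permutation(idx_neg)
        train = np.concatenate([tr_pos[:n_tr_pos], tr_neg[:n_tr_neg]])
        test = np.concatenate([tr_pos[n_tr_pos:], tr_neg[n_tr_neg:]])
        preds, decs = _eval_split(X, y, train, test, spec, A_max)
        err_sum += (preds != y[test]).mean(axis=1)
        y_pool.append(y[test]); pred_pool.append(preds); dec_pool.append(decs)
    err_curve = err_sum / n_reps
    y_pool = np.concatenate(y_pool)
    pred_pool = np.concatenate(pred_pool, axis=1)
    dec_pool = np.concatenate(dec_pool, axis=1)
    return _summarise("mccv", err_curve, y_pool, pred_pool, dec_pool, len(y))
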