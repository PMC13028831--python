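"""Subwindow permutation analysis (SPA), COSS ranking and rank tests.

SPA is a supervised Monte Carlo variable-selection scheme: many PLS-LDA
sub-models are fitted on random stratified subsets of samples and random
subsets of variables.  For every sub-model the out-of-subset error is
recorded twice per included variable — once with the held-out values
intact ("normal") and once with that variable's held-out values permuted
across test samples ("permuted").  A variable that carries predictive
information degrades the sub-model when permuted, so its permuted errors
stochastically exceed its normal errors; the one-sided Mann–Whitney
probability of that excess is the variable's p-value, and
``COSS = -log10(p)`` is its conditional synergistic score.  Variables with
p below a nominal threshold (default 0.05, i.e. COSS > 1.30) are selected.

The exact Mann–Whitney U test used inside SPA is also exposed for
univariate group comparisons, alongside 1.5-IQR boxplot statistics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from gonadnmr.chemometrics import (
    NEG_LABEL, POS_LABEL, _as_labels, _fit_lda, fit_pls_nipals, scale_matrix,
    ScalingSpec,
)

logger = logging.getLogger(__name__)

#: p-values below this are clamped before taking log10 (finite precision).
P_FLOOR = 1e-300

#: largest n1+n2 for which the exact U distribution is enumerated.
EXACT_LIMIT = 20


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

@dataclass
class MWUResult:
    """Mann–Whitney U comparison of two independent samples."""

    U: float
    p_two_sided: float
    p_one_sided: float  # alternative: x stochastically greater than y
    group_medians: tuple
    n1: int
    n2: int
    method: str  # "exact" or "normal_approx"


def mann_whitney(x, y, sided: str = "two-sided") -> MWUResult:
    """Mann–Whitney U test of ``x`` vs ``y``.

    The exact permutation distribution of U is used when ``n1 + n2 <= 20``
    and the pooled data are tie-free; otherwise mid-ranks with the
    tie-corrected normal approximation (continuity-corrected).  Both the
    two-sided p and the one-sided p for "x greater" are reported; ``sided``
    selects which one is considered primary by callers ("two-sided",
    "greater" or "less").
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if sided not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {sided!r}")
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == len(pooled)
    exact = tie_free and len(pooled) <= EXACT_LIMIT
    method = "exact" if exact else "asymptotic"
    kwargs = dict(method=method, use_continuity=True)
    res_two = sps.mannwhitneyu(x, y, alternative="two-sided", **kwargs)
    res_gt = sps.mannwhitneyu(x, y, alternative="greater", **kwargs)
    return MWUResult(
        U=float(res_two.statistic),
        p_two_sided=float(res_two.pvalue),
        p_one_sided=float(res_gt.pvalue),
        group_medians=(float(np.median(x)), float(np.median(y))),
        n1=len(x), n2=len(y),
        method="exact" if exact else "normal_approx",
    )


def coss_transform(p: float) -> float:
    """Conditional synergistic score: ``COSS = -log10(p)``.

    Monotone decreasing in p; p = 0.05 maps to ~1.30, the nominal
    selection threshold.  p must lie in (0, 1]; values below 1e-300 are
    clamped (and logged) to keep the logarithm finite.
    """
    p = float(p)
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p must be in (0, 1], got {p}")
    if p < P_FLOOR:
        logger.warning("coss_transform: p=%g clamped to %g", p, P_FLOOR)
        p = P_FLOOR
    return float(-np.log10(p))


# ---------------------------------------------------------------------------
# SPA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SPAConfig:
    """Monte Carlo settings for subwindow permutation analysis.

    Defaults: 1000 iterations, 75% of each class per sub-model,
    ``q_vars = ceil(sqrt(V))`` clipped to [5, 15] when None, two inner
    latent variables (the validated model complexity), alpha 0.05.
    """

    n_iter: int = 1000
    sample_fraction: float = 0.75
    q_vars: Optional[int] = None
    inner_lv: int = 2
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.sample_fraction < 1:
            raise ValueError("sample_fraction must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")

    def resolve_q(self, n_vars: int) -> int:
        if self.q_vars is not None:
            if not 1 <= self.q_vars <= n_vars:
                raise ValueError(f"q_vars must be in [1, {n_vars}]")
            return self.q_vars
        q = int(np.ceil(np.sqrt(n_vars)))
        return int(np.clip(q, min(5, n_vars), min(15, n_vars)))


@dataclass
class SPAResult:
    """Per-variable SPA outcome."""

    var_labels: np.ndarray
    p_value: np.ndarray
    coss: np.ndarray
    n_inclusions: np.ndarray
    mean_error_normal: np.ndarray
    mean_error_permuted: np.ndarray
    selected: np.ndarray
    config: SPAConfig = field(repr=False, default=None)

    def ranking(self) -> np.ndarray:
        """Variable indices ordered by decreasing COSS."""
        return np.argsort(-self.coss, kind="stable")


def run_spa(X, y, cfg: SPAConfig, var_labels=None) -> SPAResult:
    """Run subwindow permutation analysis on a feature matrix.

    ``X`` should already carry the chosen global scaling; each sub-model
    additionally autoscales on its own training subset so held-out rows
    never contribute statistics.  Permutation is applied to the held-out
    partition only, per sub-model, so normal and permuted errors are
    paired on identical sub-models.  Deterministic under ``cfg.seed``.
    """
    X = np.asarray(X, dtype=float)
    y = _as_labels(y)
    n, V = X.shape
    if var_labels is None:
        var_labels = np.arange(V)
    var_labels = np.asarray(var_labels)
    q = cfg.resolve_q(V)
    rng = np.random.default_rng(cfg.seed)
    idx_pos = np.flatnonzero(y == POS_LABEL)
    idx_neg = np.flatnonzero(y == NEG_LABEL)
    n_tr_pos = max(int(round(cfg.sample_fraction * len(idx_pos))), 2)
    n_tr_neg = max(int(round(cfg.sample_fraction * len(idx_neg))), 2)
    if n_tr_pos >= len(idx_pos) or n_tr_neg >= len(idx_neg):
        raise ValueError("sample_fraction leaves an empty test partition")

    errs_normal = [[] for _ in range(V)]
    errs_perm = [[] for _ in range(V)]
    inner_spec = ScalingSpec(scale="auto")

    for _ in range(cfg.n_iter):
        perm_pos = rng.permutation(idx_pos)
        perm_neg = rng.permutation(idx_neg)
        train = np.concatenate([perm_pos[:n_tr_pos], perm_neg[:n_tr_neg]])
        test = np.concatenate([perm_pos[n_tr_pos:], perm_neg[n_tr_neg:]])
        vars_ = rng.choice(V, size=q, replace=False)

        Xtr, stats_ = scale_matrix(X[np.ix_(train, vars_)], inner_spec)
        Xte, _ = scale_matrix(X[np.ix_(test, vars_)], inner_spec, train_stats=stats_)
        if Xtr.shape[1] == 0:
            continue
        a_fit = min(cfg.inner_lv, len(train) - 1, Xtr.shape[1])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            model = fit_pls_nipals(Xtr, y[train], a_fit)
        y_te = y[test]
        e0 = float(np.mean(model.predict(Xte) != y_te))
        kept_vars = vars_[stats_.kept]
        for j, v in enumerate(kept_vars):
            Xp = Xte.copy()
            Xp[:, j] = Xp[rng.permutation(len(test)), j]
            ep = float(np.mean(model.predict(Xp) != y_te))
            errs_normal[v].append(e0)
            errs_perm[v].append(ep)

    n_incl = np.array([len(e) for e in errs_normal])
    if (n_incl == 0).any():
        missing = var_labels[n_incl == 0]
        raise RuntimeError(
            f"{len(missing)} variable(s) never sampled (e.g. {missing[:5]}); "
            f"increase n_iter above {cfg.n_iter}")

    p = np.empty(V)
    mean_n = np.empty(V)
    mean_p = np.empty(V)
    for v in range(V):
        en = np.asarray(errs_normal[v])
        ep = np.asarray(errs_perm[v])
        mean_n[v] = en.mean()
        mean_p[v] = ep.mean()
        # one-sided: permuted errors stochastically exceed normal errors
        p[v] = mann_whitney(ep, en, sided="greater").p_one_sided
    p = np.clip(p, P_FLOOR, 1.0)
    coss = -np.log10(p)
    return SPAResult(var_labels=var_labels, p_value=p, coss=coss,
                     n_inclusions=n_incl, mean_error_normal=mean_n,
                     mean_error_permuted=mean_p, selected=p < cfg.alpha,
                     config=cfg)


# ---------------------------------------------------------------------------
# boxplot statistics
# ---------------------------------------------------------------------------

@dataclass
class BoxplotStats:
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray


def boxplot_stats(values) -> BoxplotStats:
    """Median, quartiles, 1.5-IQR whiskers and outliers.

    Quartiles use linear interpolation (type-7).  Whiskers sit at the most
    extreme data points within 1.5 x IQR beyond the quartiles; points
    outside are listed as outliers.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return BoxplotStats(
        median=float(med), q1=float(q1), q3=float(q3),
        whisker_low=float(inside.min()), whisker_high=float(inside.max()),
        outliers=np.sort(v[(v < lo_fence) | (v > hi_fence)]),
    )
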