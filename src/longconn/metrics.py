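"""ROC machinery, bootstrap confidence intervals and report assembly.

Conventions: labels are binary with 1 = diseased; a subject is called
positive when its score is **at or above** the threshold.  AUC follows the
Mann-Whitney pair-counting convention (ties count 1/2).  The bootstrap
"confidence interval" is the (5th, 95th) percentile pair of 1000 AUC
replicates, each computed on ceil(0.8 n) prediction-label pairs resampled
jointly with replacement — i.e. a 90% percentile interval, reported as
such.  The operating threshold maximizes sensitivity^2 + specificity^2
over the ROC's threshold set, ties broken toward the lower threshold
(higher sensitivity, the screening-friendly choice); a fixed-0.5 report is
always emitted alongside it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import rankdata


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D arrays of equal length")
    if not np.isfinite(s).all():
        raise ValueError("scores contain non-finite values")
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    return s, y


def auc(scores, labels) -> float:
    """Area under the ROC curve by the rank (Mann-Whitney) formula.

    Equals the fraction of (positive, negative) pairs where the positive
    scores higher, counting ties as 1/2.
    """
    s, y = _validate(scores, labels)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    ranks = rankdata(s)  # average ranks implement the tie-1/2 convention
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class RocCurve:
    """ROC operating points with representative thresholds.

    Point i corresponds to calling positive every score >= thresholds[i];
    thresholds are gap midpoints between adjacent distinct scores (so any
    value in the open gap yields the same confusion matrix), running from
    above the largest score (point (0, 0)) down to the smallest score
    (point (1, 1)).
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray

    def area(self) -> float:
        return float(np.trapezoid(self.tpr, self.fpr))


def roc_curve(scores, labels) -> RocCurve:
    """Enumerate all distinct operating points of the score vector."""
    s, y = _validate(scores, labels)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos

    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    # indices where the (descending) score changes: one operating point per
    # distinct score value
    distinct = np.flatnonzero(np.diff(s_sorted) != 0)
    cut = np.r_[distinct, len(s_sorted) - 1]

    tp = np.cumsum(y_sorted)[cut]
    fp = np.cumsum(1 - y_sorted)[cut]
    uniq = s_sorted[cut]  # descending distinct scores

    # the point cut at distinct score u_i is realized by any threshold in
    # (u_{i+1}, u_i]; represent it by the gap midpoint (the smallest score
    # itself for the all-positive point (1, 1))
    gap = (uniq[0] - uniq[-1]) / len(uniq) if len(uniq) > 1 else 1.0
    lower = np.r_[uniq[1:], uniq[-1]]
    mids = (uniq + lower) / 2.0
    mids[-1] = uniq[-1]

    return RocCurve(
        fpr=np.r_[0.0, fp / n_neg],
        tpr=np.r_[0.0, tp / n_pos],
        thresholds=np.r_[uniq[0] + gap, mids],
    )


def optimal_threshold(roc: RocCurve) -> float:
    """Threshold maximizing sensitivity^2 + specificity^2 over the curve.

    Ties are broken toward the lower threshold.  For perfectly separated
    scores this returns the midpoint of the separating gap.
    """
    crit = roc.tpr**2 + (1.0 - roc.fpr) ** 2
    best = crit.max()
    # thresholds are descending; the last maximizer is the lowest threshold
    idx = np.flatnonzero(np.isclose(crit, best, rtol=0, atol=1e-12))[-1]
    return float(roc.thresholds[idx])


@dataclass
class ConfusionMetrics:
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    kappa: float
    tp: int
    fn: int
    tn: int
    fp: int


def classification_metrics(scores, labels, threshold: float) -> ConfusionMetrics:
    """Confusion-matrix metrics at a given threshold (positive iff >=)."""
    s, y = _validate(scores, labels)
    if not 0.0 <= threshold <= 1.0:
        warnings.warn(f"threshold {threshold} outside [0, 1]", stacklevel=2)
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    n = len(y)
    p_o = (tp + tn) / n
    p_e = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / n**2
    kappa = 0.0 if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)
    return ConfusionMetrics(
        sensitivity=sens,
        specificity=spec,
        balanced_accuracy=(sens + spec) / 2.0,
        kappa=kappa,
        tp=tp, fn=fn, tn=tn, fp=fp,
    )


@dataclass
class BootstrapResult:
    ci_low: float
    ci_high: float
    replicates: np.ndarray = field(repr=False)
    fpr_grid: np.ndarray = field(repr=False)
    tpr_band_low: np.ndarray = field(repr=False)
    tpr_band_high: np.ndarray = field(repr=False)


def bootstrap_ci(
    scores,
    labels,
    n_reps: int = 1000,
    keep_frac: float = 0.8,
    seed: int = 0,
    n_grid: int = 101,
) -> BootstrapResult:
    """Percentile bootstrap of the AUC and an ROC band.

    Each replicate resamples ceil(keep_frac * n) prediction-label pairs
    jointly with replacement (redrawn if single-class) and records its AUC
    and its ROC interpolated on a fixed FPR grid; the interval is the
    (5th, 95th) percentile pair of the replicate AUCs.
    """
    s, y = _validate(scores, labels)
    n = len(s)
    if min(int(y.sum()), n - int(y.sum())) < 4:
        warnings.warn("fewer than 4 subjects per class: bootstrap is unstable",
                      stacklevel=2)
    m = int(np.ceil(keep_frac * n))
    rng = np.random.default_rng(seed)
    grid = np.linspace(0.0, 1.0, n_grid)

    reps = np.empty(n_reps)
    bands = np.empty((n_reps, n_grid))
    for r in range(n_reps):
        for _ in range(1000):
            idx = rng.integers(0, n, size=m)
            if 0 < y[idx].sum() < m:
                break
        else:  # pragma: no cover - would need a pathological cohort
            raise RuntimeError("could not draw a two-class bootstrap resample")
        roc = roc_curve(s[idx], y[idx])
        reps[r] = roc.area()
        bands[r] = np.interp(grid, roc.fpr, roc.tpr)

    lo, hi = np.percentile(reps, [5.0, 95.0])
    blo, bhi = np.percentile(bands, [5.0, 95.0], axis=0)
    return BootstrapResult(
        ci_low=float(lo), ci_high=float(hi), replicates=reps,
        fpr_grid=grid, tpr_band_low=blo, tpr_band_high=bhi,
    )


def _ridge_logit_p(X: np.ndarray, y: np.ndarray, alpha: float = 0.5) -> float:
    """Wald p for the first non-constant coefficient of a ridge-penalized
    logistic fit — fallback when the unpenalized MLE separates."""
    from scipy.optimize import minimize

    pen = np.ones(X.shape[1]) * alpha
    pen[0] = 0.0  # leave the intercept unpenalized

    def nll(beta):
        eta = X @ beta
        return float(np.sum(np.logaddexp(0.0, eta) - y * eta) + 0.5 * np.sum(pen * beta**2))

    def grad(beta):
        p = expit(X @ beta)
        return X.T @ (p - y) + pen * beta

    res = minimize(nll, np.zeros(X.shape[1]), jac=grad, method="BFGS")
    p = expit(X @ res.x)
    W = p * (1 - p)
    H = X.T @ (X * W[:, None]) + np.diag(pen)
    cov = np.linalg.inv(H)
    z = res.x[1] / np.sqrt(cov[1, 1])
    from scipy.stats import norm

    return float(2.0 * norm.sf(abs(z)))


def covariate_adjusted_p(scores, labels, age, gender) -> float:
    """Significance of the progression score adjusted for age and gender.

    Fits logistic regression of group on (score, age, gender) and returns
    the two-sided Wald p-value of the score coefficient.  Under perfect or
    quasi-separation the MLE diverges; a ridge-penalized fit is used
    instead and a warning emitted.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if np.ptp(s) == 0:
        raise ValueError("score is constant; its coefficient is undefined")
    age = np.asarray(age, dtype=float)
    g = np.asarray(
        [1.0 if str(v).upper().startswith("M") else 0.0 for v in np.asarray(gender)]
        if np.asarray(gender).dtype.kind in "OUS"
        else np.asarray(gender, dtype=float)
    )
    if len(y) <= 5:
        raise ValueError("too few subjects for a 3-covariate logistic model")

    def _std(v):
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else v - v.mean()

    # standardize so the Wald test (and the ridge fallback's penalty) is
    # insensitive to covariate units; p-values of the MLE are unaffected
    X = sm.add_constant(np.column_stack([_std(s), _std(age), g - g.mean()]))

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        # on the standardized scale |beta| ~ 10 means an odds ratio of e^10
        # per SD: the hallmark of (quasi-)separation, where Wald SEs are junk
        if (
            fit.mle_retvals.get("converged", False)
            and np.isfinite(fit.bse).all()
            and np.abs(fit.params).max() < 10.0
        ):
            return float(fit.pvalues[1])
    except Exception:
        pass
    warnings.warn(
        "logistic MLE did not converge (separation?); using ridge-penalized fit",
        stacklevel=2,
    )
    return _ridge_logit_p(X, y)


@dataclass
class ScalarMarkerResult:
    auc: float
    p_value: float
    flipped: bool  # True if the marker was negated to keep AUC >= 0.5


def scalar_marker_eval(values, labels, age=None, gender=None) -> ScalarMarkerResult:
    """Discriminative ability of a single clinical marker.

    The raw marker (a cross-sectional scale value or a longitudinal
    difference) is treated as the score; if its AUC falls below 0.5 the
    orientation is flipped (and recorded) so that higher always means more
    diseased.  The p-value is covariate-adjusted when age/gender are
    supplied, otherwise the Wald p of a univariate logistic fit.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels).astype(int)
    if np.ptp(v) == 0:
        raise ValueError("marker is constant")
    a = auc(v, y)
    flipped = a < 0.5
    if flipped:
        v, a = -v, 1.0 - a
    if age is not None and gender is not None:
        p = covariate_adjusted_p(v, y, age, gender)
    else:
        X = sm.add_constant((v - v.mean()) / v.std())
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            p = float(fit.pvalues[1])
            if not np.isfinite(p) or abs(fit.params[1]) >= 1e3:
                raise ValueError
        except Exception:
            p = _ridge_logit_p(X, y)
    return ScalarMarkerResult(auc=a, p_value=p, flipped=flipped)


@dataclass
class EvaluationReport:
    """Everything reported for one group contrast."""

    auc: float
    ci_low: float
    ci_high: float
    chosen_threshold: float
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    kappa: float
    fixed_threshold_metrics: dict  # the always-emitted threshold-0.5 variant
    adjusted_p: float | None
    n_pos: int
    n_neg: int
    settings: dict

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate(
    scores,
    labels,
    age=None,
    gender=None,
    n_boot: int = 1000,
    seed: int = 0,
    threshold: float | None = None,
    settings: dict | None = None,
) -> tuple[EvaluationReport, RocCurve, BootstrapResult]:
    """Assemble the full evaluation for one contrast.

    If ``threshold`` is None the sens^2+spec^2-optimal threshold of this
    contrast's own ROC is used; passing a threshold evaluates at an
    externally derived operating point instead (e.g. scoring the prodromal
    contrast at the PD/control threshold).
    """
    s, y = _validate(scores, labels)
    roc = roc_curve(s, y)
    boot = bootstrap_ci(s, y, n_reps=n_boot, seed=seed)
    thr = optimal_threshold(roc) if threshold is None else float(threshold)
    cm = classification_metrics(s, y, thr)
    cm05 = classification_metrics(s, y, 0.5)
    adj_p = None
    if age is not None and gender is not None:
        adj_p = covariate_adjusted_p(s, y, age, gender)
    report = EvaluationReport(
        auc=auc(s, y),
        ci_low=boot.ci_low,
        ci_high=boot.ci_high,
        chosen_threshold=thr,
        sensitivity=cm.sensitivity,
        specificity=cm.specificity,
        balanced_accuracy=cm.balanced_accuracy,
        kappa=cm.kappa,
        fixed_threshold_metrics={
            "threshold": 0.5,
            "sensitivity": cm05.sensitivity,
            "specificity": cm05.specificity,
            "balanced_accuracy": cm05.balanced_accuracy,
            "kappa": cm05.kappa,
        },
        adjusted_p=adj_p,
        n_pos=int(y.sum()),
        n_neg=int(len(y) - y.sum()),
        settings=dict(settings or {}, n_boot=n_boot, seed=seed,
                      ci="percentile 5th-95th", threshold_rule=(
                          "max sens^2+spec^2" if threshold is None else "external")),
    )
    return report, roc, boot
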