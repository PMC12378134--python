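"""Validation statistics for defect scores and HMR.

Implements the agreement and diagnostic analyses used to validate a normal
database against clinical readings:

* Pearson correlation with Bland-Altman mean difference and 95% limits of
  agreement between two scoring variants;
* empirical ROC analysis — the AUC as the Mann-Whitney exceedance
  probability (ties count one half), a DeLong variance for its confidence
  interval, the DeLong paired test for comparing two markers measured on the
  same subjects, and a Youden-index operating point;
* Kruskal-Wallis contrasts of a marker across disease groups;
* a multivariable logistic model combining HMR with a summed defect score,
  whose fitted probability serves as the combined diagnostic marker.

Direction convention: a higher defect score indicates disease, a lower HMR
indicates disease; markers where low values are abnormal are negated
internally so every ROC uses the unified "higher = case" orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats


class EvaluationError(ValueError):
    """Raised for degenerate inputs (single class, unpaired data, ...)."""


# ---------------------------------------------------------------------------
# Agreement (Pearson + Bland-Altman)

@dataclass
class AgreementResult:
    pearson_r: float          # NaN when either input is constant
    mean_difference: float
    loa_lower: float
    loa_upper: float
    n: int

    def to_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "mean_difference": self.mean_difference,
            "loa_lower": self.loa_lower,
            "loa_upper": self.loa_upper,
            "n": self.n,
        }


def agreement(x: Sequence[float], y: Sequence[float]) -> AgreementResult:
    """Pearson r plus Bland-Altman statistics for paired measurements.

    Differences are ``x - y``; limits of agreement are
    mean(d) +/- 1.96 * SD(d) with the sample SD (n - 1).  If either input is
    constant the correlation is undefined and reported as NaN, while the
    Bland-Altman quantities are still returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise EvaluationError("paired inputs must be equal-length 1D arrays")
    if x.size < 3:
        raise EvaluationError("need at least 3 pairs")
    d = x - y
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(x, y)[0])
    return AgreementResult(r, md, md - 1.96 * sd, md + 1.96 * sd, x.size)


# ---------------------------------------------------------------------------
# ROC / AUC with DeLong variance

@dataclass
class ROCResult:
    auc: float
    auc_ci: tuple[float, float]
    sensitivity: float
    specificity: float
    accuracy: float
    cutoff: float
    n_cases: int
    n_controls: int
    direction: str = "higher"

    def to_dict(self) -> dict:
        return {
            "auc": self.auc, "auc_ci": list(self.auc_ci),
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "accuracy": self.accuracy, "cutoff": self.cutoff,
            "n_cases": self.n_cases, "n_controls": self.n_controls,
            "direction": self.direction,
        }


def _check_labels(labels: np.ndarray) -> None:
    if labels.min() < 0 or labels.max() > 1:
        raise EvaluationError("labels must be 0 (control) / 1 (case)")
    if labels.sum() == 0 or labels.sum() == labels.size:
        raise EvaluationError("need at least one case and one control")


def _delong_placements(scores: np.ndarray, labels: np.ndarray
                       ) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and the DeLong per-subject placement values via midranks."""
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    m, n = cases.size, controls.size
    all_ranks = stats.rankdata(np.concatenate([cases, controls]))
    case_ranks = stats.rankdata(cases)
    control_ranks = stats.rankdata(controls)
    # placement of each case among controls and vice versa
    v10 = (all_ranks[:m] - case_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - control_ranks) / m
    auc = float(v10.mean())
    return auc, v10, v01


def _delong_variance(v10: np.ndarray, v01: np.ndarray) -> float:
    s10 = v10.var(ddof=1) if v10.size > 1 else 0.0
    s01 = v01.var(ddof=1) if v01.size > 1 else 0.0
    return float(s10 / v10.size + s01 / v01.size)


def auc_mann_whitney(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Empirical AUC: probability a random case outscores a random control,
    ties counting one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_labels(labels)
    auc, _, _ = _delong_placements(scores, labels)
    return auc


def roc(
    scores: Sequence[float],
    labels: Sequence[int],
    direction: str = "higher",
    ci_level: float = 0.95,
) -> ROCResult:
    """Empirical ROC analysis of one marker.

    ``direction='higher'`` means larger marker values indicate disease;
    ``'lower'`` negates the marker internally (the HMR convention).  The CI
    is the normal-approximation interval with the DeLong variance, clipped
    to [0, 1].  The reported operating point maximizes the Youden index
    (sensitivity + specificity - 1); the cutoff is the smallest
    direction-aligned marker value called positive, reported on the original
    scale.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise EvaluationError("scores and labels must align")
    _check_labels(labels)
    if direction not in ("higher", "lower"):
        raise EvaluationError(f"unknown direction {direction!r}")
    s = scores if direction == "higher" else -scores

    auc, v10, v01 = _delong_placements(s, labels)
    se = np.sqrt(_delong_variance(v10, v01))
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    ci = (max(0.0, auc - z * se), min(1.0, auc + z * se))

    # Youden-optimal cutoff over the observed thresholds ("positive" = s >= t)
    thresholds = np.unique(s)
    best = (-np.inf, thresholds[0], 0.0, 0.0)
    n_cases = int(labels.sum())
    n_controls = labels.size - n_cases
    for t in thresholds:
        pos = s >= t
        sens = (pos & (labels == 1)).sum() / n_cases
        spec = (~pos & (labels == 0)).sum() / n_controls
        if sens + spec - 1.0 > best[0] + 1e-12:
            best = (sens + spec - 1.0, t, sens, spec)
    _, cut, sens, spec = best
    acc = (sens * n_cases + spec * n_controls) / labels.size
    cutoff = float(cut if direction == "higher" else -cut)
    return ROCResult(auc, ci, float(sens), float(spec), float(acc), cutoff,
                     n_cases, n_controls, direction)


def compare_rocs(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[int],
    direction_a: str = "higher",
    direction_b: str = "higher",
) -> tuple[float, float]:
    """DeLong paired test for the AUC difference of two markers.

    Both markers must be measured on the same subjects in the same order.
    Returns ``(auc_a - auc_b, two-sided p)``; symmetric in A and B up to the
    sign of the difference.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if a.shape != b.shape or a.shape != labels.shape:
        raise EvaluationError("markers must be paired on identical subjects")
    _check_labels(labels)
    if direction_a == "lower":
        a = -a
    if direction_b == "lower":
        b = -b

    auc_a, v10a, v01a = _delong_placements(a, labels)
    auc_b, v10b, v01b = _delong_placements(b, labels)
    m, n = v10a.size, v01a.size
    var_a = _delong_variance(v10a, v01a)
    var_b = _delong_variance(v10b, v01b)
    if m > 1 and n > 1:
        cov = (np.cov(v10a, v10b, ddof=1)[0, 1] / m
               + np.cov(v01a, v01b, ddof=1)[0, 1] / n)
    else:
        cov = 0.0
    var_diff = var_a + var_b - 2.0 * cov
    diff = auc_a - auc_b
    if var_diff <= 1e-15:
        return diff, 1.0 if abs(diff) < 1e-12 else 0.0
    z = diff / np.sqrt(var_diff)
    return diff, float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Group contrasts

@dataclass
class GroupContrast:
    group_labels: list[str]
    group_n: list[int]
    group_mean: list[float]
    group_median: list[float]
    h_stat: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "groups": self.group_labels, "n": self.group_n,
            "mean": self.group_mean, "median": self.group_median,
            "kruskal_h": self.h_stat, "p_value": self.p_value,
        }


def kruskal_wallis(values: Sequence[float], groups: Sequence[str]) -> GroupContrast:
    """Tie-corrected Kruskal-Wallis H test of a marker across groups."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise EvaluationError("values and group labels must align")
    names = sorted(set(groups.tolist()))
    if len(names) < 2:
        raise EvaluationError("need at least 2 groups")
    samples = [values[groups == g] for g in names]
    if np.ptp(values) == 0:
        h, p = 0.0, 1.0  # all observations tied: no evidence of any contrast
    else:
        h, p = stats.kruskal(*samples)
    return GroupContrast(
        group_labels=names,
        group_n=[int(s.size) for s in samples],
        group_mean=[float(s.mean()) for s in samples],
        group_median=[float(np.median(s)) for s in samples],
        h_stat=float(h), p_value=float(p),
    )


# ---------------------------------------------------------------------------
# Combined logistic model

@dataclass
class CombinedModel:
    intercept: float
    beta_hmr: float
    beta_score: float
    deviance: float
    deviance_hmr_only: float
    deviance_score_only: float
    converged: bool
    separation_flag: bool
    probabilities: np.ndarray

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.intercept, self.beta_hmr, self.beta_score])

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept, "beta_hmr": self.beta_hmr,
            "beta_score": self.beta_score, "deviance": self.deviance,
            "deviance_hmr_only": self.deviance_hmr_only,
            "deviance_score_only": self.deviance_score_only,
            "converged": self.converged, "separation_flag": self.separation_flag,
        }


def _binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _fit_logistic(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool, bool]:
    """ML logistic fit by IRLS; returns (params, fitted p, converged, separated)."""
    model = sm.GLM(y, X, family=sm.families.Binomial())
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(maxiter=100, tol=1e-8)
        params = np.asarray(res.params)
        fitted = np.asarray(res.fittedvalues)
        # near-degenerate fitted probabilities signal quasi-separation
        separated = bool(np.all((fitted < 1e-8) | (fitted > 1 - 1e-8)))
        return params, fitted, bool(res.converged), separated
    except Exception:
        # perfect separation: report a weakly ridge-penalized fit, flagged
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit_regularized(alpha=1e-6, disp=0)
        params = np.asarray(res.params)
        fitted = 1.0 / (1.0 + np.exp(-X @ params))
        return params, fitted, True, True


def fit_combined(
    hmr_values: Sequence[float],
    defect_scores: Sequence[float],
    labels: Sequence[int],
) -> CombinedModel:
    """Logistic combination of HMR and summed defect score.

    Fits logit P(case) = b0 + b1*HMR + b2*score by maximum likelihood and
    also the two nested single-predictor models for the deviance comparison.
    The fitted probability is the combined marker to feed into :func:`roc`
    (direction 'higher').  Perfect separation is flagged, not fatal.
    """
    h = np.asarray(hmr_values, dtype=float)
    s = np.asarray(defect_scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if h.shape != s.shape or h.shape != y.shape:
        raise EvaluationError("predictors and labels must align")
    if np.any(~np.isfinite(h)) or np.any(~np.isfinite(s)):
        raise EvaluationError("missing values in predictors")
    if np.ptp(h) == 0 or np.ptp(s) == 0:
        raise EvaluationError("both predictors must be non-constant")
    _check_labels(y.astype(int))

    ones = np.ones_like(h)
    X_full = np.column_stack([ones, h, s])
    params, fitted, converged, separated = _fit_logistic(X_full, y)
    dev = _binomial_deviance(y, fitted)
    _, fit_h, _, _ = _fit_logistic(np.column_stack([ones, h]), y)
    _, fit_s, _, _ = _fit_logistic(np.column_stack([ones, s]), y)
    return CombinedModel(
        intercept=float(params[0]), beta_hmr=float(params[1]),
        beta_score=float(params[2]), deviance=dev,
        deviance_hmr_only=_binomial_deviance(y, fit_h),
        deviance_score_only=_binomial_deviance(y, fit_s),
        converged=converged, separation_flag=separated,
        probabilities=fitted,
    )
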