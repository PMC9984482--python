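"""Statistical battery linking PPV indices to functional outcome.

The analysis suite applied to a stroke cohort:

* Spearman rank correlation between each PPV index and the ordinal mRS
  score (first-pass association screen);
* Mann-Whitney U comparisons between patient subgroups;
* multivariable logistic regression of the dichotomized outcome on each
  index, with odds ratios expressed per 10 mmHg increase of the index and
  Wald 95 % confidence intervals — four nested model specifications:

  =====  ===========================================================
  M1     outcome ~ index (unadjusted)
  M2     outcome ~ index + thrombolysed + mean PP
  M3     as M2, but outcome from the severity-adjusted rule
  M4     M2 covariates + age + sex + history of myocardial infarction
  =====  ===========================================================

* ROC analysis per index/outcome pair: empirical AUC (trapezoid, equal to
  the Mann-Whitney probability with ties counted 1/2), DeLong variance for
  the AUC confidence interval and the test of AUC = 0.5, Youden's index
  J = max(sensitivity + specificity - 1) and the attaining cut-off.

Logistic fits delegate to statsmodels (Newton iterations, i.e. IRLS);
rank tests delegate to scipy. The ROC/DeLong machinery is implemented
here. Missing data are handled complete-case per model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .outcomes import OutcomeAssessment, dichotomize_mrs, severity_adjusted_outcome

__all__ = [
    "ModelResult",
    "ROCResult",
    "spearman_rho",
    "mann_whitney_u",
    "fit_logistic",
    "run_model_suite",
    "roc_analysis",
    "outcome_vector",
    "MODEL_IDS",
]

MODEL_IDS = ("M1", "M2", "M3", "M4")

_Z95 = 1.959963984540054  # two-sided 95 % normal quantile


@dataclass(frozen=True)
class ModelResult:
    """One fitted logistic model for one PPV index and horizon."""

    model_id: str
    predictor: str
    coef: dict[str, float] = field(default_factory=dict)
    se: dict[str, float] = field(default_factory=dict)
    or_per_10mmHg: float = float("nan")
    ci95: tuple[float, float] = (float("nan"), float("nan"))
    p_value: float = float("nan")
    n_used: int = 0
    converged: bool = False
    error: str | None = None


@dataclass(frozen=True)
class ROCResult:
    auc: float
    auc_ci95: tuple[float, float]
    youden_index: float
    cutoff: float
    p_value: float
    n_pos: int
    n_neg: int


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with midranks for ties.

    Returns (rho, two-sided p) where p uses the t approximation on n-2
    degrees of freedom. Constant input is an error (rho undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    if x.size < 3:
        raise ValueError("need n >= 3 for a Spearman correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman rho is undefined for a constant vector")
    rho, p = st.spearmanr(x, y)
    return float(rho), float(p)


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Mann-Whitney U with midranks; returns (min(U_a, U_b), two-sided p).

    The p-value uses exact enumeration when both samples have n <= 8 and
    no ties straddle the groups; otherwise the normal approximation with
    tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and not has_ties) else "asymptotic"
    res = st.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u_a = float(res.statistic)
    u_min = min(u_a, a.size * b.size - u_a)
    return u_min, float(res.pvalue)


def _check_design(X: np.ndarray) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix (collinear or constant column)")


def fit_logistic(
    y,
    X: pd.DataFrame,
    predictor: str,
    *,
    scale: float = 10.0,
    model_id: str = "M1",
    max_iter: int = 100,
    tol: float = 1e-8,
) -> ModelResult:
    """Maximum-likelihood logistic fit with the OR reported per ``scale``
    units of ``predictor``.

    ``X`` holds the covariates (no intercept column; one is added). The
    named predictor column is divided by ``scale`` before fitting, so
    exp(coefficient) is directly the OR per ``scale`` mmHg and the Wald
    interval is exp(beta +/- 1.96 se) on that scale. Rows with missing
    values are dropped (complete-case). Perfect separation is flagged via
    ``converged=False`` rather than raising; a singular design raises.
    """
    y = pd.Series(np.asarray(y, dtype=float), index=X.index)
    data = X.copy()
    if predictor not in data.columns:
        raise KeyError(f"predictor {predictor!r} not in design columns {list(data.columns)}")
    data = data.assign(_y=y).dropna()
    yv = data.pop("_y").to_numpy()
    if not set(np.unique(yv)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if np.all(yv == yv[0]):
        raise ValueError("degenerate outcome: only one class present")
    data[predictor] = data[predictor] / scale
    design = sm.add_constant(data, has_constant="add")
    _check_design(design.to_numpy())
    if design.shape[0] <= design.shape[1]:
        raise ValueError("fewer observations than parameters")

    sep_flag = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fit = sm.Logit(yv, design).fit(
                disp=0, method="newton", maxiter=max_iter, tol=tol
            )
        except Exception as exc:  # PerfectSeparationError and kin
            return ModelResult(
                model_id=model_id,
                predictor=predictor,
                n_used=int(design.shape[0]),
                converged=False,
                error=f"separation_or_fit_failure: {exc}",
            )
        for w in caught:
            if "separation" in str(w.message).lower():
                sep_flag = True
    converged = bool(fit.mle_retvals.get("converged", False)) and not sep_flag
    beta = float(fit.params[predictor])
    se = float(fit.bse[predictor])
    or10 = float(np.exp(beta))
    ci = (float(np.exp(beta - _Z95 * se)), float(np.exp(beta + _Z95 * se)))
    return ModelResult(
        model_id=model_id,
        predictor=predictor,
        coef={k: float(v) for k, v in fit.params.items()},
        se={k: float(v) for k, v in fit.bse.items()},
        or_per_10mmHg=or10,
        ci95=ci,
        p_value=float(fit.pvalues[predictor]),
        n_used=int(design.shape[0]),
        converged=converged,
        error="perfect_separation" if sep_flag else None,
    )


def outcome_vector(cohort: pd.DataFrame, horizon: str, rule: str = "dichotomized") -> pd.Series:
    """0/1 outcome labels (1 = unfavorable) for a cohort table.

    ``horizon`` is '30d' or '90d'; ``rule`` selects plain mRS
    dichotomization or the severity-adjusted rule (which additionally
    reads ``nihss_admission``). Missing mRS propagates as NaN.
    """
    col = f"mrs_{horizon}"
    if col not in cohort.columns:
        raise KeyError(f"cohort lacks column {col!r}")
    out = []
    for mrs, nihss in zip(cohort[col], cohort["nihss_admission"]):
        if pd.isna(mrs):
            out.append(np.nan)
            continue
        a = OutcomeAssessment(int(mrs), int(nihss), horizon)  # type: ignore[arg-type]
        lab = dichotomize_mrs(a) if rule == "dichotomized" else severity_adjusted_outcome(a)
        out.append(lab.as_int())
    return pd.Series(out, index=cohort.index, dtype=float)


_MODEL_COVARIATES = {
    "M1": [],
    "M2": ["thrombolysed", "mean_pp"],
    "M3": ["thrombolysed", "mean_pp"],
    "M4": ["thrombolysed", "mean_pp", "age", "female", "myocardial_infarction"],
}


def run_model_suite(cohort: pd.DataFrame, index_name: str, horizon: str) -> list[ModelResult]:
    """Fit the four model specifications for one PPV index and horizon.

    Per-model failures (degenerate outcome, separation, singularity) are
    recorded in the corresponding :class:`ModelResult` and do not abort
    the other models.
    """
    if index_name not in cohort.columns:
        raise KeyError(f"index {index_name!r} not in cohort")
    results = []
    for mid in MODEL_IDS:
        rule = "severity_adjusted" if mid == "M3" else "dichotomized"
        covs = [c for c in _MODEL_COVARIATES[mid] if c != index_name]
        try:
            y = outcome_vector(cohort, horizon, rule)
            X = cohort[[index_name] + covs].astype(float)
            res = fit_logistic(y, X, index_name, model_id=mid)
        except Exception as exc:
            res = ModelResult(model_id=mid, predictor=index_name, error=str(exc))
        results.append(res)
    return results


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance via placement values."""
    m, n = pos.size, neg.size
    # placement of each positive among negatives and vice versa, ties = 1/2;
    # AUC from the integer win count so tie-free data give exact ratios
    wins = np.empty(m)
    for i, s in enumerate(pos):
        wins[i] = np.sum(s > neg) + 0.5 * np.sum(s == neg)
    v10 = wins / n
    v01 = np.empty(n)
    for j, s in enumerate(neg):
        v01[j] = (np.sum(pos > s) + 0.5 * np.sum(pos == s)) / m
    auc = float(wins.sum() / (m * n))
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    return auc, s10 / m + s01 / n


def roc_analysis(scores, labels) -> ROCResult:
    """Empirical ROC of "predict unfavorable if score >= cutoff".

    AUC equals the probability a random positive outscores a random
    negative (ties 1/2); its CI and the test of AUC = 0.5 use the DeLong
    variance. The reported cut-off is the smallest observed score whose
    threshold rule attains the maximal Youden J.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-d vectors")
    if not set(np.unique(labels)) <= {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both outcome classes must be present for ROC analysis")

    auc, var = _delong_variance(pos, neg)
    se = float(np.sqrt(var))
    if se > 0:
        z = (auc - 0.5) / se
        p = float(2 * st.norm.sf(abs(z)))
    else:
        p = 0.0 if auc != 0.5 else 1.0
    ci = (max(0.0, auc - _Z95 * se), min(1.0, auc + _Z95 * se))

    best_j, best_cut = -np.inf, np.nan
    for t in np.sort(np.unique(scores)):  # ascending: ties broken toward lower score
        sens = np.mean(pos >= t)
        spec = np.mean(neg < t)
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_cut = float(j), float(t)
    return ROCResult(
        auc=auc,
        auc_ci95=ci,
        youden_index=best_j,
        cutoff=best_cut,
        p_value=p,
        n_pos=int(pos.size),
        n_neg=int(neg.size),
    )
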