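"""Association models: logistic/linear regressions, ROC AUC, VIF.

The exposure of interest (thalamus volume, cm³) is always the first
predictor; adjusted models add age, sex and intracranial volume, and a
sensitivity flag further adds surgery descriptors.  Odds ratios are per
unit (cm³) increment with Wald 95% intervals; model accuracy is the ROC
AUC of the fitted probabilities (Mann–Whitney concordance, ties half).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

ADJUSTMENT_COVARIATES = ("age_years", "sex", "icv_cm3")
SURGERY_COVARIATES = ("surgery_duration_min", "surgery_type")
VIF_FLAG_THRESHOLD = 2.5
_Z975 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class ModelSpec:
    outcome: str
    predictors: tuple[str, ...]
    family: Literal["logistic", "linear"]

    def __post_init__(self) -> None:
        if self.family not in ("logistic", "linear"):
            raise ValueError(f"unknown family {self.family!r}")
        if not self.predictors:
            raise ValueError("at least one predictor required")
        if self.predictors[0] != "thalamus_cm3":
            raise ValueError("thalamus_cm3 must be the first predictor")

    @classmethod
    def unadjusted(cls, outcome: str, family: Literal["logistic", "linear"] = "logistic") -> "ModelSpec":
        return cls(outcome, ("thalamus_cm3",), family)

    @classmethod
    def adjusted(
        cls,
        outcome: str,
        family: Literal["logistic", "linear"] = "logistic",
        surgery_sensitivity: bool = False,
    ) -> "ModelSpec":
        preds: tuple[str, ...] = ("thalamus_cm3", *ADJUSTMENT_COVARIATES)
        if surgery_sensitivity:
            preds = preds + SURGERY_COVARIATES
        return cls(outcome, preds, family)


@dataclass
class LogisticFit:
    spec: ModelSpec
    predictors: tuple[str, ...]        # expanded design columns (after dummies)
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    odds_ratios: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    p_values: dict[str, float]
    auc: float
    auc_p: float
    vif: dict[str, float]
    n_used: int
    converged: bool
    vif_flag: bool = field(init=False)

    def __post_init__(self) -> None:
        self.vif_flag = any(v > VIF_FLAG_THRESHOLD for v in self.vif.values())


class SeparationError(RuntimeError):
    """Perfect separation: the logistic MLE does not exist."""


def _expand_design(df: pd.DataFrame, predictors: Sequence[str]) -> pd.DataFrame:
    """Numeric design matrix; categorical columns become indicator contrasts."""
    blocks = []
    for name in predictors:
        col = df[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
            blocks.append(dummies)
        else:
            blocks.append(col.astype(float).to_frame(name))
    return pd.concat(blocks, axis=1)


def _complete_cases(df: pd.DataFrame, outcome: str, predictors: Sequence[str]) -> pd.DataFrame:
    return df[[outcome, *predictors]].dropna()


def fit_logistic(data: pd.DataFrame, spec: ModelSpec) -> LogisticFit:
    """Maximum-likelihood logistic fit with intercept on complete cases.

    Reports OR = exp(β) per unit increment, Wald 95% CI = exp(β ± 1.96·SE)
    and Wald p per predictor, plus ROC AUC of the fitted probabilities and
    per-predictor VIFs.  Perfect separation is reported as non-converged
    (``converged=False``), never as a silent estimate.
    """
    if spec.family != "logistic":
        raise ValueError("fit_logistic requires a logistic ModelSpec")
    rows = _complete_cases(data, spec.outcome, spec.predictors)
    y = rows[spec.outcome].astype(float)
    classes = set(y.unique())
    if not classes <= {0.0, 1.0}:
        raise ValueError(f"outcome {spec.outcome!r} must be dichotomous 0/1, saw {sorted(classes)}")
    if len(classes) < 2:
        raise ValueError(f"outcome {spec.outcome!r} has a single class; model not estimable")
    X = _expand_design(rows, spec.predictors)
    Xc = sm.add_constant(X, has_constant="add")

    converged = True
    with np.errstate(all="ignore"):
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", False))
        except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as exc:
            logger.warning("logistic fit failed (%s); refitting with regularization off-path", exc)
            raise SeparationError(str(exc)) from exc
    # huge Wald SEs are the practical signature of quasi-separation
    if converged and np.any(np.asarray(res.bse) > 1e4):
        converged = False

    names = list(X.columns)
    params = res.params
    bse = res.bse
    coeffs = {n: float(params[n]) for n in names}
    ses = {n: float(bse[n]) for n in names}
    ors = {n: float(np.exp(params[n])) for n in names}
    ci = {n: (float(np.exp(params[n] - _Z975 * bse[n])), float(np.exp(params[n] + _Z975 * bse[n]))) for n in names}
    pvals = {n: float(res.pvalues[n]) for n in names}

    scores = np.asarray(res.predict(Xc))
    auc, auc_p = roc_auc(scores, y.to_numpy())
    vifs = vif(X) if X.shape[1] >= 2 else {names[0]: 1.0}
    return LogisticFit(
        spec=spec,
        predictors=tuple(names),
        coefficients=coeffs,
        standard_errors=ses,
        odds_ratios=ors,
        ci95=ci,
        p_values=pvals,
        auc=auc,
        auc_p=auc_p,
        vif=vifs,
        n_used=int(len(rows)),
        converged=converged,
    )


def roc_auc(scores, labels, method: Literal["mannwhitney", "delong"] = "mannwhitney") -> tuple[float, float]:
    """ROC AUC as the Mann–Whitney concordance probability (ties half).

    The p-value tests AUC = 0.5; by default the normal approximation to the
    Mann–Whitney U statistic (tie-corrected), with a DeLong-variance
    alternative behind the ``method`` flag.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    n1, n0 = len(pos), len(neg)
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    auc = float(u / (n1 * n0))
    if method == "mannwhitney":
        p = float(stats.mannwhitneyu(pos, neg, alternative="two-sided", method="asymptotic").pvalue)
    elif method == "delong":
        p = _delong_p(pos, neg, auc)
    else:
        raise ValueError(f"unknown method {method!r}")
    return auc, p


def _delong_p(pos: np.ndarray, neg: np.ndarray, auc: float) -> float:
    """DeLong variance of a single AUC; normal test of AUC = 0.5."""
    # placement values: per-case fraction of controls ranked below (ties half)
    v10 = np.array([(np.sum(x > neg) + 0.5 * np.sum(x == neg)) / len(neg) for x in pos])
    v01 = np.array([(np.sum(pos > x) + 0.5 * np.sum(pos == x)) / len(pos) for x in neg])
    var = np.var(v10, ddof=1) / len(pos) + np.var(v01, ddof=1) / len(neg)
    if var <= 0:
        return 1.0 if np.isclose(auc, 0.5) else 0.0
    z = (auc - 0.5) / np.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


def vif(design: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factors: VIF_j = 1/(1 − R²_j) from regressing
    column j on the remaining columns plus an intercept.

    Exact collinearity yields ``inf`` for the involved columns.
    """
    X = design.astype(float)
    if X.shape[1] < 2:
        raise ValueError("VIF requires at least 2 predictors")
    if (X.std(ddof=0) == 0).any():
        zero = list(X.columns[X.std(ddof=0) == 0])
        raise ValueError(f"zero-variance predictor(s): {zero}")
    out: dict[str, float] = {}
    arr = X.to_numpy()
    n = arr.shape[0]
    for j, name in enumerate(X.columns):
        yj = arr[:, j]
        others = np.column_stack([np.ones(n), np.delete(arr, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        out[name] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def fit_linear_composite(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """OLS of a continuous composite on the predictors, with intercept.

    Returns a frame indexed by predictor with beta, se, ci_low, ci_high, p
    (Wald 95% intervals), plus the intercept row.
    """
    if spec.family != "linear":
        raise ValueError("fit_linear_composite requires a linear ModelSpec")
    rows = _complete_cases(data, spec.outcome, spec.predictors)
    y = rows[spec.outcome].astype(float)
    X = _expand_design(rows, spec.predictors)
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        raise ValueError(
            f"rank-deficient design: rank {rank} < {Xc.shape[1]} columns {list(Xc.columns)}"
        )
    res = sm.OLS(y, Xc).fit()
    table = pd.DataFrame(
        {
            "beta": res.params,
            "se": res.bse,
            "ci_low": res.params - _Z975 * res.bse,
            "ci_high": res.params + _Z975 * res.bse,
            "p": res.pvalues,
        }
    )
    table.attrs["n_used"] = int(len(rows))
    return table


def standardize_composite(
    cohort: pd.DataFrame, reference: pd.DataFrame
) -> pd.Series:
    """Composite z per subject against a reference population.

    Each oriented parameter is z-scored against the reference mean/SD and
    the available z's are averaged; all-missing rows get NaN.
    """
    ref = reference[cohort.columns]
    mu = ref.mean()
    sd = ref.std(ddof=1)
    zero = sd[sd <= 0]
    if len(zero):
        raise ValueError(f"zero-variance reference parameter(s): {list(zero.index)}")
    z = (cohort - mu) / sd
    return z.mean(axis=1, skipna=True)


def logistic_results_table(fits: dict[str, LogisticFit]) -> pd.DataFrame:
    """Long-format results table (one row per model × predictor)."""
    rows = []
    for model_id, fit in fits.items():
        for name in fit.predictors:
            lo, hi = fit.ci95[name]
            rows.append(
                {
                    "model": model_id,
                    "predictor": name,
                    "beta": fit.coefficients[name],
                    "se": fit.standard_errors[name],
                    "or": fit.odds_ratios[name],
                    "ci_low": lo,
                    "ci_high": hi,
                    "p": fit.p_values[name],
                    "auc": fit.auc,
                    "auc_p": fit.auc_p,
                    "vif": fit.vif.get(name, np.nan),
                    "n_used": fit.n_used,
                    "converged": fit.converged,
                }
            )
    return pd.DataFrame(rows)
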