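"""Repeated-measures condition comparison.

Fits a linear mixed-effects model per outcome (gait condition as a fixed
effect, participant random intercept, REML) — on balanced one-observation-
per-cell data this random-intercept structure is exactly the compound-
symmetric covariance of a classical repeated-measures analysis.  All six
pairwise condition contrasts are tested with Wald tests on the fixed
effects, and paired Cohen's d (mean difference over the SD of the paired
differences) is reported as the effect size.  No multiple-testing
correction is applied by default; Holm adjustment is available.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CONDITIONS

__all__ = ["ConditionComparison", "cohens_d", "fit_condition_model"]

ALPHA = 0.05


@dataclass(frozen=True)
class ConditionComparison:
    """One pairwise condition contrast for one outcome."""

    outcome: str
    condition_a: str
    condition_b: str
    mean_difference: float  # a - b
    p_value: float
    cohens_d: float
    significant: bool
    method: str = "mixed_model"  # or "paired_t" fallback

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        star = "*" if self.significant else " "
        return (
            f"{self.outcome}: {self.condition_a} vs {self.condition_b} "
            f"diff={self.mean_difference:+.3g} p={self.p_value:.3g}{star} "
            f"d={self.cohens_d:.2f}"
        )


def cohens_d(a, b) -> float:
    """Paired Cohen's d: mean(a - b) / SD(a - b).

    The within-subject denominator is used because the outcomes are
    repeated measures on the same participants.  Zero-variance differences
    with a nonzero mean return signed infinity; identical samples return 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-D paired samples")
    diff = a - b
    sd = float(np.std(diff, ddof=1)) if diff.size > 1 else 0.0
    mean = float(np.mean(diff))
    if sd == 0.0:
        if mean == 0.0:
            return 0.0
        return math_inf_signed(mean)
    return mean / sd


def math_inf_signed(x: float) -> float:
    return float(np.inf) if x > 0 else float(-np.inf)


def _pairwise_from_fit(result, conditions, outcome, pivot, alpha):
    """Wald tests for all pairwise contrasts of the condition effect."""
    comparisons = []
    params = result.params
    names = list(result.model.exog_names)
    k = len(names)
    cov = np.asarray(result.cov_params())[:k, :k]
    beta = np.asarray(params)[:k]

    def coef_vector(cond):
        v = np.zeros(k)
        for j, name in enumerate(names):
            if name == "Intercept":
                v[j] = 1.0
            elif name.endswith(f"[T.{cond}]"):
                v[j] = 1.0
        return v

    for a, b in itertools.combinations(conditions, 2):
        c = coef_vector(a) - coef_vector(b)
        est = float(c @ beta)
        se = float(np.sqrt(c @ cov @ c))
        if se == 0.0:
            p = 1.0
        else:
            from scipy import stats as sps

            p = 2.0 * sps.norm.sf(abs(est / se))
        comparisons.append(
            ConditionComparison(
                outcome=outcome,
                condition_a=a,
                condition_b=b,
                mean_difference=est,
                p_value=float(p),
                cohens_d=cohens_d(pivot[a], pivot[b]),
                significant=bool(p <= alpha),
                method="mixed_model",
            )
        )
    return comparisons


def _paired_t_fallback(conditions, outcome, pivot, alpha):
    from scipy import stats as sps

    comparisons = []
    for a, b in itertools.combinations(conditions, 2):
        diff = pivot[a].to_numpy() - pivot[b].to_numpy()
        if np.allclose(np.std(diff, ddof=1) if diff.size > 1 else 0.0, 0.0):
            p = 1.0 if np.allclose(diff.mean(), 0.0) else 0.0
        else:
            p = float(sps.ttest_rel(pivot[a], pivot[b]).pvalue)
        comparisons.append(
            ConditionComparison(
                outcome=outcome,
                condition_a=a,
                condition_b=b,
                mean_difference=float(diff.mean()),
                p_value=p,
                cohens_d=cohens_d(pivot[a], pivot[b]),
                significant=bool(p <= alpha),
                method="paired_t",
            )
        )
    return comparisons


def fit_condition_model(
    data: pd.DataFrame,
    outcome: str,
    participant_col: str = "participant_id",
    condition_col: str = "condition",
    alpha: float = ALPHA,
    holm: bool = False,
) -> list[ConditionComparison]:
    """Mixed-model comparison of an outcome across gait conditions.

    ``data`` holds one row per participant x condition (aggregate trials
    first; see the pipeline).  Degenerate data (zero between- and
    within-participant variance) and singular fits fall back to paired
    t-tests with a warning.
    """
    needed = {participant_col, condition_col, outcome}
    if not needed.issubset(data.columns):
        raise ValueError(f"data must contain columns {sorted(needed)}")
    df = data[[participant_col, condition_col, outcome]].dropna()
    conditions = [c for c in CONDITIONS if c in set(df[condition_col])]
    if len(conditions) < 2:
        conditions = sorted(set(df[condition_col]))
    if df[participant_col].nunique() < 2 or len(conditions) < 2:
        raise ValueError("need at least 2 participants and 2 conditions")

    pivot = df.pivot_table(
        index=participant_col, columns=condition_col, values=outcome
    )[conditions]

    if np.allclose(df[outcome].var(ddof=0), 0.0):
        comparisons = _paired_t_fallback(conditions, outcome, pivot, alpha)
        comparisons = [
            ConditionComparison(
                **{**c.__dict__, "p_value": 1.0, "significant": False}
            )
            for c in comparisons
        ]
        return comparisons

    import statsmodels.formula.api as smf

    tmp = df.rename(
        columns={outcome: "_y", participant_col: "_pid", condition_col: "_cond"}
    ).copy()
    tmp["_cond"] = pd.Categorical(tmp["_cond"], categories=conditions)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.mixedlm("_y ~ C(_cond)", tmp, groups=tmp["_pid"]).fit(
                reml=True
            )
        if not np.all(np.isfinite(np.asarray(fit.cov_params()))):
            raise ValueError("singular covariance")
        comparisons = _pairwise_from_fit(fit, conditions, outcome, pivot, alpha)
    except Exception as err:  # singular fit / convergence failure
        warnings.warn(
            f"mixed model failed for outcome {outcome!r} ({err}); "
            "falling back to paired t-tests",
            RuntimeWarning,
            stacklevel=2,
        )
        comparisons = _paired_t_fallback(conditions, outcome, pivot, alpha)

    if holm:
        comparisons = _holm_adjust(comparisons, alpha)
    return comparisons


def _holm_adjust(comparisons, alpha):
    from statsmodels.stats.multitest import multipletests

    pvals = [c.p_value for c in comparisons]
    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="holm")
    return [
        ConditionComparison(
            **{
                **c.__dict__,
                "p_value": float(p),
                "significant": bool(r),
            }
        )
        for c, p, r in zip(comparisons, p_adj, reject)
    ]
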