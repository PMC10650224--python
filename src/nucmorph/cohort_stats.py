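"""Group-level summaries, between-group tests and panel performance.

Patients are grouped by bone-metastasis status.  Each of the nine
patient-level parameters is summarized per group (mean, standard
deviation, median, quartiles, range), compared between groups with a
univariate regression of status on the parameter (logistic by default,
Wald p on the slope; Welch's t as an alternative), and the cut-off panel's
per-criterion prevalence plus the sensitivity/specificity of the
``n_cr ≥ 6`` high-risk rule are reported.
"""

from __future__ import annotations

import warnings
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from pydantic import BaseModel, ConfigDict, Field
from scipy import stats as sps

from .model import Finding, MetastasisStatus
from .morphometry import PARAMETER_NAMES
from .scoring import CRITERION_NAMES, CriteriaResult

__all__ = [
    "GroupSummary",
    "GroupTestResult",
    "PanelPerformance",
    "group_summary",
    "parameter_pvalue",
    "pvalue_from_groups",
    "panel_performance",
    "adjust_pvalues",
    "summary_table",
]

TestMethod = Literal["logistic_wald", "welch_t"]

_GROUPS = (MetastasisStatus.bone_metastasis, MetastasisStatus.no_bone_metastasis)


class GroupSummary(BaseModel):
    """Distributional summary of one parameter in one outcome group."""

    model_config = ConfigDict(frozen=True)

    parameter: str
    group: MetastasisStatus
    n: int = Field(ge=0)
    mean: Optional[float] = None
    sd: Optional[float] = None  # withheld for n < 2
    median: Optional[float] = None
    q1: Optional[float] = None
    q3: Optional[float] = None
    minimum: Optional[float] = None
    maximum: Optional[float] = None


class GroupTestResult(BaseModel):
    """Between-group test of one parameter; ``p_value`` may be omitted."""

    model_config = ConfigDict(frozen=True)

    parameter: str
    method: TestMethod
    p_value: Optional[float] = None
    n_metastasis: int = 0
    n_control: int = 0
    findings: tuple[Finding, ...] = ()


class PanelPerformance(BaseModel):
    """Per-criterion prevalence per group and high-risk rule performance."""

    model_config = ConfigDict(frozen=True)

    criterion_fractions: dict[str, dict[str, Optional[float]]]
    sensitivity: Optional[float] = None  # P(n_cr ≥ 6 | bone metastasis)
    specificity: Optional[float] = None  # P(n_cr ≤ 5 | no bone metastasis)
    n_metastasis: int = 0
    n_control: int = 0


def _parameter_values(
    results: Sequence[CriteriaResult], parameter: str, group: MetastasisStatus
) -> np.ndarray:
    if parameter not in PARAMETER_NAMES:
        raise KeyError(f"unknown parameter {parameter!r}")
    values = [
        r.morphometrics.parameter(parameter)
        for r in results
        if r.metastasis_status is group and r.morphometrics is not None
    ]
    return np.asarray([v for v in values if v is not None], dtype=float)


def group_summary(results: Sequence[CriteriaResult]) -> list[GroupSummary]:
    """Summarize the nine parameters per metastasis-status group."""
    summaries = []
    for parameter in PARAMETER_NAMES:
        for group in _GROUPS:
            x = _parameter_values(results, parameter, group)
            if x.size == 0:
                summaries.append(
                    GroupSummary(parameter=parameter, group=group, n=0)
                )
                continue
            q1, med, q3 = np.percentile(x, [25, 50, 75])
            summaries.append(
                GroupSummary(
                    parameter=parameter,
                    group=group,
                    n=int(x.size),
                    mean=float(np.mean(x)),
                    sd=float(np.std(x, ddof=1)) if x.size >= 2 else None,
                    median=float(med),
                    q1=float(q1),
                    q3=float(q3),
                    minimum=float(np.min(x)),
                    maximum=float(np.max(x)),
                )
            )
    return summaries


def parameter_pvalue(
    results: Sequence[CriteriaResult],
    parameter: str,
    method: TestMethod = "logistic_wald",
) -> GroupTestResult:
    """Univariate between-group test of one parameter.

    ``logistic_wald`` regresses metastasis status on the (internally
    standardized) parameter and reports the Wald p of the slope;
    ``welch_t`` is the unequal-variance two-sample t test.  Degenerate
    variance and complete separation are flagged and leave the p-value
    unset.
    """
    x_meta = _parameter_values(results, parameter, MetastasisStatus.bone_metastasis)
    x_ctrl = _parameter_values(results, parameter, MetastasisStatus.no_bone_metastasis)
    return pvalue_from_groups(x_meta, x_ctrl, method=method, parameter=parameter)


def pvalue_from_groups(
    x_meta: np.ndarray,
    x_ctrl: np.ndarray,
    method: TestMethod = "logistic_wald",
    parameter: str = "",
) -> GroupTestResult:
    """The between-group test on raw per-group value arrays."""
    x_meta = np.asarray(x_meta, dtype=float)
    x_ctrl = np.asarray(x_ctrl, dtype=float)
    base = dict(
        parameter=parameter,
        method=method,
        n_metastasis=int(x_meta.size),
        n_control=int(x_ctrl.size),
    )
    if x_meta.size < 2 or x_ctrl.size < 2:
        return GroupTestResult(
            **base,
            findings=(
                Finding(
                    level="error",
                    code="insufficient_group_size",
                    message="both groups need at least two patients",
                    subject=parameter,
                ),
            ),
        )
    x = np.concatenate([x_meta, x_ctrl])
    if np.std(x) == 0.0:
        return GroupTestResult(
            **base,
            findings=(
                Finding(
                    level="error",
                    code="degenerate_variance",
                    message="parameter has zero variance across the cohort",
                    subject=parameter,
                ),
            ),
        )
    y = np.concatenate([np.ones(x_meta.size), np.zeros(x_ctrl.size)])

    if method == "welch_t":
        res = sps.ttest_ind(x_meta, x_ctrl, equal_var=False)
        return GroupTestResult(**base, p_value=float(res.pvalue))

    # standardize the predictor: the Wald z of the slope is then exactly
    # invariant under affine rescaling of the parameter
    z = (x - np.mean(x)) / np.std(x)
    if x_meta.max() < x_ctrl.min() or x_ctrl.max() < x_meta.min():
        return GroupTestResult(
            **base,
            findings=(
                Finding(
                    level="error",
                    code="complete_separation",
                    message="groups are completely separated on this parameter",
                    subject=parameter,
                ),
            ),
        )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, sm.add_constant(z)).fit(disp=0, maxiter=200)
        p = float(fit.pvalues[1])
        if not np.isfinite(p):
            raise ValueError("non-finite Wald p-value")
    except Exception as exc:  # statsmodels raises several exception types here
        return GroupTestResult(
            **base,
            findings=(
                Finding(
                    level="error",
                    code="logistic_fit_failed",
                    message=str(exc),
                    subject=parameter,
                ),
            ),
        )
    return GroupTestResult(**base, p_value=min(max(p, np.nextafter(0, 1)), 1.0))


def adjust_pvalues(
    tests: Sequence[GroupTestResult], method: Literal["bonferroni", "fdr_bh"]
) -> dict[str, float]:
    """Optional multiple-testing adjustment across parameters."""
    usable = [t for t in tests if t.p_value is not None]
    if not usable:
        return {}
    raw = np.array([t.p_value for t in usable])
    adjusted = sm.stats.multipletests(raw, method=method)[1]
    return {t.parameter: float(p) for t, p in zip(usable, adjusted)}


def panel_performance(results: Sequence[CriteriaResult]) -> PanelPerformance:
    """Per-criterion prevalence per group and n_cr ≥ 6 rule performance."""
    meta = [r for r in results if r.metastasis_status is MetastasisStatus.bone_metastasis]
    ctrl = [
        r for r in results if r.metastasis_status is MetastasisStatus.no_bone_metastasis
    ]

    def fraction(group: list[CriteriaResult], pred) -> Optional[float]:
        if not group:
            return None
        return sum(1 for r in group if pred(r)) / len(group)

    fractions = {
        name: {
            "bone_metastasis": fraction(meta, lambda r, n=name: r.flags[n]),
            "no_bone_metastasis": fraction(ctrl, lambda r, n=name: r.flags[n]),
        }
        for name in CRITERION_NAMES
    }
    return PanelPerformance(
        criterion_fractions=fractions,
        sensitivity=fraction(meta, lambda r: r.n_cr >= 6),
        specificity=fraction(ctrl, lambda r: r.n_cr <= 5),
        n_metastasis=len(meta),
        n_control=len(ctrl),
    )


def summary_table(
    results: Sequence[CriteriaResult], method: TestMethod = "logistic_wald"
) -> pd.DataFrame:
    """One row per parameter: group summaries side by side plus the p-value."""
    summaries = {(s.parameter, s.group): s for s in group_summary(results)}
    rows = []
    for parameter in PARAMETER_NAMES:
        row: dict = {"parameter": parameter}
        for group, tag in (
            (MetastasisStatus.bone_metastasis, "metastasis"),
            (MetastasisStatus.no_bone_metastasis, "control"),
        ):
            s = summaries[(parameter, group)]
            row[f"{tag}_n"] = s.n
            row[f"{tag}_mean"] = s.mean
            row[f"{tag}_sd"] = s.sd
            row[f"{tag}_median"] = s.median
            row[f"{tag}_q1"] = s.q1
            row[f"{tag}_q3"] = s.q3
        row["p_value"] = parameter_pvalue(results, parameter, method).p_value
        rows.append(row)
    return pd.DataFrame(rows)
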