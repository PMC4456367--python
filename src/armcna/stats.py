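"""Exact contingency testing and survival analysis.

Fisher's exact test uses the two-sided point-probability rule: the p-value
sums the hypergeometric probabilities of every table with the observed
margins that is no more likely than the observed one.  Survival analysis is
Kaplan–Meier estimation with the log-rank test for group comparisons and a
Cox proportional-hazards model (Efron tie handling) for multivariate
adjustment; times are in months.  No multiple-testing correction is applied
— each test is reported marginally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps

__all__ = [
    "TestResult",
    "fisher_exact_two_sided",
    "km_logrank",
    "cox_multivariate",
]


@dataclass
class TestResult:
    """Outcome of one statistical test, with its inputs echoed."""

    method: str
    statistic: float | None
    p_value: float | None
    estimate: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    inputs: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.p_value is not None and not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise ValueError("p-value outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "estimate": self.estimate,
            "ci_95": [self.ci_low, self.ci_high],
            "inputs": self.inputs,
            "flags": self.flags,
        }


def fisher_exact_two_sided(table) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 table (point-probability rule).

    Cells must be non-negative integers.  An empty margin carries no
    information: p = 1 with a warning flag.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("Fisher test requires a 2x2 table")
    if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise ValueError("table cells must be non-negative integers")
    arr = arr.astype(int)
    inputs = {"table": arr.tolist()}
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        warnings.warn("empty margin in contingency table; p set to 1", stacklevel=2)
        return TestResult("fisher_exact_two_sided", None, 1.0,
                          inputs=inputs, flags=["empty-margin"])
    odds, p = sps.fisher_exact(arr, alternative="two-sided")
    return TestResult("fisher_exact_two_sided", float(odds), float(min(p, 1.0)),
                      estimate=float(odds), inputs=inputs)


def km_logrank(records: pd.DataFrame, group_col: str = "group",
               time_col: str = "pfs_months", event_col: str = "pfs_event"):
    """Kaplan–Meier curves per group and the k-sample log-rank test.

    Returns ``(curves, result)``: *curves* is a long DataFrame (group, time,
    survival, at_risk) of the product-limit estimates evaluated at each
    group's observed times; *result* a :class:`TestResult` with the log-rank
    chi-square (k-1 df) and p-value.
    """
    groups = records[group_col]
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("log-rank comparison needs >= 2 groups")
    if records[event_col].sum() < 1:
        raise ValueError("no events observed in any group")
    if (records[time_col] < 0).any():
        raise ValueError("negative survival time")
    frames = []
    for lev in levels:
        sub = records[groups == lev]
        km = KaplanMeierFitter()
        km.fit(sub[time_col], sub[event_col], label=str(lev))
        tab = km.event_table
        frames.append(pd.DataFrame({
            "group": lev,
            "time": tab.index.to_numpy(),
            "survival": km.survival_function_.iloc[:, 0].to_numpy(),
            "at_risk": tab["at_risk"].to_numpy(),
        }))
    curves = pd.concat(frames, ignore_index=True)
    lr = multivariate_logrank_test(records[time_col], groups, records[event_col])
    result = TestResult(
        "logrank", float(lr.test_statistic), float(lr.p_value),
        inputs={"groups": {str(l): int((groups == l).sum()) for l in levels},
                "df": len(levels) - 1},
    )
    return curves, result


def cox_multivariate(records: pd.DataFrame, covariates: list[str],
                     time_col: str = "pfs_months", event_col: str = "pfs_event",
                     ) -> dict[str, TestResult]:
    """Cox proportional-hazards fit; one TestResult per covariate.

    Partial-likelihood maximization with Efron tie handling; hazard ratios
    with Wald 95% CIs.  Constant covariates are rejected; monotone
    likelihood (complete separation) is flagged with estimates suppressed.
    """
    n_events = int(records[event_col].sum())
    if n_events < len(covariates) + 1:
        raise ValueError("too few events for the requested covariates")
    for cov in covariates:
        if records[cov].nunique() < 2:
            raise ValueError(f"covariate {cov!r} is constant (no information)")
    df = records[[time_col, event_col, *covariates]].astype(float)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col=time_col, event_col=event_col)
    except ConvergenceError:
        return {cov: TestResult("cox_ph", None, None,
                                flags=["monotone-likelihood"],
                                inputs={"covariate": cov, "n_events": n_events})
                for cov in covariates}
    out = {}
    summary = cph.summary
    for cov in covariates:
        row = summary.loc[cov]
        flags = []
        if abs(row["coef"]) > 10:  # HR beyond e^10: effectively separated
            flags.append("monotone-likelihood")
        out[cov] = TestResult(
            "cox_ph",
            float(row["z"]),
            float(row["p"]),
            estimate=None if flags else float(np.exp(row["coef"])),
            ci_low=None if flags else float(np.exp(row["coef lower 95%"])),
            ci_high=None if flags else float(np.exp(row["coef upper 95%"])),
            inputs={"covariate": cov, "n": len(df), "n_events": n_events},
            flags=flags,
        )
    return out
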