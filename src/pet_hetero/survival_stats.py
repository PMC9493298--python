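"""The study's inferential pipeline for disease-free survival.

Normality-routed two-group comparisons (chi-square / Student's t /
Wilcoxon rank-sum after Shapiro-Wilk), Kaplan-Meier estimation, the
log-rank test, univariate and multivariate Cox proportional-hazards
regression (Efron tie handling, via lifelines), and ROC-based optimal
cutoff selection by the Youden index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from .errors import (
    ConvergenceFailureError,
    DegenerateTableError,
    EmptyInputError,
    NoEventsError,
    OneClassError,
)

SHAPIRO_ALPHA = 0.05


@dataclass(frozen=True)
class KmCurve:
    """Product-limit survival curve evaluated at the event times."""

    event_times: tuple[float, ...]
    at_risk: tuple[int, ...]
    events: tuple[int, ...]
    survival: tuple[float, ...]


@dataclass(frozen=True)
class LogRankResult:
    chi2: float
    df: int
    p: float


@dataclass(frozen=True)
class CoxCovariate:
    name: str
    coef: float
    hr: float
    ci95: tuple[float, float]
    p: float
    se: float


@dataclass(frozen=True)
class CoxResult:
    covariates: tuple[CoxCovariate, ...]
    log_likelihood: float
    n: int
    n_events: int
    converged: bool

    def __getitem__(self, name: str) -> CoxCovariate:
        for cov in self.covariates:
            if cov.name == name:
                return cov
        raise KeyError(name)


@dataclass(frozen=True)
class CutoffResult:
    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float
    auc: float


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    test_used: str  # chi_square | t_test | rank_sum
    statistic: float
    p: float
    normality_p: float | None = None


def km_estimate(times, events) -> KmCurve:
    """Kaplan-Meier product-limit estimator; censoring shrinks risk sets
    without producing steps."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise EmptyInputError("no observations")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    rows = table[table["observed"] > 0]
    surv = kmf.survival_function_["KM_estimate"]
    return KmCurve(
        event_times=tuple(float(t) for t in rows.index),
        at_risk=tuple(int(v) for v in rows["at_risk"]),
        events=tuple(int(v) for v in rows["observed"]),
        survival=tuple(float(surv.loc[t]) for t in rows.index),
    )


def logrank_test(group_a, group_b) -> LogRankResult:
    """Mantel-Haenszel two-group log-rank test (chi-square, 1 df)."""
    ta, ea = (np.asarray(v) for v in group_a)
    tb, eb = (np.asarray(v) for v in group_b)
    if ea.sum() + eb.sum() == 0:
        raise NoEventsError("log-rank undefined with zero events in both groups")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return LogRankResult(chi2=float(res.test_statistic), df=1, p=float(res.p_value))


def cox_fit(
    table: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "dfs_months",
    event_col: str = "event",
) -> CoxResult:
    """Cox proportional-hazards fit with Efron handling of tied event times.

    Wald 95% confidence intervals and p-values per coefficient. Monotone
    likelihood / separation raises ConvergenceFailureError rather than
    returning a silently diverged fit.
    """
    if table[event_col].sum() == 0:
        raise NoEventsError("Cox model requires at least one event")
    for name in covariates:
        if table[name].nunique() < 2:
            raise ConvergenceFailureError(
                f"covariate {name!r} is constant: no information in the partial likelihood"
            )
    cph = CoxPHFitter()
    data = table[covariates + [duration_col, event_col]]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(data, duration_col=duration_col, event_col=event_col)
    except ConvergenceError as err:
        raise ConvergenceFailureError(str(err)) from err
    summary = cph.summary
    covs = tuple(
        CoxCovariate(
            name=name,
            coef=float(summary.loc[name, "coef"]),
            hr=float(summary.loc[name, "exp(coef)"]),
            ci95=(
                float(summary.loc[name, "exp(coef) lower 95%"]),
                float(summary.loc[name, "exp(coef) upper 95%"]),
            ),
            p=float(summary.loc[name, "p"]),
            se=float(summary.loc[name, "se(coef)"]),
        )
        for name in covariates
    )
    return CoxResult(
        covariates=covs,
        log_likelihood=float(cph.log_likelihood_),
        n=int(len(data)),
        n_events=int(data[event_col].sum()),
        converged=True,
    )


def optimal_cutoff_roc(marker, outcome) -> CutoffResult:
    """ROC-based optimal cutoff: the midpoint between adjacent distinct
    marker values that maximizes the Youden index J = sens + spec - 1.

    Higher marker values are treated as predicting the event. Ties in J are
    broken toward the smaller cutoff; AUC is the trapezoidal area, equal to
    the normalized Mann-Whitney U statistic.
    """
    marker = np.asarray(marker, dtype=float)
    outcome = np.asarray(outcome, dtype=int)
    pos = marker[outcome == 1]
    neg = marker[outcome == 0]
    if pos.size == 0 or neg.size == 0:
        raise OneClassError("both outcome classes must be present")
    distinct = np.unique(marker)
    if distinct.size < 2:
        raise OneClassError("marker is constant; no cutoff exists")
    cutoffs = (distinct[:-1] + distinct[1:]) / 2.0
    best = None
    for c in cutoffs:
        sens = float(np.mean(pos >= c))
        spec = float(np.mean(neg < c))
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, c, sens, spec)
    j, c, sens, spec = best
    auc = float(roc_auc_score(outcome, marker))
    return CutoffResult(
        cutoff=float(c), sensitivity=sens, specificity=spec, youden_j=j, auc=auc
    )


def _is_binary(values: pd.Series) -> bool:
    uniq = pd.unique(values.dropna())
    return len(uniq) <= 2 and set(np.asarray(uniq, dtype=float)) <= {0.0, 1.0}


def compare_groups(
    table: pd.DataFrame,
    variables: list[str],
    group_flag: str,
    categorical: set[str] | None = None,
) -> list[GroupComparison]:
    """Two-group comparison battery with Shapiro-Wilk routing.

    Categorical variables get a chi-square test on the contingency table;
    continuous ones get Student's t-test when both groups pass Shapiro-Wilk
    at alpha 0.05, and the Wilcoxon rank-sum test otherwise.
    """
    categorical = categorical or set()
    groups = table[group_flag]
    if groups.nunique() != 2:
        raise DegenerateTableError("group flag must define exactly two groups")
    g0, g1 = sorted(pd.unique(groups))
    results = []
    for name in variables:
        col = table[name]
        if name in categorical or _is_binary(col):
            contingency = pd.crosstab(col, groups)
            if (contingency.sum(axis=0) == 0).any() or (contingency.sum(axis=1) == 0).any():
                raise DegenerateTableError(f"empty row/column for {name!r}")
            chi2, p, _, _ = sps.chi2_contingency(contingency.to_numpy(), correction=False)
            results.append(
                GroupComparison(variable=name, test_used="chi_square",
                                statistic=float(chi2), p=float(p))
            )
            continue
        a = col[groups == g0].dropna().to_numpy(dtype=float)
        b = col[groups == g1].dropna().to_numpy(dtype=float)
        sw_a = sps.shapiro(a).pvalue if len(a) >= 3 else 0.0
        sw_b = sps.shapiro(b).pvalue if len(b) >= 3 else 0.0
        normality_p = float(min(sw_a, sw_b))
        if normality_p > SHAPIRO_ALPHA:
            stat, p = sps.ttest_ind(a, b)
            test = "t_test"
        else:
            stat, p = sps.ranksums(a, b)
            test = "rank_sum"
        results.append(
            GroupComparison(variable=name, test_used=test, statistic=float(stat),
                            p=float(p), normality_p=normality_p)
        )
    return results
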