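"""Treatment-effect and chat-topic statistics for the group-round panel.

The pipeline has four stages:

* pairwise treatment regressions — for each pair of arms, the group-round
  outcome is regressed on a treatment indicator plus a linear round
  covariate (groups learn over time), with heteroskedasticity-robust
  standard errors clustered on group.  On a balanced panel the indicator
  is orthogonal to round, so the treatment coefficient equals the raw
  difference in arm means — a useful closed-form check.  The indicator
  marks the FIRST arm of the pair, so the coefficient is the first arm's
  performance relative to the second.
* multiplicity handling — a Bonferroni threshold (family alpha over the
  six pairs) and Benjamini–Hochberg step-up adjustment at a configurable
  false discovery rate (0.25 by default here).
* topic–performance models — for each chat sub-category, outcome on the
  per-round topic count, round indicators (round 1 base) and total
  messages per round, with a group random intercept (REML).
* Welch's unequal-variance t-tests on per-game topic totals between the
  two communication arms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RegressionResult",
    "TestResult",
    "CollinearityError",
    "pairwise_treatment_model",
    "bonferroni_threshold",
    "bh_adjust",
    "topic_performance_model",
    "welch_test",
    "run_pairwise_battery",
    "run_topic_battery",
    "OUTCOMES",
    "ALL_PAIRS",
]

OUTCOMES = ("mean_coin_harvest", "optimal_difference")
ALL_PAIRS = (("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("B", "D"), ("C", "D"))


class CollinearityError(ValueError):
    """Raised when a model term is constant / perfectly collinear."""


@dataclass(frozen=True)
class RegressionResult:
    outcome: str
    term: str
    coefficient: float
    std_error: float
    p_value: float
    n_obs: int
    n_groups: int
    r_squared: float
    covariates: str
    clustering: str
    extra: dict = field(default_factory=dict)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    mean_x: float
    mean_y: float
    n_x: int
    n_y: int


def pairwise_treatment_model(
    panel: pd.DataFrame,
    pair: tuple[str, str],
    outcome: str = "mean_coin_harvest",
) -> RegressionResult:
    """OLS of a group-round outcome on a treatment indicator + round,
    with group-clustered robust (HC) standard errors.

    The indicator is 1 for rows of ``pair[0]``; the coefficient is
    therefore the first arm's mean outcome relative to the second, net of
    the linear round trend.
    """
    first, second = pair
    if outcome not in panel.columns:
        raise ValueError(f"outcome {outcome!r} not in panel")
    present = set(panel["treatment"].unique())
    for t in pair:
        if t not in present:
            raise ValueError(f"treatment {t!r} absent from panel")
    sub = panel[panel["treatment"].isin(pair)].copy()
    for t in pair:
        if sub.loc[sub["treatment"] == t, "group_id"].nunique() < 2:
            raise ValueError(
                f"treatment {t!r} has fewer than 2 groups; "
                "clustered errors need replication"
            )
    sub["treat"] = (sub["treatment"] == first).astype(float)
    X = sm.add_constant(sub[["treat", "round"]].astype(float))
    model = sm.OLS(sub[outcome].astype(float), X)
    fit = model.fit(cov_type="cluster", cov_kwds={"groups": sub["group_id"]})
    return RegressionResult(
        outcome=outcome,
        term=f"{first} versus {second}",
        coefficient=float(fit.params["treat"]),
        std_error=float(fit.bse["treat"]),
        p_value=float(fit.pvalues["treat"]),
        n_obs=int(fit.nobs),
        n_groups=int(sub["group_id"].nunique()),
        r_squared=float(fit.rsquared),
        covariates="treatment indicator + linear round",
        clustering="group-clustered HC robust",
    )


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold ``alpha / m``."""
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if m < 1:
        raise ValueError(f"number of models must be >= 1, got {m}")
    return alpha / m


def bh_adjust(
    pvalues: Sequence[float], q: float = 0.25
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up adjustment at false discovery rate ``q``.

    Returns (adjusted p-values, rejection flags) in the input order.  The
    adjusted values are the monotone step-up quantities
    ``min_k>=rank (m p_(k) / k)``; a hypothesis is rejected iff its
    adjusted value is at most ``q``.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not (0.0 < q < 1.0):
        raise ValueError(f"FDR level must lie in (0, 1), got {q}")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def topic_performance_model(
    panel: pd.DataFrame,
    topic: str,
    outcome: str = "mean_coin_harvest",
) -> RegressionResult:
    """Random-intercept panel model of outcome on a topic's message count.

    Covariates: the per-round count of ``topic``, round indicators with
    round 1 as base, and total messages per round.  The group-level
    random intercept is estimated by REML (feasible GLS).  A topic with
    no variation raises :class:`CollinearityError` so a batch caller can
    record the failure per topic and continue.
    """
    for col in (topic, outcome, "total_messages", "round", "group_id"):
        if col not in panel.columns:
            raise ValueError(f"panel lacks required column {col!r}")
    data = panel.copy()
    if data[topic].nunique() <= 1:
        raise CollinearityError(f"topic {topic!r} has a constant count column")
    data["round"] = data["round"].astype(int)
    formula = f"{outcome} ~ {topic} + total_messages + C(round)"
    model = smf.mixedlm(formula, data, groups=data["group_id"])
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise CollinearityError(
            f"design matrix for topic {topic!r} is rank deficient"
        )
    # lbfgs is fastest but its score step can hit a singular GLS weighting
    # when the random-intercept variance collapses; fall back to the
    # derivative-free powell path before declaring the topic degenerate.
    fit = None
    for method in ("lbfgs", "powell"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = model.fit(reml=True, method=method, maxiter=500)
            break
        except np.linalg.LinAlgError:
            continue
    if fit is None:
        raise CollinearityError(f"topic {topic!r}: singular random-effects fit")
    if not (np.isfinite(fit.params[topic]) and np.isfinite(fit.pvalues[topic])):
        raise CollinearityError(
            f"topic {topic!r}: unstable fit (non-finite estimate or p-value)"
        )
    resid = fit.resid
    r2 = 1.0 - np.var(resid) / np.var(data[outcome].astype(float))
    return RegressionResult(
        outcome=outcome,
        term=topic,
        coefficient=float(fit.params[topic]),
        std_error=float(fit.bse[topic]),
        p_value=float(fit.pvalues[topic]),
        n_obs=int(fit.nobs),
        n_groups=int(data["group_id"].nunique()),
        r_squared=float(r2),
        covariates="topic count + total messages + round indicators (round 1 base)",
        clustering="group random intercept (REML)",
        extra={
            "conf_int_low": float(fit.conf_int().loc[topic, 0]),
            "conf_int_high": float(fit.conf_int().loc[topic, 1]),
        },
    )


def welch_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Welch's unequal-variance t-test with Welch–Satterthwaite df."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            return TestResult(0.0, float(x.size + y.size - 2), 1.0,
                              float(x.mean()), float(y.mean()), x.size, y.size)
        raise ValueError("degenerate samples: zero variance with unequal means")
    if vx == 0.0 or vy == 0.0:
        raise ValueError("degenerate sample: one sample has zero variance")
    res = scipy.stats.ttest_ind(x, y, equal_var=False)
    return TestResult(
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        mean_x=float(x.mean()),
        mean_y=float(y.mean()),
        n_x=int(x.size),
        n_y=int(y.size),
    )


# ---------------------------------------------------------------------------
# batteries


def run_pairwise_battery(
    panel: pd.DataFrame,
    pairs: Iterable[tuple[str, str]] = ALL_PAIRS,
    outcomes: Iterable[str] = OUTCOMES,
    alpha: float = 0.05,
    fdr: float = 0.25,
) -> pd.DataFrame:
    """All pairwise treatment models; Bonferroni and BH flags per outcome.

    Multiplicity is handled within each outcome family (one family per
    outcome, six pairwise models each by default).
    """
    pairs = [p for p in pairs]
    rows = []
    for outcome in outcomes:
        results = [pairwise_treatment_model(panel, pair, outcome) for pair in pairs]
        pvals = [r.p_value for r in results]
        thr = bonferroni_threshold(alpha, len(results))
        p_adj, rej = bh_adjust(pvals, fdr)
        for r, pa, rj in zip(results, p_adj, rej):
            rows.append({
                "model": "pairwise", "outcome": outcome, "term": r.term,
                "estimate": r.coefficient, "se": r.std_error, "p": r.p_value,
                "p_adjusted": float(pa),
                "significant_bonferroni": r.p_value < thr,
                "rejected_bh": bool(rj),
                "n": r.n_obs, "groups": r.n_groups,
            })
    return pd.DataFrame(rows)


def run_topic_battery(
    panel: pd.DataFrame,
    topics: Iterable[str],
    outcomes: Iterable[str] = OUTCOMES,
    fdr: float = 0.25,
) -> pd.DataFrame:
    """One random-effects model per topic and outcome, BH-adjusted per
    outcome family; degenerate (constant-count) topics are reported with
    an error note instead of aborting the batch.
    """
    rows = []
    for outcome in outcomes:
        fitted: list[RegressionResult] = []
        failed: list[tuple[str, str]] = []
        for topic in topics:
            try:
                fitted.append(topic_performance_model(panel, topic, outcome))
            except CollinearityError as err:
                failed.append((topic, str(err)))
        p_adj, rej = bh_adjust([r.p_value for r in fitted], fdr)
        for r, pa, rj in zip(fitted, p_adj, rej):
            rows.append({
                "model": "topic", "outcome": outcome, "term": r.term,
                "estimate": r.coefficient, "se": r.std_error, "p": r.p_value,
                "p_adjusted": float(pa), "rejected_bh": bool(rj),
                "n": r.n_obs, "groups": r.n_groups, "error": "",
            })
        for topic, msg in failed:
            rows.append({
                "model": "topic", "outcome": outcome, "term": topic,
                "estimate": np.nan, "se": np.nan, "p": np.nan,
                "p_adjusted": np.nan, "rejected_bh": False,
                "n": 0, "groups": 0, "error": msg,
            })
    return pd.DataFrame(rows)
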