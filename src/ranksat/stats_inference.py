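"""Inferential statistics applied to derived judgement quantities.

Thin, validated wrappers around scipy/statsmodels: proportional-odds
(cumulative-logit) ordinal regression with per-coefficient Wald tests and
Nagelkerke pseudo-R², tie-corrected Kendall tau-b, Pearson correlation, and
pooled-variance two-sample comparison with Cohen's d.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.miscmodels.ordinal_model import OrderedModel

__all__ = [
    "OrdinalRegressionResult",
    "GroupComparison",
    "proportional_odds_fit",
    "nagelkerke_r2",
    "kendall_tau",
    "pearson_r",
    "two_sample_comparison",
]


@dataclass(frozen=True)
class OrdinalRegressionResult:
    """Proportional-odds fit: a coefficient table plus likelihood summaries.

    ``table`` has one row per predictor with columns
    ``coef, se, wald, p`` (Wald = (coef/se)², 1 df).
    """

    table: pd.DataFrame
    ll_model: float
    ll_null: float
    nagelkerke_r2: float
    n: int


@dataclass(frozen=True)
class GroupComparison:
    """Pooled-variance t-test between two groups with Cohen's d."""

    mean_a: float
    mean_b: float
    se_a: float
    se_b: float
    t: float
    df: int
    p: float
    cohens_d: float
    n_a: int
    n_b: int


def nagelkerke_r2(ll_null: float, ll_model: float, n: int) -> float:
    """Nagelkerke pseudo-R²:
    [1 - exp(2(ll_null - ll_model)/n)] / [1 - exp(2 ll_null / n)].
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if ll_model < ll_null - 1e-8:
        raise ValueError("model log-likelihood is below the null's")
    cox_snell = 1.0 - math.exp(2.0 * (ll_null - ll_model) / n)
    max_r2 = 1.0 - math.exp(2.0 * ll_null / n)
    if max_r2 <= 0:
        return 0.0
    return min(1.0, max(0.0, cox_snell / max_r2))


def proportional_odds_fit(
    outcomes: np.ndarray | pd.Series,
    predictors: pd.DataFrame,
) -> OrdinalRegressionResult:
    """MLE of the cumulative-logit proportional-odds model.

    Outcomes are ordinal (e.g. dissatisfaction 1–5, higher = more
    dissatisfied); predictors are numeric columns.  The intercept-only
    (null) log-likelihood is the multinomial log-likelihood of the category
    proportions, which the threshold-only cumulative model attains exactly.
    """
    y = np.asarray(outcomes)
    X = pd.DataFrame(predictors)
    if len(y) != len(X):
        raise ValueError("outcomes and predictors must align")
    counts = pd.Series(y).value_counts()
    if len(counts) < 2:
        raise ValueError("outcomes contain a single category; nothing to model")
    if (X.nunique() <= 1).any():
        bad = X.columns[X.nunique() <= 1].tolist()
        raise ValueError(f"constant predictor(s): {bad}")

    endog = pd.Series(pd.Categorical(y, ordered=True), index=X.index)
    model = OrderedModel(endog, X, distr="logit")
    with np.errstate(all="ignore"):
        res = model.fit(method="bfgs", disp=False, maxiter=500)
    k = X.shape[1]
    coefs = res.params.iloc[:k]
    ses = res.bse.iloc[:k]
    if not np.all(np.isfinite(coefs)) or not np.all(np.isfinite(ses)) or np.any(ses > 1e4):
        raise ValueError(
            "ordinal regression did not yield finite estimates "
            "(possible complete separation or singular design)"
        )
    n = len(y)
    ll_null = float(np.sum(counts * np.log(counts / n)))
    ll_model = float(res.llf)
    wald = (coefs / ses) ** 2
    table = pd.DataFrame(
        {
            "coef": coefs,
            "se": ses,
            "wald": wald,
            "p": stats.chi2.sf(wald, df=1),
        }
    )
    return OrdinalRegressionResult(
        table=table,
        ll_model=ll_model,
        ll_null=ll_null,
        nagelkerke_r2=nagelkerke_r2(ll_null, max(ll_model, ll_null), n),
        n=n,
    )


def kendall_tau(x, y) -> float:
    """Tie-corrected Kendall tau-b between two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of at least 3 values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Kendall tau is undefined for a constant vector")
    tau = stats.kendalltau(x, y, variant="b").statistic
    return float(tau)


def pearson_r(x, y) -> float:
    """Product-moment correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of at least 3 values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson r is undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def two_sample_comparison(group_a, group_b) -> GroupComparison:
    """Independent-samples pooled-variance t-test plus Cohen's d.

    df = n_a + n_b - 2; d uses the pooled standard deviation, so identical
    group means give d = 0 and the reported t/df pair matches the pooled
    convention (e.g. groups of 38 and 25 give df = 61).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled_var = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    if pooled_var <= 0:
        raise ValueError("zero pooled variance; comparison undefined")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    d = (a.mean() - b.mean()) / math.sqrt(pooled_var)
    return GroupComparison(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        se_a=float(a.std(ddof=1) / math.sqrt(na)),
        se_b=float(b.std(ddof=1) / math.sqrt(nb)),
        t=float(t),
        df=na + nb - 2,
        p=float(p),
        cohens_d=float(d),
        n_a=na,
        n_b=nb,
    )
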