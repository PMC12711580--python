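"""Brunner–Munzel studentized rank test and time-point comparisons.

The Brunner–Munzel test targets the stochastic superiority probability
``p = P(X < Y) + 1/2 P(X = Y)`` of two independent samples.  With pooled
midranks ``R`` and within-group ranks, the estimate is

    p_hat = (Rbar_2 - (n2 + 1) / 2) / n1,

and the studentized statistic

    W = n1 n2 (Rbar_2 - Rbar_1) / (N * sqrt(n1 v1 + n2 v2)),

where ``v_k`` is the sample variance of (pooled rank - within-group
rank) in group k, is referred to a t distribution with
Welch–Satterthwaite degrees of freedom.  The test is robust to unequal
variances, handles ties through midranks, and behaves well at the very
small group sizes (3-4 meristems) typical of confocal time courses.

When both rank variances vanish (complete separation or all-ties) the t
form divides by zero; the implementation then falls back to the exact
permutation distribution of ``p_hat`` whenever the number of group
assignments C(N, n1) is at most 184,756 (= C(20, 10)).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, t as t_dist

from .io import SamQuantError

_MAX_EXACT_COMBINATIONS = 184_756


@dataclass(frozen=True)
class BMResult:
    """Outcome of one Brunner–Munzel comparison."""

    p_hat: float
    statistic: float
    df: float
    p_value: float
    n1: int
    n2: int
    degenerate: bool
    method: str  # "t-approximation" | "exact-permutation"


def brunner_munzel(x, y) -> BMResult:
    """Two-sided Brunner–Munzel test of sample ``x`` against sample ``y``.

    Swapping the samples maps ``p_hat`` to ``1 - p_hat``, negates the
    statistic and preserves the p-value.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise SamQuantError(
            f"brunner_munzel requires at least 2 observations per sample "
            f"(got {n1} and {n2})"
        )
    N = n1 + n2
    pooled = np.concatenate([x, y])
    R = rankdata(pooled)  # midranks
    Rx, Ry = R[:n1], R[n1:]
    rbar1, rbar2 = Rx.mean(), Ry.mean()
    p_hat = (rbar2 - (n2 + 1) / 2.0) / n1

    wx = rankdata(x)
    wy = rankdata(y)
    v1 = float(np.var(Rx - wx, ddof=1))
    v2 = float(np.var(Ry - wy, ddof=1))

    if v1 == 0.0 and v2 == 0.0:
        p_value = _exact_permutation_p(R, n1, n2, p_hat)
        return BMResult(
            p_hat=float(p_hat),
            statistic=math.nan,
            df=math.nan,
            p_value=p_value,
            n1=n1,
            n2=n2,
            degenerate=True,
            method="exact-permutation",
        )

    se = math.sqrt(n1 * v1 + n2 * v2)
    statistic = n1 * n2 * (rbar2 - rbar1) / (N * se)
    df = (n1 * v1 + n2 * v2) ** 2 / (
        (n1 * v1) ** 2 / (n1 - 1) + (n2 * v2) ** 2 / (n2 - 1)
    )
    p_value = min(1.0, 2.0 * float(t_dist.sf(abs(statistic), df)))
    return BMResult(
        p_hat=float(p_hat),
        statistic=float(statistic),
        df=float(df),
        p_value=p_value,
        n1=n1,
        n2=n2,
        degenerate=False,
        method="t-approximation",
    )


def _exact_permutation_p(R: np.ndarray, n1: int, n2: int, p_hat_obs: float) -> float:
    """Exact two-sided permutation p-value of ``p_hat`` under exchangeability.

    Pooled midranks are invariant under relabeling, so ``p_hat`` of a
    relabeled split is a mean of a rank subset; the two-sided p-value is
    the fraction of the C(N, n1) splits whose ``p_hat`` is at least as
    far from 1/2 as the observed one.
    """
    N = n1 + n2
    n_comb = math.comb(N, n1)
    if n_comb > _MAX_EXACT_COMBINATIONS:
        return math.nan
    obs = abs(p_hat_obs - 0.5)
    combos = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(N), n1)),
        dtype=np.intp,
        count=n_comb * n1,
    ).reshape(n_comb, n1)
    sum1 = R[combos].sum(axis=1)
    rbar2 = (R.sum() - sum1) / n2
    ph = (rbar2 - (n2 + 1) / 2.0) / n1
    count = int(np.count_nonzero(np.abs(ph - 0.5) >= obs - 1e-12))
    return count / n_comb


# ---------------------------------------------------------------------------
# pairwise time-point comparisons

COMPARISON_COLUMNS = [
    "channel",
    "region",
    "baseline",
    "comparison",
    "n1",
    "n2",
    "p_hat",
    "statistic",
    "df",
    "p_value",
    "method",
    "alpha",
    "significant",
    "reason",
]


def _time_key(tp: str):
    digits = "".join(ch for ch in str(tp) if ch.isdigit())
    return (int(digits) if digits else 0, str(tp))


def pairwise_timepoints(
    summaries: pd.DataFrame,
    baseline: str,
    alpha: float = 0.1,
    value_col: str = "median",
) -> pd.DataFrame:
    """Baseline-vs-later Brunner–Munzel tests on per-meristem medians.

    Each meristem contributes one observation (its median normalized
    concentration) per channel and region, avoiding pseudoreplication
    over nuclei.  For every channel x region, the baseline time point is
    compared two-sidedly against each later time point; no multiplicity
    correction is applied (callers can correct downstream — alpha is
    recorded in the output).  Groups with fewer than 2 usable meristems
    yield a row with the test skipped and the reason recorded.
    """
    if not 0 < alpha < 1:
        raise SamQuantError(f"alpha must be in (0, 1), got {alpha}")
    tps = sorted(summaries["time_point"].unique(), key=_time_key)
    if baseline not in tps:
        raise SamQuantError(f"baseline time point {baseline!r} not in summaries")
    later = [tp for tp in tps if _time_key(tp) > _time_key(baseline)]
    rows = []
    for channel in pd.unique(summaries["channel"]):
        for region in pd.unique(summaries["region"]):
            sub = summaries[
                (summaries["channel"] == channel) & (summaries["region"] == region)
            ]
            base_vals = sub.loc[sub["time_point"] == baseline, value_col].dropna()
            for tp in later:
                comp_vals = sub.loc[sub["time_point"] == tp, value_col].dropna()
                row = {
                    "channel": channel,
                    "region": region,
                    "baseline": baseline,
                    "comparison": tp,
                    "n1": int(base_vals.size),
                    "n2": int(comp_vals.size),
                    "alpha": alpha,
                }
                if base_vals.size < 2 or comp_vals.size < 2:
                    row.update(
                        p_hat=np.nan,
                        statistic=np.nan,
                        df=np.nan,
                        p_value=np.nan,
                        method="skipped",
                        significant=False,
                        reason="fewer than 2 meristems with data in a group",
                    )
                else:
                    res = brunner_munzel(base_vals.to_numpy(), comp_vals.to_numpy())
                    row.update(
                        p_hat=res.p_hat,
                        statistic=res.statistic,
                        df=res.df,
                        p_value=res.p_value,
                        method=res.method,
                        significant=bool(
                            np.isfinite(res.p_value) and res.p_value < alpha
                        ),
                        reason="",
                    )
                rows.append(row)
    return pd.DataFrame(rows, columns=COMPARISON_COLUMNS)


# ---------------------------------------------------------------------------
# simulation harness


@dataclass(frozen=True)
class RejectionRate:
    rate: float
    ci_low: float
    ci_high: float
    n_reps: int


def type1_power_sim(
    n1: int,
    n2: int,
    effect: float,
    n_reps: int,
    alpha: float,
    seed: int,
) -> RejectionRate:
    """Empirical rejection rate of the test under a normal shift model.

    Draws ``x ~ N(0, 1)`` (size n1) and ``y ~ N(effect, 1)`` (size n2)
    ``n_reps`` times, runs the two-sided test, and returns the fraction
    of p-values below ``alpha`` with a normal-approximation 95% binomial
    CI.  ``effect = 0`` estimates the type-I error level.
    """
    if n_reps < 100:
        raise SamQuantError("n_reps must be >= 100 for a stable estimate")
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        x = rng.standard_normal(n1)
        y = rng.standard_normal(n2) + effect
        res = brunner_munzel(x, y)
        if np.isfinite(res.p_value) and res.p_value < alpha:
            rejections += 1
    rate = rejections / n_reps
    half = 1.96 * math.sqrt(max(rate * (1 - rate), 1e-12) / n_reps)
    return RejectionRate(rate, max(0.0, rate - half), min(1.0, rate + half), n_reps)
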