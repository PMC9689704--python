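"""Confidence-interval constructions for sensitivity/specificity estimates.

Five interval kinds are used across the correction methods: the Wald
interval for simple proportions (full-data and complete-case analysis), a
normal bootstrap interval (inverse probability bootstrap), the
bias-corrected and accelerated (BCa) bootstrap interval (inverse
probability weighting), Rubin's rules with a t reference (multiple
imputation), and a log-odds delta-method interval for the Begg-Greenes
estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "IntervalSpec",
    "wald_ci",
    "boot_normal_ci",
    "boot_bca_ci",
    "rubin_pool",
    "RubinPooled",
    "bg_analytic_ci",
]

INTERVAL_KINDS = ("wald", "boot_normal", "boot_bca", "rubin", "bg_analytic")


@dataclass(frozen=True)
class IntervalSpec:
    kind: str
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.kind not in INTERVAL_KINDS:
            raise ValueError(f"unknown interval kind {self.kind!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


def _clip(lo: float, hi: float) -> tuple[float, float]:
    return max(0.0, lo), min(1.0, hi)


def wald_ci(p_hat: float, n_eff: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wald interval p +- z * sqrt(p(1-p)/n), clipped to [0, 1]."""
    if n_eff < 1:
        raise ValueError("n_eff must be >= 1")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    half = z * np.sqrt(p_hat * (1.0 - p_hat) / n_eff)
    return _clip(p_hat - half, p_hat + half)


def boot_normal_ci(
    mean_rep: float, sd_rep: float, alpha: float = 0.05
) -> tuple[float, float]:
    """Normal bootstrap interval: estimate +- z * bootstrap SE, clipped."""
    if sd_rep < 0:
        raise ValueError("sd_rep must be nonnegative")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return _clip(mean_rep - z * sd_rep, mean_rep + z * sd_rep)


def boot_bca_ci(
    replicates: Sequence[float],
    point_est: float,
    jackknife_estimates: Sequence[float],
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Bias-corrected and accelerated (BCa) bootstrap percentile interval.

    The bias correction ``z0`` comes from the fraction of bootstrap
    replicates below the point estimate; the acceleration ``a`` from the
    skewness of the jackknife (leave-one-out) estimates.  When every
    replicate is identical the interval degenerates to a point and a
    warning is emitted.
    """
    reps = np.sort(np.asarray(replicates, dtype=float))
    if reps.size < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    if np.all(reps == reps[0]):
        import warnings

        warnings.warn("all bootstrap replicates identical; degenerate BCa interval")
        return float(reps[0]), float(reps[0])

    prop_below = np.mean(reps < point_est)
    # guard the probit at 0 or 1 by a half-replicate continuity correction
    prop_below = min(max(prop_below, 0.5 / reps.size), 1.0 - 0.5 / reps.size)
    z0 = stats.norm.ppf(prop_below)

    jack = np.asarray(jackknife_estimates, dtype=float)
    dev = jack.mean() - jack
    denom = 6.0 * (dev**2).sum() ** 1.5
    a = (dev**3).sum() / denom if denom > 0 else 0.0

    out = []
    for q in (alpha / 2.0, 1.0 - alpha / 2.0):
        z = stats.norm.ppf(q)
        adj = stats.norm.cdf(z0 + (z0 + z) / (1.0 - a * (z0 + z)))
        out.append(_quantile_norm_inter(reps, float(adj)))
    return out[0], out[1]


def _quantile_norm_inter(sorted_reps: np.ndarray, q: float) -> float:
    """Bootstrap order-statistic quantile, interpolated on the probit scale.

    The conventional percentile lookup for bootstrap intervals: rank
    r = (R+1)q selects order statistics, with interpolation between them
    linear in the normal quantile of the rank.  Extreme ranks fall back to
    the smallest/largest replicate.
    """
    r = sorted_reps.size
    rk = (r + 1) * q
    k = int(np.trunc(rk))
    if k <= 0:
        return float(sorted_reps[0])
    if k >= r:
        return float(sorted_reps[-1])
    if k == rk:
        return float(sorted_reps[k - 1])
    t_k, t_k1 = sorted_reps[k - 1], sorted_reps[k]
    g = (stats.norm.ppf(q) - stats.norm.ppf(k / (r + 1))) / (
        stats.norm.ppf((k + 1) / (r + 1)) - stats.norm.ppf(k / (r + 1))
    )
    return float(t_k + g * (t_k1 - t_k))


class RubinPooled(NamedTuple):
    """Pooled multiple-imputation estimate with its variance decomposition."""

    estimate: float
    total_var: float
    within_var: float
    between_var: float
    df: float
    ci: tuple[float, float]


def rubin_pool(
    estimates: Sequence[float],
    within_vars: Sequence[float],
    alpha: float = 0.05,
) -> RubinPooled:
    """Combine per-imputation estimates by Rubin's rules.

    Pooled estimate is the mean over imputations; total variance
    T = W + (1 + 1/m) B with W the mean within-imputation variance and B
    the between-imputation sample variance; degrees of freedom by the
    classic (m-1)(1 + W/((1+1/m)B))^2 formula; CI from the t reference.
    """
    q = np.asarray(estimates, dtype=float)
    w = np.asarray(within_vars, dtype=float)
    m = q.size
    if m < 2 or w.size != m:
        raise ValueError("need m >= 2 estimates with matching within-variances")
    qbar = float(q.mean())
    wbar = float(w.mean())
    b = float(q.var(ddof=1))
    total = wbar + (1.0 + 1.0 / m) * b
    if b > 0:
        df = (m - 1) * (1.0 + wbar / ((1.0 + 1.0 / m) * b)) ** 2
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    else:
        df = np.inf
        tcrit = stats.norm.ppf(1.0 - alpha / 2.0)
    half = tcrit * np.sqrt(total)
    return RubinPooled(
        estimate=qbar,
        total_var=total,
        within_var=wbar,
        between_var=b,
        df=float(df),
        ci=(qbar - half, qbar + half),
    )


def bg_analytic_ci(
    sn_or_sp: float, var_log_odds: float, alpha: float = 0.05
) -> tuple[float, float]:
    """Delta-method interval on the log-odds scale, back-transformed.

    Used for the Begg-Greenes estimator: a normal interval for
    logit(estimate) with the supplied variance, mapped through the inverse
    logit, which keeps the interval inside (0, 1) without clipping.
    """
    if not 0.0 < sn_or_sp < 1.0:
        # boundary estimate: the log-odds variance is uninformative
        return sn_or_sp, sn_or_sp
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    logit = np.log(sn_or_sp / (1.0 - sn_or_sp))
    half = z * np.sqrt(var_log_odds)
    lo, hi = logit - half, logit + half
    expit = lambda x: 1.0 / (1.0 + np.exp(-x))
    return float(expit(lo)), float(expit(hi))
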