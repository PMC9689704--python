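"""Sensitivity/specificity estimators under partial verification.

Six methods are provided.  Full-data analysis (FDA) is the benchmark on
completely verified data; complete-case analysis (CCA) is the naive,
biased analysis of verified subjects only.  Four corrections operate under
the missing-at-random assumption that verification depends only on the
test result:

* Begg-Greenes (BG): Bayes-theorem reassembly of Sn/Sp from the test
  marginal P(T) and the predictive values P(D | T, V=1).
* Inverse probability weighting (IPWE): Horvitz-Thompson weighting of
  verified subjects by the inverse verification propensity.
* Multiple imputation (MI): missing disease statuses drawn repeatedly from
  a logistic model of D on T, full-data estimates pooled by Rubin's rules.
* Inverse probability bootstrap (IPB): weighted bootstrap of the verified
  subjects with resampling probabilities proportional to the inverse
  propensity, producing debiased synthetic samples; the point estimate is
  the mean of the per-sample full-data estimates and the SE their
  standard deviation.

All methods reduce to functions of the six observable cell counts, so each
accepts either a subject-level :class:`~pvb.data_model.VerificationDataset`
or a :class:`~pvb.data_model.CellCounts` directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from .data_model import (
    AccuracyEstimate,
    CellCounts,
    VerificationDataset,
    reduce_to_counts,
)
from .intervals import (
    bg_analytic_ci,
    boot_bca_ci,
    boot_normal_ci,
    rubin_pool,
    wald_ci,
)
from .propensity import PropensityModel, fit_propensity, ipb_weights

__all__ = [
    "BootstrapReplicateSet",
    "ImputationSet",
    "estimate_fda",
    "estimate_cca",
    "estimate_bg",
    "estimate_ipwe",
    "impute_disease",
    "estimate_mi",
    "estimate_ipb",
    "estimate_all",
    "METHODS",
]

METHODS = ("fda", "cca", "bg", "ipwe", "mi", "ipb")


def _as_counts(data: VerificationDataset | CellCounts) -> CellCounts:
    return reduce_to_counts(data) if isinstance(data, VerificationDataset) else data


def _clip01(lo: float, hi: float) -> tuple[float, float]:
    return max(0.0, lo), min(1.0, hi)


@dataclass(frozen=True)
class BootstrapReplicateSet:
    """Per-replicate Sn/Sp values from the weighted bootstrap.

    Replicates in which a quantity is undefined (no diseased or no
    non-diseased subjects drawn) are excluded from that quantity's vector;
    ``n_degenerate`` counts replicates where Sn or Sp was undefined.
    """

    sn_reps: np.ndarray
    sp_reps: np.ndarray
    b_requested: int
    n_degenerate: int

    def __post_init__(self) -> None:
        if self.n_degenerate < 0 or self.b_requested < 1:
            raise ValueError("invalid bootstrap accounting")


@dataclass(frozen=True)
class ImputationSet:
    """Per-imputation full-data estimates and their within-imputation variances."""

    sn: np.ndarray
    sp: np.ndarray
    sn_var: np.ndarray
    sp_var: np.ndarray

    @property
    def m(self) -> int:
        return len(self.sn)

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("need at least m=2 imputations")


def _proportion_pair(
    n11: int, n01: int, n10: int, n00: int
) -> tuple[float, float]:
    """Sn and Sp from a 2x2 (test x disease) table; errors on empty classes."""
    if n11 + n01 == 0:
        raise ValueError("Sn undefined: no diseased subjects")
    if n10 + n00 == 0:
        raise ValueError("Sp undefined: no non-diseased subjects")
    return n11 / (n11 + n01), n00 / (n10 + n00)


def estimate_fda(
    data: VerificationDataset | CellCounts, alpha: float = 0.05
) -> AccuracyEstimate:
    """Full-data analysis: the standard Sn/Sp on completely verified data.

    Sn = P(T=1 | D=1), Sp = P(T=0 | D=0); Wald intervals.
    """
    c = _as_counts(data)
    if not c.fully_verified:
        raise ValueError("FDA requires fully verified data (u1 = u0 = 0)")
    sn, sp = _proportion_pair(c.s11, c.s01, c.s10, c.s00)
    n_d1, n_d0 = c.s11 + c.s01, c.s10 + c.s00
    return AccuracyEstimate(
        method="fda",
        sn=sn,
        sp=sp,
        sn_se=float(np.sqrt(sn * (1 - sn) / n_d1)),
        sp_se=float(np.sqrt(sp * (1 - sp) / n_d0)),
        sn_ci=wald_ci(sn, n_d1, alpha),
        sp_ci=wald_ci(sp, n_d0, alpha),
        alpha=alpha,
    )


def estimate_cca(
    data: VerificationDataset | CellCounts, alpha: float = 0.05
) -> AccuracyEstimate:
    """Complete-case analysis: Sn/Sp among verified subjects only.

    Biased under partial verification (test-positives are over-verified, so
    Sn is inflated and Sp deflated); included as the uncorrected reference.
    """
    c = _as_counts(data)
    sn, sp = _proportion_pair(c.s11, c.s01, c.s10, c.s00)
    n_d1, n_d0 = c.s11 + c.s01, c.s10 + c.s00
    return AccuracyEstimate(
        method="cca",
        sn=sn,
        sp=sp,
        sn_se=float(np.sqrt(sn * (1 - sn) / n_d1)),
        sp_se=float(np.sqrt(sp * (1 - sp) / n_d0)),
        sn_ci=wald_ci(sn, n_d1, alpha),
        sp_ci=wald_ci(sp, n_d0, alpha),
        alpha=alpha,
    )


def cca_asymptotic_sn_sp(
    sn_true: float, sp_true: float, pv1: float, pv0: float
) -> tuple[float, float]:
    """Large-sample limits of the complete-case Sn/Sp under MAR verification.

    Among the diseased, test-positives are verified with probability pv1
    and test-negatives with pv0, so the complete-case Sn converges to
    ``sn*pv1 / (sn*pv1 + (1-sn)*pv0)``; symmetrically for Sp.  Serves as
    the closed-form oracle for the CCA bias in simulation studies.
    """
    sn_lim = sn_true * pv1 / (sn_true * pv1 + (1.0 - sn_true) * pv0)
    sp_lim = sp_true * pv0 / (sp_true * pv0 + (1.0 - sp_true) * pv1)
    return sn_lim, sp_lim


def estimate_bg(
    data: VerificationDataset | CellCounts, alpha: float = 0.05
) -> AccuracyEstimate:
    """Begg-Greenes correction via Bayes' theorem.

    Uses P(T=t) from all N subjects and the predictive values
    P(D | T=t, V=1) from the verified subjects:

        Sn = P(T=1) p1 / [P(T=1) p1 + P(T=0) p0],    p_t = P(D=1 | T=t, V=1)

    and the mirror-image expression for Sp.  Unbiased under MAR because
    the predictive values are estimable from verified subjects alone.
    The interval is a delta-method normal interval on the log-odds scale.
    """
    c = _as_counts(data)
    k1, k0 = c.s11 + c.s10, c.s01 + c.s00
    if k1 == 0 or k0 == 0:
        raise ValueError("BG requires verified cases in both test strata")
    pt1, pt0 = c.p_t1, 1.0 - c.p_t1
    p1, p0 = c.s11 / k1, c.s01 / k0
    sn_num, sn_den = pt1 * p1, pt1 * p1 + pt0 * p0
    sp_num, sp_den = pt0 * (1 - p0), pt1 * (1 - p1) + pt0 * (1 - p0)
    if sn_den == 0:
        raise ValueError("Sn undefined: no verified diseased subjects")
    if sp_den == 0:
        raise ValueError("Sp undefined: no verified non-diseased subjects")
    sn, sp = sn_num / sn_den, sp_num / sp_den

    # log-odds delta-method variance; the three components come from the
    # independent binomials P(T=1) (n=N) and p_t (n=k_t)
    var_pt = 1.0 / (c.total * pt1 * pt0) if 0 < pt1 < 1 else 0.0
    var_sn = var_pt
    var_sn += (1 - p1) / (k1 * p1) if p1 > 0 else 0.0
    var_sn += (1 - p0) / (k0 * p0) if p0 > 0 else 0.0
    var_sp = var_pt
    var_sp += p1 / (k1 * (1 - p1)) if p1 < 1 else 0.0
    var_sp += p0 / (k0 * (1 - p0)) if p0 < 1 else 0.0

    # SE on the probability scale via the logistic derivative
    sn_se = float(np.sqrt(var_sn) * sn * (1 - sn))
    sp_se = float(np.sqrt(var_sp) * sp * (1 - sp))
    return AccuracyEstimate(
        method="bg",
        sn=sn,
        sp=sp,
        sn_se=sn_se,
        sp_se=sp_se,
        sn_ci=bg_analytic_ci(sn, var_sn, alpha),
        sp_ci=bg_analytic_ci(sp, var_sp, alpha),
        alpha=alpha,
    )


def _ipwe_point(c: CellCounts, ps: PropensityModel) -> tuple[float, float]:
    w1, w0 = 1.0 / ps.ps_t1, 1.0 / ps.ps_t0
    sn_den = c.s11 * w1 + c.s01 * w0
    sp_den = c.s10 * w1 + c.s00 * w0
    if sn_den == 0:
        raise ValueError("Sn undefined: no verified diseased subjects")
    if sp_den == 0:
        raise ValueError("Sp undefined: no verified non-diseased subjects")
    return c.s11 * w1 / sn_den, c.s00 * w0 / sp_den


def estimate_ipwe(
    data: VerificationDataset | CellCounts,
    ps: PropensityModel | None = None,
    alpha: float = 0.05,
    ci_boot: int = 0,
    rng: np.random.Generator | None = None,
) -> AccuracyEstimate:
    """Inverse probability weighting estimator (Horvitz-Thompson style).

    Each verified subject is weighted by the inverse of its verification
    propensity.  With the saturated (stratum-proportion) propensity fit
    this is algebraically identical to the Begg-Greenes estimator.

    Set ``ci_boot`` to a positive bootstrap size to attach BCa intervals
    (the full dataset is resampled and the propensity refitted per
    replicate); otherwise no interval is reported.
    """
    c = _as_counts(data)
    if ps is None:
        ps = fit_propensity(c)
    sn, sp = _ipwe_point(c, ps)
    sn_ci = sp_ci = None
    sn_se = sp_se = None
    if ci_boot > 0:
        if rng is None:
            raise ValueError("rng required for the bootstrap interval")
        sn_ci, sp_ci, sn_se, sp_se = _ipwe_bca(c, ci_boot, rng, sn, sp, alpha)
    return AccuracyEstimate(
        method="ipwe",
        sn=sn,
        sp=sp,
        sn_se=sn_se,
        sp_se=sp_se,
        sn_ci=sn_ci,
        sp_ci=sp_ci,
        alpha=alpha,
    )


def _ipwe_from_cell_matrix(cells: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized IPWE with refitted propensity; cells columns follow
    (s11, s10, s01, s00, u1, u0); undefined entries come back as nan."""
    s11, s10, s01, s00, u1, u0 = (cells[:, i].astype(float) for i in range(6))
    with np.errstate(divide="ignore", invalid="ignore"):
        ps1 = (s11 + s10) / (s11 + s10 + u1)
        ps0 = (s01 + s00) / (s01 + s00 + u0)
        w1, w0 = 1.0 / ps1, 1.0 / ps0
        sn = s11 * w1 / (s11 * w1 + s01 * w0)
        sp = s00 * w0 / (s10 * w1 + s00 * w0)
    return sn, sp


def _ipwe_bca(
    c: CellCounts,
    b: int,
    rng: np.random.Generator,
    sn: float,
    sp: float,
    alpha: float,
) -> tuple[tuple[float, float], tuple[float, float], float, float]:
    """Nonparametric BCa interval for IPWE by resampling all N subjects.

    Subjects fall into six exchangeable types, so a bootstrap resample is a
    multinomial over the six cells and the jackknife has at most six
    distinct leave-one-out values (expanded by multiplicity).
    """
    base = np.array([c.s11, c.s10, c.s01, c.s00, c.u1, c.u0])
    draws = rng.multinomial(c.total, base / c.total, size=b)
    sn_r, sp_r = _ipwe_from_cell_matrix(draws)

    jack_cells = np.repeat(base[None, :], 6, axis=0) - np.eye(6, dtype=int)
    present = base > 0
    sn_j6, sp_j6 = _ipwe_from_cell_matrix(jack_cells[present])
    mult = base[present]
    sn_jack = np.repeat(sn_j6, mult)
    sp_jack = np.repeat(sp_j6, mult)

    sn_valid = sn_r[np.isfinite(sn_r)]
    sp_valid = sp_r[np.isfinite(sp_r)]
    sn_ci = boot_bca_ci(sn_valid, sn, sn_jack[np.isfinite(sn_jack)], alpha)
    sp_ci = boot_bca_ci(sp_valid, sp, sp_jack[np.isfinite(sp_jack)], alpha)
    return (
        _clip01(*sn_ci),
        _clip01(*sp_ci),
        float(np.std(sn_valid, ddof=1)),
        float(np.std(sp_valid, ddof=1)),
    )


def impute_disease(
    data: VerificationDataset | CellCounts,
    m: int,
    rng: np.random.Generator,
    on_separation: str = "error",
) -> ImputationSet:
    """Proper multiple imputation of missing disease statuses.

    The imputation model is the logistic regression
    ``logit P(D=1 | T) = b0 + b1 T`` fitted to the verified subjects.  With
    a single binary covariate the fit is saturated, so drawing the
    coefficients from their asymptotic normal posterior is equivalent to
    drawing the two stratum log-odds independently.  Each imputation draws
    coefficients, then fills the missing D values Bernoulli; the per-
    imputation full-data Sn/Sp and their Wald variances are recorded.

    A verified stratum whose observed outcomes are all 0 or all 1 makes
    the logistic likelihood degenerate (perfect separation).  By default
    this is an error advising a larger verified sample or a different
    method.  ``on_separation="augment"`` instead augments each degenerate
    stratum with half a pseudo-success and half a pseudo-failure before
    fitting, the standard data-augmentation fix for separation in
    imputation models.
    """
    if m < 2:
        raise ValueError("need m >= 2 imputations")
    if on_separation not in ("error", "augment"):
        raise ValueError("on_separation must be 'error' or 'augment'")
    c = _as_counts(data)
    k1, k0 = c.s11 + c.s10, c.s01 + c.s00
    if k1 == 0 or k0 == 0:
        raise ValueError(
            "imputation model inestimable: a test stratum has no verified "
            "subjects; use a larger sample or a different method"
        )
    separated = c.s11 == 0 or c.s10 == 0 or c.s01 == 0 or c.s00 == 0
    if separated and on_separation == "error":
        raise ValueError(
            "perfect separation in the imputation model (a verified test "
            "stratum shows a single disease outcome); use a larger verified "
            "sample, a different method, or on_separation='augment'"
        )
    a1 = 0.5 if (c.s11 == 0 or c.s10 == 0) else 0.0
    a0 = 0.5 if (c.s01 == 0 or c.s00 == 0) else 0.0
    p1_hat = (c.s11 + a1) / (k1 + 2 * a1)
    p0_hat = (c.s01 + a0) / (k0 + 2 * a0)
    var_l1 = 1.0 / ((k1 + 2 * a1) * p1_hat * (1 - p1_hat))
    var_l0 = 1.0 / ((k0 + 2 * a0) * p0_hat * (1 - p0_hat))

    l1 = rng.normal(logit(p1_hat), np.sqrt(var_l1), size=m)
    l0 = rng.normal(logit(p0_hat), np.sqrt(var_l0), size=m)
    d1 = rng.binomial(c.u1, expit(l1)) if c.u1 > 0 else np.zeros(m, dtype=int)
    d0 = rng.binomial(c.u0, expit(l0)) if c.u0 > 0 else np.zeros(m, dtype=int)

    c11 = c.s11 + d1
    c01 = c.s01 + d0
    c10 = c.s10 + (c.u1 - d1)
    c00 = c.s00 + (c.u0 - d0)
    n_d1 = c11 + c01
    n_d0 = c10 + c00
    if np.any(n_d1 == 0) or np.any(n_d0 == 0):
        raise ValueError("an imputed dataset has an empty disease class")
    sn = c11 / n_d1
    sp = c00 / n_d0
    return ImputationSet(
        sn=sn,
        sp=sp,
        sn_var=sn * (1 - sn) / n_d1,
        sp_var=sp * (1 - sp) / n_d0,
    )


def estimate_mi(imps: ImputationSet, alpha: float = 0.05) -> AccuracyEstimate:
    """Pool per-imputation full-data estimates by Rubin's rules."""
    sn_pool = rubin_pool(imps.sn, imps.sn_var, alpha)
    sp_pool = rubin_pool(imps.sp, imps.sp_var, alpha)
    return AccuracyEstimate(
        method="mi",
        sn=sn_pool.estimate,
        sp=sp_pool.estimate,
        sn_se=float(np.sqrt(sn_pool.total_var)),
        sp_se=float(np.sqrt(sp_pool.total_var)),
        sn_ci=_clip01(*sn_pool.ci),
        sp_ci=_clip01(*sp_pool.ci),
        sn_ci_raw=sn_pool.ci,
        sp_ci_raw=sp_pool.ci,
        alpha=alpha,
    )


def ipb_replicates_counts(
    c: CellCounts,
    ps: PropensityModel,
    b: int,
    rng: np.random.Generator,
) -> BootstrapReplicateSet:
    """Weighted-bootstrap replicates via the four-cell multinomial fast path.

    Verified subjects fall into four exchangeable (T, D) types, so
    resampling n subjects with normalized inverse-propensity probabilities
    is a four-cell multinomial with per-type mass proportional to
    ``count / PS``.  Distributionally identical to subject-level weighted
    resampling, and what makes large simulation studies affordable.
    """
    counts4 = np.array([c.s11, c.s10, c.s01, c.s00], dtype=float)
    inv_ps = np.array(
        [1 / ps.ps_t1, 1 / ps.ps_t1, 1 / ps.ps_t0, 1 / ps.ps_t0]
    )
    mass = counts4 * inv_ps
    q = mass / mass.sum()
    draws = rng.multinomial(c.n, q, size=b)
    return _reps_from_draws(draws, b)


def ipb_replicates_subject(
    data: VerificationDataset,
    ps: PropensityModel,
    b: int,
    rng: np.random.Generator,
) -> BootstrapReplicateSet:
    """Literal subject-level weighted resampler (reference implementation).

    Kept for validation of the count-level fast path; identical in
    distribution but far slower.
    """
    v = data.verified == 1
    t = data.test[v]
    d = data.disease[v]
    w = ipb_weights(ps.for_tests(t))
    n = len(t)
    sn = np.full(b, np.nan)
    sp = np.full(b, np.nan)
    for i in range(b):
        idx = rng.choice(n, size=n, replace=True, p=w)
        td, dd = t[idx], d[idx]
        n11 = np.sum((td == 1) & (dd == 1))
        n01 = np.sum((td == 0) & (dd == 1))
        n10 = np.sum((td == 1) & (dd == 0))
        n00 = np.sum((td == 0) & (dd == 0))
        if n11 + n01 > 0:
            sn[i] = n11 / (n11 + n01)
        if n10 + n00 > 0:
            sp[i] = n00 / (n10 + n00)
    bad = ~np.isfinite(sn) | ~np.isfinite(sp)
    return BootstrapReplicateSet(
        sn_reps=sn[np.isfinite(sn)],
        sp_reps=sp[np.isfinite(sp)],
        b_requested=b,
        n_degenerate=int(bad.sum()),
    )


def _reps_from_draws(draws: np.ndarray, b: int) -> BootstrapReplicateSet:
    x11, x10, x01, x00 = (draws[:, i] for i in range(4))
    with np.errstate(divide="ignore", invalid="ignore"):
        sn = np.where(x11 + x01 > 0, x11 / (x11 + x01), np.nan)
        sp = np.where(x10 + x00 > 0, x00 / (x10 + x00), np.nan)
    bad = ~np.isfinite(sn) | ~np.isfinite(sp)
    return BootstrapReplicateSet(
        sn_reps=sn[np.isfinite(sn)],
        sp_reps=sp[np.isfinite(sp)],
        b_requested=b,
        n_degenerate=int(bad.sum()),
    )


def estimate_ipb(
    data: VerificationDataset | CellCounts,
    ps: PropensityModel | None = None,
    b: int = 1000,
    rng: np.random.Generator | None = None,
    alpha: float = 0.05,
    point: str = "mean",
    variant: str = "debias_once",
) -> tuple[AccuracyEstimate, BootstrapReplicateSet]:
    """Inverse probability bootstrap correction of Sn and Sp.

    Fit (or accept) the verification propensity PS = P(V=1|T) and form
    normalized inverse-propensity resampling weights over the n verified
    subjects.  With the default ``variant="debias_once"``, one weighted
    resample of size n is drawn first — the debiased synthetic dataset
    that IPB exists to produce, on which any full-data analysis can run —
    and the ``b`` bootstrap samples are ordinary resamples of it, giving
    the point estimate (mean of the per-sample Sn/Sp), the SE (their
    standard deviation) and the normal bootstrap interval.  Because the
    estimate carries the sampling noise of the debiased dataset on top of
    the noise of the original sample, IPB is less precise than the direct
    weighting estimators; that trade-off is the price of obtaining
    analysis-ready debiased data.

    ``variant="weighted"`` instead draws all ``b`` samples directly with
    the inverse-propensity weights and averages them, a smoothed
    weighting estimator whose replicate-to-replicate variability matches
    the plug-in IPWE.

    ``point="plugin"`` substitutes the direct weighted estimate for the
    bootstrap mean.  Bootstrap samples with an empty disease class leave
    the affected quantity undefined and are excluded from its mean/SD; a
    warning is emitted above 1% incidence.
    """
    if rng is None:
        raise ValueError("estimate_ipb requires a seeded rng")
    if b < 2:
        raise ValueError("need b >= 2 bootstrap samples")
    c = _as_counts(data)
    if c.n < 2:
        raise ValueError("need at least 2 verified subjects")
    if ps is None:
        ps = fit_propensity(c)
    if variant == "weighted":
        reps = ipb_replicates_counts(c, ps, b, rng)
    elif variant == "debias_once":
        counts4 = np.array([c.s11, c.s10, c.s01, c.s00], dtype=float)
        inv_ps = np.array(
            [1 / ps.ps_t1, 1 / ps.ps_t1, 1 / ps.ps_t0, 1 / ps.ps_t0]
        )
        mass = counts4 * inv_ps
        synthetic = rng.multinomial(c.n, mass / mass.sum())
        draws = rng.multinomial(c.n, synthetic / c.n, size=b)
        reps = _reps_from_draws(draws, b)
    else:
        raise ValueError("variant must be 'debias_once' or 'weighted'")
    if len(reps.sn_reps) == 0 or len(reps.sp_reps) == 0:
        raise ValueError("all bootstrap replicates degenerate")
    if reps.n_degenerate > 0.01 * b:
        warnings.warn(
            f"{reps.n_degenerate}/{b} degenerate bootstrap replicates excluded"
        )
    if point == "mean":
        sn, sp = float(reps.sn_reps.mean()), float(reps.sp_reps.mean())
    elif point == "plugin":
        sn, sp = _ipwe_point(c, ps)
    else:
        raise ValueError("point must be 'mean' or 'plugin'")
    sn_se = float(np.std(reps.sn_reps, ddof=1))
    sp_se = float(np.std(reps.sp_reps, ddof=1))
    sn_raw = (sn - _z(alpha) * sn_se, sn + _z(alpha) * sn_se)
    sp_raw = (sp - _z(alpha) * sp_se, sp + _z(alpha) * sp_se)
    est = AccuracyEstimate(
        method="ipb",
        sn=sn,
        sp=sp,
        sn_se=sn_se,
        sp_se=sp_se,
        sn_ci=boot_normal_ci(sn, sn_se, alpha),
        sp_ci=boot_normal_ci(sp, sp_se, alpha),
        sn_ci_raw=sn_raw,
        sp_ci_raw=sp_raw,
        alpha=alpha,
    )
    return est, reps


def _z(alpha: float) -> float:
    from scipy.stats import norm

    return float(norm.ppf(1.0 - alpha / 2.0))


def estimate_all(
    data: VerificationDataset | CellCounts,
    methods: tuple[str, ...] = METHODS,
    b: int = 1000,
    m: int | None = None,
    rng: np.random.Generator | None = None,
    alpha: float = 0.05,
) -> list[AccuracyEstimate]:
    """Run a set of methods on one dataset; skips FDA when data are partial.

    ``m`` defaults to the percentage of incomplete cases (rounded, at least
    2), the usual rule of thumb for choosing the number of imputations.
    """
    c = _as_counts(data)
    if rng is None:
        rng = np.random.default_rng()
    if m is None:
        m = max(2, round(100 * (c.u1 + c.u0) / c.total))
    out: list[AccuracyEstimate] = []
    for method in methods:
        if method == "fda":
            if c.fully_verified:
                out.append(estimate_fda(c, alpha))
            continue
        if method == "cca":
            out.append(estimate_cca(c, alpha))
        elif method == "bg":
            out.append(estimate_bg(c, alpha))
        elif method == "ipwe":
            out.append(estimate_ipwe(c, alpha=alpha, ci_boot=b, rng=rng))
        elif method == "mi":
            out.append(estimate_mi(impute_disease(c, m, rng), alpha))
        elif method == "ipb":
            est, _ = estimate_ipb(c, b=b, rng=rng, alpha=alpha)
            out.append(est)
        else:
            raise ValueError(f"unknown method {method!r}")
    return out
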