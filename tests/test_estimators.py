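import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pvb.data_model import CellCounts, counts_to_dataset
from pvb.estimators import (
    cca_asymptotic_sn_sp,
    estimate_bg,
    estimate_cca,
    estimate_fda,
    estimate_ipb,
    estimate_ipwe,
    estimate_mi,
    impute_disease,
    ipb_replicates_counts,
    ipb_replicates_subject,
)
from pvb.propensity import PropensityModel, fit_propensity
from pvb.simulate import ScenarioConfig, generate_replicate_counts


class TestFda:
    def test_balanced_table(self):
        e = estimate_fda(CellCounts(s11=40, s10=10, s01=10, s00=40))
        assert (e.sn, e.sp) == (0.8, 0.8)

    def test_no_false_negatives_gives_sn_one(self):
        e = estimate_fda(CellCounts(s11=7, s10=3, s01=0, s00=5))
        assert e.sn == 1.0

    def test_expected_count_table_recovers_truth(self):
        # expected counts for p=0.1, Sn=0.9, Sp=0.6 at N=100
        e = estimate_fda(CellCounts(s11=9, s10=36, s01=1, s00=54))
        assert e.sn == pytest.approx(0.9)
        assert e.sp == pytest.approx(0.6)

    def test_rejects_partial_data(self, toy_counts):
        with pytest.raises(ValueError, match="fully verified"):
            estimate_fda(toy_counts)

    def test_empty_disease_class_is_an_error(self):
        with pytest.raises(ValueError, match="undefined"):
            estimate_fda(CellCounts(s11=0, s10=5, s01=0, s00=5))


class TestCca:
    def test_toy_fixture(self, toy_counts):
        e = estimate_cca(toy_counts)
        assert e.sn == pytest.approx(40 / 45)
        assert e.sp == pytest.approx(20 / 30)

    def test_equals_fda_on_fully_verified_data(self):
        c = CellCounts(s11=30, s10=12, s01=8, s00=50)
        assert estimate_cca(c).sn == estimate_fda(c).sn
        assert estimate_cca(c).sp == estimate_fda(c).sp

    def test_asymptotic_limit_closed_form(self):
        sn_lim, sp_lim = cca_asymptotic_sn_sp(0.6, 0.6, 0.8, 0.4)
        assert sn_lim == pytest.approx(0.75)
        assert sp_lim == pytest.approx(0.42857142857)
        # expected verified counts reproduce the limit exactly
        c = CellCounts(s11=192, s10=192, s01=64, s00=144, u1=48, u0=360)
        e = estimate_cca(c)
        assert e.sn == pytest.approx(sn_lim)
        assert e.sp == pytest.approx(sp_lim)


class TestBg:
    def test_toy_fixture_hand_arithmetic(self, toy_counts):
        e = estimate_bg(toy_counts)
        assert e.sn == pytest.approx(0.8)
        assert e.sp == pytest.approx(0.8)

    def test_equals_fda_under_full_verification(self):
        c = CellCounts(s11=33, s10=17, s01=11, s00=39)
        f = estimate_fda(c)
        b = estimate_bg(c)
        assert b.sn == pytest.approx(f.sn, abs=1e-12)
        assert b.sp == pytest.approx(f.sp, abs=1e-12)

    @pytest.mark.parametrize(
        "p, sn, sp", [(0.4, 0.6, 0.6), (0.1, 0.9, 0.6), (0.4, 0.6, 0.9)]
    )
    def test_expected_counts_recover_truth_under_mar(self, p, sn, sp):
        """BG applied to the expected-count table is exactly unbiased."""
        n = 100000
        pi = (sn * p, (1 - sn) * p, (1 - sp) * (1 - p), sp * (1 - p))
        c = CellCounts(
            s11=round(pi[0] * n * 0.8),
            s10=round(pi[2] * n * 0.8),
            s01=round(pi[1] * n * 0.4),
            s00=round(pi[3] * n * 0.4),
            u1=round((pi[0] + pi[2]) * n * 0.2),
            u0=round((pi[1] + pi[3]) * n * 0.6),
        )
        e = estimate_bg(c)
        assert e.sn == pytest.approx(sn, abs=1e-12)
        assert e.sp == pytest.approx(sp, abs=1e-12)

    def test_empty_verified_stratum_is_an_error(self):
        with pytest.raises(ValueError, match="both test strata"):
            estimate_bg(CellCounts(s11=10, s10=5, s01=0, s00=0, u0=20))


class TestIpwe:
    def test_toy_fixture_hand_arithmetic(self, toy_counts):
        ps = PropensityModel(ps_t1=1.0, ps_t0=0.5, source="known")
        e = estimate_ipwe(toy_counts, ps)
        assert e.sn == pytest.approx(0.8)
        assert e.sp == pytest.approx(0.8)

    def test_unit_propensity_reduces_to_cca(self, toy_counts):
        ps = PropensityModel(ps_t1=1.0, ps_t0=1.0, source="known")
        e = estimate_ipwe(toy_counts, ps)
        c = estimate_cca(toy_counts)
        assert e.sn == pytest.approx(c.sn)
        assert e.sp == pytest.approx(c.sp)

    @given(
        s11=st.integers(1, 200),
        s10=st.integers(1, 200),
        s01=st.integers(1, 200),
        s00=st.integers(1, 200),
        u1=st.integers(0, 200),
        u0=st.integers(0, 200),
    )
    @settings(max_examples=100, derandomize=True)
    def test_identity_with_bg_under_saturated_fit(self, s11, s10, s01, s00, u1, u0):
        """IPWE with the stratum-proportion propensity equals Begg-Greenes."""
        c = CellCounts(s11=s11, s10=s10, s01=s01, s00=s00, u1=u1, u0=u0)
        ipwe = estimate_ipwe(c)
        bg = estimate_bg(c)
        assert abs(ipwe.sn - bg.sn) < 1e-12
        assert abs(ipwe.sp - bg.sp) < 1e-12

    def test_bca_interval_contains_point(self, toy_counts, rng):
        e = estimate_ipwe(toy_counts, ci_boot=500, rng=rng)
        assert e.sn_ci[0] <= e.sn <= e.sn_ci[1]
        assert e.sp_ci[0] <= e.sp <= e.sp_ci[1]


class TestImputeAndMi:
    def test_no_missing_data_reduces_to_fda(self, rng):
        c = CellCounts(s11=40, s10=10, s01=10, s00=40)
        imps = impute_disease(c, m=5, rng=rng)
        assert np.ptp(imps.sn) == 0
        e = estimate_mi(imps)
        assert e.sn == pytest.approx(estimate_fda(c).sn)
        assert e.sp == pytest.approx(estimate_fda(c).sp)

    def test_imputed_rate_tracks_observed_stratum_rate(self, toy_counts):
        """Mean imputed disease probability in the T=0 stratum stays near
        the observed 5/25 = 0.2 (posterior-draw curvature allows a little
        upward drift)."""
        rng = np.random.default_rng(4)
        imps = impute_disease(toy_counts, m=2000, rng=rng)
        # u0=25 unverified T=0 subjects; reconstruct imputed diseased count
        # from each imputation's completed Sn denominator: n_d1 = 45 + d0
        n_d1 = np.round(40 / imps.sn).astype(int)
        d0 = n_d1 - 45
        assert abs(d0.mean() / 25 - 0.2) < 0.05

    def test_perfect_separation_raises_by_default(self, rng):
        c = CellCounts(s11=10, s10=5, s01=0, s00=20, u1=3, u0=30)
        with pytest.raises(ValueError, match="separation"):
            impute_disease(c, m=5, rng=rng)
        imps = impute_disease(c, m=50, rng=rng, on_separation="augment")
        assert imps.m == 50

    def test_pooled_estimates_within_unit_interval(self, toy_counts, rng):
        e = estimate_mi(impute_disease(toy_counts, m=30, rng=rng))
        assert 0 <= e.sn <= 1 and 0 <= e.sp <= 1
        assert e.sn_ci[0] <= e.sn <= e.sn_ci[1]


def _enumerate_weighted_multinomial_sn(n, q):
    """Exact E[Sn] of one weighted bootstrap sample by full enumeration,
    conditional on the drawn sample containing at least one diseased."""
    total_p = 0.0
    total_sn = 0.0
    for x11 in range(n + 1):
        for x10 in range(n + 1 - x11):
            for x01 in range(n + 1 - x11 - x10):
                x00 = n - x11 - x10 - x01
                p = stats.multinomial.pmf([x11, x10, x01, x00], n, q)
                if x11 + x01 > 0:
                    total_p += p
                    total_sn += p * x11 / (x11 + x01)
    return total_sn / total_p


class TestIpb:
    def test_constant_ps_reduces_to_plain_bootstrap_of_cca(self, rng):
        c = CellCounts(s11=40, s10=10, s01=10, s00=40, u1=10, u0=10)
        ps = PropensityModel(ps_t1=0.7, ps_t0=0.7, source="known")
        est, reps = estimate_ipb(c, ps=ps, b=4000, rng=rng)
        cca = estimate_cca(c)
        assert abs(est.sn - cca.sn) < 3 * est.sn_se
        assert abs(est.sp - cca.sp) < 3 * est.sp_se

    def test_toy_fixture_resampling_composition(self, toy_counts, rng):
        """Inverse-propensity mass makes both test strata equally likely
        per draw, so E(T=1 draws) = n/2 and Sn concentrates near 0.8."""
        ps = fit_propensity(toy_counts)
        reps = ipb_replicates_counts(toy_counts, ps, b=20000, rng=rng)
        assert reps.sn_reps.mean() == pytest.approx(0.8, abs=0.01)

    def test_weighted_replicates_match_exact_enumeration(self, rng):
        """Monte-Carlo replicate mean against exhaustive enumeration of the
        weighted four-cell multinomial at small n."""
        c = CellCounts(s11=2, s10=1, s01=1, s00=2, u1=2, u0=4)
        ps = PropensityModel(ps_t1=0.8, ps_t0=0.4, source="known")
        counts4 = np.array([2, 1, 1, 2], dtype=float)
        mass = counts4 / np.array([0.8, 0.8, 0.4, 0.4])
        q = mass / mass.sum()
        exact = _enumerate_weighted_multinomial_sn(c.n, q)
        reps = ipb_replicates_counts(c, ps, b=100000, rng=rng)
        mc_se = reps.sn_reps.std(ddof=1) / np.sqrt(len(reps.sn_reps))
        assert abs(reps.sn_reps.mean() - exact) < 4 * mc_se

    def test_count_path_matches_subject_path_distribution(self, toy_dataset):
        """KS agreement of the four-cell fast path with literal weighted
        resampling of subjects."""
        from pvb.data_model import reduce_to_counts

        c = reduce_to_counts(toy_dataset)
        ps = fit_propensity(c)
        fast = ipb_replicates_counts(c, ps, b=10000, rng=np.random.default_rng(1))
        slow = ipb_replicates_subject(
            toy_dataset, ps, b=2000, rng=np.random.default_rng(2)
        )
        ks = stats.ks_2samp(fast.sn_reps, slow.sn_reps)
        assert ks.pvalue > 0.01

    def test_point_estimate_and_ci_structure(self, toy_counts, rng):
        est, reps = estimate_ipb(toy_counts, b=2000, rng=rng)
        assert 0 <= est.sn <= 1
        assert est.sn_ci[0] <= est.sn <= est.sn_ci[1]
        assert reps.b_requested == 2000
        assert len(reps.sn_reps) + reps.n_degenerate >= len(reps.sn_reps)

    def test_plugin_point_equals_ipwe(self, toy_counts, rng):
        est, _ = estimate_ipb(toy_counts, b=100, rng=rng, point="plugin")
        ipwe = estimate_ipwe(toy_counts)
        assert est.sn == pytest.approx(ipwe.sn)
        assert est.sp == pytest.approx(ipwe.sp)

    def test_rng_is_required(self, toy_counts):
        with pytest.raises(ValueError, match="rng"):
            estimate_ipb(toy_counts, b=100)


def test_all_methods_coincide_on_fully_verified_data(rng):
    """With nothing missing every estimator returns the same Sn/Sp (up to
    Monte-Carlo error for the resampling-based ones)."""
    cfg = ScenarioConfig(p=0.4, sn_true=0.6, sp_true=0.6, n=4000, seed=8)
    complete, _ = generate_replicate_counts(cfg, np.random.default_rng(8))
    c = complete.as_counts()
    fda = estimate_fda(c)
    assert estimate_cca(c).sn == pytest.approx(fda.sn)
    assert estimate_bg(c).sn == pytest.approx(fda.sn, abs=1e-12)
    assert estimate_ipwe(c).sn == pytest.approx(fda.sn, abs=1e-12)
    mi = estimate_mi(impute_disease(c, m=10, rng=rng))
    assert mi.sn == pytest.approx(fda.sn)
    ipb, _ = estimate_ipb(c, b=3000, rng=rng)
    assert abs(ipb.sn - fda.sn) < 3 * ipb.sn_se
    assert abs(ipb.sp - fda.sp) < 3 * ipb.sp_se
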