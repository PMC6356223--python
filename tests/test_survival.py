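import warnings

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test as lifelines_logrank

from cnvdrive.survival import (
    SurvivalError,
    density_intersection_threshold,
    dichotomize,
    km_estimate,
    logrank_and_hr,
    mfs_analysis,
)


class TestKaplanMeier:
    def test_no_events_means_flat_curve(self):
        curve = km_estimate([5, 8], [0, 0])
        assert np.allclose(curve.survival, 1.0)

    def test_three_subject_product_limit(self):
        curve = km_estimate([1, 2, 3], [1, 1, 0])
        # S(1)=2/3, S(2)=1/3, unchanged at the censoring time 3
        by_time = dict(zip(curve.times, curve.survival))
        assert by_time[1.0] == pytest.approx(2 / 3)
        assert by_time[2.0] == pytest.approx(1 / 3)
        assert by_time[3.0] == pytest.approx(1 / 3)

    def test_curve_monotone_and_matches_ecdf_without_censoring(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(10, size=50)
        curve = km_estimate(times, np.ones(50, dtype=int))
        assert (np.diff(curve.survival) <= 1e-12).all()
        assert curve.survival[0] <= 1.0
        # no censoring → product-limit equals the empirical survival function
        for t, s in zip(curve.times, curve.survival):
            assert s == pytest.approx((times > t).mean(), abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(SurvivalError):
            km_estimate([], [])


def _logrank_oracle(times, events, g1_mask):
    """Independent per-event-time O/E/V accumulation."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    o1 = e1 = v = 0.0
    for t in sorted(set(times[events == 1])):
        at = times >= t
        n, n1 = at.sum(), (at & g1_mask).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & g1_mask).sum()
        o1 += d1
        e1 += d * n1 / n
        if n > 1:
            v += d * n1 / n * (1 - n1 / n) * (n - d) / (n - 1)
    return (o1 - e1) ** 2 / v, o1, e1


class TestLogRank:
    def test_identical_groups_are_null(self):
        times = [2, 4, 6, 8, 2, 4, 6, 8]
        events = [1, 1, 0, 1, 1, 1, 0, 1]
        groups = ["a"] * 4 + ["b"] * 4
        res = logrank_and_hr(times, events, groups)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)
        assert res.hazard_ratio == pytest.approx(1.0)

    def test_six_subject_fixture_matches_hand_accumulation(self):
        times = [1.0, 3.0, 5.0, 2.0, 4.0, 6.0]
        events = [1, 1, 0, 1, 1, 1]
        groups = np.array(["a", "a", "a", "b", "b", "b"])
        res = logrank_and_hr(times, events, groups)
        stat, o1, e1 = _logrank_oracle(times, events, groups == "a")
        assert res.statistic == pytest.approx(stat)
        assert res.observed[0] == pytest.approx(o1)
        assert res.expected[0] == pytest.approx(e1)
        total = sum(events)
        assert sum(res.observed) == pytest.approx(total)
        assert sum(res.expected) == pytest.approx(total)

    def test_agrees_with_lifelines_on_random_data(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            n = 60
            groups = rng.random(n) < 0.5
            times = rng.exponential(np.where(groups, 5, 10))
            events = (rng.random(n) < 0.7).astype(int)
            if groups.all() or not groups.any():
                continue
            res = logrank_and_hr(times, events, np.where(groups, "g1", "g0"))
            ref = lifelines_logrank(
                times[groups], times[~groups], events[groups], events[~groups]
            )
            assert res.statistic == pytest.approx(ref.test_statistic, rel=1e-6)
            assert res.p == pytest.approx(ref.p_value, rel=1e-6)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        times = rng.exponential(8, 30)
        events = (rng.random(30) < 0.6).astype(int)
        groups = np.where(rng.random(30) < 0.5, "x", "y")
        r1 = logrank_and_hr(times, events, groups)
        swapped = np.where(groups == "x", "y", "x")
        r2 = logrank_and_hr(times, events, swapped)
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p == pytest.approx(r2.p)

    def test_explicit_reference_group_inverts_hr(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(8, 40)
        events = np.ones(40, dtype=int)
        groups = np.array(["low"] * 20 + ["high"] * 20)
        a = logrank_and_hr(times, events, groups, group1="low")
        b = logrank_and_hr(times, events, groups, group1="high")
        assert a.hazard_ratio == pytest.approx(1 / b.hazard_ratio)


class TestDensityThreshold:
    def test_equal_variance_normals_cross_at_midpoint(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 2000)
        b = rng.normal(2, 1, 2000)
        res = density_intersection_threshold(a, b)
        assert abs(res.threshold - 1.0) < 0.05
        assert not res.fallback

    def test_identical_groups_fall_back_to_mean(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 200)
        with pytest.warns(UserWarning, match="pooled mean"):
            res = density_intersection_threshold(a, a.copy())
        assert res.fallback
        assert res.threshold == pytest.approx(a.mean(), abs=1e-9)

    def test_zero_variance_group_falls_back_to_midpoint_of_means(self):
        b = np.random.default_rng(6).normal(3, 1, 50)
        with pytest.warns(UserWarning, match="midpoint"):
            res = density_intersection_threshold(np.full(20, 1.0), b)
        assert res.threshold == pytest.approx((1.0 + b.mean()) / 2)

    def test_bimodal_fixture_matches_finer_grid_scan(self):
        """With a bimodal group the density difference crosses zero several
        times; the crossing restricted to the median window and nearest the
        midpoint of the group medians must match a 10×-resolution grid scan."""
        rng = np.random.default_rng(7)
        # group A: bimodal (modes at 0 and 4); group B: unimodal in A's valley
        a = np.concatenate([rng.normal(0, 0.5, 360), rng.normal(4, 0.5, 240)])
        b = rng.normal(1.8, 0.5, 600)
        res = density_intersection_threshold(a, b, grid_size=1024)
        from scipy.stats import gaussian_kde

        kde_a, kde_b = gaussian_kde(a, "silverman"), gaussian_kde(b, "silverman")
        bw = max(kde_a.factor * a.std(ddof=1), kde_b.factor * b.std(ddof=1))
        pooled = np.concatenate([a, b])
        grid = np.linspace(pooled.min() - 3 * bw, pooled.max() + 3 * bw, 10240)
        diff = kde_a(grid) - kde_b(grid)
        sign_change = np.nonzero(np.sign(diff[:-1]) * np.sign(diff[1:]) < 0)[0]
        assert len(sign_change) > 1  # the restriction logic is exercised
        med_a, med_b = np.median(a), np.median(b)
        w_lo, w_hi = min(med_a, med_b), max(med_a, med_b)
        cands = [
            g for i in sign_change
            if w_lo <= (g := grid[i]) <= w_hi
        ]
        mid = (med_a + med_b) / 2
        fine = min(cands, key=lambda x: abs(x - mid))
        assert res.threshold == pytest.approx(fine, abs=(grid[1] - grid[0]) * 12)


class TestDichotomize:
    def test_mean_cutoff_boundary_is_high(self):
        values = pd.Series([1, 2, 3, 6], index=list("abcd"), dtype=float)
        labels, cut = dichotomize(values, "mean")
        assert cut == pytest.approx(3.0)
        assert labels.tolist() == ["low", "low", "high", "high"]

    def test_fixed_threshold_below_min_puts_all_high(self):
        values = pd.Series([5.0, 6.0], index=["a", "b"])
        with pytest.warns(UserWarning):
            labels, _ = dichotomize(values, "fixed", threshold=0.0)
        assert (labels == "high").all()

    def test_matches_elementwise_comparison(self):
        rng = np.random.default_rng(8)
        values = pd.Series(rng.normal(7, 1, 50))
        labels, cut = dichotomize(values, "fixed", threshold=7.0)
        for v, lab in zip(values, labels):
            assert lab == ("low" if v < 7.0 else "high")


class TestMfsAnalysis:
    @pytest.fixture()
    def prepared(self, small_cohort):
        from cnvdrive.cnv import aggregate_gene_status, filter_probes
        from cnvdrive.expression import select_representative_probes

        sim = small_cohort
        cnv, _ = filter_probes(
            sim.bundle.cnv, constitutional_regions=sim.constitutional_regions
        )
        cnv = cnv.subset_samples(cnv.tumor_samples)
        status = aggregate_gene_status(cnv)
        rep = select_representative_probes(sim.bundle.expr)
        return sim, rep, status

    def test_driver_low_stratum_has_worse_survival(self, prepared):
        sim, rep, status = prepared
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sa = mfs_analysis(
                sim.bundle, sim.truth.driver_gene, rep, status,
                method="density_intersection",
            )
        assert sa.logrank.hazard_ratio > 1.0
        assert set(sa.curves) == {"low", "high"}

    def test_all_unknown_chemotherapy_is_hard_error(self, prepared):
        sim, rep, status = prepared
        clin = sim.bundle.clinical.data.copy()
        clin["chemotherapy"] = pd.array([pd.NA] * len(clin), dtype="boolean")
        bundle = type(sim.bundle)(
            cnv=sim.bundle.cnv, expr=sim.bundle.expr,
            clinical=type(sim.bundle.clinical)(clin),
            pathways=sim.bundle.pathways,
        )
        with pytest.raises(SurvivalError, match="chemotherapy"):
            mfs_analysis(bundle, sim.truth.driver_gene, rep, status, subset="chemo")

    def test_metastatic_at_diagnosis_exclusion_bookkeeping(self, prepared):
        sim, rep, status = prepared
        clin = sim.bundle.clinical.data.copy()
        flagged = clin.index[:5]
        clin.loc[flagged, "metastatic_at_diagnosis"] = True
        clin.loc[flagged, "metastasis"] = True
        bundle = type(sim.bundle)(
            cnv=sim.bundle.cnv, expr=sim.bundle.expr,
            clinical=type(sim.bundle.clinical)(clin),
            pathways=sim.bundle.pathways,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sa_excl = mfs_analysis(
                bundle, sim.truth.driver_gene, rep, status, method="mean",
                exclude_metastatic_at_diagnosis=True,
            )
            sa_incl = mfs_analysis(
                bundle, sim.truth.driver_gene, rep, status, method="mean",
                exclude_metastatic_at_diagnosis=False,
            )
        assert sa_excl.n_excluded_metastatic_at_diagnosis == 5
        assert len(sa_incl.strata) - len(sa_excl.strata) == 5
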