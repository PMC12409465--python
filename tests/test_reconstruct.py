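import warnings

import numpy as np
import pytest

from kmipd import (
    PERFECT_DIGITIZER,
    ArmTotals,
    AtRiskTable,
    DigitizedCurve,
    IPDataset,
    cox_hr,
    default_scenario,
    km_estimate,
    preprocess_curve,
    reconstruct_arm,
    render_digitized,
    simulate_trial,
    split_intervals,
)
from kmipd.reconstruct import _round_half_up

from conftest import make_small_ipd


def curve_of(points, preprocessed=True) -> DigitizedCurve:
    t, s = zip(*points)
    return DigitizedCurve(np.array(t), np.array(s), preprocessed=preprocessed)


def exact_render(ipd: IPDataset, atrisk_times):
    """Noise-free digitization of one arm's exact KM step corners."""
    return render_digitized(ipd, PERFECT_DIGITIZER, atrisk_times)


class TestSplitIntervals:
    def test_basic_binning(self):
        c = curve_of([(0, 1), (2, 0.9), (4, 0.8), (6, 0.7)])
        bins, _ = split_intervals(c, AtRiskTable([0, 5], [10, 7]))
        assert [b.tolist() for b in bins] == [[0, 1, 2], [3]]

    def test_single_at_risk_time_one_bin(self):
        c = curve_of([(0, 1), (2, 0.9), (4, 0.8)])
        bins, _ = split_intervals(c, AtRiskTable([0], [10]))
        assert bins[0].tolist() == [0, 1, 2]

    def test_boundary_click_goes_to_later_interval(self):
        c = curve_of([(0, 1), (5, 0.9), (6, 0.8)])
        bins, _ = split_intervals(c, AtRiskTable([0, 5], [10, 9]))
        assert [b.tolist() for b in bins] == [[0], [1, 2]]

    def test_trailing_at_risk_entries_dropped_with_warning(self):
        c = curve_of([(0, 1), (2, 0.9)])
        with pytest.warns(UserWarning, match="beyond the last click"):
            bins, table = split_intervals(c, AtRiskTable([0, 10], [10, 5]))
        assert len(table) == 1
        assert bins[0].tolist() == [0, 1]


class TestRounding:
    @pytest.mark.parametrize(
        "x,expected", [(0.5, 1), (1.5, 2), (2.49, 2), (-0.5, 0), (2.5, 3)]
    )
    def test_half_up(self, x, expected):
        assert _round_half_up(x) == expected


class TestReconstructArm:
    def test_flat_curve_all_censoring(self):
        # no drops: the at-risk decline is pure censoring, spread evenly
        c = curve_of([(0, 1), (10, 1)])
        res = reconstruct_arm(c, AtRiskTable([0, 10], [100, 80]))
        ipd = res.ipd
        assert len(ipd) == 100
        assert ipd.n_events == 0
        inner = ipd.time[(ipd.time > 0) & (ipd.time < 10)]
        assert inner.size == 20
        np.testing.assert_allclose(np.sort(inner), np.arange(1, 21) * 10 / 21)
        assert (ipd.time == 10).sum() == 80
        assert res.converged

    @pytest.mark.parametrize("seed,n", [(1, 20), (2, 35), (3, 50), (4, 12)])
    def test_roundtrip_exactness_small_datasets(self, seed, n):
        # exact step coordinates + at-risk at every event time + true
        # totals recover event times and counts exactly (oracle = source)
        src = make_small_ipd(seed, n)
        km = km_estimate(src)
        atrisk_times = np.concatenate(([0.0], km.times))
        raw, table, totals = exact_render(src, atrisk_times)
        curve, _ = preprocess_curve(raw)
        res = reconstruct_arm(curve, table, totals)
        rec = res.ipd
        np.testing.assert_allclose(
            np.sort(rec.time[rec.event == 1]), np.sort(src.time[src.event == 1])
        )
        assert rec.n_events == src.n_events
        assert len(rec) == len(src)
        km_rec = km_estimate(rec)
        np.testing.assert_allclose(km_rec.times, km.times)
        np.testing.assert_allclose(km_rec.surv, km.surv)

    def test_published_at_risk_counts_reproduced(self):
        src = make_small_ipd(7, 40)
        atrisk_times = np.arange(0.0, src.time.max() + 1, 5.0)
        raw, table, totals = exact_render(src, atrisk_times)
        curve, _ = preprocess_curve(raw)
        res = reconstruct_arm(curve, table, totals)
        assert res.converged
        # direct counting on the reconstruction reproduces every
        # published at-risk count at its published time
        for t, n in zip(table.times, table.counts):
            assert (res.ipd.time >= t - 1e-9).sum() == n

    def test_conservation_and_n_total(self):
        src = make_small_ipd(11, 30)
        raw, table, totals = exact_render(src, [0.0, 8.0, 16.0])
        curve, _ = preprocess_curve(raw)
        res = reconstruct_arm(curve, table, totals)
        assert len(res.ipd) == totals.n_total
        res2 = reconstruct_arm(curve, table, ArmTotals())
        assert len(res2.ipd) == table.counts[0]

    def test_determinism(self):
        src = make_small_ipd(13, 25)
        raw, table, totals = exact_render(src, [0.0, 10.0])
        curve, _ = preprocess_curve(raw)
        a = reconstruct_arm(curve, table, totals)
        b = reconstruct_arm(curve, table, totals)
        np.testing.assert_array_equal(a.ipd.time, b.ipd.time)
        np.testing.assert_array_equal(a.ipd.event, b.ipd.event)

    def test_two_arm_hr_close_to_source_fit(self):
        # perfect digitization: Cox HR on reconstructed data within 5%
        # of the Cox HR on the source data (oracle = source-data fit)
        sc = default_scenario(seed=21)
        ipd = simulate_trial(sc)
        hr_src = cox_hr(ipd)
        atrisk_times = np.arange(0.0, 36.1, 4.5)
        arms = []
        for a in (0, 1):
            arm = ipd.select_arm(a)
            raw, table, totals = exact_render(arm, atrisk_times)
            curve, _ = preprocess_curve(raw)
            res = reconstruct_arm(curve, table, totals)
            arms.append(
                IPDataset(res.ipd.time, res.ipd.event, np.full(len(res.ipd), a, int))
            )
        hr_rec = cox_hr(IPDataset.concat(arms))
        assert abs(hr_rec.hr - hr_src.hr) / hr_src.hr < 0.05

    def test_curve_fidelity_noise_free(self):
        # KM of the reconstruction tracks the read-in curve closely
        arm = simulate_trial(default_scenario(seed=5)).select_arm(0)
        raw, table, totals = exact_render(arm, np.arange(0.0, 36.1, 4.5))
        curve, _ = preprocess_curve(raw)
        res = reconstruct_arm(curve, table, totals)
        assert res.fit_stats["rmse"] < 0.02

    def test_unattainable_constraint_flagged(self):
        # counts demand more survivors than the curve's drops allow
        c = curve_of([(0, 1), (5, 0.2), (10, 0.1)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = reconstruct_arm(c, AtRiskTable([0, 10], [10, 9]))
        assert not res.converged
        sol = res.solutions[0]
        assert sol.residual != 0
        assert sol.c_k == 0  # censoring clamped at zero, minimal residual

    def test_no_at_risk_mode_warns(self):
        src = make_small_ipd(17, 30)
        raw, _, totals = exact_render(src, [0.0])
        curve, _ = preprocess_curve(raw)
        with pytest.warns(UserWarning, match="unreliable"):
            res = reconstruct_arm(
                curve, AtRiskTable([0.0], [len(src)]), ArmTotals(n_total=len(src))
            )
        assert len(res.ipd) == len(src)

    def test_d_total_forces_event_deficit_distribution(self):
        # censoring hidden in the final unanchored interval: without
        # d_total events are overcounted there; d_total corrects the total
        src = make_small_ipd(19, 40, cens_frac=0.4)
        raw, table, totals = exact_render(src, [0.0, 6.0])
        curve, _ = preprocess_curve(raw)
        with_t = reconstruct_arm(curve, table, totals)
        assert with_t.ipd.n_events == src.n_events

    def test_interval_solutions_recorded_per_published_time(self):
        src = make_small_ipd(23, 30)
        raw, table, totals = exact_render(src, [0.0, 8.0, 16.0])
        curve, _ = preprocess_curve(raw)
        res = reconstruct_arm(curve, table, totals)
        assert len(res.solutions) == len(table)
        assert all(s.residual == 0 for s in res.solutions[:-1])
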