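"""AUC reduction, % antinociception and group statistics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import isobolab as il
from isobolab.metrics import ComputationError

from conftest import GRID, make_group, make_timecourse


def piecewise_linear_auc_oracle(times, counts, t0, t1):
    """Exact integral of the linear interpolant: midpoint rule per segment.

    The midpoint rule is exact on each linear piece, so summing it over the
    knot-aligned segmentation of [t0, t1] is an independent closed-form
    oracle for the trapezoid implementation.
    """
    times = np.asarray(times, float)
    knots = np.unique(np.concatenate([[t0, t1], times[(times > t0) & (times < t1)]]))
    total = 0.0
    for a, b in zip(knots, knots[1:]):
        mid = np.interp(0.5 * (a + b), times, counts)
        total += mid * (b - a)
    return total


counts_strategy = st.lists(
    st.integers(min_value=0, max_value=30), min_size=13, max_size=13
).map(tuple)


class TestTrapezoidAuc:
    def test_constant_rate_rectangle(self):
        assert il.trapezoid_auc(GRID, [2] * 13, (0, 60)) == pytest.approx(120.0)

    def test_triangle(self):
        assert il.trapezoid_auc([0, 5, 10], [0, 4, 0], (0, 10)) == pytest.approx(20.0)

    def test_window_partition_additivity(self):
        full = il.trapezoid_auc(GRID, [4] * 13, (0, 60))
        p1 = il.trapezoid_auc(GRID, [4] * 13, (0, 15))
        p2 = il.trapezoid_auc(GRID, [4] * 13, (15, 60))
        assert (p1, p2) == (pytest.approx(60.0), pytest.approx(180.0))
        assert p1 + p2 == pytest.approx(full) == pytest.approx(240.0)

    @pytest.mark.parametrize(
        "times,counts,window",
        [
            (GRID, [1] * 13, (30, 30)),  # inverted/empty window
            ([0, 5], [1, 1], (0, 10)),  # window beyond data
            ([0], [1], (0, 0)),  # single point
        ],
    )
    def test_bad_windows_rejected(self, times, counts, window):
        with pytest.raises(ValueError):
            il.trapezoid_auc(times, counts, window)

    @given(
        counts=counts_strategy,
        window=st.tuples(
            st.floats(min_value=0, max_value=29), st.floats(min_value=31, max_value=60)
        ),
    )
    def test_matches_midpoint_oracle(self, counts, window):
        t0, t1 = window
        ours = il.trapezoid_auc(GRID, counts, (t0, t1))
        oracle = piecewise_linear_auc_oracle(GRID, counts, t0, t1)
        assert ours == pytest.approx(oracle, abs=1e-9)


class TestSplitPhases:
    def test_constant_rate_closed_form(self):
        tc = make_timecourse((2,) * 13)
        auc = il.split_phase_aucs(tc)
        assert auc.phase1 == pytest.approx(30.0)
        assert auc.phase2 == pytest.approx(90.0)
        assert auc.overall == pytest.approx(120.0)

    def test_all_zero(self):
        auc = il.split_phase_aucs(make_timecourse((0,) * 13))
        assert (auc.phase1, auc.phase2, auc.overall) == (0.0, 0.0, 0.0)

    def test_early_plateau_then_decay_hand_oracle(self):
        # 6 flinches/min through 15 min, linear drop to 0 at 20, zero after:
        # phase 1 = 6*15 = 90; phase 2 = triangle 15->20 = 15; overall 105.
        counts = (6, 6, 6, 6) + (0,) * 9
        auc = il.split_phase_aucs(make_timecourse(counts))
        assert auc.phase1 == pytest.approx(90.0)
        assert auc.phase2 == pytest.approx(15.0)
        assert auc.overall == pytest.approx(105.0)

    @given(counts=counts_strategy)
    def test_phase_partition_exact(self, counts):
        auc = il.split_phase_aucs(make_timecourse(counts))
        assert auc.phase1 + auc.phase2 == pytest.approx(auc.overall, rel=1e-12)


class TestPercentAntinociception:
    @pytest.mark.parametrize(
        "vehicle,treated,expected",
        [(600, 600, 0.0), (600, 0, 100.0), (600, 420, 30.0), (600, 900, -50.0)],
    )
    def test_formula(self, vehicle, treated, expected):
        assert il.percent_antinociception(vehicle, treated) == pytest.approx(expected)

    def test_degenerate_vehicle_rejected(self):
        with pytest.raises(ComputationError):
            il.percent_antinociception(0.0, 10.0)

    @given(
        a=st.floats(min_value=0, max_value=1e3),
        b=st.floats(min_value=0, max_value=1e3),
        ref=st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_strictly_decreasing_in_treated_auc(self, a, b, ref):
        lo, hi = sorted([a, b])
        if lo == hi:
            return
        assert il.percent_antinociception(ref, lo) > il.percent_antinociception(ref, hi)


class TestSummarizeGroup:
    def test_self_comparison_is_zero(self, vehicle_group):
        s = il.summarize_group(vehicle_group, vehicle_group)
        assert s.effect_overall == pytest.approx(0.0, abs=1e-9)
        assert s.n == 6

    def test_halved_counts_give_50_percent(self, vehicle_group):
        halved = make_group(
            [tuple(c // 2 for c in tc.counts) for tc in vehicle_group.members],
            label="treated",
        )
        # integer halving of even counts only, to keep the ratio exact
        even = make_group(
            [tuple(2 * (c // 2) for c in tc.counts) for tc in vehicle_group.members],
            label="veh-even",
            is_vehicle=True,
        )
        s = il.summarize_group(halved, even)
        assert s.effect_overall == pytest.approx(50.0, abs=1e-9)

    def test_scaling_all_counts_leaves_effects_unchanged(self, vehicle_group):
        treated = make_group(
            [tuple(max(0, c - 1) for c in tc.counts) for tc in vehicle_group.members],
            label="treated",
        )
        base = il.summarize_group(treated, vehicle_group)
        scale = 3
        veh3 = make_group(
            [tuple(scale * c for c in tc.counts) for tc in vehicle_group.members],
            label="vehicle3x",
            is_vehicle=True,
        )
        trt3 = make_group(
            [tuple(scale * c for c in tc.counts) for tc in treated.members],
            label="treated3x",
        )
        scaled = il.summarize_group(trt3, veh3)
        assert scaled.effect_overall == pytest.approx(base.effect_overall, rel=1e-12)
        assert scaled.effect_phase1 == pytest.approx(base.effect_phase1, rel=1e-12)
        assert scaled.effect_phase2 == pytest.approx(base.effect_phase2, rel=1e-12)

    def test_recovers_true_suppression_at_large_n(self):
        # 30% true suppression; with n = 200 the mean % effect is within 2%.
        params = il.SimulationParams(seed=5, n_per_group=200)
        dose_a = il.ground_truth_ed(params, "A", level=30.0)
        study = il.simulate_study(
            params, [("vehicle", 0.0, 0.0), ("treated", dose_a, 0.0)]
        )
        vehicle = next(g for g in study if g.is_vehicle)
        treated = next(g for g in study if not g.is_vehicle)
        s = il.summarize_group(treated, vehicle)
        assert s.effect_overall == pytest.approx(30.0, abs=2.0)

    def test_requires_vehicle_flag(self, vehicle_group):
        unflagged = make_group(
            [tc.counts for tc in vehicle_group.members], label="notveh"
        )
        with pytest.raises(ValueError):
            il.summarize_group(vehicle_group, unflagged)


def _summary_from_values(label, values):
    values = tuple(float(v) for v in values)
    n = len(values)
    return il.AntinociceptionSummary(
        group_label=label,
        dose=1.0,
        effect_phase1=0.0,
        effect_phase2=0.0,
        effect_overall=float(np.mean(values)),
        se_overall=float(np.std(values, ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        n=n,
        auc_vehicle_ref=100.0,
        auc_mean=100.0,
        effects_overall=values,
    )


class TestAnovaBonferroni:
    def test_identical_groups_no_signal(self):
        g = _summary_from_values("a", [1, 1, 1, 1])
        h = _summary_from_values("b", [1, 1, 1, 1])
        res = il.anova_bonferroni([g, h], control_label="a")
        assert res.f_stat == 0.0
        assert res.p_value == 1.0
        assert res.comparisons[0][2] == 1.0

    def test_separated_group_flagged(self):
        rng = np.random.default_rng(0)
        groups = [
            _summary_from_values("control", rng.normal(0, 1e-6, 6)),
            _summary_from_values("null", rng.normal(0, 1e-6, 6)),
            _summary_from_values("active", rng.normal(50, 1e-6, 6)),
        ]
        res = il.anova_bonferroni(groups, control_label="control")
        adj = {label: p_adj for label, _, p_adj in res.comparisons}
        assert adj["active"] < 0.001
        assert adj["null"] > 0.05

    def test_small_group_rejected(self):
        g = _summary_from_values("a", [1.0])
        h = _summary_from_values("b", [1, 2])
        with pytest.raises(ValueError):
            il.anova_bonferroni([g, h], control_label="a")

    def test_type_i_error_controlled(self):
        # 1000 studies of 3 equal-mean groups: familywise rejection <= alpha.
        rng = np.random.default_rng(42)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            groups = [
                _summary_from_values(lab, rng.normal(20.0, 8.0, 6))
                for lab in ("control", "g1", "g2")
            ]
            res = il.anova_bonferroni(groups, control_label="control")
            if any(p_adj < 0.05 for _, _, p_adj in res.comparisons):
                rejections += 1
        assert rejections / n_rep <= 0.05
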