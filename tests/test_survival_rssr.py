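from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp

from crtscan import (
    CRTSet,
    InterpolatedCurve,
    RSSRProfile,
    ProfileEntry,
    SurvivalCurve,
    compute_mbp_grid,
    detect_mbp_star,
    interpolate,
    rssr,
    rssr_profile,
    survival_curve,
)
from oracles import brute_interpolate_at, brute_rssr, brute_survival


def curve_from_durations(durations, mbp=1.0):
    frame = pd.DataFrame({"duration": durations, "animal_id": "f", "receiver_id": "A"})
    return survival_curve(CRTSet(mbp=mbp, frame=frame))


def step_value(curve, t):
    """Evaluate the survivor step function at an arbitrary t."""
    idx = np.searchsorted(curve.times, t, side="right") - 1
    return curve.survival[idx]


class TestSurvivalCurve:
    def test_fraction_strictly_larger(self):
        curve = curve_from_durations([1, 2, 3, 4])
        assert step_value(curve, 2.5) == 0.5
        assert brute_survival([1, 2, 3, 4], 2.5) == 0.5

    def test_all_durations_equal(self):
        curve = curve_from_durations([7, 7, 7])
        assert step_value(curve, 6.9) == 1.0
        assert step_value(curve, 7) == 0.0

    def test_zero_duration_crts_enter_the_curve(self):
        curve = curve_from_durations([0, 0, 5])
        assert step_value(curve, 0) == pytest.approx(1 / 3)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            curve_from_durations([])

    def test_per_animal_restriction(self):
        frame = pd.DataFrame(
            {
                "duration": [1, 2, 50],
                "animal_id": ["a", "a", "b"],
                "receiver_id": "A",
            }
        )
        curve = survival_curve(CRTSet(mbp=1, frame=frame), animal_id="a")
        assert curve.times[-1] == 2

    def test_matches_kaplan_meier_without_censoring(self):
        # with no censoring the Kaplan-Meier estimate reduces to the
        # empirical survivor function; lifelines is the independent route
        from lifelines import KaplanMeierFitter

        durations = [0, 0, 3, 5, 5, 9, 12]
        curve = curve_from_durations(durations)
        kmf = KaplanMeierFitter().fit(durations)
        for t, s in zip(curve.times, curve.survival):
            assert s == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0])
            )

    @given(
        durations=st.lists(
            st.integers(min_value=0, max_value=100), min_size=1, max_size=60
        )
    )
    def test_survivor_function_axioms(self, durations):
        curve = curve_from_durations(durations)
        s = curve.survival
        assert curve.times[0] == 0
        assert ((s >= 0) & (s <= 1)).all()
        assert (np.diff(s) <= 0).all()
        assert s[-1] == 0  # nothing exceeds the maximum duration
        for t, v in zip(curve.times, s):
            assert v == pytest.approx(brute_survival(durations, t))


class TestInterpolate:
    def test_midpoint_of_a_line(self):
        curve = SurvivalCurve(1, np.array([0.0, 10.0]), np.array([1.0, 0.5]))
        interp = interpolate(curve, 1, 100)
        assert interp.values[5] == pytest.approx(0.75)
        assert interp.defined.all()

    def test_wide_span_discarded(self):
        curve = SurvivalCurve(1, np.array([0.0, 200.0]), np.array([1.0, 0.2]))
        interp = interpolate(curve, 1, 100)
        assert interp.defined[0] and interp.defined[200]  # raw points survive
        assert not interp.defined[1:200].any()
        assert np.isnan(interp.values[1:200]).all()

    def test_no_extrapolation_beyond_last_point(self):
        curve = SurvivalCurve(1, np.array([0.0, 4.0]), np.array([1.0, 0.0]))
        interp = interpolate(curve, 3, 100)
        # grid stops at floor(4/3) * 3 = 3
        assert interp.values.size == 2

    @given(
        durations=st.lists(
            st.integers(min_value=0, max_value=300), min_size=1, max_size=40
        ),
        t_max=st.integers(min_value=1, max_value=150),
        step=st.sampled_from([1, 2, 5]),
    )
    def test_each_defined_value_matches_two_point_formula(self, durations, t_max, step):
        curve = curve_from_durations(durations)
        interp = interpolate(curve, step, t_max)
        times = curve.times.tolist()
        surv = curve.survival.tolist()
        for i, (value, defined) in enumerate(zip(interp.values, interp.defined)):
            expected = brute_interpolate_at(times, surv, i * step, t_max)
            if expected is None:
                assert not defined
            else:
                assert defined
                assert value == pytest.approx(expected)

    def test_nonpositive_parameters_rejected(self):
        curve = SurvivalCurve(1, np.array([0.0, 1.0]), np.array([1.0, 0.0]))
        with pytest.raises(ValueError):
            interpolate(curve, 0, 10)
        with pytest.raises(ValueError):
            interpolate(curve, 1, 0)


def make_interp(values, defined=None, step=1.0):
    values = np.asarray(values, dtype=float)
    if defined is None:
        defined = ~np.isnan(values)
    return InterpolatedCurve(1.0, step, values, np.asarray(defined))


class TestRSSR:
    def test_identical_curves_give_zero(self):
        a = make_interp([1.0, 0.5, 0.2])
        value, t_count = rssr(a, make_interp([1.0, 0.5, 0.2]))
        assert value == 0.0
        assert t_count == 3

    def test_constant_offset(self):
        a = make_interp([0.9, 0.5, 0.3, 0.1])
        b = make_interp([0.8, 0.4, 0.2, 0.0])
        value, t_count = rssr(a, b)
        assert value == pytest.approx(0.01)
        assert t_count == 4

    def test_symmetry(self):
        a = make_interp([1.0, 0.6, np.nan, 0.1])
        b = make_interp([0.9, np.nan, 0.3, 0.05])
        assert rssr(a, b) == rssr(b, a)

    def test_disjoint_defined_sets_error(self):
        a = make_interp([1.0, np.nan])
        b = make_interp([np.nan, 0.5])
        with pytest.raises(ValueError, match="no overlap"):
            rssr(a, b)

    def test_mismatched_grid_steps_error(self):
        with pytest.raises(ValueError, match="grid step"):
            rssr(make_interp([1.0], step=1), make_interp([1.0], step=2))

    def test_undefined_points_do_not_contribute(self):
        a = make_interp([1.0, 0.5, 0.25])
        b = make_interp([1.0, 0.5, 0.25])
        padded_a = make_interp([1.0, 0.5, 0.25, np.nan, np.nan])
        padded_b = make_interp([1.0, 0.5, 0.25, 0.9, np.nan])
        assert rssr(padded_a, padded_b) == rssr(a, b)

    def test_renormalization_is_scale_free_in_t(self):
        # duplicating the defined span doubles T but leaves the mean alone
        a = make_interp([0.9, 0.5])
        b = make_interp([0.8, 0.4])
        a2 = make_interp([0.9, 0.5, 0.9, 0.5])
        b2 = make_interp([0.8, 0.4, 0.8, 0.4])
        assert rssr(a2, b2)[0] == pytest.approx(rssr(a, b)[0])
        assert rssr(a2, b2)[1] == 2 * rssr(a, b)[1]

    @given(
        values=hnp.arrays(
            float,
            st.integers(min_value=1, max_value=30),
            elements=st.floats(0, 1),
        ),
        noise=hnp.arrays(
            float, 30, elements=st.floats(-0.5, 0.5)
        ),
        mask_seed=st.integers(0, 2**16),
    )
    def test_matches_bruteforce_accumulation(self, values, noise, mask_seed):
        n = values.size
        rng = np.random.default_rng(mask_seed)
        defined_a = rng.random(n) < 0.8
        defined_b = rng.random(n) < 0.8
        a = make_interp(values, defined_a)
        b = make_interp(np.clip(values + noise[:n], 0, 1), defined_b)
        expected, expected_t = brute_rssr(a.values, a.defined, b.values, b.defined)
        if expected is None:
            with pytest.raises(ValueError):
                rssr(a, b)
        else:
            value, t_count = rssr(a, b)
            assert value == pytest.approx(expected)
            assert t_count == expected_t


class TestProfile:
    def test_hand_traced_profile(self, tiny_table):
        # gaps 4 / 8 / 18: mbp=5 -> durations {4,0,0}; mbp=10,15 -> {12,0}
        grid = compute_mbp_grid(5, 3)
        profile = rssr_profile(tiny_table, grid, 1, 100)
        assert [e.mbp for e in profile.entries] == [5, 10]
        expected = Fraction(1, 5) * (
            (Fraction(1, 3) - Fraction(1, 2)) ** 2
            + (Fraction(1, 4) - Fraction(11, 24)) ** 2
            + (Fraction(1, 6) - Fraction(5, 12)) ** 2
            + (Fraction(1, 12) - Fraction(3, 8)) ** 2
            + (Fraction(0) - Fraction(1, 3)) ** 2
        )
        assert profile.entries[0].rssr == pytest.approx(float(expected))
        assert profile.entries[0].overlap == 5
        assert profile.entries[1].rssr == 0.0

    def test_gaps_below_grid_give_all_zero(self):
        from crtscan import DetectionTable

        table = DetectionTable.from_records(
            [("A", "f", t) for t in [0, 2, 4, 6, 20, 22, 24]]
        )
        profile = rssr_profile(table, compute_mbp_grid(50, 4), 1, 1000)
        assert (profile.values == 0).all()

    def test_deterministic(self, tiny_table):
        grid = compute_mbp_grid(5, 3)
        p1 = rssr_profile(tiny_table, grid, 1, 100)
        p2 = rssr_profile(tiny_table, grid, 1, 100)
        assert p1.entries == p2.entries

    def test_single_value_grid_rejected(self, tiny_table):
        with pytest.raises(ValueError, match=">= 2"):
            rssr_profile(tiny_table, compute_mbp_grid(5, 1), 1, 100)

    def test_export(self, tiny_table, tmp_path):
        profile = rssr_profile(tiny_table, compute_mbp_grid(5, 3), 1, 100)
        path = tmp_path / "profile.tsv"
        profile.write(path)
        back = pd.read_csv(path, sep="\t")
        assert list(back.columns) == ["mbp", "mbp_next", "rssr", "overlap"]
        assert len(back) == 2


def profile_of(values, delta=100):
    entries = [
        ProfileEntry(mbp=(i + 1) * delta, mbp_next=(i + 2) * delta, rssr=v, overlap=10)
        for i, v in enumerate(values)
    ]
    return RSSRProfile(delta_mbp=delta, entries=entries)


class TestDetectMBPStar:
    def test_all_zero_profile_returns_smallest_grid_value(self):
        assert detect_mbp_star(profile_of([0.0, 0.0, 0.0])) == 100

    def test_threshold_criterion(self):
        profile = profile_of([1.0, 0.5, 0.01, 0.005, 0.004])
        assert detect_mbp_star(profile, rel_threshold=0.05) == 300

    def test_never_stabilizing_returns_none(self):
        profile = profile_of([1.0, 0.01, 1.0, 0.9])
        assert detect_mbp_star(profile, rel_threshold=0.05) is None

    def test_min_run_requires_enough_tail_entries(self):
        profile = profile_of([1.0, 1.0, 1.0, 0.001])
        assert detect_mbp_star(profile, rel_threshold=0.05, min_run=1) == 400
        assert detect_mbp_star(profile, rel_threshold=0.05, min_run=2) is None

    def test_result_recorded_on_profile(self):
        profile = profile_of([1.0, 0.0, 0.0])
        star = detect_mbp_star(profile, rel_threshold=0.05)
        assert profile.mbp_star == star == 200

    def test_empty_profile(self):
        assert detect_mbp_star(RSSRProfile(delta_mbp=100, entries=[])) is None
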