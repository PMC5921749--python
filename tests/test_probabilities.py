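"""Product integral, state probability curves, contrasts and bootstrap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spellmsm.hazards import CumulativeHazard, nelson_aalen
from spellmsm.probabilities import (
    EmptyGroupError,
    InitialStateModel,
    StateProbabilityCurve,
    bootstrap_bands,
    build_intensity_path,
    contrast_curves,
    empirical_initial_distribution,
    product_integral,
    ratio_of_differences,
    state_probabilities,
)
from spellmsm.states import STATE_INDEX, STATES
from spellmsm.trajectories import StateTrajectory

from conftest import make_counting_table


def hz(transition, times, increments):
    return CumulativeHazard(transition, np.asarray(times), np.asarray(increments))


class TestIntensityPath:
    def test_single_increment_fills_one_row(self):
        path = build_intensity_path({("work", "unemployment"): hz(("work", "unemployment"), [1.0], [0.2])})
        step = np.eye(5) + path.increments[0]
        np.testing.assert_allclose(step[STATE_INDEX["work"]], [0.8, 0.2, 0, 0, 0])

    def test_no_hazards_give_identity_product(self):
        path = build_intensity_path({})
        np.testing.assert_array_equal(product_integral(path, 0, 10), np.eye(5))

    def test_diagonal_is_negative_row_sum(self):
        path = build_intensity_path(
            {
                ("work", "unemployment"): hz(("work", "unemployment"), [1.0], [0.2]),
                ("work", "education"): hz(("work", "education"), [1.0], [0.1]),
            }
        )
        assert path.increments[0, 0, 0] == pytest.approx(-0.3)

    def test_oversized_step_raises_naming_state_and_time(self):
        bad = {
            ("work", "unemployment"): hz(("work", "unemployment"), [2.5], [0.7]),
            ("work", "education"): hz(("work", "education"), [2.5], [0.5]),
        }
        with pytest.raises(ValueError, match="work") as err:
            build_intensity_path(bad)
        assert "2.5" in str(err.value)

    def test_truncation_mode_cuts_before_first_invalid_jump(self):
        bad = {
            ("work", "unemployment"): hz(("work", "unemployment"), [1.0, 2.5], [0.2, 0.7]),
            ("work", "education"): hz(("work", "education"), [2.5], [0.5]),
        }
        path = build_intensity_path(bad, on_invalid="truncate")
        assert path.truncated_at == 2.5
        assert path.times.tolist() == [1.0]

    def test_jump_times_merge_after_canonical_rounding(self):
        t = 3.123456789
        path = build_intensity_path(
            {
                ("work", "unemployment"): hz(("work", "unemployment"), [t + 2e-10], [0.1]),
                ("work", "education"): hz(("work", "education"), [t - 2e-10], [0.1]),
            }
        )
        assert len(path.times) == 1

    def test_hazard_out_of_disability_rejected(self):
        with pytest.raises(ValueError, match="disability"):
            build_intensity_path({("disability", "work"): hz(("disability", "work"), [1.0], [0.1])})


class TestProductIntegral:
    def test_equal_endpoints_give_identity(self):
        path = build_intensity_path({("work", "unemployment"): hz(("work", "unemployment"), [1.0], [0.2])})
        np.testing.assert_array_equal(product_integral(path, 3.0, 3.0), np.eye(5))

    def test_two_jump_scalar_product(self):
        path = build_intensity_path(
            {("work", "unemployment"): hz(("work", "unemployment"), [1.0, 2.0], [0.2, 0.25])}
        )
        p = product_integral(path, 0, 2)
        assert p[0, 0] == pytest.approx(0.8 * 0.75)

    def test_rows_sum_to_one_and_entries_in_unit_interval(self, rng):
        hazards = {}
        for tr in (("work", "unemployment"), ("unemployment", "work"), ("sick_leave", "disability")):
            times = np.sort(rng.uniform(0, 12, 30))
            hazards[tr] = hz(tr, times, rng.uniform(0, 0.2, 30))
        path = build_intensity_path(hazards)
        p = product_integral(path, 0, 12)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-10)
        assert (p >= -1e-12).all() and (p <= 1 + 1e-12).all()

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_chapman_kolmogorov_identity(self, seed):
        """P(s,u) equals P(s,t) @ P(t,u) to 1e-12 on random paths."""
        rng = np.random.default_rng(seed)
        hazards = {}
        transitions = [("work", "unemployment"), ("unemployment", "work"),
                       ("work", "sick_leave"), ("sick_leave", "work"),
                       ("unemployment", "disability")]
        for tr in transitions:
            k = rng.integers(5, 25)
            times = np.sort(rng.uniform(0, 12, k))
            hazards[tr] = hz(tr, times, rng.uniform(0, 0.3, k))
        path = build_intensity_path(hazards)
        s, t, u = np.sort(rng.uniform(0, 12.5, 3))
        left = product_integral(path, s, u)
        right = product_integral(path, s, t) @ product_integral(path, t, u)
        np.testing.assert_allclose(left, right, atol=1e-12)

    def test_disability_column_is_monotone_and_row_is_absorbing(self, clean_model):
        res = clean_model.fit()
        path = res.intensity_path
        times = np.linspace(0, 12.5, 25)
        dis = STATE_INDEX["disability"]
        values = [product_integral(path, 0, t)[:, dis] for t in times]
        diffs = np.diff(np.asarray(values), axis=0)
        assert (diffs >= -1e-12).all()
        p = product_integral(path, 0, 12.5)
        np.testing.assert_array_equal(p[dis], np.eye(5)[dis])

    def test_kaplan_meier_reduction_is_exact(self, rng):
        """A single-hazard 2-state path: P_11(0,t) == prod(1 - d/n) == KM."""
        from lifelines import KaplanMeierFitter

        n = 300
        exit_times = np.round(rng.exponential(3.0, n), 1) + 0.1  # force ties
        status = (rng.random(n) < 0.7).astype(int)
        table = make_counting_table(
            [(i, "work", "unemployment", 0.0, exit_times[i], status[i]) for i in range(n)]
        )
        na = nelson_aalen(table, ("work", "unemployment"))
        path = build_intensity_path({("work", "unemployment"): na})
        km_manual = np.cumprod(1 - na.increments)
        ours = np.array([product_integral(path, 0, t)[0, 0] for t in na.times])
        np.testing.assert_array_equal(ours, km_manual)
        km = KaplanMeierFitter().fit(exit_times, status)
        np.testing.assert_allclose(
            ours, km.survival_function_at_times(na.times).to_numpy(), atol=1e-12
        )


class TestInitialDistribution:
    def traj(self, pid, state):
        return StateTrajectory(pid, [(0.0, 12.5, state)])

    def test_all_work_start(self):
        trajectories = {i: self.traj(i, "work") for i in range(4)}
        np.testing.assert_array_equal(
            empirical_initial_distribution(trajectories), [1, 0, 0, 0, 0]
        )

    def test_sixty_forty_split(self):
        trajectories = {i: self.traj(i, "work") for i in range(6)}
        trajectories.update({i + 6: self.traj(i + 6, "education") for i in range(4)})
        np.testing.assert_allclose(
            empirical_initial_distribution(trajectories), [0.6, 0, 0.4, 0, 0]
        )

    def test_weights_shift_the_proportions(self):
        trajectories = {0: self.traj(0, "work"), 1: self.traj(1, "education")}
        w = pd.Series({0: 3.0, 1: 1.0})
        np.testing.assert_allclose(
            empirical_initial_distribution(trajectories, weights=w), [0.75, 0, 0.25, 0, 0]
        )

    def test_empty_group_raises(self):
        with pytest.raises(EmptyGroupError):
            empirical_initial_distribution({}, person_ids=[])

    def test_zero_coefficient_model_is_uniform_over_modeled_states(self):
        model = InitialStateModel(
            states=["work", "unemployment", "education"],
            columns=["const", "exposure"],
            params=np.zeros((2, 2)),
        )
        probs = model.predict({"exposure": 1.0})
        np.testing.assert_allclose(probs[[0, 1, 2]], 1 / 3)
        assert probs[[3, 4]].sum() == 0

    def test_model_based_matches_empirical_for_intercept_only(self, clean_model):
        """A multinomial model on a constant-only design reproduces the
        empirical starting proportions."""
        from spellmsm.probabilities import initial_distribution

        ids = list(clean_model.trajectories)[:400]
        design = pd.DataFrame(index=pd.Index(ids, name="person_id"))
        emp = empirical_initial_distribution(clean_model.trajectories, ids)
        mod = initial_distribution(
            clean_model.trajectories, ids, mode="model_based", design=design, pattern={}
        )
        np.testing.assert_allclose(mod, emp, atol=1e-6)


class TestCurvesAndContrasts:
    def make_curve(self, times, probs, label=""):
        return StateProbabilityCurve(np.asarray(times), np.asarray(probs), label)

    def test_curve_at_time_zero_is_initial_distribution(self):
        path = build_intensity_path(
            {("work", "unemployment"): hz(("work", "unemployment"), [1.0], [0.2])}
        )
        init = np.array([0.7, 0.1, 0.2, 0, 0])
        curve = state_probabilities(path, init)
        np.testing.assert_array_equal(curve.at(0.0), init)

    def test_degenerate_init_tracks_matrix_row(self):
        path = build_intensity_path(
            {("work", "unemployment"): hz(("work", "unemployment"), [1.0, 2.0], [0.2, 0.25])}
        )
        init = np.eye(5)[0]
        curve = state_probabilities(path, init)
        for t in (0.5, 1.5, 2.5):
            np.testing.assert_allclose(curve.at(t), product_integral(path, 0, t)[0])

    def test_probabilities_sum_to_one_along_the_curve(self, clean_model):
        curve = clean_model.fit().state_probability_curve()
        np.testing.assert_allclose(curve.probabilities.sum(axis=1), 1.0, atol=1e-10)
        dis = curve.probabilities[:, STATE_INDEX["disability"]]
        assert (np.diff(dis) >= -1e-12).all()

    def test_identical_curves_give_null_contrasts(self):
        curve = self.make_curve([0, 1, 2], np.tile([0.5, 0.2, 0.2, 0.1, 0.0], (3, 1)))
        diff = contrast_curves(curve, curve, "difference")
        ratio = contrast_curves(curve, curve, "ratio")
        np.testing.assert_array_equal(diff.values, 0.0)
        finite = ~np.isnan(ratio.values)
        np.testing.assert_array_equal(ratio.values[finite], 1.0)

    def test_difference_and_ratio_arithmetic(self):
        a = self.make_curve([0, 1], [[0.5, 0.5, 0, 0, 0], [0.5, 0.5, 0, 0, 0]])
        b = self.make_curve([0, 1], [[0.4, 0.6, 0, 0, 0], [0.4, 0.6, 0, 0, 0]])
        diff = contrast_curves(a, b, "difference")
        ratio = contrast_curves(a, b, "ratio")
        assert diff.at(1.0)[0] == pytest.approx(0.1)
        assert ratio.at(1.0)[0] == pytest.approx(1.25)

    def test_zero_denominator_is_flagged_not_fabricated(self):
        a = self.make_curve([0], [[0.5, 0.5, 0, 0, 0]])
        b = self.make_curve([0], [[0.4, 0.6, 0, 0, 0]])
        ratio = contrast_curves(a, b, "ratio")
        assert np.isnan(ratio.values[0, 2])
        assert ratio.undefined[0, 2]

    def test_union_grid_uses_step_interpolation(self):
        a = self.make_curve([0, 2], [[1, 0, 0, 0, 0], [0.5, 0.5, 0, 0, 0]])
        b = self.make_curve([0, 1], [[1, 0, 0, 0, 0], [0.8, 0.2, 0, 0, 0]])
        diff = contrast_curves(a, b, "difference")
        assert diff.times.tolist() == [0, 1, 2]
        assert diff.at(1.0)[0] == pytest.approx(1.0 - 0.8)
        assert diff.at(2.0)[0] == pytest.approx(0.5 - 0.8)

    def test_ratio_of_difference_curves(self):
        d1 = contrast_curves(
            self.make_curve([0], [[0.6, 0.4, 0, 0, 0]]),
            self.make_curve([0], [[0.5, 0.5, 0, 0, 0]]),
            "difference",
        )
        d2 = contrast_curves(
            self.make_curve([0], [[0.7, 0.3, 0, 0, 0]]),
            self.make_curve([0], [[0.5, 0.5, 0, 0, 0]]),
            "difference",
        )
        meta = ratio_of_differences(d1, d2)
        assert meta.values[0, 0] == pytest.approx(0.1 / 0.2)
        assert np.isnan(meta.values[0, 2])  # 0/0 flagged

    def test_tidy_export_shape(self):
        curve = self.make_curve([0, 1], np.tile([0.5, 0.2, 0.2, 0.1, 0.0], (2, 1)), "g")
        frame = curve.to_frame()
        assert set(frame.columns) == {"time", "state", "probability", "group"}
        assert len(frame) == 2 * len(STATES)


class TestBootstrap:
    def test_constant_estimator_gives_zero_width_bands(self):
        bands = bootstrap_bands(lambda ids: np.array([1.0, 2.0]), [1, 2, 3], B=2, seed=0)
        np.testing.assert_array_equal(bands["lower"], bands["upper"])

    def test_same_seed_reproduces_bands(self):
        def estimate(ids):
            return np.array([np.mean(ids), np.var(ids)])

        a = bootstrap_bands(estimate, np.arange(50), B=30, seed=42)
        b = bootstrap_bands(estimate, np.arange(50), B=30, seed=42)
        np.testing.assert_array_equal(a["lower"], b["lower"])
        np.testing.assert_array_equal(a["upper"], b["upper"])

    def test_empty_group_replicates_are_skipped_and_counted(self):
        calls = {"n": 0}

        def estimate(ids):
            calls["n"] += 1
            if calls["n"] % 2 == 0:
                raise EmptyGroupError("empty arm")
            return np.array([float(np.mean(ids))])

        bands = bootstrap_bands(estimate, np.arange(10), B=10, seed=1)
        assert bands["n_skipped"] == 5
        assert bands["n_replicates"] == 5

    def test_interval_coverage_for_a_mean(self):
        """Percentile bootstrap covers a known mean at roughly the nominal
        rate (reduced scale: 60 outer replicates, B=120)."""
        rng = np.random.default_rng(7)
        covered = 0
        outer = 60
        for k in range(outer):
            sample = rng.normal(0.3, 1.0, 80)

            def estimate(ids, sample=sample):
                return np.array([sample[np.asarray(ids, int)].mean()])

            bands = bootstrap_bands(estimate, np.arange(80), B=120, seed=k)
            if bands["lower"][0] <= 0.3 <= bands["upper"][0]:
                covered += 1
        assert 0.85 <= covered / outer <= 1.0
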