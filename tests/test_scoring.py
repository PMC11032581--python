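"""Trial scoring: error statistics, exclusion rules, summaries."""

import numpy as np
import pandas as pd
import pytest

from gridpi import ArenaSpec, location_error, signed_angular_error
from gridpi.scoring import (
    angular_errors,
    boundary_crossing,
    classify_trial,
    condition_deltas,
    distance_error,
    oob_chisq,
    oob_proxy_signed_error,
    score_trial,
    score_trials,
    summarize,
)

from conftest import make_trajectory


class TestLocationError:
    def test_identity_and_pythagorean(self):
        assert location_error((0, 0), (0, 0)) == 0.0
        assert location_error((0, 0), (3, 4)) == 5.0

    def test_symmetry_and_hypot_oracle(self, rng):
        for _ in range(1000):
            p, q = rng.normal(size=2), rng.normal(size=2)
            d = location_error(p, q)
            assert d == pytest.approx(np.hypot(*(p - q)), abs=1e-12)
            assert d == location_error(q, p)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            location_error((np.inf, 0), (0, 0))


class TestAngularErrors:
    def test_paper_worked_example(self):
        """A_true = 120, A_est = -220 -> signed -20 (overturn), absolute 340."""
        assert signed_angular_error(120.0, -220.0) == pytest.approx(-20.0)
        assert abs(120.0 - (-220.0)) == pytest.approx(340.0)

    def test_signed_wrap_other_direction(self):
        assert signed_angular_error(-170.0, 170.0) == pytest.approx(20.0)

    def test_perfect_turn_zero(self, simple_cones):
        traj = make_trajectory(simple_cones, [simple_cones[0]])
        abs_err, signed_err = angular_errors(traj)
        assert abs_err == pytest.approx(0.0, abs=1e-9)
        assert signed_err == pytest.approx(0.0, abs=1e-9)

    def test_known_offset_response(self, simple_cones):
        """Responding rotated CCW by delta from the true angle -> signed -delta."""
        c3 = simple_cones[2]
        true_vec = simple_cones[0] - c3
        delta = np.radians(25.0)
        rot = np.array(
            [[np.cos(delta), -np.sin(delta)], [np.sin(delta), np.cos(delta)]]
        )
        traj = make_trajectory(simple_cones, [c3 + rot @ true_vec])
        abs_err, signed_err = angular_errors(traj)
        assert signed_err == pytest.approx(-25.0, abs=1e-9)
        assert abs_err == pytest.approx(25.0, abs=1e-9)

    def test_cumulative_estimator_agrees_after_wrap(self, simple_cones):
        c3 = simple_cones[2]
        true_vec = simple_cones[0] - c3
        delta = np.radians(-40.0)
        rot = np.array(
            [[np.cos(delta), -np.sin(delta)], [np.sin(delta), np.cos(delta)]]
        )
        end = c3 + rot @ true_vec
        path = c3 + np.linspace(0, 1, 30)[1:, None] * (end - c3)
        traj = make_trajectory(simple_cones, path)
        _, signed_allo = angular_errors(traj, estimator="allocentric")
        _, signed_cum = angular_errors(traj, estimator="cumulative")
        assert signed_cum == pytest.approx(signed_allo, abs=1e-6)


class TestDistanceError:
    def test_true_response_zero(self, simple_cones):
        traj = make_trajectory(simple_cones, [simple_cones[0]])
        assert distance_error(traj) == pytest.approx(0.0, abs=1e-12)

    def test_short_response(self, simple_cones):
        c3, c1 = simple_cones[2], simple_cones[0]
        u = (c1 - c3) / np.hypot(*(c1 - c3))
        traj = make_trajectory(simple_cones, [c3 + 2.0 * u])
        true_len = np.hypot(*(c1 - c3))
        assert distance_error(traj) == pytest.approx(true_len - 2.0, abs=1e-9)

    def test_independent_recomputation(self, rng, arena):
        from gridpi import AgentParams, generate_triangle, simulate_trial

        ag = AgentParams(oob_propensity=0.0)
        for seed in range(50):
            cones = generate_triangle(arena, seed)
            traj = simulate_trial(cones, ag, "B", arena, seed)
            if traj.response is None:
                continue
            d_true = np.linalg.norm(cones[0] - cones[2])
            d_est = np.linalg.norm(traj.response - cones[2])
            assert distance_error(traj) == pytest.approx(abs(d_true - d_est))


class TestClassification:
    def test_clean_trial_included(self, simple_cones):
        traj = make_trajectory(simple_cones, [simple_cones[0]])
        assert classify_trial(traj) == "included"

    def test_no_trigger_is_no_return(self, simple_cones):
        traj = make_trajectory(simple_cones, [simple_cones[0]], with_trigger=False)
        assert classify_trial(traj) == "no_return"

    def test_sample_outside_square_is_oob(self, simple_cones):
        # x = 2.3 m from center of a 4 m arena lies outside half-width 2.0
        traj = make_trajectory(simple_cones, [[1.9, 1.5], [2.3, 1.6]])
        assert classify_trial(traj) == "out_of_bounds"

    def test_retracing_through_cone2(self, simple_cones):
        path = [simple_cones[1] + [0.05, 0.05], simple_cones[0]]
        traj = make_trajectory(simple_cones, path)
        assert classify_trial(traj) == "retracing"

    def test_scored_outcome_flags(self, simple_cones):
        out = score_trial(make_trajectory(simple_cones, [simple_cones[0]]))
        assert not out.excluded and out.exclusion_reason == "none"
        out = score_trial(
            make_trajectory(simple_cones, [simple_cones[0]], with_trigger=False)
        )
        assert out.excluded and np.isnan(out.location_error)


class TestOobProxy:
    def test_heading_preserved_through_wall(self, simple_cones):
        """Walking exactly toward cone1 but through the wall -> proxy error 0."""
        c3, c1 = simple_cones[2], simple_cones[0]
        u = (c1 - c3) / np.hypot(*(c1 - c3))
        far = c3 + 8.0 * u  # overshoots through the boundary
        path = c3 + np.linspace(0, 1, 60)[1:, None] * (far - c3)
        traj = make_trajectory(simple_cones, path)
        assert classify_trial(traj) == "out_of_bounds"
        assert oob_proxy_signed_error(traj) == pytest.approx(0.0, abs=1e-9)

    def test_planted_underturn_recovered(self, simple_cones):
        c3, c1 = simple_cones[2], simple_cones[0]
        true_vec = c1 - c3
        delta = np.radians(-25.0)  # underturn by 25 deg -> signed error +25
        rot = np.array(
            [[np.cos(delta), -np.sin(delta)], [np.sin(delta), np.cos(delta)]]
        )
        far = c3 + 8.0 * (rot @ true_vec) / np.hypot(*true_vec)
        path = c3 + np.linspace(0, 1, 120)[1:, None] * (far - c3)
        traj = make_trajectory(simple_cones, path)
        assert classify_trial(traj) == "out_of_bounds"
        assert oob_proxy_signed_error(traj) == pytest.approx(25.0, abs=0.5)

    def test_included_trial_raises(self, simple_cones):
        traj = make_trajectory(simple_cones, [simple_cones[0]])
        with pytest.raises(ValueError):
            oob_proxy_signed_error(traj)

    def test_crossing_point_on_border(self, simple_cones):
        traj = make_trajectory(simple_cones, [[1.9, 1.5], [2.4, 1.7]])
        cross = boundary_crossing(traj)
        assert np.max(np.abs(cross)) == pytest.approx(2.0, abs=1e-9)


class TestRigidMotionInvariance:
    def test_scoring_invariant_to_rotation_translation(self, rng, simple_cones):
        theta = rng.uniform(0, 2 * np.pi)
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        shift = rng.uniform(-5, 5, size=2)
        response = simple_cones[2] + 0.8 * (simple_cones[0] - simple_cones[2])
        big = ArenaSpec(side_length=40.0, min_return=3.6, max_return=4.0)
        t1 = make_trajectory(simple_cones, [response], arena=big)
        moved_cones = (rot @ simple_cones.T).T + shift
        t2 = make_trajectory(moved_cones, [rot @ response + shift], arena=big)
        o1, o2 = score_trial(t1), score_trial(t2)
        assert o1.location_error == pytest.approx(o2.location_error, abs=1e-9)
        assert o1.distance_error == pytest.approx(o2.distance_error, abs=1e-9)
        assert o1.abs_angular_error == pytest.approx(o2.abs_angular_error, abs=1e-9)
        assert o1.signed_angular_error == pytest.approx(
            o2.signed_angular_error, abs=1e-9
        )


def test_location_error_law_of_cosines(rng, simple_cones):
    """Location error agrees with the law of cosines on the error triangle."""
    c3, c1 = simple_cones[2], simple_cones[0]
    true_len = np.hypot(*(c1 - c3))
    big = ArenaSpec(side_length=40.0)
    for _ in range(200):
        est_len = rng.uniform(0.5, 6.0)
        ang = rng.uniform(-np.pi, np.pi)
        true_dir = np.arctan2(*(c1 - c3)[::-1])
        resp = c3 + est_len * np.array(
            [np.cos(true_dir + ang), np.sin(true_dir + ang)]
        )
        traj = make_trajectory(simple_cones, [resp], arena=big)
        out = score_trial(traj)
        if out.excluded:  # e.g. a random direction grazing the cone2 corridor
            continue
        expected = np.sqrt(
            true_len**2
            + est_len**2
            - 2 * true_len * est_len * np.cos(np.radians(out.abs_angular_error))
        )
        assert out.location_error == pytest.approx(expected, abs=1e-9)


class TestSummaries:
    def _toy_table(self):
        rows = []
        for pid, base in (("a", 1.0), ("b", 2.0)):
            for cond, extra in (("A", 0.0), ("B", 0.5), ("C", 1.5)):
                for t in range(12):
                    rows.append(
                        {
                            "pid": pid,
                            "trial": t,
                            "condition": cond,
                            "included": True,
                            "reason": "none",
                            "location_error": base + extra,
                            "distance_error": 0.1,
                            "abs_angular_error": 10.0,
                            "signed_angular_error": -5.0,
                            "oob_proxy_signed_error": np.nan,
                        }
                    )
        return pd.DataFrame(rows)

    def test_constant_errors_give_exact_deltas(self):
        summary = summarize(self._toy_table())
        row = summary[(summary["pid"] == "a") & (summary["condition"] == "C")]
        assert row["mean_location_error"].iloc[0] == pytest.approx(2.5)
        assert row["delta_location_error"].iloc[0] == pytest.approx(1.5)
        assert (summary["n_included"] == 12).all()
        deltas = condition_deltas(summary)
        assert deltas.loc["b", "delta_BA"] == pytest.approx(0.5)

    def test_fully_excluded_condition_gives_missing_delta(self):
        df = self._toy_table()
        mask = (df["pid"] == "a") & (df["condition"] == "C")
        df.loc[mask, "included"] = False
        df.loc[mask, "reason"] = "out_of_bounds"
        summary = summarize(df)  # must not raise
        row = summary[(summary["pid"] == "a") & (summary["condition"] == "C")]
        assert np.isnan(row["delta_location_error"].iloc[0])
        assert row["n_oob"].iloc[0] == 12

    def test_count_invariant_per_condition(self, arena):
        from gridpi import CohortSpec, simulate_cohort

        _, trajs = simulate_cohort(CohortSpec(n_participants=3, seed=11))
        summary = summarize(score_trials(trajs))
        counts = summary[["n_included", "n_oob", "n_retrace", "n_no_return"]]
        assert (counts.sum(axis=1) == 12).all()

    def test_oob_chisq_requires_two_groups(self):
        df = self._toy_table()
        with pytest.raises(ValueError):
            oob_chisq(df, pd.Series({"a": "g1", "b": "g1"}))
        chi2, p, table = oob_chisq(df, pd.Series({"a": "g1", "b": "g2"}))
        assert 0 <= p <= 1 and table.values.sum() == len(df)
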