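"""Directional GLM analysis: designs, orientation, magnitude, stability."""

import numpy as np
import pandas as pd
import pytest

from gridpi import (
    EventTable,
    GridDirectionModel,
    GridSimSpec,
    RoiTimeSeries,
    control_symmetries,
    estimate_orientation,
    group_stats,
    quantify_magnitude,
    simulate_grid_bold,
    spatial_stability,
    temporal_stability,
    tsnr,
)
from gridpi.grid import _orientations_from_betas, build_design


def small_events(n=24, headings=None):
    onsets = 10.0 + np.arange(n) * 6.0
    h = np.linspace(0, 345, n) % 360 if headings is None else headings
    return EventTable(onsets, np.full(n, 2.0), np.asarray(h, dtype=float))


class TestBuildDesign:
    def test_equal_headings_raise_naming_columns(self):
        ev = small_events(12, headings=np.full(12, 45.0))
        with pytest.raises(ValueError, match="sin|cos"):
            build_design(ev, 6, 2.531, 80)

    def test_modulators_orthogonal_to_boxcar_after_centering(self):
        ev = small_events(36)
        X, names = build_design(ev, 6, 2.531, 110)
        box = X[:, names.index("boxcar")]
        for col in ("sin(6*phi)", "cos(6*phi)"):
            mod = X[:, names.index(col)]
            corr = np.dot(mod - mod.mean(), box - box.mean())
            corr /= np.linalg.norm(mod - mod.mean()) * np.linalg.norm(box - box.mean())
            assert abs(corr) < 0.05

    def test_events_beyond_scan_raise(self):
        ev = small_events(12)
        with pytest.raises(ValueError, match="scan duration"):
            build_design(ev, 6, 2.531, 10)

    def test_nuisance_columns_appended(self):
        ev = small_events(12)
        nuis = np.random.default_rng(0).normal(size=(60, 2))
        X, names = build_design(ev, 6, 2.531, 60, nuisance=nuis)
        assert names[-3:] == ["nuisance0", "nuisance1", "intercept"]
        assert X.shape == (60, 6)


class TestOrientation:
    def test_atan2_edge_case(self):
        betas = np.array([[0.0], [1.0]])  # beta_sin = 0, beta_cos > 0
        theta, amp = _orientations_from_betas(
            betas, ["sin(6*phi)", "cos(6*phi)"], 6
        )
        assert theta[0] == 0.0 and amp[0] == 1.0

    def test_noiseless_recovery_to_machine_precision(self):
        spec = GridSimSpec(n_voxels=4, true_orientation=23.0, noise_sd=0.0, seed=2)
        series, events, _ = simulate_grid_bold(spec)
        est = estimate_orientation(series, events)
        assert np.allclose(est.theta_v, 23.0, atol=1e-6)
        assert est.roi_mean_deg == pytest.approx(23.0, abs=1e-6)

    def test_wraparound_mean_is_circular_not_arithmetic(self):
        """theta_true = 59 deg with jitter must average to ~59, not ~30."""
        spec = GridSimSpec(
            n_voxels=40,
            true_orientation=59.0,
            orientation_jitter_sd=3.0,
            noise_sd=0.0,
            seed=7,
        )
        series, events, _ = simulate_grid_bold(spec)
        est = estimate_orientation(series, events)
        dist_to_59 = abs((est.roi_mean_deg - 59.0 + 30.0) % 60.0 - 30.0)
        assert dist_to_59 < 2.0

    def test_too_few_events_raise(self):
        spec = GridSimSpec(n_voxels=2, noise_sd=0.0, seed=0, n_events=8)
        series, events, _ = simulate_grid_bold(spec)
        few = events.subset(np.arange(8) < 4)  # 2 per partition < 4 params
        with pytest.raises(ValueError, match="events"):
            estimate_orientation(series, few)


class TestMagnitude:
    def test_matched_orientation_recovers_amplitude(self):
        spec = GridSimSpec(n_voxels=4, true_orientation=17.0, noise_sd=0.0, seed=3)
        series, events, _ = simulate_grid_bold(spec)
        mag, _ = quantify_magnitude(series, events, 17.0)
        assert mag == pytest.approx(spec.modulation_amplitude, rel=1e-6)

    def test_antialigned_orientation_flips_sign(self):
        spec = GridSimSpec(n_voxels=4, true_orientation=17.0, noise_sd=0.0, seed=3)
        series, events, _ = simulate_grid_bold(spec)
        mag_aligned, _ = quantify_magnitude(series, events, 17.0)
        mag_anti, _ = quantify_magnitude(series, events, 47.0)  # +30 deg in 6-fold
        assert mag_anti == pytest.approx(-mag_aligned, rel=1e-6)

    def test_partition_swap_symmetry_noiseless(self):
        spec = GridSimSpec(n_voxels=5, noise_sd=0.0, seed=9)
        series, events, _ = simulate_grid_bold(spec)
        m1 = GridDirectionModel(series, events).fit().magnitude
        m2 = GridDirectionModel(series, events.swap_partition()).fit().magnitude
        assert abs(m1 - m2) < 1e-6


class TestFoldEquivariance:
    def test_heading_rotation_shifts_orientation_and_keeps_magnitude(self):
        spec = GridSimSpec(n_voxels=4, true_orientation=11.0, noise_sd=0.0, seed=5)
        series, events, _ = simulate_grid_bold(spec)
        res = GridDirectionModel(series, events).fit()
        delta = 14.0
        shifted = EventTable(
            events.onset_s,
            events.duration_s,
            (events.heading_deg + delta) % 360.0,
            events.partition,
        )
        res2 = GridDirectionModel(series, shifted).fit()
        shift = (res2.mean_orientation_deg - res.mean_orientation_deg) % 60.0
        assert shift == pytest.approx(delta % 60.0, abs=1e-6)
        assert res2.magnitude == pytest.approx(res.magnitude, abs=1e-6)


class TestStability:
    def test_identical_orientations_fully_coherent(self):
        r, z, p = spatial_stability(np.full(20, 31.4), 6)
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_rayleigh_z_closed_form(self, rng):
        """pingouin's z must equal n * R^2 computed independently."""
        theta = rng.uniform(0, 60, size=50)
        r, z, p = spatial_stability(theta, 6)
        alpha = np.radians(6 * theta)
        r_manual = np.hypot(np.sin(alpha).mean(), np.cos(alpha).mean())
        assert z == pytest.approx(50 * r_manual**2, rel=1e-9)

    def test_uniform_orientations_null_p(self, rng):
        ps = []
        for _ in range(200):
            theta = rng.uniform(0, 60, size=40)
            ps.append(spatial_stability(theta, 6)[2])
        assert 0.25 < np.mean(np.asarray(ps) < 0.5) < 0.75

    def test_needs_two_voxels(self):
        with pytest.raises(ValueError):
            spatial_stability(np.array([10.0]), 6)

    def test_noiseless_temporal_stability_is_100(self):
        spec = GridSimSpec(n_voxels=6, noise_sd=0.0, seed=1)
        series, events, _ = simulate_grid_bold(spec)
        assert temporal_stability(series, events) == 100.0

    def test_orientation_drift_reduces_stability_monotonically(self):
        values = []
        for drift in (0.0, 25.0, 45.0):
            spec = GridSimSpec(
                n_voxels=24, drift_deg_per_run=drift, noise_sd=0.3, seed=6
            )
            series, events, _ = simulate_grid_bold(spec)
            values.append(temporal_stability(series, events))
        assert values[0] >= values[1] >= values[2]
        assert values[2] < 50.0


class TestControlSymmetries:
    def test_fold6_control_path_is_bitwise_identical(self):
        spec = GridSimSpec(n_voxels=4, noise_sd=0.4, seed=12)
        series, events, _ = simulate_grid_bold(spec)
        main = GridDirectionModel(series, events).fit()
        ctrl = control_symmetries(series, events, folds=(6,))[6]
        assert ctrl.magnitude == main.magnitude
        assert np.array_equal(ctrl.orientations_deg, main.orientations_deg)

    def test_unidirectional_signal_found_by_fold1(self):
        spec = GridSimSpec(
            n_voxels=8, n_fold=1, true_orientation=181.0, noise_sd=0.0, seed=13
        )
        series, events, _ = simulate_grid_bold(spec)
        res1 = control_symmetries(series, events, folds=(1,))[1]
        assert res1.magnitude == pytest.approx(1.0, rel=1e-6)
        assert res1.preferred_direction_deg == pytest.approx(181.0, abs=1e-6)


class TestTsnr:
    def test_definition_and_scaling(self, rng):
        base = 100.0 + rng.normal(0, 2.0, size=(1, 4000))
        series = RoiTimeSeries(base, tr_s=2.531)
        per_voxel, roi = tsnr(series)
        assert roi == pytest.approx(50.0, rel=0.05)
        series2 = RoiTimeSeries(
            100.0 + 2.0 * (base - 100.0), tr_s=2.531
        )
        _, roi2 = tsnr(series2)
        assert roi2 == pytest.approx(roi / 2.0, rel=0.01)

    def test_zero_variance_voxel_warned_and_nan(self):
        data = np.vstack([np.ones(50), np.random.default_rng(0).normal(size=50)])
        with pytest.warns(UserWarning):
            series = RoiTimeSeries(data, tr_s=2.0)
        with pytest.warns(UserWarning):
            per_voxel, roi = tsnr(series)
        assert np.isnan(per_voxel[0]) and np.isfinite(roi)

    def test_tsnr_magnitude_correlation_null(self):
        rows = []
        for seed in range(40):
            spec = GridSimSpec(n_voxels=6, noise_sd=1.0, seed=seed)
            series, events, _ = simulate_grid_bold(spec)
            res = GridDirectionModel(series, events).fit()
            _, roi_tsnr = tsnr(series)
            rows.append({"magnitude": res.magnitude, "tsnr": roi_tsnr})
        from scipy.stats import pearsonr

        df = pd.DataFrame(rows)
        r, p = pearsonr(df["magnitude"], df["tsnr"])
        assert p > 0.01 or abs(r) < 0.45


class TestGroupStats:
    def test_all_zero_magnitudes(self):
        df = pd.DataFrame({"magnitude": np.zeros(10)})
        out = group_stats(df)
        row = out["one_sample"].set_index("metric").loc["magnitude"]
        assert row["t"] == 0.0 and row["p"] == 1.0

    def test_requires_three_participants(self):
        with pytest.raises(ValueError):
            group_stats(pd.DataFrame({"magnitude": [1.0, 2.0]}))

    def test_welch_and_pearson_paths(self, rng):
        df = pd.DataFrame(
            {
                "magnitude": rng.normal(size=30),
                "temporal_stability_pct": rng.uniform(0, 100, 30),
                "spatial_rayleigh_z": rng.uniform(0, 5, 30),
                "group": np.repeat(["x", "y"], 15),
                "age_y": rng.uniform(43, 66, 30),
            }
        )
        out = group_stats(df, group_col="group", continuous_cols=("age_y",))
        assert set(out) == {"one_sample", "welch", "pearson"}
        assert (out["pearson"]["p"] <= 1).all()
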