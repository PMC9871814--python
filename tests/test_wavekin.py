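"""Front detection, speed estimation, direction classes, fold change, stats."""

import numpy as np
import pandas as pd
import pytest

from rootwave.kymo import Kymograph, build_kymograph
from rootwave.rootsim import Camera, preset_scenario, render_stack
from rootwave.rootsim.scenario import activation_time
from rootwave.pipeline import longitudinal_roi
from rootwave.wavekin import (
    FrontConfig,
    classify_direction,
    compare_conditions,
    detect_front,
    estimate_speed,
    estimate_wave,
    fold_change,
    summarize_replicates,
    transverse_speed,
)

from conftest import arclength_of_positions


def synthetic_kymograph(front_times, times, amplitude=1000.0, baseline=100.0,
                        positions=None, tau=2.0):
    """Rows rise along a logistic at the given per-position front times."""
    front_times = np.asarray(front_times, float)
    p = len(front_times)
    if positions is None:
        positions = np.arange(p) * 10.0
    with np.errstate(over="ignore"):
        m = 1 / (1 + np.exp(-(times[None, :] - front_times[:, None]) / tau))
    matrix = baseline + amplitude * np.where(np.isfinite(front_times[:, None]), m, 0.0)
    return Kymograph(matrix, positions, times, "longitudinal")


class TestDetectFront:
    def test_noiseless_preset_front_times_match_ground_truth(self, small_phantom):
        cam = Camera(n_frames=180, seed=0)
        sc = preset_scenario("nacl_tip_full", small_phantom.geometry)
        stack, truth = render_stack(small_phantom, sc, cam, noise=False)
        kym = build_kymograph(stack, longitudinal_roi(small_phantom), "longitudinal")
        front = detect_front(kym)
        s = arclength_of_positions(small_phantom, kym.positions_um)
        valid = np.isfinite(front) & (s > 60) & (s < 250)
        assert valid.sum() > 20
        expected = truth.activation_time(s[valid], 0.0)
        # detected half-max within half a frame + interpolation slack
        assert np.abs(front[valid] - expected).max() < cam.frame_interval_s + 0.2

    def test_constant_profile_detects_nothing(self):
        times = np.arange(100) * 0.5
        kym = Kymograph(np.full((5, 100), 300.0), np.arange(5.0), times,
                        "longitudinal")
        assert np.all(np.isnan(detect_front(kym)))

    def test_baseline_window_must_fit_recording(self):
        times = np.arange(10) * 0.5
        kym = Kymograph(np.ones((3, 10)), np.arange(3.0), times, "longitudinal")
        with pytest.raises(ValueError, match="baseline window"):
            detect_front(kym, FrontConfig(baseline_window_s=30.0))

    def test_edge_guard_drops_late_crossings(self):
        times = np.arange(200) * 0.5   # 100 s
        front_truth = np.array([20.0, 40.0, 95.0])
        kym = synthetic_kymograph(front_truth, times)
        front = detect_front(kym, FrontConfig(edge_guard_s=10.0))
        assert np.isfinite(front[0]) and np.isfinite(front[1])
        assert np.isnan(front[2])


class TestEstimateSpeed:
    def test_exact_front_times_recover_known_speed(self):
        positions = np.arange(0, 800, 10.0)
        u = 6.8
        fronts = 12.0 + positions / u
        fit = estimate_speed(fronts, positions)
        assert fit.speed_um_s == pytest.approx(u, rel=1e-9)
        assert fit.direction == "shoot_ward"
        assert fit.n_positions_used == len(positions)

    def test_time_reversal_negates_speed(self):
        rng = np.random.default_rng(0)
        positions = np.arange(0, 500, 10.0)
        fronts = 5.0 + positions / 9.4 + rng.normal(0, 0.1, positions.size)
        fwd = estimate_speed(fronts, positions)
        rev = estimate_speed(fronts.max() + fronts.min() - fronts, positions)
        assert rev.speed_um_s == pytest.approx(-fwd.speed_um_s, rel=1e-9)
        assert {fwd.direction, rev.direction} == {"shoot_ward", "tip_ward"}

    def test_insufficient_coverage_raises(self):
        with pytest.raises(ValueError, match="insufficient front coverage"):
            estimate_speed(np.array([1.0, 2.0, np.nan]), np.array([0.0, 10.0, 20.0]))

    def test_instantaneous_front_is_unresolved(self):
        fit = estimate_speed(np.full(10, 7.0), np.arange(10.0))
        assert fit.direction == "none"
        assert not np.isfinite(fit.speed_um_s)


class TestClassifyDirection:
    def test_v_profile_splits_into_two_branches(self):
        positions = np.arange(0, 1000, 10.0)
        s0 = 500.0
        u = 11.0
        fronts = 10.0 + np.abs(positions - s0) / u
        fit = classify_direction(estimate_speed(fronts, positions))
        assert fit.direction == "bidirectional"
        tipward, shootward = fit.branch_speeds_um_s
        assert tipward == pytest.approx(-u, rel=1e-6)
        assert shootward == pytest.approx(u, rel=1e-6)

    def test_monotone_profile_keeps_single_branch(self):
        positions = np.arange(0, 500, 10.0)
        fronts = 5.0 + positions / 5.9
        fit = classify_direction(estimate_speed(fronts, positions))
        assert fit.direction == "shoot_ward"
        assert fit.branch_speeds_um_s is None

    def test_tiny_tail_does_not_fake_a_branch(self):
        # 3 stray points past the minimum must not flip the classification
        positions = np.arange(0, 500, 10.0)
        fronts = 5.0 + (positions.max() - positions) / 6.8
        fronts[-3:] = [6.0, 7.0, 8.0]
        fit = classify_direction(estimate_speed(fronts, positions))
        assert fit.direction == "tip_ward"


class TestTransverse:
    def test_symmetric_full_treatment_has_no_net_transverse_slope(self):
        times = np.arange(200) * 0.5
        r = np.arange(-50, 51, 5.0)
        fronts = 20.0 + np.abs(r) / 9.4    # symmetric V about the midline
        kym = synthetic_kymograph(fronts, times, positions=r)
        fit = transverse_speed(kym)
        # robust slope of a symmetric V is ~0 → unresolved direction
        assert abs(fit.speed_um_s) < 1.0 or fit.direction in ("none", "bidirectional")

    def test_one_sided_crossing_recovers_transverse_speed(self):
        times = np.arange(200) * 0.5
        r = np.arange(-50, 51, 5.0)
        fronts = 15.0 + (r + 50) / 9.4
        kym = synthetic_kymograph(fronts, times, positions=r)
        fit = transverse_speed(kym)
        assert abs(fit.speed_um_s) == pytest.approx(9.4, rel=0.02)


class TestFoldChange:
    def test_constant_trace_is_unity(self):
        t = np.arange(100) * 0.5
        assert fold_change(t, np.full(100, 800.0), background_adu=0.0) == 1.0

    def test_scale_invariance_after_background_correction(self):
        t = np.arange(200) * 0.5
        v = 300.0 + 600.0 / (1 + np.exp(-(t - 40) / 3))
        f1 = fold_change(t, 100.0 + v, background_adu=100.0)
        f2 = fold_change(t, 100.0 + 2 * v, background_adu=100.0)
        assert f1 == pytest.approx(f2, rel=1e-6)
        assert f1 == pytest.approx(3.0, rel=0.01)

    def test_nonpositive_baseline_rejected(self):
        t = np.arange(50) * 0.5
        with pytest.raises(ValueError, match="baseline"):
            fold_change(t, np.full(50, 90.0), background_adu=100.0)


class TestReplicates:
    def test_hand_computed_summary(self):
        s = summarize_replicates([6, 7, 8])
        assert s.mean == 7.0
        assert s.sd == pytest.approx(1.0)
        assert s.n == 3

    def test_single_value_sd_undefined(self):
        s = summarize_replicates([4.2])
        assert s.n == 1 and np.isnan(s.sd)

    def test_permutation_invariance(self):
        a = summarize_replicates([3.0, 1.0, 2.0])
        b = summarize_replicates([1.0, 2.0, 3.0])
        assert (a.mean, a.sd, a.n) == (b.mean, b.sd, b.n)


def _grouped(rng, shift_cell=None, shift=0.0, n=5):
    rows = []
    for sec in ["Tip", "ME1", "ME2"]:
        for trt in ["control", "nacl"]:
            mu = 100.0 + (shift if (sec, trt) == shift_cell else 0.0)
            for _ in range(n):
                rows.append({"section": sec, "treatment": trt,
                             "intensity_adu": rng.normal(mu, 5.0)})
    return pd.DataFrame(rows)


class TestCompareConditions:
    def test_identical_groups_rarely_significant(self):
        """Type-I control: ≥ 18/20 seeded runs with no significant contrast."""
        clean = 0
        for seed in range(20):
            _, tukey = compare_conditions(_grouped(np.random.default_rng(seed)))
            clean += int(not tukey["significant"].any())
        assert clean >= 18

    def test_large_shift_detected_and_verified_by_permutation(self):
        rng = np.random.default_rng(11)
        df = _grouped(rng, shift_cell=("Tip", "nacl"), shift=50.0)   # 10 pooled SD
        _, tukey = compare_conditions(df)
        hit = tukey[(tukey["group1"] == "Tip:control") & (tukey["group2"] == "Tip:nacl")]
        assert bool(hit["significant"].iloc[0])
        # independent oracle: permutation test on the shifted contrast
        a = df.query("section=='Tip' and treatment=='control'")["intensity_adu"].to_numpy()
        b = df.query("section=='Tip' and treatment=='nacl'")["intensity_adu"].to_numpy()
        obs = abs(a.mean() - b.mean())
        pool = np.concatenate([a, b])
        perm = np.random.default_rng(0)
        count = 0
        for _ in range(500):
            perm.shuffle(pool)
            count += abs(pool[:len(a)].mean() - pool[len(a):].mean()) >= obs
        assert count / 500 < 0.05

    def test_single_replicate_cell_rejected(self):
        df = _grouped(np.random.default_rng(0), n=2)
        df = df.drop(df.index[0])
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_conditions(df)

    def test_unbalanced_cells_run_and_report(self):
        df = pd.concat([_grouped(np.random.default_rng(1), n=3),
                        _grouped(np.random.default_rng(2), n=2)])
        anova, tukey = compare_conditions(df)
        assert {"C(section)", "C(treatment)"} <= set(
            e.split(":")[0] for e in anova["effect"])
        assert len(tukey) == 15   # 6 groups → 15 pairs
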