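"""Stack rendering: noiseless identity, determinism, noise statistics."""

import numpy as np
import pytest

from rootwave.rootsim import (
    Camera,
    Scenario,
    build_phantom,
    generate_preset,
    preset_names,
    preset_scenario,
    render_stack,
    wave_multiplier,
)


def scenario_for(phantom, **kw):
    base = dict(preset_name="t", treatment_site="tip", sidedness="full",
                init_arclength_um=0.0, longitudinal_speed_um_s=10.0,
                amplitude_fold=2.0, onset_time_s=5.0)
    base.update(kw)
    return Scenario(**base)


def test_noiseless_unblurred_render_is_exact(small_phantom):
    cam = Camera(n_frames=40, psf_sigma_um=0.0, seed=1)
    sc = scenario_for(small_phantom)
    stack, _ = render_stack(small_phantom, sc, cam, noise=False, blur=False)
    ys, xs = np.nonzero(small_phantom.mask)
    for ti in (0, 20, 39):
        m = wave_multiplier(sc, small_phantom.s_um[ys, xs],
                            small_phantom.r_um[ys, xs], stack.times_s[ti])
        expected = np.rint(cam.background_adu + cam.baseline_adu * m)
        assert np.array_equal(stack.frames[ti, ys, xs], expected)
    # off-root pixels carry exactly the background
    assert np.all(stack.frames[0][~small_phantom.mask] == cam.background_adu)


def test_same_seed_gives_byte_identical_stacks(small_phantom):
    cam = Camera(n_frames=30, seed=42)
    sc = scenario_for(small_phantom)
    a, ta = render_stack(small_phantom, sc, cam)
    b, tb = render_stack(small_phantom, sc, cam)
    assert a.frames.tobytes() == b.frames.tobytes()
    assert ta.stack_sha256 == tb.stack_sha256
    c, _ = render_stack(small_phantom, sc, Camera(n_frames=30, seed=43))
    assert a.frames.tobytes() != c.frames.tobytes()


def test_static_scene_noise_is_unbiased(small_phantom):
    """Monte-Carlo oracle: temporal mean of a static noisy scene ≈ baseline."""
    cam = Camera(n_frames=200, seed=7)
    sc = scenario_for(small_phantom, amplitude_fold=1.0)   # no wave
    stack, _ = render_stack(small_phantom, sc, cam)
    ys, xs = np.nonzero(small_phantom.mask)
    # interior pixels only: away from every blurred boundary (flanks, cap, cut)
    interior = (np.abs(small_phantom.r_um[ys, xs]) < 40) \
        & (small_phantom.s_um[ys, xs] > 80) \
        & (small_phantom.s_um[ys, xs] < small_phantom.geometry.length_um - 80)
    vals = stack.frames[:, ys[interior], xs[interior]].astype(float)
    target = cam.background_adu + cam.baseline_adu
    mean = vals.mean(axis=0)
    se = vals.std(axis=0, ddof=1) / np.sqrt(cam.n_frames)
    frac_outside = np.mean(np.abs(mean - target) > 3 * se)
    # ~0.3% of pixels expected outside ±3 SE by chance
    assert frac_outside < 0.02
    # and the grand mean is spot on
    assert mean.mean() == pytest.approx(target, rel=1e-3)


def test_activation_truth_linear_in_arclength(small_phantom):
    _, truth = render_stack(
        small_phantom,
        scenario_for(small_phantom, longitudinal_speed_um_s=8.0,
                     init_arclength_um=100.0),
        Camera(n_frames=20, seed=0), noise=False)
    s = truth.s_grid_um
    ta = truth.t_a_s
    side = s >= 100.0
    slopes = np.diff(ta[side]) / np.diff(s[side])
    assert np.allclose(slopes, 1 / 8.0)
    assert np.all(np.isinf(ta[~side] if (~side).any() else np.array([np.inf])))


def test_amplitude_conservation_noiseless(small_phantom):
    """Spatial max of the noiseless final frame / baseline equals the fold."""
    cam = Camera(n_frames=60, psf_sigma_um=0.0, seed=0)
    sc = scenario_for(small_phantom, amplitude_fold=4.0, onset_time_s=0.0,
                      longitudinal_speed_um_s=100.0)
    stack, _ = render_stack(small_phantom, sc, cam, noise=False, blur=False)
    peak = stack.frames[-1].astype(float).max() - cam.background_adu
    assert peak / cam.baseline_adu == pytest.approx(4.0, rel=1e-3)


def test_preset_table_and_errors(small_phantom):
    assert "nacl_tip_full" in preset_names()
    sc = preset_scenario("nacl_tip_full")
    assert sc.longitudinal_speed_um_s == pytest.approx(5.9)
    assert sc.amplitude_fold == pytest.approx(2.5)
    sc2 = preset_scenario("peg_tip_oneside")
    assert sc2.longitudinal_speed_um_s == pytest.approx(14.2)
    assert sc2.sidedness == "one_sided"
    with pytest.raises(KeyError, match="valid presets"):
        preset_scenario("does_not_exist")


def test_preonset_frames_match_control_statistics(small_phantom):
    """Before onset every preset is statistically the control scene."""
    cam = Camera(n_frames=30, seed=3)
    sc_wave = scenario_for(small_phantom, onset_time_s=1e6)  # never fires
    sc_ctrl = scenario_for(small_phantom, amplitude_fold=1.0)
    a, _ = render_stack(small_phantom, sc_wave, cam)
    b, _ = render_stack(small_phantom, sc_ctrl, cam)
    ys, xs = np.nonzero(small_phantom.mask)
    va = a.frames[:, ys, xs].astype(float).ravel()
    vb = b.frames[:, ys, xs].astype(float).ravel()
    se = np.sqrt(va.var() / va.size + vb.var() / vb.size)
    assert abs(va.mean() - vb.mean()) < 3 * se


def test_ground_truth_roundtrip(tmp_path, small_phantom):
    from rootwave.rootsim import GroundTruth

    _, truth = render_stack(small_phantom, scenario_for(small_phantom),
                            Camera(n_frames=20, seed=0), noise=False)
    p = truth.write(tmp_path / "x.truth.json")
    back = GroundTruth.read(p)
    assert back.scenario == truth.scenario
    assert np.allclose(back.t_a_s, truth.t_a_s)
    assert back.stack_sha256 == truth.stack_sha256
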