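"""Wave-front kinematics: detection, speed, direction, fold change, stats.

The estimation chain realising the headline numbers:

1. **Front detection** — per kymograph position, the front time is the
   first crossing of baseline + f·(peak − baseline) (half-max, f = 0.5 by
   default) after a light temporal smoothing, linearly interpolated between
   frames.  Positions whose dynamic range stays below k baseline standard
   deviations (default k = 4) report no front, as do positions whose
   crossing falls inside the trailing ``edge_guard_s`` of the recording
   (a front still rising when the video ends has a biased half-max time).
2. **Speed** — Theil–Sen slope of position (µm) versus front time (s);
   robust to stalled or mis-detected positions.  Positive slope means the
   front moves toward larger positions (shoot-ward on the longitudinal
   axis under the tip-left convention).
3. **Direction** — single-branch sign → shoot_ward / tip_ward; a V-shaped
   front-time profile with an interior minimum is split at the minimum and
   both branches fitted; opposite signs with both speeds above threshold →
   bidirectional.
4. **Fold change** — background-corrected peak/baseline ratio of a section
   trace.
5. **Replicate summaries and condition comparisons** — mean ± SD (n−1) and
   a two-way fixed-effects ANOVA (section x treatment) with Tukey HSD
   pairwise comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.stats import theilslopes

from .kymo import Kymograph

DIRECTIONS = ("shoot_ward", "tip_ward", "bidirectional", "none")


@dataclass(frozen=True)
class FrontConfig:
    """Tunables of the front detector."""

    baseline_window_s: float = 10.0   # pre-onset window defining the baseline
    fraction: float = 0.5             # f of half-max criterion
    smooth_frames: int = 3            # moving-mean width (frames)
    min_range_sd: float = 4.0         # k: dynamic range must exceed k·SD(baseline)
    edge_guard_s: float = 25.0        # discard crossings this close to the end
    #                                   (plateau window + ~3 rise times: keeps
    #                                   the trailing window pure plateau for
    #                                   every retained position)
    onset_guard_s: float = 20.0       # exclude ~this much travel around the
    #                                   initiation locus from the slope fit:
    #                                   near the origin the rise is truncated
    #                                   by the onset and not a pure travelling
    #                                   waveform; the transient lasts up to a
    #                                   rise time plus the transverse
    #                                   equilibration of the root width
    #                                   (applied in position space,
    #                                   onset_guard_s × |provisional speed|)
    peak_mode: str = "plateau"        # plateau (trailing-window mean) | max
    plateau_window_s: float = 10.0    # trailing window for the plateau estimate
    criterion: str = "half_max"       # half_max | k_sigma
    k_sigma: float = 4.0              # threshold multiplier for the k_sigma criterion

    def __post_init__(self) -> None:
        if not 0 < self.fraction < 1:
            raise ValueError("fraction must be in (0, 1)")
        if self.smooth_frames < 1:
            raise ValueError("smooth_frames must be >= 1")
        if self.criterion not in ("half_max", "k_sigma"):
            raise ValueError("criterion must be 'half_max' or 'k_sigma'")
        if self.peak_mode not in ("plateau", "max"):
            raise ValueError("peak_mode must be 'plateau' or 'max'")
        if self.plateau_window_s <= 0:
            raise ValueError("plateau_window_s must be > 0")


@dataclass
class WaveFit:
    """Estimated front kinematics for one kymograph."""

    speed_um_s: float                    # signed Theil-Sen slope (primary branch)
    speed_sd: float                      # half-width of the 95% CI / 1.96
    direction: str
    n_positions_used: int
    front_times_s: np.ndarray            # per input position, NaN = no front
    positions_um: np.ndarray
    fit_quality: dict = field(default_factory=dict)
    branch_speeds_um_s: tuple[float, float] | None = None  # (tip-ward, shoot-ward)

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")


def detect_front(kym: Kymograph, cfg: FrontConfig = FrontConfig()) -> np.ndarray:
    """Per-position front (activation) times in seconds; NaN where none.

    Vectorised over positions: smooth each row with a centred moving mean,
    take the baseline statistics from the leading ``baseline_window_s``,
    and report the first threshold crossing by linear interpolation.
    """
    times = kym.times_s
    dt = float(np.median(np.diff(times)))
    n_base = int(np.floor(cfg.baseline_window_s / dt))
    if n_base < 2:
        raise ValueError("baseline window shorter than two frames")
    if n_base >= len(times):
        raise ValueError(
            f"baseline window ({cfg.baseline_window_s} s) is not shorter than "
            f"the recording ({times[-1]:.1f} s)"
        )

    raw = kym.matrix.astype(float)
    if cfg.smooth_frames > 1:
        prof = uniform_filter1d(raw, cfg.smooth_frames, axis=1, mode="nearest")
    else:
        prof = raw

    # baseline statistics from the raw rows: the centred moving mean would
    # leak the first post-onset frames into the tail of the baseline window,
    # and the smoothed peak of a signal-free position stays well below
    # 4 raw-SD, so pure-noise positions are rejected
    base_mean = raw[:, :n_base].mean(axis=1)
    base_sd = raw[:, :n_base].std(axis=1, ddof=1)
    # plateau mode: estimate the top level from a trailing window so its
    # statistics are identical for every position (the max over all frames
    # is an extreme-value statistic whose bias grows with how long a
    # position has been at plateau, tilting front times with position);
    # the edge guard below ensures kept positions have plateaued before
    # the window starts
    if cfg.peak_mode == "plateau":
        n_pl = max(int(np.floor(cfg.plateau_window_s / dt)), 1)
        peak = prof[:, -n_pl:].mean(axis=1)
    else:
        peak = prof.max(axis=1)
    rng = peak - base_mean

    if cfg.criterion == "half_max":
        thresh = base_mean + cfg.fraction * rng
    else:
        thresh = base_mean + cfg.k_sigma * base_sd
    detectable = rng > cfg.min_range_sd * np.maximum(base_sd, 1e-12)

    above = prof >= thresh[:, None]
    above[:, :n_base] = False          # baseline frames cannot host the front
    has_cross = above.any(axis=1)
    first = np.argmax(above, axis=1)

    front = np.full(kym.matrix.shape[0], np.nan)
    ok = detectable & has_cross & (first > 0)
    if ok.any():
        i = first[ok]
        rows = np.nonzero(ok)[0]
        y1 = prof[rows, i]
        y0 = prof[rows, i - 1]
        th = thresh[ok]
        frac = np.where(y1 > y0, (th - y0) / np.where(y1 > y0, y1 - y0, 1.0), 1.0)
        front[ok] = times[i - 1] + np.clip(frac, 0.0, 1.0) * (times[i] - times[i - 1])
    if cfg.edge_guard_s > 0:
        front[front > times[-1] - cfg.edge_guard_s] = np.nan
    return front


def _theil_sen(times: np.ndarray, positions: np.ndarray,
               min_separation_um: float = 20.0) -> tuple[float, float, dict]:
    """Theil-Sen slope of position vs time with an SD proxy and residual scale.

    The median is taken over pairs separated by at least
    ``min_separation_um``: for nearly coincident positions the noisy time
    difference in the denominator can change sign, throwing those pairwise
    slopes to the opposite tail and biasing the median away from zero
    error.  If no pair satisfies the floor, all pairs are used.
    """
    if np.ptp(times) <= 0:
        return np.nan, np.nan, {"median_abs_residual_um": np.nan}
    dp = positions[:, None] - positions[None, :]
    dt = times[:, None] - times[None, :]
    sel = dp > max(min_separation_um, 0.0)
    if not sel.any():
        sel = dp > 0
    with np.errstate(divide="ignore"):
        slopes = dp[sel] / dt[sel]
    slope = float(np.median(slopes[np.isfinite(slopes)]))
    # CI-based SD proxy and intercept from the classic estimator
    res = theilslopes(positions, times, alpha=0.95)
    intercept = float(np.median(positions - slope * times))
    resid = positions - (intercept + slope * times)
    sd = (res.high_slope - res.low_slope) / (2 * 1.959964)
    return slope, float(sd), {
        "median_abs_residual_um": float(np.median(np.abs(resid)))}


def estimate_speed(
    front_times_s: np.ndarray,
    positions_um: np.ndarray,
    min_speed_um_s: float = 1.0,
) -> WaveFit:
    """Signed propagation speed from per-position front times.

    Requires fronts at >= 3 positions.  A front-time profile with no time
    spread (instantaneous activation) yields direction 'none' with an
    unresolved (NaN) speed.
    """
    front_times_s = np.asarray(front_times_s, dtype=float)
    positions_um = np.asarray(positions_um, dtype=float)
    if front_times_s.shape != positions_um.shape:
        raise ValueError("front_times and positions must align")
    valid = np.isfinite(front_times_s)
    n = int(valid.sum())
    if n < 3:
        raise ValueError(f"insufficient front coverage: {n} positions with a front")

    t, p = front_times_s[valid], positions_um[valid]
    slope, sd, quality = _theil_sen(t, p)
    quality["inlier_fraction"] = n / len(front_times_s)

    if not np.isfinite(slope):
        direction = "none"
    elif abs(slope) < min_speed_um_s:
        direction = "none"
    elif slope > 0:
        direction = "shoot_ward"
    else:
        direction = "tip_ward"
    return WaveFit(slope, sd, direction, n, front_times_s, positions_um, quality)


def classify_direction(
    fit: WaveFit,
    min_branch_points: int = 3,
    min_branch_fraction: float = 0.05,
    min_speed_um_s: float = 1.0,
) -> WaveFit:
    """Refine a fit's direction label, detecting bidirectional V profiles.

    If the front times form a V with the minimum at an interior position
    (the initiation locus), both branches are fitted separately; opposite
    signed slopes both above ``min_speed_um_s`` give 'bidirectional', with
    the branch speeds stored as (tip-ward, shoot-ward).  Each branch must
    hold at least ``min_branch_points`` and ``min_branch_fraction`` of the
    detected positions, so a handful of optical-bleed bins past the
    initiation locus cannot fake a branch.
    """
    valid = np.isfinite(fit.front_times_s)
    t = fit.front_times_s[valid]
    p = fit.positions_um[valid]
    need = max(min_branch_points, int(np.ceil(min_branch_fraction * len(t))))
    if len(t) < 2 * need:
        return fit
    i_min = int(np.argmin(t))
    if i_min < need or i_min > len(t) - 1 - need:
        return fit

    # the vertex point belongs to neither branch cleanly (and after the
    # onset guard it is the lone survivor on one side of the gap), so both
    # branch fits exclude it
    s_lo, sd_lo, q_lo = _theil_sen(t[:i_min], p[:i_min])
    s_hi, sd_hi, q_hi = _theil_sen(t[i_min + 1:], p[i_min + 1:])
    if (np.isfinite(s_lo) and np.isfinite(s_hi)
            and s_lo * s_hi < 0
            and abs(s_lo) > min_speed_um_s and abs(s_hi) > min_speed_um_s):
        tipward, shootward = (s_lo, s_hi) if s_lo < 0 else (s_hi, s_lo)
        quality = dict(fit.fit_quality)
        quality["branch_residuals_um"] = (q_lo["median_abs_residual_um"],
                                          q_hi["median_abs_residual_um"])
        return WaveFit(
            speed_um_s=shootward,
            speed_sd=float(np.hypot(sd_lo, sd_hi) / np.sqrt(2)),
            direction="bidirectional",
            n_positions_used=fit.n_positions_used,
            front_times_s=fit.front_times_s,
            positions_um=fit.positions_um,
            fit_quality=quality,
            branch_speeds_um_s=(tipward, shootward),
        )
    return fit


def estimate_wave(
    kym: Kymograph,
    cfg: FrontConfig = FrontConfig(),
    min_speed_um_s: float = 1.0,
) -> WaveFit:
    """Full chain: detect fronts, fit the slope, classify direction.

    After a provisional fit, positions within onset_guard_s × |provisional
    speed| of the earliest-front position are excluded and the fit is
    repeated: around the initiation locus the rise is truncated by the
    treatment onset rather than a time-shifted copy of the travelling
    waveform, which biases half-max times there.  The exclusion is by
    position (deterministic), not by detected time, so noise cannot select
    which positions survive the cut.
    """
    front = detect_front(kym, cfg)
    fit = estimate_speed(front, kym.positions_um, min_speed_um_s)
    if cfg.onset_guard_s > 0 and np.isfinite(fit.speed_um_s) \
            and abs(fit.speed_um_s) >= min_speed_um_s:
        valid = np.isfinite(front)
        p_star = kym.positions_um[valid][np.argmin(front[valid])]
        w = cfg.onset_guard_s * abs(fit.speed_um_s)
        front = front.copy()
        front[np.abs(kym.positions_um - p_star) <= w] = np.nan
        if np.isfinite(front).sum() >= 3:
            fit = estimate_speed(front, kym.positions_um, min_speed_um_s)
    return classify_direction(fit, min_speed_um_s=min_speed_um_s)


def transverse_speed(
    kym_transverse: Kymograph,
    cfg: FrontConfig = FrontConfig(),
    min_speed_um_s: float = 1.0,
) -> WaveFit:
    """Speed of a transversely moving front across the root width.

    Identical to the longitudinal estimator but with positions equal to the
    signed transverse coordinate; a symmetric (full-treatment) activation
    has no net transverse slope and classifies as 'none'.  The onset guard
    is disabled here: the whole root width activates within roughly one
    rise time, so guarding the earliest fronts would discard most rows
    (the analysis ROI is instead trimmed away from the treated flank).
    """
    from dataclasses import replace

    front = detect_front(kym_transverse, replace(cfg, onset_guard_s=0.0))
    front_valid = np.isfinite(front)
    if front_valid.sum() < 3:
        raise ValueError(
            f"insufficient front coverage: {int(front_valid.sum())} positions")
    fit = estimate_speed(front, kym_transverse.positions_um, min_speed_um_s)
    if fit.direction in ("shoot_ward", "tip_ward"):
        # transverse axis: direction labels do not apply; keep the sign in speed
        fit.direction = "none" if abs(fit.speed_um_s) < min_speed_um_s else fit.direction
    return fit


def fold_change(
    times_s: np.ndarray,
    trace: np.ndarray,
    baseline_window_s: float = 10.0,
    background_adu: float = 0.0,
    smooth_frames: int = 3,
) -> float:
    """Peak-over-baseline intensity ratio of a section trace.

    Both peak and baseline are background-corrected before the ratio, so
    the result is invariant to rescaling the (corrected) intensities.
    """
    times_s = np.asarray(times_s, dtype=float)
    trace = np.asarray(trace, dtype=float)
    base_sel = times_s < baseline_window_s
    if base_sel.sum() < 2:
        raise ValueError("baseline window must cover >= 2 frames")
    # baseline from the raw trace (a centred moving mean would leak the
    # first post-onset frames into the baseline window); peak from the
    # smoothed trace for robustness to single-frame noise excursions
    baseline = trace[base_sel].mean() - background_adu
    if baseline <= 0:
        raise ValueError("non-positive background-corrected baseline")
    smoothed = (uniform_filter1d(trace, smooth_frames, mode="nearest")
                if smooth_frames > 1 else trace)
    peak = smoothed.max() - background_adu
    return float(peak / baseline)


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean ± SD over replicates, reported the way the field prints them."""

    mean: float
    sd: float          # n-1 denominator; NaN when n = 1 (undefined)
    n: int
    values: tuple[float, ...]


def summarize_replicates(values) -> ReplicateSummary:
    vals = tuple(float(v) for v in np.asarray(values, dtype=float).ravel())
    if len(vals) < 1:
        raise ValueError("need at least one replicate")
    arr = np.asarray(vals)
    sd = float(arr.std(ddof=1)) if len(vals) > 1 else float("nan")
    return ReplicateSummary(float(arr.mean()), sd, len(vals), vals)


def compare_conditions(
    df: pd.DataFrame,
    value: str = "intensity_adu",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-way fixed-effects ANOVA (section x treatment) with Tukey HSD.

    ``df`` holds one row per replicate with columns ``section``,
    ``treatment`` and the response column (typically the per-replicate mean
    intensity over a stated time window).  Every section x treatment cell
    needs >= 2 replicates.  Returns (anova_table, tukey_table); the Tukey
    table compares all section:treatment group pairs with a ``significant``
    flag at the requested alpha.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    needed = {"section", "treatment", value}
    if not needed.issubset(df.columns):
        raise ValueError(f"data must have columns {sorted(needed)}")
    counts = df.groupby(["section", "treatment"], observed=True).size()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"cells with fewer than 2 replicates: {bad}")

    data = df.rename(columns={value: "response"})
    model = ols("response ~ C(section) * C(treatment)", data=data).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    anova = anova.rename_axis("effect").reset_index()
    anova["n_cells"] = len(counts)

    groups = (data["section"].astype(str) + ":" + data["treatment"].astype(str))
    tk = pairwise_tukeyhsd(data["response"].to_numpy(), groups.to_numpy(), alpha=alpha)
    tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    tukey["significant"] = tukey["reject"].astype(bool)
    return anova, tukey
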