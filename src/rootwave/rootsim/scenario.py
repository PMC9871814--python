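"""Wave scenarios and the space-time intensity multiplier.

A treatment-triggered calcium front is modelled as a travelling activation
surface in the root's (s, r) coordinates.  Each position activates at

    t_a(s, r) = t0 + Δt_long(s) + Δt_trans(r)

where Δt_long = (s − s0)/u on the propagation side (|s − s0|/|u| on both
sides for a bidirectional front) and Δt_trans = |r − r_flank| / v_T for
one-sided treatments (zero for full treatments).  The local fluorescence
multiplier then rises along a logistic from 1 to the plateau fold A with a
10–90% rise time τ, half-rise exactly at t_a:

    m(s, r, t) = 1 + (A − 1) · σ((t − t_a) / k),   k = τ / (2 ln 9)

gated to exactly 1 before the treatment onset t0.  Positions on the wrong
side of a non-bidirectional front, or beyond the midline when a one-sided
wave does not cross, never activate.

Sign conventions: s = 0 at the tip apex, increasing shoot-ward; a positive
longitudinal speed is shoot-ward.  r is signed across the midline; the
treated flank of a one-sided scenario sits at r = treated_flank_r_um.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.special import expit

TREATMENT_SITES = ("tip", "differentiation_zone")
SIDEDNESS = ("full", "one_sided")


@dataclass(frozen=True)
class Scenario:
    """Ground-truth wave parameters for one synthetic recording."""

    preset_name: str
    treatment_site: str                  # tip | differentiation_zone
    sidedness: str                       # full | one_sided
    init_arclength_um: float             # s0, front origin from the tip apex
    longitudinal_speed_um_s: float       # signed u; positive = shoot-ward
    amplitude_fold: float                # plateau / baseline, >= 1
    bidirectional: bool = False
    transverse_speed_um_s: float | None = None
    treated_flank_r_um: float | None = None   # r of the treated flank (one_sided)
    crosses_midline: bool = True
    rise_time_s: float = 5.0             # tau, 10-90% front rise
    onset_time_s: float = 10.0           # t0, treatment arrival

    def __post_init__(self) -> None:
        if self.treatment_site not in TREATMENT_SITES:
            raise ValueError(f"treatment_site must be one of {TREATMENT_SITES}")
        if self.sidedness not in SIDEDNESS:
            raise ValueError(f"sidedness must be one of {SIDEDNESS}")
        if not self.amplitude_fold >= 1.0:
            raise ValueError("amplitude_fold must be >= 1")
        if not self.rise_time_s > 0:
            raise ValueError("rise_time_s must be > 0")
        if self.onset_time_s < 0:
            raise ValueError("onset_time_s must be >= 0")
        if self.amplitude_fold > 1.0 and self.longitudinal_speed_um_s == 0:
            raise ValueError("a propagating front needs |u| > 0")
        if self.sidedness == "one_sided" and self.treated_flank_r_um is None:
            raise ValueError("one_sided scenarios must designate a treated flank")

    @property
    def has_wave(self) -> bool:
        return self.amplitude_fold > 1.0

    @property
    def logistic_scale_s(self) -> float:
        """Logistic time constant k such that the 10-90% rise spans tau."""
        return self.rise_time_s / (2.0 * np.log(9.0))

    def to_json(self) -> dict:
        return asdict(self)

    @classmethod
    def from_json(cls, d: dict) -> "Scenario":
        return cls(**d)


def activation_time(scenario: Scenario, s, r) -> np.ndarray:
    """Ground-truth activation (half-rise) time t_a for positions (s, r).

    Returns +inf for positions the front never reaches.  Pure function of
    the scenario; broadcasting over array s and r.
    """
    s = np.asarray(s, dtype=float)
    r = np.asarray(r, dtype=float)
    if not scenario.has_wave:
        return np.broadcast_to(np.inf, np.broadcast_shapes(s.shape, r.shape)).copy()

    u = scenario.longitudinal_speed_um_s
    ds = s - scenario.init_arclength_um
    if scenario.bidirectional:
        dt_long = np.abs(ds) / abs(u)
    else:
        dt_long = ds / u
        dt_long = np.where(dt_long >= 0, dt_long, np.inf)

    dt_trans = 0.0
    if scenario.sidedness == "one_sided" and scenario.transverse_speed_um_s:
        r_flank = scenario.treated_flank_r_um
        dt_trans = np.abs(r - r_flank) / scenario.transverse_speed_um_s
        if not scenario.crosses_midline:
            blocked = np.sign(r) == -np.sign(r_flank)
            dt_trans = np.where(blocked, np.inf, dt_trans)

    return scenario.onset_time_s + dt_long + dt_trans


def wave_multiplier(scenario: Scenario, s, r, t) -> np.ndarray:
    """Unitless intensity multiplier in [1, A] at positions (s, r), times t.

    Broadcasts over s, r, t; exactly 1 before onset, monotonically
    non-decreasing in t, plateau = amplitude_fold.
    """
    t = np.asarray(t, dtype=float)
    if not scenario.has_wave:
        return np.broadcast_to(
            1.0, np.broadcast_shapes(np.shape(s), np.shape(r), t.shape)).copy()
    t_a = activation_time(scenario, s, r)
    with np.errstate(over="ignore"):
        rise = expit((t - t_a) / scenario.logistic_scale_s)
    m = 1.0 + (scenario.amplitude_fold - 1.0) * rise
    return np.where(t >= scenario.onset_time_s, m, 1.0)
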