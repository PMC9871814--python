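"""Closed-form microfluidic transit model for the observation channel.

At a constant volumetric flow rate Q the solution front advances through
the free cross-section of the channel at

    v = Q / A_free,      A_free = A_chan · (1 − φ)

with φ the fraction of the cross-section occluded by the root, and fills a
channel of length L in t = L / v.  Comparing v with a measured signal
speed gives the decoupling ratio v_flow / v_signal: a large ratio excludes
advection of the stimulus as the carrier of the observed wave.

Defaults reproduce the study conditions: Q = 20 µL/min through a 12 mm
channel with an effective free cross-section of 48 900 µm² (back-calculated
from the printed transit speed; the chamber cross-section is not stated in
text), giving v ≈ 6.8×10³ µm/s and a fill time of ≈ 1.76 s — three orders
of magnitude above the 4–14 µm/s calcium waves.
"""

from __future__ import annotations

from dataclasses import dataclass

#: µm³ per µL
_UL_TO_UM3 = 1.0e9

#: decoupling threshold: flow faster than the signal by this factor
DECOUPLING_THRESHOLD = 100.0


@dataclass(frozen=True)
class ChannelSpec:
    """Observation-channel geometry and perfusion settings."""

    length_um: float = 12_000.0
    flow_rate_ul_min: float = 20.0
    cross_section_um2: float = 97_800.0     # open-channel cross-section
    root_occlusion_fraction: float = 0.5    # effective free-area fraction lost

    def __post_init__(self) -> None:
        if self.length_um <= 0:
            raise ValueError("length_um must be > 0")
        if self.flow_rate_ul_min <= 0:
            raise ValueError("flow_rate_ul_min must be > 0")
        if self.cross_section_um2 <= 0:
            raise ValueError("cross_section_um2 must be > 0")
        if not 0 <= self.root_occlusion_fraction < 1:
            raise ValueError("root_occlusion_fraction must be in [0, 1)")

    @property
    def free_area_um2(self) -> float:
        return self.cross_section_um2 * (1.0 - self.root_occlusion_fraction)

    @property
    def flow_rate_um3_s(self) -> float:
        return self.flow_rate_ul_min * _UL_TO_UM3 / 60.0


def transit_velocity(spec: ChannelSpec = ChannelSpec()) -> float:
    """Mean advective front speed v = Q / A_free in µm/s."""
    a_free = spec.free_area_um2
    if a_free <= 0:
        raise ValueError("free cross-section must be positive")
    return spec.flow_rate_um3_s / a_free


def fill_time(length_um: float, velocity_um_s: float) -> float:
    """Seconds for the solution front to traverse ``length_um``."""
    if length_um <= 0:
        raise ValueError("length_um must be > 0")
    if velocity_um_s <= 0:
        raise ValueError("velocity_um_s must be > 0")
    return length_um / velocity_um_s


def decoupling_ratio(
    v_flow_um_s: float, v_signal_um_s: float,
    threshold: float = DECOUPLING_THRESHOLD,
) -> tuple[float, bool]:
    """(v_flow / v_signal, advection-decoupled flag at the given threshold)."""
    if v_signal_um_s <= 0:
        raise ValueError("signal speed must be > 0")
    if v_flow_um_s <= 0:
        raise ValueError("flow speed must be > 0")
    ratio = v_flow_um_s / v_signal_um_s
    return ratio, ratio > threshold


def flow_report(spec: ChannelSpec = ChannelSpec(),
                signal_speed_um_s: float | None = None) -> dict:
    """Velocity, fill time and (optionally) the decoupling ratio as a dict."""
    v = transit_velocity(spec)
    out = {
        "transit_velocity_um_s": v,
        "fill_time_s": fill_time(spec.length_um, v),
        "free_area_um2": spec.free_area_um2,
    }
    if signal_speed_um_s is not None:
        ratio, decoupled = decoupling_ratio(v, signal_speed_um_s)
        out["decoupling_ratio"] = ratio
        out["advection_decoupled"] = decoupled
    return out
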