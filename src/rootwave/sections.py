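"""Five-section linear sampling along the root axis.

Five straight transects — Tip, ME1, ME2 (meristem/elongation) and ED1, ED2
(elongation/differentiation) — are placed perpendicular to the root axis at
arclengths anchor + (0, 290, 580, 870, 1450) µm from the tip, i.e. 290 µm
between sections 1–4 and 580 µm between sections 4 and 5.  Each section's
trace is the *mean* intensity (ADU) of the pixels within a half-width of
the transect, per frame (plot-profile semantics; the kymograph module sums
instead).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .stackio import ImageStack

log = logging.getLogger(__name__)

SECTION_LABELS = ("Tip", "ME1", "ME2", "ED1", "ED2")
DEFAULT_SPACINGS_UM = (290.0, 290.0, 290.0, 580.0)


@dataclass(frozen=True)
class SectionLayout:
    """Placement rule for the five sampling sections."""

    labels: tuple[str, ...] = SECTION_LABELS
    anchor_um: float = 0.0                       # arclength of section 1
    spacings_um: tuple[float, ...] = DEFAULT_SPACINGS_UM
    section_length_um: float = 120.0             # transect length across the root

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.spacings_um) + 1:
            raise ValueError("need one more label than spacings")
        if any(s <= 0 for s in self.spacings_um):
            raise ValueError("spacings must be positive")
        if self.section_length_um <= 0:
            raise ValueError("section_length_um must be positive")
        if self.anchor_um < 0:
            raise ValueError("anchor_um must be >= 0")

    @property
    def centre_arclengths_um(self) -> np.ndarray:
        return self.anchor_um + np.concatenate([[0.0], np.cumsum(self.spacings_um)])

    @property
    def span_um(self) -> float:
        return float(sum(self.spacings_um))


@dataclass(frozen=True)
class Section:
    """One placed transect: centre point, unit normal, half-length (µm)."""

    label: str
    centre_um: tuple[float, float]
    normal: tuple[float, float]          # unit vector perpendicular to the axis
    half_length_um: float
    arclength_um: float

    @property
    def endpoints_um(self) -> np.ndarray:
        c = np.asarray(self.centre_um)
        n = np.asarray(self.normal)
        return np.vstack([c - self.half_length_um * n, c + self.half_length_um * n])


@dataclass
class SectionTraces:
    """Per-section mean-intensity time series on a shared time grid."""

    times_s: np.ndarray
    traces: dict[str, np.ndarray]
    half_width_px: float

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        for label, v in self.traces.items():
            v = np.asarray(v, dtype=float)
            if v.shape != self.times_s.shape:
                raise ValueError(f"trace {label!r} length mismatch")
            if np.any(v < 0):
                raise ValueError(f"trace {label!r} has negative intensities")
            self.traces[label] = v

    def to_records(self) -> "pd.DataFrame":
        import pandas as pd

        rows = []
        for label, v in self.traces.items():
            rows.append(pd.DataFrame({
                "time_s": self.times_s, "section": label, "intensity_adu": v}))
        return pd.concat(rows, ignore_index=True)


def place_sections(
    axis_um: np.ndarray,
    layout: SectionLayout = SectionLayout(),
) -> list[Section]:
    """Place transects perpendicular to the axis at the layout arclengths.

    ``axis_um`` is the root axis polyline in frame-local µm coordinates,
    tip apex first.  Arclength is measured along the polyline (not the
    chord), so the section spacing is preserved on curved roots.
    """
    axis_um = np.asarray(axis_um, dtype=float)
    if axis_um.ndim != 2 or axis_um.shape[1] != 2 or len(axis_um) < 2:
        raise ValueError("axis must be an (M>=2, 2) polyline in µm")
    seg = np.diff(axis_um, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    if np.any(seg_len == 0):
        raise ValueError("axis has zero-length segments")
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]

    centres = layout.centre_arclengths_um
    required = float(centres[-1])
    if total < required:
        raise ValueError(
            f"root axis is {total:.0f} µm long but the section layout requires "
            f"{required:.0f} µm (anchor {layout.anchor_um:.0f} + span "
            f"{layout.span_um:.0f})"
        )

    sections = []
    for label, a in zip(layout.labels, centres):
        j = int(np.clip(np.searchsorted(cum, a, side="right") - 1, 0, len(seg) - 1))
        t = (a - cum[j]) / seg_len[j]
        centre = axis_um[j] + t * seg[j]
        tangent = seg[j] / seg_len[j]
        normal = (-tangent[1], tangent[0])
        sections.append(Section(label, (float(centre[0]), float(centre[1])),
                                (float(normal[0]), float(normal[1])),
                                layout.section_length_um / 2.0, float(a)))
    return sections


def extract_traces(
    stack: ImageStack,
    sections: list[Section],
    half_width_px: float = 2.0,
    root_mask: np.ndarray | None = None,
) -> SectionTraces:
    """Mean intensity within ``half_width_px`` of each transect, per frame.

    If ``root_mask`` is given, a transect whose pixel band misses the mask
    entirely triggers a warning (the trace is still computed).
    """
    h, w = stack.shape
    px = stack.pixel_size_um
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.column_stack([xx.ravel() * px, yy.ravel() * px])

    traces: dict[str, np.ndarray] = {}
    for sec in sections:
        c = np.asarray(sec.centre_um)
        n = np.asarray(sec.normal)
        tang = np.array([-n[1], n[0]])
        rel = pts - c
        along = rel @ n            # coordinate along the transect
        across = rel @ tang        # perpendicular offset from the transect line
        sel = (np.abs(along) <= sec.half_length_um) \
            & (np.abs(across) <= half_width_px * px)
        if not sel.any():
            raise ValueError(f"section {sec.label!r} lies outside the frame")
        ys, xs = yy.ravel()[sel], xx.ravel()[sel]
        if root_mask is not None and not root_mask[ys, xs].any():
            log.warning("section %s lies entirely outside the root mask", sec.label)
        traces[sec.label] = stack.frames[:, ys, xs].mean(axis=1)

    return SectionTraces(stack.times_s, traces, half_width_px)


def resample_trace(times_s: np.ndarray, values: np.ndarray, grid_s: np.ndarray) -> np.ndarray:
    """Linear-interpolation resampling of a trace onto an even grid.

    The grid must lie within the trace's time span; extrapolation is an
    error.  Grid nodes coinciding with native sample times reproduce the
    native values exactly.
    """
    times_s = np.asarray(times_s, dtype=float)
    values = np.asarray(values, dtype=float)
    grid_s = np.asarray(grid_s, dtype=float)
    if times_s.shape != values.shape:
        raise ValueError("times and values must have equal length")
    if np.any(np.diff(times_s) <= 0):
        raise ValueError("times must be strictly increasing")
    eps = 1e-9
    if grid_s.min() < times_s[0] - eps or grid_s.max() > times_s[-1] + eps:
        raise ValueError(
            f"grid [{grid_s.min():.4g}, {grid_s.max():.4g}] s extends beyond the "
            f"trace span [{times_s[0]:.4g}, {times_s[-1]:.4g}] s"
        )
    return np.interp(grid_s, times_s, values)
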