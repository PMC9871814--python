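"""Kymograph construction: per-frame intensity summation inside an ROI.

A kymograph collapses each frame to a 1-D profile by *summing* pixel
intensities in bins along the chosen image axis (longitudinal = along the
root, binned by x; transverse = across the root, binned by y, for the
tip-left horizontal stacks the simulator renders).  Bin assignment is by
pixel centre, so per-frame totals over all bins equal the ROI pixel sum
exactly — summation, not averaging, deliberately distinct from the section
traces which use the mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .stackio import ImageStack, RoiSpec

log = logging.getLogger(__name__)

AXES = ("longitudinal", "transverse")


@dataclass
class Kymograph:
    """P x T matrix of binned intensity sums (ADU)."""

    matrix: np.ndarray            # (P, T)
    positions_um: np.ndarray      # (P,) bin centres along the chosen axis
    times_s: np.ndarray           # (T,)
    axis: str                     # longitudinal | transverse
    roi: RoiSpec | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("kymograph matrix must be 2-D (positions x times)")
        p, t = self.matrix.shape
        if p < 2 or t < 2:
            raise ValueError("kymograph needs >= 2 positions and >= 2 times")
        if len(self.positions_um) != p or len(self.times_s) != t:
            raise ValueError("axis vectors do not match the matrix shape")
        if np.any(np.diff(self.positions_um) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.axis not in AXES:
            raise ValueError(f"axis must be one of {AXES}")
        if self.matrix.min() < 0:
            raise ValueError("kymograph intensities must be non-negative")


def build_kymograph(
    stack: ImageStack,
    roi: RoiSpec,
    axis: str = "longitudinal",
    bin_um: float | None = None,
) -> Kymograph:
    """Sum ROI pixel intensities into position bins, per frame.

    ``bin_um`` defaults to one pixel; narrower bins are rejected.  Every ROI
    pixel contributes to exactly one bin, keyed on its centre coordinate
    (x for the longitudinal axis, y for the transverse axis) in µm.
    """
    if axis not in AXES:
        raise ValueError(f"axis must be one of {AXES}")
    px = stack.pixel_size_um
    if bin_um is None:
        bin_um = px
    if bin_um < px - 1e-9:
        raise ValueError(f"bin_um = {bin_um} is narrower than a pixel ({px} µm)")

    mask = roi.mask(stack.shape)     # raises if the ROI leaves the frame
    ys, xs = np.nonzero(mask)
    if len(ys) == 0:
        raise ValueError("ROI covers no pixels")
    coord_px = xs if axis == "longitudinal" else ys
    coord_um = coord_px * px

    lo = coord_um.min()
    idx = np.floor((coord_um - lo) / bin_um + 1e-9).astype(np.intp)
    n_bins = int(idx.max()) + 1
    centres = lo + (np.arange(n_bins) + 0.5) * bin_um

    # sort pixels by bin once, then per-frame segment sums
    order = np.argsort(idx, kind="stable")
    idx_sorted = idx[order]
    ys_s, xs_s = ys[order], xs[order]
    boundaries = np.searchsorted(idx_sorted, np.arange(n_bins))
    occupied = np.unique(idx_sorted)

    pix = stack.frames[:, ys_s, xs_s].astype(np.int64)     # (T, N)
    sums = np.add.reduceat(pix, boundaries, axis=1)        # (T, n_bins)
    # reduceat repeats the next segment for empty bins; zero them
    empty = np.setdiff1d(np.arange(n_bins), occupied, assume_unique=False)
    if len(empty):
        sums[:, empty] = 0

    return Kymograph(sums.T, centres, stack.times_s, axis, roi)


def normalize_kymograph(
    kyms: Kymograph | list[Kymograph],
    mode: str = "global",
    percentile_clip: float | None = None,
) -> list[Kymograph]:
    """Min-max scale kymographs to [0, 1] for display.

    ``global`` maps one shared min/max over all inputs to 0/1 (the shared
    colour scale used when comparing samples); ``per_sample`` scales each
    independently.  ``percentile_clip = q`` replaces min/max by the q-th and
    (100-q)-th percentiles, clipping outliers.  A constant-valued input in
    per_sample mode maps to all zeros with a warning.
    """
    if mode not in ("global", "per_sample"):
        raise ValueError("mode must be 'global' or 'per_sample'")
    single = isinstance(kyms, Kymograph)
    klist = [kyms] if single else list(kyms)
    if not klist:
        raise ValueError("need at least one kymograph")

    def limits(arrs: list[np.ndarray]) -> tuple[float, float]:
        flat = np.concatenate([a.ravel() for a in arrs]).astype(float)
        if percentile_clip is not None:
            return (float(np.percentile(flat, percentile_clip)),
                    float(np.percentile(flat, 100 - percentile_clip)))
        return float(flat.min()), float(flat.max())

    out = []
    if mode == "global":
        lo, hi = limits([k.matrix for k in klist])
    for k in klist:
        if mode == "per_sample":
            lo, hi = limits([k.matrix])
        if hi <= lo:
            log.warning("constant-valued kymograph normalises to all zeros")
            norm = np.zeros_like(k.matrix, dtype=float)
        else:
            norm = np.clip((k.matrix.astype(float) - lo) / (hi - lo), 0.0, 1.0)
        out.append(Kymograph(norm, k.positions_um, k.times_s, k.axis, k.roi))
    return out


def kymograph_to_records(kym: Kymograph) -> "pd.DataFrame":
    """Long-format table (position_um, time_s, intensity_adu) for CSV export."""
    import pandas as pd

    p, t = np.meshgrid(kym.positions_um, kym.times_s, indexing="ij")
    return pd.DataFrame({
        "position_um": p.ravel(),
        "time_s": t.ravel(),
        "intensity_adu": kym.matrix.ravel(),
    })


def kymograph_from_records(df: "pd.DataFrame", axis: str = "longitudinal") -> Kymograph:
    """Rebuild a Kymograph from its long-format CSV table."""
    positions = np.unique(df["position_um"].to_numpy())
    times = np.unique(df["time_s"].to_numpy())
    pivot = df.pivot_table(index="position_um", columns="time_s",
                           values="intensity_adu")
    return Kymograph(pivot.to_numpy(), positions, times, axis)
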