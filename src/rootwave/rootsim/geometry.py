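"""Root geometry and its rasterisation into a coordinate-annotated phantom.

The visible root is modelled as a tube of constant radius around a
centerline polyline (tip first), closed by a hemispherical cap at the tip
and cut flat at the shoot end (the real root continues out of the field of
view).  Rasterisation assigns every root pixel an axial arclength ``s``
(µm, 0 at the tip apex, increasing shoot-ward) and a signed transverse
coordinate ``r`` (µm, across the midline) — the coordinate system in which
wave kinetics are defined and recovered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def polyline_project(points: np.ndarray, polyline: np.ndarray):
    """Project points onto a polyline.

    Parameters
    ----------
    points : (N, 2) array of (x, y)
    polyline : (M, 2) array of (x, y), M >= 2, non-degenerate segments

    Returns
    -------
    arclength : (N,) arclength of the nearest point, clamped to [0, total]
    signed_dist : (N,) distance to the nearest (clamped) foot point, signed
        by the cross product of the segment tangent with the offset (positive
        = left of the tangent direction).  For points projecting past an end
        this is the full Euclidean distance to the end vertex.
    overshoot : (N,) unclamped axial overshoot in µm past the ends
        (negative before the start, positive past the end, 0 in between)
    """
    pts = np.asarray(points, dtype=float)
    pl = np.asarray(polyline, dtype=float)
    seg = np.diff(pl, axis=0)                       # (M-1, 2)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    if np.any(seg_len == 0):
        raise ValueError("polyline has zero-length segments")
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])

    # vectorised over segments: N x (M-1)
    d = pts[:, None, :] - pl[None, :-1, :]
    t_raw = (d * seg[None]).sum(-1) / (seg_len ** 2)[None]
    t = np.clip(t_raw, 0.0, 1.0)
    foot = pl[None, :-1, :] + t[..., None] * seg[None]
    dist2 = ((pts[:, None, :] - foot) ** 2).sum(-1)
    j = np.argmin(dist2, axis=1)
    rows = np.arange(len(pts))

    arc = cum[j] + t[rows, j] * seg_len[j]
    off = pts - foot[rows, j]
    cross = seg[j, 0] * off[:, 1] - seg[j, 1] * off[:, 0]
    signed = np.sqrt(dist2[rows, j]) * np.sign(np.where(cross == 0, 1.0, cross))
    # perpendicular component only (for end overshoot the distance includes
    # the axial part; callers needing the pure perpendicular use first/last
    # segment projections via the overshoot)
    over = np.zeros(len(pts))
    first = j == 0
    over[first] += np.minimum(t_raw[first, 0], 0.0) * seg_len[0]
    last = j == len(seg) - 1
    over[last] += np.maximum(t_raw[last, -1] - 1.0, 0.0) * seg_len[-1]
    return arc, signed, over


@dataclass(frozen=True)
class RootGeometry:
    """Analytic geometry of the visible primary root.

    tissue_bands are fractional radii delimiting concentric annuli
    (stele | cortex | epidermis by default); they are annotation only and do
    not affect wave kinetics.
    """

    length_um: float
    radius_um: float
    centerline: np.ndarray = field(default=None)  # (M, 2) µm, tip apex first
    tissue_bands: tuple[float, ...] = (0.5, 0.8, 1.0)

    def __post_init__(self) -> None:
        if not self.length_um > 0:
            raise ValueError("length_um must be > 0")
        if not self.radius_um > 0:
            raise ValueError("radius_um must be > 0")
        if self.centerline is None:
            # default: straight horizontal root, tip at the left
            cl = np.array([[0.0, 0.0], [self.length_um, 0.0]])
            object.__setattr__(self, "centerline", cl)
        cl = np.asarray(self.centerline, dtype=float)
        if cl.ndim != 2 or cl.shape[1] != 2 or len(cl) < 2:
            raise ValueError("centerline must be an (M>=2, 2) polyline")
        seg = np.diff(cl, axis=0)
        if np.any(np.hypot(seg[:, 0], seg[:, 1]) == 0):
            raise ValueError("centerline has zero-length segments")
        object.__setattr__(self, "centerline", cl)
        bands = tuple(self.tissue_bands)
        if not bands or abs(bands[-1] - 1.0) > 1e-12 or np.any(np.diff(bands) <= 0) \
                or bands[0] <= 0:
            raise ValueError("tissue_bands must be strictly increasing and end at 1.0")

    @property
    def arclength_um(self) -> float:
        seg = np.diff(self.centerline, axis=0)
        return float(np.hypot(seg[:, 0], seg[:, 1]).sum())


@dataclass
class RootPhantom:
    """Rasterised root: boolean mask plus per-pixel (s, r) coordinates."""

    mask: np.ndarray              # (H, W) bool
    s_um: np.ndarray              # (H, W) float32, NaN outside the mask
    r_um: np.ndarray              # (H, W) float32, NaN outside the mask
    tissue: np.ndarray            # (H, W) int8, annulus index, -1 outside
    geometry: RootGeometry
    pixel_size_um: float
    origin_um: tuple[float, float]   # world coords of pixel (0, 0) centre

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def axis_polyline_px(self) -> np.ndarray:
        """Centerline (apex first) in pixel coordinates of this frame."""
        ox, oy = self.origin_um
        return (self.geometry.centerline - [ox, oy]) / self.pixel_size_um

    def axis_polyline_um(self) -> np.ndarray:
        """Centerline (apex first) in frame-local µm coordinates."""
        ox, oy = self.origin_um
        return self.geometry.centerline - [ox, oy]


def build_phantom(
    geometry: RootGeometry,
    pixel_size_um: float,
    frame_shape: tuple[int, int] | None = None,
    margin_um: float = 40.0,
) -> RootPhantom:
    """Rasterise a root geometry onto the camera pixel grid.

    If ``frame_shape`` is None the frame is sized to the root's bounding box
    plus ``margin_um`` on every side; otherwise the root must fit inside the
    given (H, W) frame or a ValueError is raised.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    cl = geometry.centerline
    rad = geometry.radius_um

    lo = cl.min(axis=0) - rad - margin_um
    hi = cl.max(axis=0) + rad + margin_um
    if frame_shape is None:
        w = int(np.ceil((hi[0] - lo[0]) / pixel_size_um))
        h = int(np.ceil((hi[1] - lo[1]) / pixel_size_um))
        origin = (float(lo[0]), float(lo[1]))
    else:
        h, w = frame_shape
        origin = (0.0, 0.0)
        need_w = (cl[:, 0].max() + rad) / pixel_size_um
        need_h = (cl[:, 1].max() + rad) / pixel_size_um
        if cl[:, 0].min() - rad < 0 or cl[:, 1].min() - rad < 0 \
                or need_w > w or need_h > h:
            raise ValueError(
                f"geometry exceeds the {h}x{w} frame "
                f"(needs {int(np.ceil(need_h))}x{int(np.ceil(need_w))} px)"
            )

    yy, xx = np.mgrid[0:h, 0:w]
    px_world = np.column_stack([
        origin[0] + (xx.ravel() + 0.0) * pixel_size_um,
        origin[1] + (yy.ravel() + 0.0) * pixel_size_um,
    ])
    # pixel centres: index i maps to origin + i*px (origin already at the
    # centre of pixel 0 by construction of lo)

    # axis truncated at arclength = radius so clamping at the tip end yields
    # the hemispherical cap; the shoot end is cut flat via the overshoot
    total = geometry.arclength_um
    if total < rad:
        raise ValueError("root shorter than its radius")
    axis = _resample_polyline(cl, rad, total)
    arc, signed, over = polyline_project(px_world, axis)
    dist = np.abs(signed)
    # body: perpendicular distance <= radius; tip cap: clamping at the axis
    # start makes `dist` the Euclidean distance to the cap centre; shoot end
    # is cut flat by excluding positive overshoot
    inside = (dist <= rad) & (over <= 0)
    # cap pixels: replace the full distance by its perpendicular component so
    # r stays a transverse coordinate
    cap = over < 0
    if cap.any():
        seg0 = axis[1] - axis[0]
        l0 = float(np.hypot(*seg0))
        rel = px_world[cap] - axis[0]
        signed[cap] = (seg0[0] * rel[:, 1] - seg0[1] * rel[:, 0]) / l0
    # s = axial coordinate from the apex (apex sits one radius tip-ward of
    # the truncated axis start)
    s = np.clip(rad + arc + np.minimum(over, 0.0), 0.0, None)

    mask = inside.reshape(h, w)
    if not mask.any():
        raise ValueError("rasterised root is empty at this pixel size")
    s_img = np.full((h, w), np.nan, dtype=np.float32)
    r_img = np.full((h, w), np.nan, dtype=np.float32)
    s_img[mask] = s.reshape(h, w)[mask]
    r_img[mask] = signed.reshape(h, w)[mask]

    tissue = np.full((h, w), -1, dtype=np.int8)
    frac = np.abs(r_img[mask]) / rad
    bands = np.asarray(geometry.tissue_bands)
    tissue[mask] = np.minimum(np.searchsorted(bands, frac), len(bands) - 1)

    return RootPhantom(mask, s_img, r_img, tissue, geometry, pixel_size_um,
                       (origin[0], origin[1]))


def _resample_polyline(cl: np.ndarray, start_arc: float, total: float) -> np.ndarray:
    """Sub-polyline from arclength ``start_arc`` to the end."""
    seg = np.diff(cl, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    j = int(np.searchsorted(cum, start_arc, side="right") - 1)
    j = min(j, len(seg) - 1)
    t = (start_arc - cum[j]) / seg_len[j]
    start_pt = cl[j] + t * seg[j]
    pts = [start_pt] + [cl[k] for k in range(j + 1, len(cl))]
    out = np.asarray(pts)
    if len(out) < 2:  # start beyond the last vertex
        out = np.vstack([start_pt, cl[-1]])
    return out
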