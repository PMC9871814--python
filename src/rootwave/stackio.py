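"""Reading and writing the pipeline's on-disk formats.

The interchange formats are deliberately plain: multi-page grayscale TIFF
for image stacks (acquisition metadata in the TIFF description tag, with a
JSON companion file as fallback), JSON for ROIs / ground truth / wave fits,
and long-format CSV for kymographs and section traces.  Pixel indices are
0-based, origin top-left, y down; arclength positions are reported in µm
from the root tip apex.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

log = logging.getLogger(__name__)

#: metadata keys embedded in the TIFF description / companion JSON
_META_KEYS = ("pixel_size_um", "frame_interval_s", "bit_depth")


@dataclass
class ImageStack:
    """A T x H x W fluorescence time-lapse in raw camera counts (ADU)."""

    frames: np.ndarray            # (T, H, W) unsigned integers
    pixel_size_um: float
    frame_interval_s: float
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be T x H x W, got shape {self.frames.shape}")
        if self.frames.shape[0] < 2:
            raise ValueError("a stack needs at least 2 frames")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.frames.min() < 0:
            raise ValueError("ADU counts must be non-negative")
        if self.frames.max() > 2 ** self.bit_depth - 1:
            raise ValueError("frame values exceed the stated bit depth")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(H, W) of a single frame."""
        return self.frames.shape[1:]

    @property
    def times_s(self) -> np.ndarray:
        """Frame acquisition times; frame i at i * frame_interval_s."""
        return np.arange(self.n_frames) * self.frame_interval_s

    @property
    def duration_s(self) -> float:
        return (self.n_frames - 1) * self.frame_interval_s


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a multi-page grayscale TIFF with metadata in the description tag.

    A companion ``<basename>.meta.json`` is written next to the TIFF so the
    metadata survives tools that strip tags.
    """
    path = Path(path)
    meta = {k: getattr(stack, k) for k in _META_KEYS}
    dtype = np.uint8 if stack.bit_depth == 8 else np.uint16
    tifffile.imwrite(path, stack.frames.astype(dtype),
                     photometric="minisblack", description=json.dumps(meta))
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))
    return path


def read_stack(
    path: str | Path,
    pixel_size_um: float | None = None,
    frame_interval_s: float | None = None,
) -> ImageStack:
    """Load a multi-page TIFF stack losslessly.

    Metadata is taken from the TIFF description tag, then from the companion
    ``.meta.json``, then from the keyword overrides (with a logged warning).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        shapes = {p.shape for p in tf.pages}
        if len(shapes) != 1:
            raise ValueError(f"ragged page sizes in {path}: {sorted(shapes)}")
        compressions = {p.compression.name for p in tf.pages}
        unsupported = compressions - {"NONE", "ADOBE_DEFLATE", "DEFLATE", "LZW", "PACKBITS"}
        if unsupported:
            raise ValueError(f"unsupported TIFF compression: {sorted(unsupported)}")
        frames = tf.asarray()
        desc = tf.pages[0].description
    if frames.ndim == 2:
        frames = frames[None]

    meta: dict = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    if not meta:
        companion = path.with_suffix(path.suffix + ".meta.json")
        if companion.exists():
            meta = json.loads(companion.read_text())

    px = meta.get("pixel_size_um", pixel_size_um)
    dt = meta.get("frame_interval_s", frame_interval_s)
    if px is None or dt is None:
        raise ValueError(
            f"{path}: no embedded metadata; pass pixel_size_um and frame_interval_s"
        )
    if "pixel_size_um" not in meta:
        log.warning("%s: pixel size not embedded, using supplied %.3g µm/px", path, px)
    if "frame_interval_s" not in meta:
        log.warning("%s: frame interval not embedded, using supplied %.3g s", path, dt)
    bit_depth = meta.get("bit_depth", 8 if frames.dtype == np.uint8 else 16)
    return ImageStack(frames, float(px), float(dt), int(bit_depth))


# ---------------------------------------------------------------------------
# Regions of interest


@dataclass
class RoiSpec:
    """A region of interest in 0-based pixel-centre coordinates.

    kind:
      * ``rectangle`` — vertices = [[x0, y0], [x1, y1]], inclusive corners
      * ``polygon`` — simple polygon, vertices in order
      * ``polyline`` — open polyline buffered by ``width_px`` (half on each side)
    """

    kind: str
    vertices: np.ndarray          # (N, 2) as (x, y)
    width_px: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("rectangle", "polygon", "polyline"):
            raise ValueError(f"unknown ROI kind {self.kind!r}")
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (N, 2) array of (x, y)")
        n_min = {"rectangle": 2, "polygon": 3, "polyline": 2}[self.kind]
        if len(self.vertices) < n_min:
            raise ValueError(f"{self.kind} ROI needs >= {n_min} vertices")
        if self.kind == "polyline" and not self.width_px:
            raise ValueError("polyline ROI requires width_px > 0")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean H x W membership mask; raises if the ROI leaves the frame."""
        h, w = shape
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        pad = (self.width_px or 0.0) / 2.0
        if (x.min() < -0.5 - pad or y.min() < -0.5 - pad
                or x.max() > w - 0.5 + pad or y.max() > h - 0.5 + pad):
            raise ValueError(f"ROI vertices fall outside the {h}x{w} frame")
        m = np.zeros(shape, dtype=bool)
        if self.kind == "rectangle":
            (x0, y0), (x1, y1) = self.vertices.min(0), self.vertices.max(0)
            m[int(round(y0)): int(round(y1)) + 1, int(round(x0)): int(round(x1)) + 1] = True
        elif self.kind == "polygon":
            from skimage.draw import polygon

            rr, cc = polygon(y, x, shape=shape)
            m[rr, cc] = True
        else:  # buffered polyline
            from .rootsim.geometry import polyline_project

            yy, xx = np.mgrid[0:h, 0:w]
            pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
            _, dist, _ = polyline_project(pts, self.vertices)
            m = (np.abs(dist) <= self.width_px / 2.0).reshape(shape)
        return m

    def to_json(self) -> dict:
        d = {"kind": self.kind, "vertices": self.vertices.tolist()}
        if self.width_px is not None:
            d["width_px"] = self.width_px
        if self.label is not None:
            d["label"] = self.label
        return d

    @classmethod
    def from_json(cls, d: dict) -> "RoiSpec":
        return cls(d["kind"], np.asarray(d["vertices"], float),
                   d.get("width_px"), d.get("label"))


def write_roi(roi: RoiSpec, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(roi.to_json(), indent=1))
    return path


def read_roi(path: str | Path) -> RoiSpec:
    return RoiSpec.from_json(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Tabular outputs

KYMOGRAPH_COLUMNS = ("position_um", "time_s", "intensity_adu")
TRACE_COLUMNS = ("time_s", "section", "intensity_adu")


def write_table(records: pd.DataFrame | list[dict], path: str | Path) -> Path:
    """Write a kymograph or trace table as CSV with a fixed header.

    The schema is recognised from the columns; mixing schemas (or any other
    column set) is an error.  Numbers are written at full precision.
    """
    df = pd.DataFrame(records)
    cols = tuple(df.columns) if len(df) or df.columns.size else None
    if cols is None:
        raise ValueError("records carry no schema (no columns)")
    if set(cols) == set(KYMOGRAPH_COLUMNS):
        df = df[list(KYMOGRAPH_COLUMNS)]
    elif set(cols) == set(TRACE_COLUMNS):
        df = df[list(TRACE_COLUMNS)]
    else:
        raise ValueError(
            f"unrecognised or mixed table schema {cols}; expected "
            f"{KYMOGRAPH_COLUMNS} or {TRACE_COLUMNS}"
        )
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
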