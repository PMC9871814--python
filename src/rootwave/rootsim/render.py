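"""Render a phantom + scenario into a noisy camera stack with ground truth.

The image model per frame is

    I = clip( blur( background + mask · B · m(s, r, t) ) + noise, bit depth )

with a Gaussian point-spread blur of scale ``psf_sigma_um``, Poisson shot
noise applied at a photon-equivalent gain, and additive Gaussian read
noise.  Identical seeds produce byte-identical stacks.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from ..stackio import ImageStack
from .geometry import RootPhantom
from .scenario import Scenario, activation_time

log = logging.getLogger(__name__)

#: frames per chunk when evaluating the multiplier / drawing noise
_CHUNK = 64


@dataclass(frozen=True)
class Camera:
    """Acquisition parameters of the emulated epifluorescence camera.

    Defaults emulate the study conditions: 568 frames over 180 s
    (Δt = 180/568 ≈ 0.3169 s), 2 µm/px at a low-magnification objective,
    16-bit counts with a ~2000 ADU in-root baseline over a ~200 ADU chamber
    background, unit photon gain and 20 ADU read noise.
    """

    pixel_size_um: float = 2.0
    n_frames: int = 568
    frame_interval_s: float = 180.0 / 568.0
    bit_depth: int = 16
    baseline_adu: float = 2000.0
    background_adu: float = 200.0
    psf_sigma_um: float = 2.0
    shot_noise_gain: float = 1.0      # ADU per photon-equivalent; 0 disables
    read_noise_adu: float = 20.0      # Gaussian sigma; 0 disables
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if not self.baseline_adu > self.background_adu >= 0:
            raise ValueError("need baseline_adu > background_adu >= 0")
        if self.shot_noise_gain < 0 or self.read_noise_adu < 0 or self.psf_sigma_um < 0:
            raise ValueError("noise and blur parameters must be >= 0")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s

    def to_json(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Machine-readable truth paired with a rendered stack."""

    scenario: Scenario
    camera: Camera
    s_grid_um: np.ndarray         # coarse arclength grid
    t_a_s: np.ndarray             # activation times on the grid (treated flank)
    stack_sha256: str | None = None

    def activation_time(self, s, r) -> np.ndarray:
        return activation_time(self.scenario, s, r)

    def to_json(self) -> dict:
        return {
            "scenario": self.scenario.to_json(),
            "camera": self.camera.to_json(),
            "s_grid_um": np.asarray(self.s_grid_um).tolist(),
            "t_a_s": [None if not np.isfinite(v) else float(v) for v in self.t_a_s],
            "stack_sha256": self.stack_sha256,
        }

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_json(), indent=1))
        return path

    @classmethod
    def from_json(cls, d: dict) -> "GroundTruth":
        t_a = np.array([np.inf if v is None else v for v in d["t_a_s"]], float)
        return cls(Scenario.from_json(d["scenario"]), Camera(**d["camera"]),
                   np.asarray(d["s_grid_um"], float), t_a, d.get("stack_sha256"))

    @classmethod
    def read(cls, path: str | Path) -> "GroundTruth":
        return cls.from_json(json.loads(Path(path).read_text()))


def render_stack(
    phantom: RootPhantom,
    scenario: Scenario,
    camera: Camera,
    noise: bool = True,
    blur: bool = True,
) -> tuple[ImageStack, GroundTruth]:
    """Render the full time-lapse and its ground-truth sidecar.

    ``noise=False`` disables both shot and read noise; ``blur=False`` (or
    ``psf_sigma_um = 0``) disables the optical blur.  With both off, root
    pixels carry exactly background + baseline · multiplier before clipping.
    """
    h, w = phantom.shape
    t = camera.times_s
    ys, xs = np.nonzero(phantom.mask)
    s = phantom.s_um[ys, xs].astype(np.float64)
    r = phantom.r_um[ys, xs].astype(np.float64)
    t_a = activation_time(scenario, s, r)
    k = scenario.logistic_scale_s
    amp = scenario.amplitude_fold - 1.0
    rng = np.random.default_rng(camera.seed)

    maxval = float(2 ** camera.bit_depth - 1)
    dtype = np.uint8 if camera.bit_depth == 8 else np.uint16
    sigma_px = camera.psf_sigma_um / camera.pixel_size_um if blur else 0.0

    # signal can differ from the flat background only inside the blur-dilated
    # root rows; pure-background rows take (cheaper) constant-rate noise
    pad = int(np.ceil(4 * sigma_px)) + 1
    y0 = max(int(ys.min()) - pad, 0)
    y1 = min(int(ys.max()) + pad + 1, h)
    ysb = ys - y0

    frames = np.empty((camera.n_frames, h, w), dtype=dtype)
    bg = camera.background_adu
    gain = camera.shot_noise_gain

    def add_noise(arr: np.ndarray) -> np.ndarray:
        if gain > 0:
            arr = rng.poisson(arr / gain) * gain
        arr = np.asarray(arr, dtype=np.float32)
        if camera.read_noise_adu > 0:
            arr += camera.read_noise_adu * rng.standard_normal(arr.shape,
                                                               dtype=np.float32)
        return arr

    def add_flat_noise(shape: tuple) -> np.ndarray:
        out = (rng.poisson(bg / gain, size=shape) * gain if gain > 0
               else np.full(shape, bg))
        out = np.asarray(out, dtype=np.float32)
        if camera.read_noise_adu > 0:
            out += camera.read_noise_adu * rng.standard_normal(shape,
                                                               dtype=np.float32)
        return out

    n_saturated = 0
    for i0 in range(0, camera.n_frames, _CHUNK):
        tc = t[i0:i0 + _CHUNK]
        nc = len(tc)
        if scenario.has_wave:
            with np.errstate(over="ignore"):
                m = 1.0 + amp * expit((tc[:, None] - t_a[None, :]) / k)
            m[tc < scenario.onset_time_s, :] = 1.0
        else:
            m = np.ones((nc, len(s)))
        band = np.full((nc, y1 - y0, w), bg, dtype=np.float32)
        band[:, ysb, xs] = bg + camera.baseline_adu * m
        if sigma_px > 0:
            gaussian_filter(band, sigma=(0, sigma_px, sigma_px),
                            output=band, mode="nearest")
        if noise:
            band = add_noise(band)
        n_saturated += int((band >= maxval).sum())
        np.clip(np.rint(band), 0, maxval, out=band)
        frames[i0:i0 + nc, y0:y1, :] = band
        for r0, r1 in ((0, y0), (y1, h)):
            if r1 > r0:
                if noise:
                    flat = add_flat_noise((nc, r1 - r0, w))
                    n_saturated += int((flat >= maxval).sum())
                    np.clip(np.rint(flat), 0, maxval, out=flat)
                    frames[i0:i0 + nc, r0:r1, :] = flat
                else:
                    frames[i0:i0 + nc, r0:r1, :] = dtype(round(bg))

    frac_sat = n_saturated / frames.size
    if frac_sat > 0.01:
        log.warning("rendered stack saturates %.1f%% of pixels", 100 * frac_sat)
    image = ImageStack(frames, camera.pixel_size_um, camera.frame_interval_s,
                       camera.bit_depth)

    s_grid = np.arange(0.0, float(np.nanmax(phantom.s_um)) + 1e-9, 10.0)
    r_truth = scenario.treated_flank_r_um if scenario.sidedness == "one_sided" else 0.0
    truth = GroundTruth(
        scenario, camera, s_grid,
        activation_time(scenario, s_grid, np.full_like(s_grid, r_truth)),
        stack_sha256=hashlib.sha256(frames.tobytes()).hexdigest(),
    )
    return image, truth
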