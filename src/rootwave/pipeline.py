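"""End-to-end orchestration: simulate → kymograph → sections → wave fits.

The pipeline renders (or loads) stacks, builds longitudinal and — for
one-sided treatments — transverse kymographs, extracts the five-section
traces, and estimates speeds, directions and fold changes, one summary row
per replicate.  Everything is deterministic given the configured seeds:
replicate i of a run with base seed b uses camera seed b + i.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import rootsim, stackio, kymo, sections as sections_mod, wavekin
from .rootsim import Camera, RootGeometry, RootPhantom

log = logging.getLogger(__name__)


def longitudinal_roi(phantom: RootPhantom, trim_um: float = 20.0) -> stackio.RoiSpec:
    """Rectangle ROI over the full-width root body.

    Columns where the root does not span its full width — the rounded tip
    cap and a blur margin at either end (``trim_um``) — are excluded:
    transverse summation over a partial transect has a different amplitude
    and rise shape, which would bias front times at the ends of the
    kymograph.
    """
    ys, xs = np.nonzero(phantom.mask)
    s = phantom.s_um[ys, xs]
    lo = phantom.geometry.radius_um + trim_um
    hi = float(np.nanmax(phantom.s_um)) - trim_um
    body = (s >= lo) & (s <= hi)
    if not body.any():
        raise ValueError("root too short for a full-width kymograph ROI")
    return stackio.RoiSpec(
        "rectangle",
        [[int(xs[body].min()), int(ys.min())], [int(xs[body].max()), int(ys.max())]],
        label="root_body",
    )


def transverse_roi(
    phantom: RootPhantom,
    centre_arclength_um: float,
    span_um: float = 200.0,
    toward_tip: bool = True,
    trim_um: float = 20.0,
) -> stackio.RoiSpec:
    """Rectangle across the root width next to an arclength locus.

    The window covers ``span_um`` of arclength ending (``toward_tip``) or
    starting at the locus — the region where a transversely propagating
    front is read out.  Rows within ``trim_um`` of the flank boundaries are
    excluded: optical blur mixes them asymmetrically with background.
    """
    if toward_tip:
        lo, hi = centre_arclength_um - span_um, centre_arclength_um
    else:
        lo, hi = centre_arclength_um, centre_arclength_um + span_um
    sel = phantom.mask & (phantom.s_um >= lo) & (phantom.s_um <= hi)
    if not sel.any():
        raise ValueError(f"no root pixels with arclength in [{lo}, {hi}] µm")
    rad = phantom.geometry.radius_um
    interior = sel & (np.abs(phantom.r_um) <= rad - trim_um)
    if not interior.any():
        interior = sel
    ys, xs = np.nonzero(interior)
    return stackio.RoiSpec(
        "rectangle",
        [[int(xs.min()), int(ys.min())], [int(xs.max()), int(ys.max())]],
        label=f"transverse@{centre_arclength_um:.0f}um",
    )


def analyze_replicate(
    stack: stackio.ImageStack,
    phantom: RootPhantom,
    scenario: rootsim.Scenario,
    background_adu: float,
    front_cfg: wavekin.FrontConfig = wavekin.FrontConfig(),
    half_width_px: float = 2.0,
) -> dict:
    """All per-replicate metrics from one stack: speeds, direction, folds."""
    roi = longitudinal_roi(phantom)
    kym_l = kymo.build_kymograph(stack, roi, "longitudinal")

    out: dict = {"direction": "none", "speed_um_s": np.nan,
                 "speed_magnitude_um_s": np.nan,
                 "branch_tipward_um_s": np.nan, "branch_shootward_um_s": np.nan,
                 "transverse_speed_um_s": np.nan, "n_front_positions": 0}
    try:
        fit = wavekin.estimate_wave(kym_l, front_cfg)
        out.update(
            direction=fit.direction,
            speed_um_s=fit.speed_um_s,
            speed_magnitude_um_s=abs(fit.speed_um_s),
            n_front_positions=fit.n_positions_used,
        )
        if fit.branch_speeds_um_s is not None:
            tipward, shootward = fit.branch_speeds_um_s
            out.update(branch_tipward_um_s=tipward, branch_shootward_um_s=shootward,
                       speed_magnitude_um_s=(abs(tipward) + abs(shootward)) / 2.0)
    except ValueError as err:
        log.info("no longitudinal wave: %s", err)

    if scenario.sidedness == "one_sided" and scenario.transverse_speed_um_s:
        toward_tip = scenario.longitudinal_speed_um_s < 0 or scenario.bidirectional
        try:
            kym_t = kymo.build_kymograph(
                stack,
                transverse_roi(phantom, scenario.init_arclength_um,
                               toward_tip=toward_tip),
                "transverse")
            fit_t = wavekin.transverse_speed(kym_t, front_cfg)
            out["transverse_speed_um_s"] = abs(fit_t.speed_um_s)
        except ValueError as err:
            log.info("no transverse wave: %s", err)

    layout = sections_mod.SectionLayout()
    secs = sections_mod.place_sections(phantom.axis_polyline_um(), layout)
    traces = sections_mod.extract_traces(stack, secs, half_width_px,
                                         root_mask=phantom.mask)
    for label in layout.labels:
        try:
            fc = wavekin.fold_change(traces.times_s, traces.traces[label],
                                     baseline_window_s=front_cfg.baseline_window_s,
                                     background_adu=background_adu)
        except ValueError:
            fc = np.nan
        out[f"fold_change_{label.lower()}"] = fc
    return out


@dataclass
class RunConfig:
    """Fully serialisable run description; config + seeds reproduce outputs."""

    presets: list[str] = field(default_factory=lambda: ["control"])
    n_replicates: int | None = None        # None → each preset's tabulated n
    base_seed: int = 1
    out_dir: str | None = None
    noise: bool = True
    write_stacks: bool = False
    camera: dict = field(default_factory=dict)        # Camera field overrides
    front: dict = field(default_factory=dict)         # FrontConfig overrides
    half_width_px: float = 2.0

    @classmethod
    def from_mapping(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_json(self) -> dict:
        return asdict(self)


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Run every preset x replicate and return the summary table.

    With ``out_dir`` set, writes summary.csv, the effective config, a log,
    and (``write_stacks``) each rendered stack + ground truth.  Any stage
    error aborts with a stage-named message; partial outputs stay on disk
    next to a FAILED marker.
    """
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "config.json").write_text(json.dumps(config.to_json(), indent=1))

    camera = Camera(**{**config.camera, "seed": 0})
    front_cfg = wavekin.FrontConfig(**config.front)
    geometry = rootsim.DEFAULT_GEOMETRY
    phantom = rootsim.build_phantom(geometry, camera.pixel_size_um)

    rows = []
    try:
        for preset in config.presets:
            scenario = rootsim.preset_scenario(preset, geometry)
            n = config.n_replicates or rootsim.preset_n_replicates(preset)
            for i in range(n):
                seed = config.base_seed + i
                try:
                    stack, truth = rootsim.generate_preset(
                        preset, seed, geometry, camera, config.noise, phantom)
                except Exception as err:
                    raise RuntimeError(f"[simulate] {preset} seed {seed}: {err}") from err
                if out_dir and config.write_stacks:
                    stem = out_dir / f"{preset}_seed{seed}"
                    stackio.write_stack(stack, stem.with_suffix(".tif"))
                    truth.write(stem.with_suffix(".truth.json"))
                try:
                    metrics = analyze_replicate(
                        stack, phantom, scenario, camera.background_adu,
                        front_cfg, config.half_width_px)
                except Exception as err:
                    raise RuntimeError(f"[analyze] {preset} seed {seed}: {err}") from err
                rows.append({"preset": preset, "seed": seed, **metrics})
                log.info("%s seed %d: %s %.3g µm/s", preset, seed,
                         rows[-1]["direction"], rows[-1]["speed_um_s"])
    except Exception:
        if out_dir:
            (out_dir / "FAILED").write_text("pipeline aborted; partial outputs kept\n")
        raise

    summary = pd.DataFrame(rows)
    if out_dir:
        summary.to_csv(out_dir / "summary.csv", index=False)
    return summary


def report(summary: pd.DataFrame) -> pd.DataFrame:
    """Per-preset replicate aggregation: mean, SD (n−1), n, modal direction."""
    out = []
    for preset, grp in summary.groupby("preset", sort=False):
        speeds = grp["speed_magnitude_um_s"].dropna()
        stats = (wavekin.summarize_replicates(speeds)
                 if len(speeds) else wavekin.ReplicateSummary(np.nan, np.nan, 0, ()))
        row = {
            "preset": preset,
            "n": len(grp),
            "direction": grp["direction"].mode().iat[0],
            "speed_mean_um_s": stats.mean,
            "speed_sd_um_s": stats.sd,
            "n_speed": stats.n,
        }
        for col in ("transverse_speed_um_s", "fold_change_tip"):
            vals = grp[col].dropna()
            row[col.replace("_um_s", "") + "_mean"] = vals.mean() if len(vals) else np.nan
        out.append(row)
    return pd.DataFrame(out)
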