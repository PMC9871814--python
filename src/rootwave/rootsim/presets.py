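"""Scenario presets encoding the study's treatment configurations.

Each preset fixes the wave ground truth (initiation site, signed speeds,
plateau fold) for one treatment x site x sidedness combination; rendering a
preset with different seeds yields independent noise realisations of the
same underlying dynamics.  Replicate i of a run with base seed b uses
camera seed b + i.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np

from .geometry import RootGeometry, RootPhantom, build_phantom
from .render import Camera, GroundTruth, render_stack
from .scenario import Scenario
from ..stackio import ImageStack

#: default visible-root geometry: 3 mm of straight root, 60 µm half-width
DEFAULT_GEOMETRY = RootGeometry(length_um=3000.0, radius_um=60.0)


def _load_table() -> dict:
    text = resources.files("rootwave.rootsim").joinpath("data/presets.json").read_text()
    return json.loads(text)["presets"]


_TABLE = _load_table()


def preset_names() -> list[str]:
    return sorted(_TABLE)


def preset_table() -> dict:
    """The raw machine-readable preset table (a fresh copy)."""
    return json.loads(json.dumps(_TABLE))


def preset_scenario(preset_name: str, geometry: RootGeometry = DEFAULT_GEOMETRY) -> Scenario:
    """Build the Scenario for a named preset on the given geometry."""
    if preset_name not in _TABLE:
        raise KeyError(
            f"unknown preset {preset_name!r}; valid presets: {', '.join(preset_names())}"
        )
    row = _TABLE[preset_name]
    flank = row.get("treated_flank")
    return Scenario(
        preset_name=preset_name,
        treatment_site=row["treatment_site"],
        sidedness=row["sidedness"],
        init_arclength_um=row["init_arclength_um"],
        longitudinal_speed_um_s=row["longitudinal_speed_um_s"],
        amplitude_fold=row["amplitude_fold"],
        bidirectional=row.get("bidirectional", False),
        transverse_speed_um_s=row.get("transverse_speed_um_s"),
        treated_flank_r_um=None if flank is None else flank * geometry.radius_um,
        crosses_midline=row.get("crosses_midline", True),
    )


def preset_n_replicates(preset_name: str) -> int:
    if preset_name not in _TABLE:
        raise KeyError(
            f"unknown preset {preset_name!r}; valid presets: {', '.join(preset_names())}"
        )
    return _TABLE[preset_name]["n_replicates"]


def generate_preset(
    preset_name: str,
    seed: int,
    geometry: RootGeometry = DEFAULT_GEOMETRY,
    camera: Camera | None = None,
    noise: bool = True,
    phantom: RootPhantom | None = None,
) -> tuple[ImageStack, GroundTruth]:
    """Render one replicate of a named preset.

    Passing a pre-built ``phantom`` (matching geometry and pixel size) skips
    re-rasterisation when rendering many replicates.
    """
    scenario = preset_scenario(preset_name, geometry)
    if camera is None:
        camera = Camera(seed=seed)
    else:
        camera = Camera(**{**camera.to_json(), "seed": seed})
    if phantom is None:
        phantom = build_phantom(geometry, camera.pixel_size_um)
    return render_stack(phantom, scenario, camera, noise=noise)
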