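"""Seeded synthetic fixtures for every stage of the pipeline.

Generates (a) polarimeter frame stacks with their ground-truth polarization
maps — homogeneous calibration beams (linear at -45 deg, circular) and the
sectored-retarder radial beam — and (b) cross-polarized confocal image series
of a birefringent fiber in air or on skin, at several fiber orientations and
focusing depths, with fiber/background masks and a JSON manifest.  Everything
is deterministic given the spec's seed: two generations from the same spec
are byte-identical on disk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile

from . import confocal_model, polarimetry, svr_model
from .polarization_core import StokesVector
from .confocal_model import (
    ConfocalImage,
    FiberScene,
    IlluminationState,
    InstrumentConfig,
)
from .polarimetry import CameraModel, DEFAULT_PROTOCOL, FrameStack
from .svr_model import PolarizationMap, SVRConfig

__all__ = [
    "POLARIMETER_SCENARIOS",
    "FIBER_SCENARIOS",
    "FixtureSpec",
    "make_polarimeter_fixture",
    "make_confocal_fixture",
    "camera_digitize",
]

POLARIMETER_SCENARIOS = ("homogeneous_linear_m45", "homogeneous_circular", "svr_radial")
FIBER_SCENARIOS = ("fiber_in_air", "fiber_in_skin")

#: default skin background: 5% of the fiber signal level, with speckle
SKIN_BACKGROUND = 0.05
SKIN_SPECKLE_SIGMA = 0.2
#: air background floor (avoids zero denominators in the ratio statistic)
AIR_BACKGROUND = 0.001


@dataclass
class FixtureSpec:
    """Fully serializable description of one synthetic data set."""

    scenario: str
    grid_shape: tuple[int, int] = (256, 256)  # polarimeter map size
    camera: CameraModel | None = field(default_factory=CameraModel)
    instrument: InstrumentConfig | None = None
    scene: FiberScene | None = None
    illumination_mode: str = "linear"
    orientations: tuple[float, ...] = (0.0, 45.0)
    depths: tuple[float, ...] = (20.0,)
    n_averaged: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in POLARIMETER_SCENARIOS + FIBER_SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")


def _truth_map(spec: FixtureSpec) -> PolarizationMap:
    if spec.scenario == "homogeneous_linear_m45":
        state = StokesVector.linear(-45.0)
        stokes = np.broadcast_to(state.as_array(), spec.grid_shape + (4,)).copy()
        return PolarizationMap(stokes)
    if spec.scenario == "homogeneous_circular":
        state = StokesVector.circular(+1)
        stokes = np.broadcast_to(state.as_array(), spec.grid_shape + (4,)).copy()
        return PolarizationMap(stokes)
    # svr_radial: horizontal beam through the default 8-sector device
    return svr_model.transmit(StokesVector.linear(0.0), SVRConfig(), spec.grid_shape)


def make_polarimeter_fixture(spec: FixtureSpec, out_dir: str | Path | None = None
                             ) -> tuple[FrameStack, PolarizationMap]:
    """Truth map + simulated frame stack for a polarimetry scenario.

    Writes the stack (8-bit TIFFs + manifest) and the truth map (float TIFF +
    mask + sidecar) under ``out_dir`` when given.
    """
    if spec.scenario not in POLARIMETER_SCENARIOS:
        raise ValueError(f"{spec.scenario!r} is not a polarimetry scenario")
    truth = _truth_map(spec)
    stack = polarimetry.simulate_stack(truth, DEFAULT_PROTOCOL, spec.camera,
                                       spec.n_averaged, spec.seed)
    if out_dir is not None:
        out_dir = Path(out_dir)
        polarimetry.save_frame_stack(stack, out_dir / "stack")
        svr_model.save_polarization_map(truth, out_dir / "truth")
    return stack, truth


def _confocal_scene(spec: FixtureSpec) -> FiberScene:
    if spec.scene is not None:
        return spec.scene
    if spec.scenario == "fiber_in_skin":
        return FiberScene(background_level=SKIN_BACKGROUND,
                          background_texture_sigma=SKIN_SPECKLE_SIGMA)
    return FiberScene(background_level=AIR_BACKGROUND)


def _illumination(spec: FixtureSpec, theta: float) -> IlluminationState:
    if spec.illumination_mode == "linear":
        return IlluminationState("linear", angle=theta)
    if spec.illumination_mode == "circular":
        return IlluminationState("circular")
    return IlluminationState("radial")


def make_confocal_fixture(spec: FixtureSpec, out_dir: str | Path | None = None) -> dict:
    """Confocal image series over orientations x depths, with masks.

    For linear illumination the orientation list rotates the *illumination*
    against a fixed fiber; for circular/radial it rotates the fiber itself
    (the modelled instrument rotates the sample).  The background texture
    seed depends on the depth index only, so all orientation arms see the
    same background realisation — the paired-arm assumption of the ratio
    statistic.

    Returns a dict with ``images[(orientation, depth)]``, per-orientation
    ``fiber_masks``, a shared ``bg_mask`` (background clear of the fiber at
    *every* orientation, so background statistics are paired across arms) and
    the manifest; writes 8-bit TIFFs + masks + manifest when ``out_dir`` is
    given.
    """
    if spec.scenario not in FIBER_SCENARIOS:
        raise ValueError(f"{spec.scenario!r} is not a fiber scenario")
    scene = _confocal_scene(spec)
    instrument = spec.instrument or InstrumentConfig()

    from dataclasses import replace

    images: dict[tuple[float, float], ConfocalImage] = {}
    fiber_masks: dict[float, np.ndarray] = {}
    bg_mask: np.ndarray | None = None
    for orient in spec.orientations:
        if spec.illumination_mode == "linear":
            sc = scene
            ill = _illumination(spec, orient)
        else:
            sc = replace(scene, fiber_axis_angle=orient)
            ill = _illumination(spec, 0.0)
        series = confocal_model.render_depth_series(sc, ill, instrument,
                                                    spec.depths, spec.seed)
        for depth, img in zip(spec.depths, series):
            images[(float(orient), float(depth))] = img
        core, bg = fixture_masks(sc, instrument)
        fiber_masks[float(orient)] = core
        bg_mask = bg if bg_mask is None else (bg_mask & bg)

    fiber_mask = fiber_masks[float(spec.orientations[0])]

    manifest = {
        "scenario": spec.scenario,
        "illumination_mode": spec.illumination_mode,
        "orientations": list(spec.orientations),
        "depths": list(spec.depths),
        "seed": spec.seed,
        "scene": asdict(scene),
        "instrument": asdict(instrument),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        peak = max(float(img.intensity.max()) for img in images.values())
        scale = peak / 0.9 if peak > 0 else 1.0
        files = {}
        for (orient, depth), img in images.items():
            name = f"img_o{orient:g}_d{depth:g}.tif"
            counts = np.clip(np.rint(img.intensity / scale * 255.0), 0, 255)
            tifffile.imwrite(out_dir / name, counts.astype(np.uint8))
            files[name] = {"orientation": orient, "depth": depth}
        for orient, mask in fiber_masks.items():
            tifffile.imwrite(out_dir / f"fiber_mask_o{orient:g}.tif",
                             mask.astype(np.uint8))
        tifffile.imwrite(out_dir / "fiber_mask.tif", fiber_mask.astype(np.uint8))
        tifffile.imwrite(out_dir / "bg_mask.tif", bg_mask.astype(np.uint8))
        manifest["files"] = files
        manifest["intensity_scale"] = scale
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {"images": images, "fiber_mask": fiber_mask, "fiber_masks": fiber_masks,
            "bg_mask": bg_mask, "manifest": manifest}


def fixture_masks(scene: FiberScene, instrument: InstrumentConfig,
                  core_fraction: float = 0.35, bg_margin_um: float = 10.0):
    """Fiber-core and background sampling masks for ROI placement.

    The fiber mask keeps the central band (|t| <= core_fraction * diameter,
    away from the image edge along the axis) where the chord — and hence the
    retardation — is close to its on-axis value; the background mask excludes
    the fiber plus a margin.
    """
    t_abs, along, inside = confocal_model.fiber_footprint(scene, instrument)
    core = t_abs <= core_fraction * scene.fiber_diameter
    core &= np.abs(along) <= 0.8 * np.abs(along).max()
    bg = t_abs > scene.fiber_diameter / 2.0 + bg_margin_um
    return core, bg


def camera_digitize(ideal_image: np.ndarray, camera: CameraModel,
                    n_frames: int = 1, seed: int | None = 0,
                    full_scale: float | None = None) -> np.ndarray:
    """Digitize an ideal intensity image through the camera chain and average.

    ``full_scale`` (intensity mapping to the top count) defaults to the
    camera's, else to auto-exposure at 90% of full scale.  Returns the
    averaged frame in digital counts (float).
    """
    ideal = np.clip(np.asarray(ideal_image, dtype=float), 0.0, None)
    fs = full_scale if full_scale is not None else camera.full_scale
    if fs is None:
        peak = float(ideal.max())
        if peak <= 0:
            raise ValueError("image has no intensity; cannot auto-expose")
        fs = peak / 0.9
    counts = ideal * (camera.max_count / fs)
    rng = np.random.default_rng(seed)
    return polarimetry.digitize_frames(counts, camera, n_frames, rng)
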