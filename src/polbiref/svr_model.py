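"""Segmented half-wave-plate retarder (SVR) producing near-radial polarization.

The device is a circular aperture tiled by ``n_sectors`` half-wave-plate
sectors (eight in the modelled instrument) whose fast axes are chosen so that a
homogeneous linearly polarized beam emerges with its local polarization
pointing along the beam azimuth — a sector-wise approximation to a radially
polarized beam.  Air gaps between sectors pass the input state unchanged; the
(small) diffraction from sector edges is not modelled.

Geometry: sector ``k`` is centred on azimuth ``phi_k = k * 360/n`` deg and
spans ``[phi_k - 180/n, phi_k + 180/n)`` minus half a gap on each side.
Azimuth is measured counter-clockwise from +x with +y up; image row index
increases downward, so row 0 is the top of the map.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .polarization_core import StokesVector, apply, linear_retarder

__all__ = [
    "OUTSIDE",
    "GAP",
    "SVRConfig",
    "PolarizationMap",
    "default_sector_axes",
    "transmit",
    "ideal_radial_map",
    "map_agreement",
    "save_polarization_map",
    "load_polarization_map",
]

#: mask code for pixels outside the device aperture
OUTSIDE = -2
#: mask code for pixels falling in an inter-sector air gap
GAP = -1


def default_sector_axes(n_sectors: int = 8, input_axis: float = 0.0) -> np.ndarray:
    """Fast-axis angle per sector so a HWP maps ``input_axis`` to the sector azimuth.

    A half-wave plate at fast axis ``a`` reflects linear polarization about the
    axis: input at angle ``t`` leaves at ``2a - t``.  Requiring the output of
    sector ``k`` (centred on azimuth ``phi_k``) to point along ``phi_k`` gives
    ``a_k = (phi_k + input_axis) / 2``.
    """
    if n_sectors < 2:
        raise ValueError("n_sectors must be >= 2")
    centers = np.arange(n_sectors) * (360.0 / n_sectors)
    return (centers + input_axis) / 2.0


@dataclass
class SVRConfig:
    """Sector geometry and fast-axis layout of the segmented retarder.

    Parameters
    ----------
    n_sectors:
        Number of wave-plate sectors (the instrument has 8).
    sector_fast_axes:
        Fast-axis angle (deg) per sector; defaults to the radial layout for a
        horizontal input beam.
    gap_angular_width:
        Angular width (deg) of the air gap between adjacent sectors; light in
        a gap passes through unmodified.  0 models the ideal device.
    retardance:
        Retardance (rad) of every sector; pi for the half-wave device.
    aperture_radius:
        Physical radius (same units as the pixel pitch); ``None`` uses the
        largest circle inscribed in the grid.
    fast_axis_jitter:
        Optional per-sector fast-axis offsets (deg) modelling cutting /
        mounting misalignment of individual sectors.
    """

    n_sectors: int = 8
    sector_fast_axes: np.ndarray | None = None
    gap_angular_width: float = 0.0
    retardance: float = np.pi
    aperture_radius: float | None = None
    fast_axis_jitter: np.ndarray | None = None
    input_axis: float = 0.0

    def __post_init__(self) -> None:
        if self.n_sectors < 2:
            raise ValueError("n_sectors must be >= 2")
        if self.gap_angular_width < 0 or self.gap_angular_width >= 360.0 / self.n_sectors:
            raise ValueError("gap width must be in [0, sector span)")
        if self.sector_fast_axes is None:
            self.sector_fast_axes = default_sector_axes(self.n_sectors, self.input_axis)
        self.sector_fast_axes = np.asarray(self.sector_fast_axes, dtype=float)
        if self.sector_fast_axes.shape != (self.n_sectors,):
            raise ValueError("need one fast axis per sector")
        if self.fast_axis_jitter is not None:
            self.fast_axis_jitter = np.asarray(self.fast_axis_jitter, dtype=float)
            if self.fast_axis_jitter.shape != (self.n_sectors,):
                raise ValueError("need one jitter value per sector")

    @property
    def effective_axes(self) -> np.ndarray:
        if self.fast_axis_jitter is None:
            return self.sector_fast_axes
        return self.sector_fast_axes + self.fast_axis_jitter

    @property
    def output_azimuths(self) -> np.ndarray:
        """Polarization azimuth (deg) each sector produces for the design input."""
        return (2.0 * self.effective_axes - self.input_axis) % 360.0


@dataclass
class PolarizationMap:
    """Per-pixel Stokes state on a regular grid.

    ``stokes`` has shape ``(H, W, 4)``; ``mask`` holds the sector index for
    in-sector pixels, ``GAP`` (-1) for gap pixels and ``OUTSIDE`` (-2) for
    pixels beyond the aperture.  ``pixel_pitch`` is in micrometres.
    """

    stokes: np.ndarray
    pixel_pitch: float = 6.0
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.stokes = np.asarray(self.stokes, dtype=float)
        if self.stokes.ndim != 3 or self.stokes.shape[-1] != 4:
            raise ValueError("stokes must have shape (H, W, 4)")
        if self.mask is None:
            self.mask = np.zeros(self.stokes.shape[:2], dtype=np.int16)
        self.mask = np.asarray(self.mask, dtype=np.int16)
        if self.mask.shape != self.stokes.shape[:2]:
            raise ValueError("mask shape must match grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.stokes.shape[:2]

    def plane(self, i: int) -> np.ndarray:
        return self.stokes[..., i]

    @property
    def in_aperture(self) -> np.ndarray:
        return self.mask != OUTSIDE

    def same_geometry(self, other: "PolarizationMap") -> bool:
        return self.shape == other.shape and np.isclose(self.pixel_pitch, other.pixel_pitch)


def _grid_polar(grid_shape: tuple[int, int], pixel_pitch: float):
    """Azimuth (deg, CCW from +x, +y up) and radius of each pixel centre."""
    h, w = grid_shape
    rows, cols = np.mgrid[0:h, 0:w]
    x = (cols - (w - 1) / 2.0) * pixel_pitch
    y = ((h - 1) / 2.0 - rows) * pixel_pitch
    phi = np.degrees(np.arctan2(y, x)) % 360.0
    r = np.hypot(x, y)
    return phi, r


def transmit(
    input_state: StokesVector,
    config: SVRConfig,
    grid_shape: tuple[int, int],
    pixel_pitch: float = 6.0,
) -> PolarizationMap:
    """Pass a homogeneous beam through the segmented retarder.

    Each in-sector pixel gets the sector's retarder applied; gap pixels carry
    the unmodified input state; pixels outside the aperture carry zero
    intensity.  For the half-wave device this conserves s0 pixel-wise and
    cannot create circular polarization from linear input.
    """
    if not input_state.is_linear:
        warnings.warn(
            "SVR input is not fully polarized linear light; the radial-output "
            "design assumption does not hold",
            stacklevel=2,
        )
    phi, r = _grid_polar(grid_shape, pixel_pitch)
    span = 360.0 / config.n_sectors
    sector = np.floor((phi + span / 2.0) / span).astype(int) % config.n_sectors
    # angular offset from the sector centre, in (-span/2, span/2]
    offset = (phi - sector * span + 180.0) % 360.0 - 180.0
    in_gap = np.abs(offset) > (span - config.gap_angular_width) / 2.0

    aperture = config.aperture_radius
    if aperture is None:
        aperture = min(grid_shape) / 2.0 * pixel_pitch
    outside = r > aperture

    s_in = input_state.as_array()
    stokes = np.empty(grid_shape + (4,), dtype=float)
    axes = config.effective_axes
    for k in range(config.n_sectors):
        sel = (sector == k) & ~in_gap & ~outside
        if not sel.any():
            continue
        m = linear_retarder(config.retardance, axes[k])
        stokes[sel] = apply(m, s_in)
    stokes[in_gap & ~outside] = s_in
    stokes[outside] = 0.0

    mask = sector.astype(np.int16)
    mask[in_gap] = GAP
    mask[outside] = OUTSIDE
    return PolarizationMap(stokes, pixel_pitch, mask)


def ideal_radial_map(
    grid_shape: tuple[int, int],
    pixel_pitch: float = 6.0,
    i0: float = 1.0,
    aperture_radius: float | None = None,
) -> PolarizationMap:
    """Continuous-limit radial beam: at azimuth phi the state is (1, cos2phi, sin2phi, 0)."""
    phi, r = _grid_polar(grid_shape, pixel_pitch)
    aperture = aperture_radius
    if aperture is None:
        aperture = min(grid_shape) / 2.0 * pixel_pitch
    outside = r > aperture
    two_phi = np.radians(2.0 * phi)
    stokes = np.stack(
        [np.full_like(phi, i0), i0 * np.cos(two_phi), i0 * np.sin(two_phi), np.zeros_like(phi)],
        axis=-1,
    )
    stokes[outside] = 0.0
    mask = np.zeros(grid_shape, dtype=np.int16)
    mask[outside] = OUTSIDE
    return PolarizationMap(stokes, pixel_pitch, mask)


def map_agreement(
    measured: PolarizationMap,
    reference: PolarizationMap,
    exclude_codes: tuple[int, ...] = (GAP, OUTSIDE),
    statistic: str = "mean",
) -> np.ndarray:
    """Per-component agreement (%) between two maps on the same grid.

    ``accuracy_i = 100 * (1 - <|dS_i| / S0_ref>)`` with the average over pixels
    whose mask (in either map) is not in ``exclude_codes`` and whose reference
    intensity is positive.  ``statistic='worst'`` replaces the average with the
    worst pixel, giving the minimum pointwise accuracy.
    """
    if not measured.same_geometry(reference):
        raise ValueError("maps have different geometry (shape or pixel pitch)")
    valid = ~np.isin(measured.mask, exclude_codes) & ~np.isin(reference.mask, exclude_codes)
    valid &= reference.plane(0) > 0
    if not valid.any():
        raise ValueError("no valid pixels to compare")
    s0 = reference.plane(0)[valid]
    acc = np.empty(4)
    for i in range(4):
        rel = np.abs(measured.plane(i)[valid] - reference.plane(i)[valid]) / s0
        if statistic == "mean":
            acc[i] = 100.0 * (1.0 - rel.mean())
        elif statistic == "worst":
            acc[i] = 100.0 * (1.0 - rel.max())
        else:
            raise ValueError("statistic must be 'mean' or 'worst'")
    return acc


# ---------------------------------------------------------------------------
# serialization: 4-plane float32 TIFF + uint8/int16 mask TIFF + JSON sidecar

def save_polarization_map(pmap: PolarizationMap, stem: str | Path) -> list[Path]:
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    tif = stem.with_suffix(".tif")
    mask_tif = stem.parent / (stem.name + ".mask.tif")
    sidecar = stem.with_suffix(".json")
    planes = np.moveaxis(pmap.stokes.astype(np.float32), -1, 0)  # (4, H, W)
    tifffile.imwrite(tif, planes, photometric="minisblack")
    tifffile.imwrite(mask_tif, pmap.mask.astype(np.int16))
    sidecar.write_text(json.dumps({
        "pixel_pitch_um": pmap.pixel_pitch,
        "planes": ["S0", "S1", "S2", "S3"],
        "mask_codes": {"outside_aperture": OUTSIDE, "gap": GAP, "sector_k": ">=0"},
    }, indent=2))
    return [tif, mask_tif, sidecar]


def load_polarization_map(stem: str | Path) -> PolarizationMap:
    stem = Path(stem)
    planes = tifffile.imread(stem.with_suffix(".tif"))
    mask = tifffile.imread(stem.parent / (stem.name + ".mask.tif"))
    meta = json.loads(stem.with_suffix(".json").read_text())
    stokes = np.moveaxis(planes, 0, -1)
    return PolarizationMap(stokes, float(meta["pixel_pitch_um"]), mask)
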