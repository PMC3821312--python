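"""Rotating circular-polarizer Stokes polarimeter: simulation and inversion.

The analyzer is a rigid unit of a linear polarizer and a quarter-wave plate
whose axes differ by 45 deg.  With the wave plate facing the light ("normal"
orientation) the unit is a circular analyzer and the detected intensity is
(S0 - S3)/2 regardless of the unit's rotation; flipped by 180 deg the
polarizer faces the light and the unit acts as a plain linear analyzer at the
polarizer's rotated axis, (S0 + S1 cos 2a + S2 sin 2a)/2.  Rotating the
flipped unit through >= 3 distinct angles plus one normal measurement makes
the linear map intensity = a(setting) . S full rank, so the four Stokes
parameters are recovered per CCD pixel by ordinary least squares.

The camera model covers the dominant noise sources of an 8-bit CCD chain:
per-frame photon shot noise (Poisson, unit gain), additive Gaussian read
noise, clipping at full scale, quantization to integer counts, and averaging
of ``n_averaged`` frames per analyzer setting (256 in the modelled
instrument) which suppresses the per-pixel noise by ~1/sqrt(N).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile

from .polarization_core import linear_polarizer, linear_retarder
from .svr_model import PolarizationMap, map_agreement

__all__ = [
    "AnalyzerSetting",
    "CameraModel",
    "FrameStack",
    "DEFAULT_PROTOCOL",
    "analyzer_first_row",
    "design_matrix",
    "simulate_stack",
    "reconstruct",
    "accuracy_report",
    "digitize_frames",
    "project_physical",
    "save_frame_stack",
    "load_frame_stack",
]


@dataclass(frozen=True)
class AnalyzerSetting:
    """One configuration of the rotatable circular-polarizer unit.

    ``orientation`` is ``"normal"`` (quarter-wave plate facing the light) or
    ``"flipped"`` (linear polarizer facing the light); ``rotation_angle`` (deg)
    rotates the whole rigid unit.  Within the unit the wave-plate fast axis
    leads the polarizer axis by 45 deg.
    """

    orientation: str
    rotation_angle: float = 0.0

    def __post_init__(self) -> None:
        if self.orientation not in ("normal", "flipped"):
            raise ValueError("orientation must be 'normal' or 'flipped'")


#: flipped (linear-analyzer) measurements at 0/45/90/135 deg + one circular one
DEFAULT_PROTOCOL: tuple[AnalyzerSetting, ...] = (
    AnalyzerSetting("flipped", 0.0),
    AnalyzerSetting("flipped", 45.0),
    AnalyzerSetting("flipped", 90.0),
    AnalyzerSetting("flipped", 135.0),
    AnalyzerSetting("normal", 0.0),
)


@dataclass
class CameraModel:
    """8-bit CCD digitization chain.

    ``full_scale`` is the input intensity mapped to the top digital count;
    ``None`` auto-exposes so the brightest ideal pixel sits at 90% of full
    scale (avoids clipping).  ``read_noise_sd`` is in digital counts per frame;
    shot noise is Poisson on the digital counts (unit gain).
    """

    bit_depth: int = 8
    full_scale: float | None = None
    read_noise_sd: float = 1.0
    shot_noise: bool = True
    pixel_pitch: float = 6.0

    @property
    def max_count(self) -> int:
        return 2 ** self.bit_depth - 1


@dataclass
class FrameStack:
    """Averaged polarimeter frames, one per analyzer setting.

    ``frames`` has shape ``(n_settings, H, W)`` in digital counts (or raw
    intensity units when no camera model was applied, ``scale is None``).
    ``scale`` is the intensity corresponding to the top count.
    """

    settings: tuple[AnalyzerSetting, ...]
    frames: np.ndarray
    n_averaged: int = 256
    camera: CameraModel | None = None
    scale: float | None = None
    seed: int | None = None
    pixel_pitch: float = 6.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.shape[0] != len(self.settings):
            raise ValueError("one frame per setting required")

    def intensities(self) -> np.ndarray:
        """Frames converted back to input intensity units."""
        if self.scale is None or self.camera is None:
            return self.frames
        return self.frames * (self.scale / self.camera.max_count)


def analyzer_first_row(setting: AnalyzerSetting) -> np.ndarray:
    """Detection row vector ``a``: detected intensity = ``a @ S``.

    Derived by composing the unit's polarizer and quarter-wave Mueller
    matrices in the order the light traverses them, then taking the first row
    (the detector is intensity-only).
    """
    pol_axis = setting.rotation_angle
    qwp_axis = setting.rotation_angle + 45.0
    pol = linear_polarizer(pol_axis)
    qwp = linear_retarder(np.pi / 2.0, qwp_axis)
    if setting.orientation == "normal":
        unit = pol @ qwp  # light hits the wave plate first
    else:
        unit = qwp @ pol  # flipped: polarizer first
    return unit.first_row


def design_matrix(protocol) -> np.ndarray:
    """Stack of analyzer rows, shape (n_settings, 4); raises if rank-deficient."""
    a = np.array([analyzer_first_row(s) for s in protocol])
    if a.shape[0] < 4 or np.linalg.matrix_rank(a, tol=1e-10) < 4:
        # name what is missing: which Stokes direction lies in the null space
        _, sv, vt = np.linalg.svd(a)
        null = vt[np.sum(sv > 1e-10):]
        names = ["S0", "S1", "S2", "S3"]
        missing = [names[i] for i in range(4) if np.any(np.abs(null[:, i]) > 1e-6)] if len(null) else names
        raise ValueError(
            "analyzer protocol is rank-deficient; add settings sensitive to "
            + ", ".join(missing)
            + " (need >= 3 distinct flipped angles plus a normal setting)"
        )
    return a


def digitize_frames(
    ideal_counts: np.ndarray,
    camera: CameraModel,
    n_frames: int,
    rng: np.random.Generator,
    chunk: int = 64,
) -> np.ndarray:
    """Noise + quantize ``n_frames`` exposures of ``ideal_counts`` and average them.

    Per frame: Poisson shot noise (if enabled), Gaussian read noise, clip to
    [0, max_count], round to integer counts.  Returns the float average.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    ideal = np.clip(np.asarray(ideal_counts, dtype=float), 0.0, None)
    acc = np.zeros_like(ideal)
    done = 0
    while done < n_frames:
        m = min(chunk, n_frames - done)
        if camera.shot_noise:
            x = rng.poisson(ideal, size=(m,) + ideal.shape).astype(float)
        else:
            x = np.broadcast_to(ideal, (m,) + ideal.shape).copy()
        if camera.read_noise_sd > 0:
            x += rng.normal(0.0, camera.read_noise_sd, size=x.shape)
        np.clip(x, 0, camera.max_count, out=x)
        np.rint(x, out=x)
        acc += x.sum(axis=0)
        done += m
    return acc / n_frames


def simulate_stack(
    truth: PolarizationMap,
    protocol=DEFAULT_PROTOCOL,
    camera: CameraModel | None = None,
    n_averaged: int = 256,
    seed: int | None = 0,
) -> FrameStack:
    """Record one averaged frame per analyzer setting from a known truth map.

    With ``camera=None`` the frames are the ideal analytic intensities (no
    noise, no quantization) — the exact-roundtrip reference path.
    """
    a = design_matrix(protocol)
    ideal = np.einsum("kj,hwj->khw", a, truth.stokes)
    np.clip(ideal, 0.0, None, out=ideal)  # tiny negatives from rounding

    if camera is None:
        return FrameStack(tuple(protocol), ideal, n_averaged, None, None, seed,
                          truth.pixel_pitch)

    full_scale = camera.full_scale
    if full_scale is None:
        peak = float(ideal.max())
        if peak <= 0:
            raise ValueError("truth map has no intensity; cannot auto-expose")
        full_scale = peak / 0.9
    counts = ideal * (camera.max_count / full_scale)
    rng = np.random.default_rng(seed)
    frames = np.empty_like(counts)
    for k in range(counts.shape[0]):
        frames[k] = digitize_frames(counts[k], camera, n_averaged, rng)
    return FrameStack(tuple(protocol), frames, n_averaged, camera, full_scale,
                      seed, truth.pixel_pitch)


def project_physical(stokes: np.ndarray) -> np.ndarray:
    """Clip the polarized part so dop <= 1, preserving its direction; s0 >= 0."""
    out = np.array(stokes, dtype=float)
    s0 = np.clip(out[..., 0], 0.0, None)
    v = out[..., 1:]
    norm = np.linalg.norm(v, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        factor = np.where(norm > s0, np.where(norm > 0, s0 / np.where(norm > 0, norm, 1.0), 0.0), 1.0)
    out[..., 0] = s0
    out[..., 1:] = v * factor[..., None]
    return out


def reconstruct(stack: FrameStack) -> tuple[PolarizationMap, np.ndarray]:
    """Per-pixel least-squares Stokes estimate from a frame stack.

    Returns the physically projected map (dop clipped to <= 1) and the
    per-pixel raw residual norm ``||A S - I||`` in intensity units.
    """
    a = design_matrix(stack.settings)
    intens = stack.intensities()
    n, h, w = intens.shape
    flat = intens.reshape(n, -1)
    pinv = np.linalg.pinv(a)
    s = pinv @ flat  # (4, N)
    resid = np.linalg.norm(a @ s - flat, axis=0).reshape(h, w)
    stokes = np.moveaxis(s.reshape(4, h, w), 0, -1)
    return PolarizationMap(project_physical(stokes), stack.pixel_pitch), resid


def accuracy_report(
    measured: PolarizationMap,
    truth: PolarizationMap,
    exclude_codes: tuple[int, ...] = (-1, -2),
) -> dict[str, np.ndarray]:
    """Mean and worst-pixel per-component accuracy (%) against a truth map."""
    return {
        "mean": map_agreement(measured, truth, exclude_codes, statistic="mean"),
        "worst_pixel": map_agreement(measured, truth, exclude_codes, statistic="worst"),
    }


# ---------------------------------------------------------------------------
# disk format: one 8-bit grayscale TIFF per setting + JSON manifest

def save_frame_stack(stack: FrameStack, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = []
    for i, frame in enumerate(stack.frames):
        name = f"frame_{i:02d}.tif"
        tifffile.imwrite(out_dir / name, np.clip(np.rint(frame), 0, 255).astype(np.uint8))
        names.append(name)
    manifest = {
        "settings": [asdict(s) for s in stack.settings],
        "files": names,
        "n_averaged": stack.n_averaged,
        "camera": asdict(stack.camera) if stack.camera else None,
        "scale": stack.scale,
        "seed": stack.seed,
        "pixel_pitch_um": stack.pixel_pitch,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def load_frame_stack(manifest_path: str | Path) -> FrameStack:
    manifest_path = Path(manifest_path)
    meta = json.loads(manifest_path.read_text())
    frames = np.stack([
        tifffile.imread(manifest_path.parent / name).astype(float) for name in meta["files"]
    ])
    settings = tuple(AnalyzerSetting(**s) for s in meta["settings"])
    camera = CameraModel(**meta["camera"]) if meta["camera"] else None
    return FrameStack(settings, frames, meta["n_averaged"], camera, meta["scale"],
                      meta["seed"], meta["pixel_pitch_um"])
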