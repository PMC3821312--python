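"""Cross-polarized confocal imaging of a birefringent fiber — forward model.

A cylindrical fiber (hair; birefringent cortex, optical axis along the fiber)
lies in the image plane of a reflectance confocal microscope with crossed
polarization detection.  Light focused to depth ``x`` inside the fiber
accumulates a phase retardation ``d = 2 pi * delta * x / lambda`` between the
field components along and across the fiber axis, and loses polarization to
multiple scattering, modelled as an exponential decay of the degree of
polarization ``p = exp(-x / l_p)``.

Detected crossed intensity per pixel is evaluated as a Mueller chain
(input state -> depolarizer -> fiber retarder at the fiber angle ``psi`` ->
crossed analyzer matched to the illumination), counting only the polarized
component: the multiply-scattered depolarized light is taken to be rejected
by the confocal pinhole, with any detected share already absorbed in the
background level ``b``.  The chain then reproduces the closed forms

* linear at ``theta``:   ``I = I0 * p * sin^2(2(theta - psi)) * sin^2(d/2) + b``
* circular:              ``I = I0 * p * sin^2(d/2) + b``
* radial (pupil average over azimuths): ``I = I0 * p * sin^2(d/2) / 2 + b``

which carry the observed phenomenology: crossed signal vanishes when linear
illumination is along or across the fiber, peaks at 45 deg, is
orientation-independent for circular and radial light, and all modes converge
to the background as depolarization wins at depth.  The factor 1/2 for radial
light mirrors its lower effective crossed throughput.  High-NA vectorial
focal fields and photon-transport scattering are outside this model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .polarization_core import (
    StokesVector,
    apply,
    depolarizer,
    linear_polarizer,
    linear_retarder,
)
from .svr_model import SVRConfig

__all__ = [
    "InstrumentConfig",
    "FiberScene",
    "IlluminationState",
    "ConfocalImage",
    "retardation",
    "depth_dop",
    "crossed_intensity",
    "render_image",
    "render_depth_series",
    "fiber_footprint",
]


@dataclass
class InstrumentConfig:
    """Confocal microscope geometry (lengths in micrometres).

    Defaults follow a reflectance confocal with an 830 nm source and a
    450 x 400 um maximum field of view digitized to 630 x 480 pixels, so a
    25 x 25 um region is 35 x 30 pixels.  NA and pinhole are carried as
    metadata only — focal-field physics is not modelled.
    """

    wavelength: float = 0.83
    field_of_view: tuple[float, float] = (450.0, 400.0)  # (x, y) um
    image_pixels: tuple[int, int] = (480, 630)  # (rows, cols)
    illumination_power: float = 1.0
    numerical_aperture: float = 0.90
    pinhole_um: float = 50.0

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")

    @property
    def pixel_size(self) -> tuple[float, float]:
        """(row, col) pixel size in um."""
        return (self.field_of_view[1] / self.image_pixels[0],
                self.field_of_view[0] / self.image_pixels[1])


@dataclass
class FiberScene:
    """A birefringent fiber against a non-birefringent background.

    ``birefringence`` defaults to ``n_e - n_o`` of keratinized hair cortex
    (1.548 - 1.541 = 0.007); passing an inconsistent explicit value raises.
    ``background_level`` is the crossed-detected background intensity (air:
    a small floor; skin: larger, optionally textured via
    ``background_texture_sigma`` as log-normal multiplicative speckle).
    ``depolarization_length`` is the 1/e length of the degree of polarization.
    ``double_pass`` doubles the optical path (illumination + detection legs);
    single pass is the default.
    """

    fiber_axis_angle: float = 0.0
    fiber_diameter: float = 80.0
    n_o: float = 1.541
    n_e: float = 1.548
    birefringence: float | None = None
    background_level: float = 0.001
    background_texture_sigma: float = 0.0
    depolarization_length: float = 100.0
    focus_depth: float = 0.0
    double_pass: bool = False
    signal_level: float = 1.0

    def __post_init__(self) -> None:
        delta = self.n_e - self.n_o
        if self.birefringence is None:
            self.birefringence = delta
        elif abs(self.birefringence - delta) > 1e-9:
            raise ValueError(
                f"birefringence {self.birefringence} inconsistent with "
                f"n_e - n_o = {delta}"
            )
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")
        if self.depolarization_length <= 0:
            raise ValueError("depolarization_length must be > 0")


@dataclass(frozen=True)
class IlluminationState:
    """Illumination polarization: linear(theta), circular(handedness) or radial.

    Radial light is modelled as an incoherent average over the pupil's local
    linear polarizations: a continuous (ideal) azimuth set, or the discrete
    output azimuths of a sectored retarder when ``svr`` is given.
    """

    mode: str
    angle: float = 0.0  # theta for linear (deg)
    handedness: int = +1  # for circular
    svr: SVRConfig | None = None
    n_azimuths: int = 16  # azimuth samples for ideal radial light

    def __post_init__(self) -> None:
        if self.mode not in ("linear", "circular", "radial"):
            raise ValueError("mode must be 'linear', 'circular' or 'radial'")
        if self.handedness not in (+1, -1):
            raise ValueError("handedness must be +1 or -1")
        if self.n_azimuths < 4:
            raise ValueError("n_azimuths must be >= 4")

    @property
    def azimuths(self) -> np.ndarray:
        """Pupil azimuths averaged over in radial mode."""
        if self.svr is not None:
            return self.svr.output_azimuths
        return np.arange(self.n_azimuths) * (360.0 / self.n_azimuths)


@dataclass
class ConfocalImage:
    """Rendered crossed-detection intensity image plus provenance metadata."""

    intensity: np.ndarray
    instrument: InstrumentConfig
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be >= 0")


def retardation(x, delta: float = 0.007, wavelength: float = 0.83,
                double_pass: bool = False):
    """Phase retardation d = 2 pi * delta * x / lambda (x and lambda in um).

    With ``double_pass`` the path is traversed twice (reflection geometry),
    doubling d.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("path length must be >= 0")
    d = 2.0 * np.pi * delta * x / wavelength
    return 2.0 * d if double_pass else d


def depth_dop(x, depolarization_length: float):
    """Degree of polarization surviving path length x: exp(-x / l_p)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("path length must be >= 0")
    if depolarization_length <= 0:
        raise ValueError("depolarization_length must be > 0")
    return np.exp(-x / depolarization_length)


def _linear_chain(theta: float, psi: float, d, p, i0: float):
    """Mueller-chain crossed intensity for linear illumination (polarized part)."""
    d = np.asarray(d, dtype=float)
    p = np.asarray(p, dtype=float)
    s_in = StokesVector.linear(theta, i0).as_array()
    chain = linear_polarizer(theta + 90.0) @ linear_retarder(d, psi) @ depolarizer(p)
    full = apply(chain, s_in)[..., 0]
    # subtract the analyzer throughput of the depolarized component (pinhole-rejected)
    return full - 0.5 * (1.0 - p) * i0


def crossed_intensity(illumination: IlluminationState, psi: float, d, p,
                      b=0.0, i0: float = 1.0):
    """Crossed-detected intensity for a retarding element at angle ``psi``.

    ``d`` (retardance, rad) and ``p`` (surviving degree of polarization)
    broadcast; ``b`` is the additive background.  The analyzer co-rotates with
    the illumination: orthogonal linear for linear light, opposite-handed
    circular for circular light, per-azimuth crossed linear for radial light.
    """
    d = np.asarray(d, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any(p < -1e-12) or np.any(p > 1.0 + 1e-12):
        raise ValueError("degree of polarization p must lie in [0, 1]")
    if illumination.mode == "linear":
        signal = _linear_chain(illumination.angle, psi, d, p, i0)
    elif illumination.mode == "circular":
        h = illumination.handedness
        s_in = StokesVector.circular(h, i0).as_array()
        # crossed circular analyzer: QWP at 45h into a polarizer blocks handedness h
        analyzer = linear_polarizer(0.0) @ linear_retarder(np.pi / 2.0, 45.0 * h)
        chain = analyzer @ linear_retarder(d, psi) @ depolarizer(p)
        signal = apply(chain, s_in)[..., 0] - 0.5 * (1.0 - p) * i0
    else:  # radial: incoherent pupil average of crossed-linear responses
        az = illumination.azimuths
        signal = np.zeros(np.broadcast(d, p).shape)
        for theta in az:
            signal = signal + _linear_chain(float(theta), psi, d, p, i0)
        signal = signal / len(az)
    return np.clip(signal, 0.0, None) + b


def fiber_footprint(scene: FiberScene, instrument: InstrumentConfig):
    """Per-pixel perpendicular distance to the fiber axis and footprint mask.

    The fiber axis passes through the image centre at ``fiber_axis_angle``.
    Returns ``(t_abs, along, inside)`` where ``t_abs`` is |distance| (um),
    ``along`` the signed coordinate along the axis, and ``inside`` the
    footprint mask |t| <= diameter/2.
    """
    rows, cols = instrument.image_pixels
    dy, dx = instrument.pixel_size
    r, c = np.mgrid[0:rows, 0:cols]
    x = (c - (cols - 1) / 2.0) * dx
    y = ((rows - 1) / 2.0 - r) * dy
    psi = np.radians(scene.fiber_axis_angle)
    t = -np.sin(psi) * x + np.cos(psi) * y
    along = np.cos(psi) * x + np.sin(psi) * y
    inside = np.abs(t) <= scene.fiber_diameter / 2.0
    return np.abs(t), along, inside


def _background_field(scene: FiberScene, shape: tuple[int, int],
                      seed: int | None) -> np.ndarray:
    """Background intensity: constant level, optionally log-normal speckle."""
    b = np.full(shape, scene.background_level, dtype=float)
    if scene.background_texture_sigma > 0:
        rng = np.random.default_rng(seed)
        sigma = scene.background_texture_sigma
        # mean-one multiplicative texture
        b *= rng.lognormal(-0.5 * sigma ** 2, sigma, size=shape)
    return b


def render_image(scene: FiberScene, illumination: IlluminationState,
                 instrument: InstrumentConfig, seed: int | None = None) -> ConfocalImage:
    """Render one crossed-polarized confocal frame of the fiber scene.

    The per-pixel optical path is the vertical extent of the circular fiber
    cross-section at that pixel's lateral offset, truncated at the focus
    depth (``min(focus_depth, chord)``); retardation and depolarization are
    evaluated on that path.  The whole frame scales with the illumination
    power.
    """
    t_abs, _, inside = fiber_footprint(scene, instrument)
    if not inside.any():
        warnings.warn("fiber footprint is empty (fiber outside field of view)",
                      stacklevel=2)
    bg = _background_field(scene, t_abs.shape, seed)
    # the fiber occludes the textured background: under the footprint only the
    # constant crossed-detection floor remains
    bg[inside] = scene.background_level
    image = bg.copy()
    if inside.any():
        half = scene.fiber_diameter / 2.0
        chord = 2.0 * np.sqrt(np.clip(half ** 2 - t_abs[inside] ** 2, 0.0, None))
        path = np.minimum(scene.focus_depth, chord)
        d = retardation(path, scene.birefringence, instrument.wavelength,
                        scene.double_pass)
        p = depth_dop(path * (2.0 if scene.double_pass else 1.0),
                      scene.depolarization_length)
        image[inside] = crossed_intensity(
            illumination, scene.fiber_axis_angle, d, p,
            b=bg[inside], i0=scene.signal_level,
        )
    image *= instrument.illumination_power
    meta = {
        "mode": illumination.mode,
        "theta": illumination.angle,
        "psi": scene.fiber_axis_angle,
        "depth": scene.focus_depth,
        "power": instrument.illumination_power,
        "seed": seed,
    }
    return ConfocalImage(image, instrument, meta)


def render_depth_series(scene: FiberScene, illumination: IlluminationState,
                        instrument: InstrumentConfig, depths,
                        seed: int | None = 0) -> list[ConfocalImage]:
    """Render one image per focusing depth (background texture seeded per depth)."""
    out = []
    for i, depth in enumerate(depths):
        sc = replace(scene, focus_depth=float(depth))
        img_seed = None if seed is None else seed + i
        out.append(render_image(sc, illumination, instrument, img_seed))
    return out
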