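"""Stokes-Mueller algebra for intensity-based polarization optics.

Conventions used throughout the package
---------------------------------------
* Angles in **degrees** in every public interface, measured counter-clockwise
  from the horizontal axis as seen looking *against* the propagation direction.
* Retardances are phases in **radians** (a half-wave plate has retardance pi).
* Stokes vectors are ``(s0, s1, s2, s3)`` with ``s3 > 0`` meaning right-circular
  light.  The absolute circular sign is a convention, not a measurement: all
  results in this package are consistent under a global flip of ``s3``.
* Mueller calculus only.  Every observable modelled here is an intensity of
  incoherently summed contributions, so field (Jones) calculus is not needed;
  coherent effects are outside the model.

All matrix constructors broadcast over array-valued angles/retardances and then
return stacked matrices of shape ``(..., 4, 4)``, which keeps per-pixel
evaluation of full optical trains vectorised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StokesVector",
    "MuellerMatrix",
    "identity",
    "rotator",
    "linear_retarder",
    "linear_polarizer",
    "depolarizer",
    "apply",
    "dop",
]

_DEG = np.pi / 180.0


def _cos2_sin2(angle_deg):
    """cos/sin of twice an angle given in degrees (broadcasting)."""
    a = 2.0 * np.asarray(angle_deg, dtype=float) * _DEG
    return np.cos(a), np.sin(a)


@dataclass(frozen=True)
class StokesVector:
    """A (possibly partially) polarized state: intensities in arbitrary linear units.

    Invariants enforced on construction: ``s0 >= 0`` and
    ``s0**2 >= s1**2 + s2**2 + s3**2`` (up to a small relative tolerance),
    i.e. the degree of polarization cannot exceed one.
    """

    s0: float
    s1: float
    s2: float
    s3: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.s0, self.s1, self.s2, self.s3]).all():
            raise ValueError("Stokes components must be finite")
        if self.s0 < 0:
            raise ValueError(f"s0 must be non-negative, got {self.s0}")
        pol = self.s1 ** 2 + self.s2 ** 2 + self.s3 ** 2
        if pol > self.s0 ** 2 * (1.0 + 1e-9) + 1e-12:
            raise ValueError(
                "unphysical Stokes vector: s1^2+s2^2+s3^2 > s0^2 "
                f"({pol:.6g} > {self.s0 ** 2:.6g})"
            )

    # -- constructors ------------------------------------------------------
    @classmethod
    def linear(cls, angle_deg: float, i0: float = 1.0) -> "StokesVector":
        """Fully polarized linear state at ``angle_deg``."""
        c, s = _cos2_sin2(angle_deg)
        return cls(i0, i0 * float(c), i0 * float(s), 0.0)

    @classmethod
    def circular(cls, handedness: int = +1, i0: float = 1.0) -> "StokesVector":
        """Fully polarized circular state; ``handedness=+1`` is right-circular."""
        if handedness not in (+1, -1):
            raise ValueError("handedness must be +1 or -1")
        return cls(i0, 0.0, 0.0, i0 * handedness)

    @classmethod
    def unpolarized(cls, i0: float = 1.0) -> "StokesVector":
        return cls(i0, 0.0, 0.0, 0.0)

    @classmethod
    def from_array(cls, a) -> "StokesVector":
        a = np.asarray(a, dtype=float)
        if a.shape != (4,):
            raise ValueError(f"expected shape (4,), got {a.shape}")
        return cls(*a.tolist())

    # -- views -------------------------------------------------------------
    def as_array(self) -> np.ndarray:
        return np.array([self.s0, self.s1, self.s2, self.s3], dtype=float)

    @property
    def dop(self) -> float:
        return dop(self)

    @property
    def is_fully_polarized(self) -> bool:
        return abs(self.dop - 1.0) < 1e-9

    @property
    def is_linear(self) -> bool:
        return self.is_fully_polarized and abs(self.s3) < 1e-9 * max(self.s0, 1.0)


@dataclass(frozen=True)
class MuellerMatrix:
    """A real 4x4 intensity-domain operator (or a broadcast stack of them)."""

    m: np.ndarray  # shape (..., 4, 4)

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=float)
        if m.shape[-2:] != (4, 4):
            raise ValueError(f"Mueller matrix must have trailing shape (4,4), got {m.shape}")
        object.__setattr__(self, "m", m)

    def __matmul__(self, other):
        if isinstance(other, MuellerMatrix):
            return MuellerMatrix(self.m @ other.m)
        if isinstance(other, StokesVector):
            return apply(self, other)
        return NotImplemented

    def __mul__(self, scalar: float) -> "MuellerMatrix":
        return MuellerMatrix(self.m * float(scalar))

    __rmul__ = __mul__

    @property
    def first_row(self) -> np.ndarray:
        """Analyzer row: detected intensity is ``first_row @ S``."""
        return self.m[..., 0, :]


def identity() -> MuellerMatrix:
    return MuellerMatrix(np.eye(4))


def _stack44(rows) -> np.ndarray:
    """Assemble a (...,4,4) array from 16 broadcastable scalar entries."""
    rows = [np.broadcast_arrays(*[np.asarray(e, dtype=float) for e in r]) for r in rows]
    flat = [e for r in rows for e in r]
    flat = np.broadcast_arrays(*flat)
    out = np.stack([np.stack(flat[4 * i: 4 * i + 4], axis=-1) for i in range(4)], axis=-2)
    return out


def rotator(angle_deg) -> MuellerMatrix:
    """Frame rotation by ``angle_deg``: the standard rotation by 2*angle in (s1, s2).

    Satisfies ``rotator(a) @ rotator(b) == rotator(a + b)``.
    """
    c, s = _cos2_sin2(angle_deg)
    z, o = np.zeros_like(c), np.ones_like(c)
    return MuellerMatrix(_stack44([
        [o, z, z, z],
        [z, c, s, z],
        [z, -s, c, z],
        [z, z, z, o],
    ]))


def linear_retarder(retardance_rad, fast_axis_deg) -> MuellerMatrix:
    """Ideal linear retarder with the given retardance, rotated to ``fast_axis_deg``.

    Retardance 0 gives the identity; retardance pi is a half-wave plate, pi/2 a
    quarter-wave plate.  With this sign convention horizontal light through a
    quarter-wave plate at +45 deg emerges right-circular (s3 = +1).
    """
    d = np.asarray(retardance_rad, dtype=float)
    cd, sd = np.cos(d), np.sin(d)
    z, o = np.zeros_like(cd), np.ones_like(cd)
    m0 = MuellerMatrix(_stack44([
        [o, z, z, z],
        [z, o, z, z],
        [z, z, cd, sd],
        [z, z, -sd, cd],
    ]))
    a = np.asarray(fast_axis_deg, dtype=float)
    return rotator(-a) @ m0 @ rotator(a)


def linear_polarizer(axis_deg) -> MuellerMatrix:
    """Ideal linear polarizer at ``axis_deg`` (idempotent, transmittance 1 along axis)."""
    c, s = _cos2_sin2(axis_deg)
    z = np.zeros_like(c)
    return MuellerMatrix(0.5 * _stack44([
        [np.ones_like(c), c, s, z],
        [c, c * c, c * s, z],
        [s, c * s, s * s, z],
        [z, z, z, z],
    ]))


def depolarizer(p) -> MuellerMatrix:
    """Isotropic partial depolarizer diag(1, p, p, p); p=1 is the identity."""
    p = np.asarray(p, dtype=float)
    if np.any(p < -1e-12) or np.any(p > 1.0 + 1e-12):
        raise ValueError("depolarization fraction p must lie in [0, 1]")
    z, o = np.zeros_like(p), np.ones_like(p)
    return MuellerMatrix(_stack44([
        [o, z, z, z],
        [z, p, z, z],
        [z, z, p, z],
        [z, z, z, p],
    ]))


def apply(m: MuellerMatrix, s):
    """Apply a Mueller matrix (stack) to a Stokes vector or a (..., 4) array."""
    mat = m.m if isinstance(m, MuellerMatrix) else np.asarray(m, dtype=float)
    if isinstance(s, StokesVector):
        out = mat @ s.as_array()
        if out.ndim == 1:
            return StokesVector.from_array(out)
        return out
    arr = np.asarray(s, dtype=float)
    return np.einsum("...ij,...j->...i", mat, arr)


def dop(s) -> float:
    """Degree of polarization sqrt(s1^2+s2^2+s3^2)/s0, in [0, 1]."""
    if isinstance(s, StokesVector):
        a = s.as_array()
    else:
        a = np.asarray(s, dtype=float)
    s0 = a[..., 0]
    if np.any(s0 <= 0):
        raise ValueError("degree of polarization undefined for s0 <= 0")
    return np.sqrt(a[..., 1] ** 2 + a[..., 2] ** 2 + a[..., 3] ** 2) / s0
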