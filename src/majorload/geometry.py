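"""Primitive geometry of unit vectors and spherical sectors (cones).

A *cone* here is a spherical sector through the origin: the set of vectors
lying within a half-apex angle of a unit axis.  The coverage test is the
algebraic condition

    (u . c)^2 - (c . c)(u . u) cos^2(theta) >= 0    and    u . c > 0

where ``u`` is the vector to be covered, ``c`` the cone axis and ``theta``
the half-apex angle.  The quadratic form alone is satisfied by both sheets
of the double cone; the positive-dot guard restricts it to the single
sector around the axis, since a load opposite the axis is a physically
distinct load case.

Angles are accepted and reported in degrees throughout the public API.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateVectorError

__all__ = ["Cone", "unit", "angle_between", "covers", "covers_any", "orthonormal_frame"]

#: vectors with a norm below this are treated as zero / directionless
_ZERO_NORM_TOL = 1e-300

#: unit-norm check tolerance for validated axes
_UNIT_TOL = 1e-12

#: relative slack of the coverage quadratic: a vector exactly on the cone
#: boundary must test as covered regardless of whether it was normalised
#: first (the discriminant is 0 there and floating-point noise is ~1e-15);
#: the slack admits directions at most ~2e-10 degrees beyond the boundary
_COVER_TOL = 1e-12


def unit(v: np.ndarray) -> np.ndarray:
    """Return ``v / ||v||`` as a float ndarray.

    Raises :class:`DegenerateVectorError` for the zero vector.  Accepts a
    single 3-vector or an ``(n, 3)`` stack (row-wise normalisation).
    """
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(n <= _ZERO_NORM_TOL):
        raise DegenerateVectorError("cannot normalise a zero vector")
    return v / n


def angle_between(a: np.ndarray, b: np.ndarray) -> float | np.ndarray:
    """Angle in degrees between unit vectors, in [0, 180].

    Dot products are clamped to [-1, 1] before arccos so that vectors equal
    up to machine precision do not fall outside the arccos domain.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = np.clip(np.sum(a * b, axis=-1), -1.0, 1.0)
    return np.degrees(np.arccos(d))


@dataclass(frozen=True)
class Cone:
    """A spherical sector: unit ``axis`` plus ``half_apex_deg`` in (0, 90)."""

    axis: np.ndarray
    half_apex_deg: float

    def __post_init__(self) -> None:
        ax = np.asarray(self.axis, dtype=float)
        if ax.shape != (3,):
            raise ValueError(f"cone axis must be a 3-vector, got shape {ax.shape}")
        if abs(np.linalg.norm(ax) - 1.0) > _UNIT_TOL:
            raise ValueError("cone axis must be a unit vector (norm within 1e-12 of 1)")
        if not 0.0 < self.half_apex_deg < 90.0:
            raise ValueError("half-apex angle must lie strictly inside (0, 90) degrees")
        object.__setattr__(self, "axis", ax)

    def covers(self, u: np.ndarray) -> bool | np.ndarray:
        return covers(self, u)


def covers(cone: Cone, u: np.ndarray) -> bool | np.ndarray:
    """True iff ``u`` lies inside the spherical sector (boundary inclusive).

    Implements the sign-symmetric quadratic coverage condition restricted to
    the sheet around the axis by the guard ``u . c > 0``.  Invariant to
    positive scaling of ``u``.  Accepts a 3-vector or an ``(n, 3)`` stack.
    """
    u = np.asarray(u, dtype=float)
    uu = np.sum(u * u, axis=-1)
    if np.any(uu <= _ZERO_NORM_TOL):
        raise DegenerateVectorError("coverage test is undefined for a zero vector")
    c = cone.axis
    uc = u @ c
    cos2 = np.cos(np.radians(cone.half_apex_deg)) ** 2
    inside = uc * uc - uu * cos2 >= -_COVER_TOL * uu  # c.c == 1 for a unit axis
    result = inside & (uc > 0.0)
    return bool(result) if result.ndim == 0 else result


def covers_any(cones: list[Cone], u: np.ndarray) -> np.ndarray:
    """Row-wise: is each vector of the ``(n, 3)`` stack inside any cone?"""
    u = np.atleast_2d(np.asarray(u, dtype=float))
    out = np.zeros(u.shape[0], dtype=bool)
    for cone in cones:
        out |= covers(cone, u)
    return out


def orthonormal_frame(axis: np.ndarray, reference: np.ndarray | None = None,
                      parallel_tol: float = 1e-9) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors completing ``axis`` to a right-handed basis.

    ``b1`` is the component of ``reference`` perpendicular to ``axis``
    (renormalised), which anchors azimuth zero to the plane spanned by the
    axis and the reference; ``b2 = axis x b1``.  When the reference is
    missing or parallel to the axis, the coordinate axis least aligned with
    ``axis`` is used instead.
    """
    axis = np.asarray(axis, dtype=float)
    b1 = None
    if reference is not None:
        ref = np.asarray(reference, dtype=float)
        perp = ref - (ref @ axis) * axis
        norm = np.linalg.norm(perp)
        if norm > parallel_tol:
            b1 = perp / norm
    if b1 is None:
        e = np.zeros(3)
        e[int(np.argmin(np.abs(axis)))] = 1.0
        perp = e - (e @ axis) * axis
        b1 = perp / np.linalg.norm(perp)
    b2 = np.cross(axis, b1)
    return b1, b2
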