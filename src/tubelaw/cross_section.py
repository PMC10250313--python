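"""Cross-section areas from polar perimeter traces.

The central cross-section of a deforming tube is exported as radial samples
(theta_i, r_i) of its perimeter.  For a star-shaped section the enclosed
area is the sum of circular wedges A = 1/2 * sum r_i^2 dtheta_i; the
``closed`` flag controls whether the wrap-around wedge between the last and
first sample is included (the physically correct closed curve) or omitted
(the literal open sum over the first N-1 samples).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError

__all__ = ["PerimeterTrace", "polar_polygon_area", "generate_shape"]

#: Angles closer than this (rad) are treated as duplicates on ingestion.
DUPLICATE_ANGLE_TOL = 1e-12

_TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class PerimeterTrace:
    """Polar samples of a closed star-shaped perimeter.

    Angles are normalized to [0, 2*pi) and sorted on construction (FEM
    exports are unordered); radii must all be positive and there must be at
    least three samples.
    """

    theta: np.ndarray
    r: np.ndarray

    def __post_init__(self):
        theta = np.mod(np.asarray(self.theta, dtype=float), _TWO_PI)
        r = np.asarray(self.r, dtype=float)
        if theta.shape != r.shape or theta.ndim != 1:
            raise DomainError("theta and r must be equal-length 1-D arrays")
        if theta.size < 3:
            raise DomainError(f"need at least 3 perimeter points, got {theta.size}")
        if not np.all(np.isfinite(theta)) or not np.all(np.isfinite(r)):
            raise DomainError("perimeter coordinates must be finite")
        if np.any(r <= 0):
            raise DomainError("all radii must be positive")
        order = np.argsort(theta, kind="stable")
        theta, r = theta[order], r[order]
        if np.any(np.diff(theta) < DUPLICATE_ANGLE_TOL):
            raise DomainError(
                f"duplicate perimeter angles (tolerance {DUPLICATE_ANGLE_TOL} rad)"
            )
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "r", r)

    @property
    def n_points(self) -> int:
        return self.theta.size


def polar_polygon_area(trace: PerimeterTrace, closed: bool = True) -> float:
    """Enclosed area [m^2] of a polar perimeter trace.

    With ``closed=False`` returns the open wedge sum
    ``1/2 * sum_{i<N} r_i^2 |theta_{i+1} - theta_i|`` which omits the wedge
    between the last and first sample; with ``closed=True`` (default) the
    wrap-around wedge ``1/2 * r_N^2 (2 pi - theta_N + theta_1)`` is added,
    which is exact for constant-radius traces at any N and spacing.
    """
    theta, r = trace.theta, trace.r
    if np.any(np.diff(theta) < 0):  # defensive; construction sorts
        raise DomainError("perimeter angles must be sorted")
    area = 0.5 * np.sum(r[:-1] ** 2 * np.abs(np.diff(theta)))
    if closed:
        area += 0.5 * r[-1] ** 2 * (_TWO_PI - theta[-1] + theta[0])
    return float(area)


def generate_shape(
    kind: str,
    n_points: int = 64,
    *,
    r0: float = 1.0,
    a: float | None = None,
    b: float | None = None,
    eps: float = 0.0,
) -> PerimeterTrace:
    """Parametric perimeter fixtures: ``circle``, ``ellipse`` or ``two_lobe``.

    circle    r(theta) = r0
    ellipse   r(theta) = a b / sqrt(b^2 cos^2 + a^2 sin^2)  (b on the vertical;
              defaults a=r0, b=0.99 r0, the seeding eccentricity used to
              control the buckling direction)
    two_lobe  r(theta) = r0 (1 - eps cos 2 theta), the lowest azimuthal mode
              of a buckled section; eps in [0, 1).
    """
    if n_points < 3:
        raise DomainError("n_points must be >= 3")
    theta = np.arange(n_points) * _TWO_PI / n_points
    if kind == "circle":
        r = np.full(n_points, float(r0))
    elif kind == "ellipse":
        a = float(a) if a is not None else float(r0)
        b = float(b) if b is not None else 0.99 * a
        if a <= 0 or b <= 0:
            raise DomainError("ellipse semi-axes must be positive")
        r = a * b / np.sqrt(b**2 * np.cos(theta) ** 2 + a**2 * np.sin(theta) ** 2)
    elif kind == "two_lobe":
        if not 0.0 <= eps < 1.0:
            raise DomainError(
                f"two-lobe amplitude must lie in [0, 1) to avoid "
                f"self-intersection, got {eps}"
            )
        r = r0 * (1.0 - eps * np.cos(2.0 * theta))
    else:
        raise DomainError(f"unknown shape kind {kind!r}")
    return PerimeterTrace(theta=theta, r=r)
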