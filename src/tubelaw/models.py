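"""Closed-form models for the mechanics of collapsible-tube buckling.

This module collects the analytic building blocks used throughout the
package:

* conversion of linear elastic constants to Neo-Hookean coefficients,
* the von Mises thin-shell formula for the external-pressure buckling of a
  clamped tube into a two-lobed cross-section,
* the mean-field (Landau) order-parameter solution near a second-order
  phase transition,
* the three empirical laws describing how the buckling critical pressure
  depends on the tube's geometric ratios (length-to-diameter ``d``,
  thickness-to-diameter ``gamma``, axial pre-stretch ``l``), with the
  published fit parameters as defaults,
* the non-dimensional pressure/area transforms under which tube laws of
  different geometries approximately collapse onto a single curve.

Sign convention
---------------
All public critical pressures are *signed intramural pressures* in Pa:
collapse is driven by negative intramural pressure, so every critical
pressure returned here is negative (or zero in degenerate limits).  Use
:func:`magnitude` where the positive magnitude is wanted.  Units are SI
throughout (Pa, m, m**2); the non-dimensional quantities are unitless.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, IllConditionedParametersWarning

__all__ = [
    "Material",
    "TubeGeometry",
    "NeoHookeanCoefficients",
    "LandauModelParams",
    "DependenceParams",
    "D_SWEEP_PARAMS",
    "GAMMA_SWEEP_PARAMS",
    "L_SWEEP_PARAMS",
    "neo_hookean_coefficients",
    "von_mises_critical_pressure",
    "ring_buckling_pressure",
    "order_parameter_mean_field",
    "predict_pcrit_d",
    "predict_pcrit_gamma",
    "predict_pcrit_l",
    "nondimensionalize",
    "dimensionalize",
    "magnitude",
]


@dataclass(frozen=True)
class Material:
    """Isotropic elastic material of the tube wall.

    Parameters
    ----------
    E : float
        Young's modulus [Pa], > 0.
    nu : float
        Poisson ratio, in [0, 0.5).  The wall is treated as nearly
        incompressible in the reference configuration (nu = 0.49).
    rho : float
        Density [kg m^-3], > 0.
    """

    E: float = 1.0e6
    nu: float = 0.49
    rho: float = 1000.0

    def __post_init__(self):
        if not self.E >= 0:
            raise DomainError(f"Young's modulus must be >= 0, got {self.E}")
        if not 0.0 <= self.nu < 0.5:
            raise DomainError(
                f"Poisson ratio must lie in [0, 0.5), got {self.nu}"
            )
        if not self.rho > 0:
            raise DomainError(f"density must be > 0, got {self.rho}")


@dataclass(frozen=True)
class TubeGeometry:
    """Non-dimensional geometry of a cylindrical collapsible tube.

    Parameters
    ----------
    d : float
        Length-to-diameter ratio l0/D of the rest configuration, > 0.
    gamma : float
        Wall thickness-to-diameter ratio h/D, in (0, 0.5).
    l : float
        Axial pre-stretch ratio (stretched length / rest length), >= 1.
    r : float
        Internal radius [m], > 0.  Headline outputs are radius-independent
        after non-dimensionalization; ``r`` only sets absolute areas.
    """

    d: float
    gamma: float
    l: float = 1.0
    r: float = 0.005

    def __post_init__(self):
        if not self.d > 0:
            raise DomainError(f"d must be > 0, got {self.d}")
        if not 0.0 < self.gamma < 0.5:
            raise DomainError(f"gamma must lie in (0, 0.5), got {self.gamma}")
        if not self.l >= 1.0:
            raise DomainError(f"pre-stretch l must be >= 1, got {self.l}")
        if not self.r > 0:
            raise DomainError(f"radius must be > 0, got {self.r}")

    @property
    def diameter(self) -> float:
        """Internal diameter D = 2 r [m]."""
        return 2.0 * self.r

    @property
    def thickness(self) -> float:
        """Wall thickness h = gamma * D [m]."""
        return self.gamma * self.diameter

    @property
    def rest_length(self) -> float:
        """Length at rest l0 = d * D [m]."""
        return self.d * self.diameter

    @property
    def stretched_length(self) -> float:
        """Length after axial pre-stretch l * l0 [m]."""
        return self.l * self.rest_length

    @property
    def rest_area(self) -> float:
        """Reference area of the central cross-section after an
        incompressible axial pre-stretch, pi r^2 / l [m^2]."""
        return np.pi * self.r**2 / self.l


@dataclass(frozen=True)
class NeoHookeanCoefficients:
    """Coefficients (chi, lam) of the Neo-Hookean strain-energy density [Pa]."""

    chi: float
    lam: float


def neo_hookean_coefficients(mat: Material) -> NeoHookeanCoefficients:
    """Convert (E, nu) to Neo-Hookean coefficients.

    chi = E / (4 (1 + nu)),  lam = nu E / ((1 - 2 nu)(1 + nu)).

    Raises
    ------
    DomainError
        If nu >= 0.5 (incompressibility singularity of lam) or nu <= -1.
    """
    nu = mat.nu
    if nu >= 0.5:
        raise DomainError(
            f"nu={nu} >= 0.5: volumetric coefficient diverges at "
            "incompressibility"
        )
    if nu <= -1.0:
        raise DomainError(f"nu={nu} <= -1 is outside the physical domain")
    chi = mat.E / (4.0 * (1.0 + nu))
    lam = nu * mat.E / ((1.0 - 2.0 * nu) * (1.0 + nu))
    return NeoHookeanCoefficients(chi=chi, lam=lam)


def von_mises_critical_pressure(mat: Material, geom: TubeGeometry) -> float:
    """Thin-shell buckling pressure of a clamped tube (two-lobed mode).

    Evaluates the classical external-pressure result

        -p_crit = 2 E gamma^3 / (1 - nu^2)
                  + [1 + (4 d / pi)^2]^-1 *
                    [2 E (7 - nu) gamma^3 / (3 (1 - nu^2)) + 2 E gamma / 3]

    and returns the *signed* critical intramural pressure (<= 0).  Derived
    under thin-shell assumptions, it overestimates the collapse pressure
    magnitude for the thick, short tubes typical of human airways.
    """
    E, nu = mat.E, mat.nu
    g, d = geom.gamma, geom.d
    ring = 2.0 * E * g**3 / (1.0 - nu**2)
    end_factor = 1.0 / (1.0 + (4.0 * d / np.pi) ** 2)
    bracket = 2.0 * E * (7.0 - nu) * g**3 / (3.0 * (1.0 - nu**2)) + 2.0 * E * g / 3.0
    return -(ring + end_factor * bracket)


def ring_buckling_pressure(mat: Material, gamma: float) -> float:
    """Signed buckling pressure of an infinitely long tube (elastic ring
    limit): p_crit = -2 E gamma^3 / (1 - nu^2)."""
    return -2.0 * mat.E * gamma**3 / (1.0 - mat.nu**2)


@dataclass(frozen=True)
class LandauModelParams:
    """Coefficients of the quartic Landau potential
    phi - phi0 = c1 (xi - xi_crit) alpha^2 + (c2/2) alpha^4."""

    c1: float
    c2: float
    xi_crit: float

    def __post_init__(self):
        if not (self.c1 > 0 and self.c2 > 0):
            raise DomainError(
                f"Landau coefficients must be positive, got c1={self.c1}, "
                f"c2={self.c2}"
            )


def order_parameter_mean_field(xi, params: LandauModelParams):
    """Equilibrium order parameter of the quartic Landau potential.

    alpha(xi) = sqrt(-(c1/c2)(xi - xi_crit)) for xi < xi_crit, else 0.
    Continuous at the transition; vectorized over ``xi``.
    """
    xi = np.asarray(xi, dtype=float)
    dx = params.xi_crit - xi
    alpha = np.sqrt(params.c1 / params.c2 * np.clip(dx, 0.0, None))
    return alpha if alpha.ndim else float(alpha)


@dataclass(frozen=True)
class DependenceParams:
    """Fitted parameters (A, B, C) of one geometric-dependence law.

    The meaning and units of B differ by law: it is a pure exponent in the
    d-law, a pressure [Pa] in the gamma-law, and a rate in the l-law.  C is
    absent (None) for the gamma-law.
    """

    A: float
    B: float
    C: float | None = None

    def __post_init__(self):
        vals = [self.A, self.B] + ([self.C] if self.C is not None else [])
        if not all(np.isfinite(v) for v in vals):
            raise DomainError(f"dependence parameters must be finite: {self}")


#: Published d-dependence fit: -p_crit(d) = A d^B + C (fixed gamma=0.06, l=1.1).
D_SWEEP_PARAMS = DependenceParams(A=2.25e4, B=-2.20, C=4.37e2)
#: Published gamma-dependence fit: -p_crit(gamma) = A gamma^3 + B gamma
#: (fixed d=3, l=1.1).
GAMMA_SWEEP_PARAMS = DependenceParams(A=2.53e6, B=3.14e4)
#: Published l-dependence fit: -p_crit(l) = A tanh(B l) + C.  A and C cancel
#: to the printed precision; predictions from these values are meaningless
#: (a warning is emitted when they are used).
L_SWEEP_PARAMS = DependenceParams(A=1.90e7, B=4.75, C=-1.90e7)


def predict_pcrit_d(d, params: DependenceParams | None = None):
    """Signed buckling critical pressure vs length-to-diameter ratio,
    p_crit(d) = -(A d^B + C).  Defaults to the published fit parameters.
    """
    if params is None:
        params = D_SWEEP_PARAMS
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise DomainError("length-to-diameter ratio d must be > 0")
    out = -(params.A * d**params.B + (params.C or 0.0))
    return out if out.ndim else float(out)


def predict_pcrit_gamma(gamma, params: DependenceParams | None = None):
    """Signed buckling critical pressure vs thickness-to-diameter ratio,
    p_crit(gamma) = -(A gamma^3 + B gamma).  Defaults to the published fit.
    """
    if params is None:
        params = GAMMA_SWEEP_PARAMS
    gamma = np.asarray(gamma, dtype=float)
    out = -(params.A * gamma**3 + params.B * gamma)
    return out if out.ndim else float(out)


def _l_params_ill_conditioned(params: DependenceParams) -> bool:
    # A + C is the asymptotic plateau of A tanh(B l) + C for large l; when the
    # printed A and C cancel to rounding, the prediction is pure cancellation
    # noise.
    c = params.C or 0.0
    scale = max(abs(params.A), abs(c))
    return scale > 0 and abs(params.A + c) < 1e-2 * scale


def predict_pcrit_l(l, params: DependenceParams | None = None):
    """Signed buckling critical pressure vs axial pre-stretch ratio,
    p_crit(l) = -(A tanh(B l) + C).

    With the published parameters A and C cancel to the printed precision,
    so the asymptotic plateau A + C — the physically meaningful quantity —
    is lost to rounding; an :class:`IllConditionedParametersWarning` is
    emitted and the returned value must not be trusted.
    """
    if params is None:
        params = L_SWEEP_PARAMS
    if _l_params_ill_conditioned(params):
        warnings.warn(
            "l-dependence parameters are ill-conditioned: A and C cancel to "
            "their stated precision, so the predicted plateau A + C is "
            "rounding noise",
            IllConditionedParametersWarning,
            stacklevel=2,
        )
    l = np.asarray(l, dtype=float)
    out = -(params.A * np.tanh(params.B * l) + (params.C or 0.0))
    return out if out.ndim else float(out)


def nondimensionalize(p_intr, area, mat: Material, geom: TubeGeometry):
    """Map (p_intr [Pa], A [m^2]) to the non-dimensional tube-law variables.

    p_hat = p_intr (1 - nu^2) / E * l^-2 gamma^-1 d,
    A_hat = A l / (pi r^2).

    Under this rescaling, tube laws measured at different (d, gamma, l)
    approximately collapse onto one curve.  Exactly inverted by
    :func:`dimensionalize`.
    """
    if mat.E <= 0:
        raise DomainError("E must be > 0 to non-dimensionalize pressures")
    p_hat = (
        np.asarray(p_intr, dtype=float)
        * (1.0 - mat.nu**2)
        / mat.E
        * geom.l**-2
        * geom.gamma**-1
        * geom.d
    )
    a_hat = np.asarray(area, dtype=float) * geom.l / (np.pi * geom.r**2)
    p_hat = p_hat if p_hat.ndim else float(p_hat)
    a_hat = a_hat if a_hat.ndim else float(a_hat)
    return p_hat, a_hat


def dimensionalize(p_hat, a_hat, mat: Material, geom: TubeGeometry):
    """Inverse of :func:`nondimensionalize`: recover (p_intr [Pa], A [m^2])."""
    p = (
        np.asarray(p_hat, dtype=float)
        * mat.E
        / (1.0 - mat.nu**2)
        * geom.l**2
        * geom.gamma
        / geom.d
    )
    a = np.asarray(a_hat, dtype=float) * np.pi * geom.r**2 / geom.l
    p = p if p.ndim else float(p)
    a = a if a.ndim else float(a)
    return p, a


def magnitude(p):
    """Positive magnitude of a signed critical pressure."""
    out = np.abs(np.asarray(p, dtype=float))
    return out if out.ndim else float(out)
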