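"""Buckling-point estimation by Landau phase-transition curve fitting.

The buckling of a collapsible tube is treated as a second-order phase
transition: the area of the central cross-section plays the role of (a
function of) the order parameter, and the loading pressure that of the
control variable.  Near the transition the mean-field order parameter
vanishes as (p_tilde_crit - p_tilde)^(1/2); to fit a wider portion of the
tube law the knee is modelled with the saturating generalization

    A - A_crit = c1 * tanh(c2 * x^beta),   x = (p_tilde_crit - p_tilde)/p_tilde

with p_tilde = -p_intr > 0 the loading (positive external) pressure, c1 and
c2 positive shape parameters, and beta the critical exponent (1/2 in
mean-field theory).  For p_tilde beyond the critical value x is negative and
x^beta is undefined for fractional beta; the odd signed-power extension
sign(x)|x|^beta continues the area drop smoothly through the knee.

Estimation is a nested optimization: for a fixed candidate A_crit the four
parameters (c1, c2, p_tilde_crit, beta) are fitted by nonlinear least
squares, and A_crit itself is chosen to minimize the residual sum of squares
(a coarse grid scan followed by a bounded scalar search, both inside the
observed area range).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from scipy.optimize import curve_fit, minimize_scalar

from .errors import EstimationError, InsufficientDataError

if TYPE_CHECKING:  # pragma: no cover - import cycle with synthetic
    from .synthetic import TubeLawCurve

__all__ = [
    "PreprocessedTubeLaw",
    "LandauFitResult",
    "landau_area_model",
    "preprocess_tubelaw",
    "fit_landau_profile",
    "estimate_buckling_point",
    "estimate_from_curve",
]

#: Default normalized-area threshold below which samples are treated as
#: wall-contact and excluded from the buckling fit.
DEFAULT_CONTACT_THRESHOLD = 0.35

#: Bounds on the critical exponent during fitting.
BETA_BOUNDS = (0.05, 2.0)


def _signed_power(x, beta):
    return np.sign(x) * np.abs(x) ** beta


def landau_area_model(p_tilde, c1, c2, p_tilde_crit, beta, a_crit):
    """Area predicted by the saturating Landau knee model at loading
    pressure ``p_tilde`` (> 0), with the signed-power extension past the
    knee."""
    x = (p_tilde_crit - p_tilde) / p_tilde
    return a_crit + c1 * np.tanh(c2 * _signed_power(x, beta))


@dataclass(frozen=True)
class PreprocessedTubeLaw:
    """A tube law made fit-ready: loading pressures p_tilde = -p_intr > 0
    sorted increasing, areas normalized, contact tail removed."""

    p_tilde: np.ndarray
    area: np.ndarray
    n_dropped_zero: int = 0
    n_dropped_contact: int = 0
    contact_threshold: float = DEFAULT_CONTACT_THRESHOLD

    def __post_init__(self):
        p = np.asarray(self.p_tilde, dtype=float)
        a = np.asarray(self.area, dtype=float)
        if p.shape != a.shape or p.ndim != 1:
            raise InsufficientDataError("p_tilde and area must be equal-length 1-D")
        if np.any(p <= 0):
            raise InsufficientDataError("p_tilde must be strictly positive")
        if np.any(np.diff(p) < 0):
            raise InsufficientDataError("p_tilde must be sorted increasing")
        if not np.all(np.isfinite(a)):
            raise InsufficientDataError("areas must be finite")
        object.__setattr__(self, "p_tilde", p)
        object.__setattr__(self, "area", a)

    @property
    def n_points(self) -> int:
        return self.p_tilde.size


def preprocess_tubelaw(
    curve: TubeLawCurve,
    contact_area_threshold: float = DEFAULT_CONTACT_THRESHOLD,
) -> PreprocessedTubeLaw:
    """Prepare a tube law for the buckling fit.

    Drops p_intr = 0 samples (the loading variable x is undefined there),
    flips sign to p_tilde = -p_intr, normalizes absolute areas by the first
    recorded area, removes everything at and beyond the first sample whose
    normalized area falls below ``contact_area_threshold`` (the wall-contact
    regime is outside the scope of the buckling model), and sorts by
    p_tilde.

    Raises
    ------
    InsufficientDataError
        If the curve has fewer than 10 samples, or fewer than 8 remain.
    """
    if curve.n_samples < 10:
        raise InsufficientDataError(
            f"need >= 10 samples spanning the knee, got {curve.n_samples}"
        )
    p_intr = np.asarray(curve.p_intr, dtype=float)
    area = np.asarray(curve.area, dtype=float)
    keep = p_intr < 0
    n_zero = int(np.sum(~keep))
    p_tilde = -p_intr[keep]
    area = area[keep]
    if not curve.normalized:
        area = area / area[0]
    order = np.argsort(p_tilde, kind="stable")
    p_tilde, area = p_tilde[order], area[order]
    below = np.nonzero(area < contact_area_threshold)[0]
    n_contact = 0
    if below.size:
        cut = below[0]
        n_contact = p_tilde.size - cut
        p_tilde, area = p_tilde[:cut], area[:cut]
    if p_tilde.size < 8:
        raise InsufficientDataError(
            f"only {p_tilde.size} samples remain after preprocessing "
            f"(threshold {contact_area_threshold})"
        )
    return PreprocessedTubeLaw(
        p_tilde=p_tilde,
        area=area,
        n_dropped_zero=n_zero,
        n_dropped_contact=n_contact,
        contact_threshold=contact_area_threshold,
    )


@dataclass(frozen=True)
class LandauFitResult:
    """Estimated buckling point of one tube law.

    ``p_crit`` is the signed critical intramural pressure (negative);
    ``a_crit`` is in the same normalization as the input areas.  Variances
    are the diagonal of the inner-fit covariance at the optimal a_crit
    (a_crit's own uncertainty is not propagated).
    """

    c1: float
    c2: float
    p_crit: float
    beta: float
    a_crit: float
    variances: dict = field(default_factory=dict)
    rss: float = np.nan
    n_points: int = 0
    converged: bool = True
    message: str = ""

    @property
    def p_tilde_crit(self) -> float:
        """Positive loading pressure at the transition, -p_crit."""
        return -self.p_crit


@dataclass(frozen=True)
class _InnerFit:
    params: np.ndarray  # (c1, c2, p_tilde_crit, beta)
    cov: np.ndarray
    rss: float
    ok: bool
    message: str = ""


def _default_start(data: PreprocessedTubeLaw) -> np.ndarray:
    p, a = data.p_tilde, data.area
    # knee location from the steepest area drop; robust data-driven start
    slope = np.gradient(a, p)
    ptc0 = float(np.clip(p[int(np.argmin(slope))], p[0], p[-1]))
    c10 = max((a.max() - a.min()) / 2.0, 1e-6)
    return np.array([c10, 1.0, ptc0, 0.5])


def fit_landau_profile(
    data: PreprocessedTubeLaw,
    a_crit: float,
    p0: np.ndarray | None = None,
) -> _InnerFit:
    """Least-squares fit of the knee model at a fixed critical area.

    Returns an ``_InnerFit`` carrying (c1, c2, p_tilde_crit, beta), their
    covariance and the residual sum of squares.  Non-convergence is flagged
    on the result (``ok=False``), never raised.
    """
    p, a = data.p_tilde, data.area
    if p0 is None:
        p0 = _default_start(data)
    lo = [1e-12, 1e-12, p[0], BETA_BOUNDS[0]]
    hi = [np.inf, np.inf, p[-1], BETA_BOUNDS[1]]
    p0 = np.clip(p0, lo, hi)

    def model(pt, c1, c2, ptc, beta):
        return landau_area_model(pt, c1, c2, ptc, beta, a_crit)

    try:
        popt, pcov = curve_fit(
            model, p, a, p0=p0, bounds=(lo, hi), maxfev=20000
        )
    except (RuntimeError, ValueError) as exc:
        return _InnerFit(
            params=np.full(4, np.nan),
            cov=np.full((4, 4), np.nan),
            rss=np.inf,
            ok=False,
            message=str(exc),
        )
    rss = float(np.sum((a - model(p, *popt)) ** 2))
    ok = bool(np.all(np.isfinite(popt)) and np.all(np.isfinite(np.diag(pcov))))
    return _InnerFit(params=popt, cov=pcov, rss=rss, ok=ok,
                     message="" if ok else "singular covariance")


def estimate_buckling_point(
    data: PreprocessedTubeLaw,
    n_grid: int = 25,
) -> LandauFitResult:
    """Full nested estimation of the buckling point of one tube law.

    A coarse scan over ``n_grid`` critical-area candidates spanning the
    observed area range guards against local minima; a bounded scalar
    search then refines the best candidate.  The inner fit at the optimum
    is packaged as a :class:`LandauFitResult` with the signed critical
    pressure p_crit = -p_tilde_crit.

    A curve with no discernible transition yields a *flagged* result
    (``converged=False``), never a silent estimate; only when every single
    candidate fit fails is an :class:`EstimationError` raised.
    """
    a = data.area
    amin, amax = float(a.min()), float(a.max())
    if amax - amin < 1e-9:
        return LandauFitResult(
            c1=np.nan, c2=np.nan, p_crit=np.nan, beta=np.nan, a_crit=np.nan,
            rss=np.nan, n_points=data.n_points, converged=False,
            message="flat curve: no area variation, no transition present",
        )

    p0 = _default_start(data)
    grid = np.linspace(amin, amax, n_grid)
    fits = [fit_landau_profile(data, ac, p0=p0) for ac in grid]
    finite = [i for i, f in enumerate(fits) if np.isfinite(f.rss)]
    if not finite:
        raise EstimationError(
            "all candidate fits failed",
            diagnostics=[
                {"a_crit": float(ac), "message": f.message}
                for ac, f in zip(grid, fits)
            ],
        )
    best_i = min(finite, key=lambda i: fits[i].rss)
    lo = grid[max(best_i - 1, 0)]
    hi = grid[min(best_i + 1, n_grid - 1)]

    def objective(ac):
        return fit_landau_profile(data, float(ac), p0=p0).rss

    res = minimize_scalar(
        objective,
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-8 * (amax - amin)},
    )
    a_best = float(res.x) if np.isfinite(res.fun) else float(grid[best_i])
    inner = fit_landau_profile(data, a_best, p0=p0)
    if inner.rss > fits[best_i].rss:  # refinement never allowed to regress
        a_best, inner = float(grid[best_i]), fits[best_i]

    c1, c2, ptc, beta = (float(v) for v in inner.params)
    var = np.diag(inner.cov)
    converged = inner.ok
    message = inner.message
    # a fit whose amplitude is indistinguishable from zero, or buried in the
    # residual noise, found no knee
    noise_rms = np.sqrt(inner.rss / max(data.n_points, 1))
    if converged and np.isfinite(var[0]) and c1 <= 3.0 * np.sqrt(max(var[0], 0.0)):
        converged = False
        message = "no significant transition amplitude (c1 within 3 sigma of 0)"
    elif converged and c1 <= 5.0 * noise_rms:
        converged = False
        message = (
            "no significant transition amplitude (c1 below 5x residual rms)"
        )
    return LandauFitResult(
        c1=c1,
        c2=c2,
        p_crit=-ptc,
        beta=beta,
        a_crit=a_best,
        variances={
            "c1": float(var[0]),
            "c2": float(var[1]),
            "p_tilde_crit": float(var[2]),
            "beta": float(var[3]),
        },
        rss=float(inner.rss),
        n_points=data.n_points,
        converged=converged,
        message=message,
    )


def estimate_from_curve(
    curve: TubeLawCurve,
    contact_area_threshold: float = DEFAULT_CONTACT_THRESHOLD,
    n_grid: int = 25,
) -> LandauFitResult:
    """Convenience chain: preprocess a raw tube law, then estimate its
    buckling point."""
    data = preprocess_tubelaw(curve, contact_area_threshold)
    return estimate_buckling_point(data, n_grid=n_grid)
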