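"""Parameter sweeps, geometric-dependence fits, phase diagrams and the
non-dimensional collapse.

A sweep runs the buckling-point estimator over a family of tube laws that
differ in one geometric parameter, then summarizes the resulting critical
pressures three ways: an empirical dependence law fitted to the sweep
(power law in d, odd cubic in gamma, saturating tanh in l), the phase
boundary that law defines in the (parameter, p_intr) plane, and the
non-dimensional critical constants obtained by rescaling every critical
point and averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import DomainError, EstimationError
from .landau import LandauFitResult, estimate_from_curve
from .models import Material, TubeGeometry, nondimensionalize
from .synthetic import TubeLawCurve

__all__ = [
    "SweepResult",
    "DependenceFit",
    "NondimensionalSummary",
    "analyze_sweep",
    "fit_dependence",
    "phase_boundary",
    "nondimensional_collapse",
]

#: Equation ids of the three dependence laws, keyed by swept parameter.
EQUATION_FOR_PARAM = {"d": 11, "gamma": 12, "l": 13}
PARAM_FOR_EQUATION = {v: k for k, v in EQUATION_FOR_PARAM.items()}


@dataclass(frozen=True)
class SweepResult:
    """Per-value buckling fits for one swept geometric parameter."""

    param: str
    values: np.ndarray
    fits: list[LandauFitResult]
    geometries: list[TubeGeometry]
    ground_truth: list[dict | None] = field(default_factory=list)

    @classmethod
    def from_points(cls, param: str, values, p_crit, a_crit=None) -> "SweepResult":
        """Build a sweep from bare (value, signed critical pressure) pairs,
        e.g. to fit a dependence law to externally obtained critical
        pressures."""
        values = np.asarray(values, dtype=float)
        p_crit = np.asarray(p_crit, dtype=float)
        if values.shape != p_crit.shape:
            raise DomainError("values and p_crit must have equal length")
        a_crit = (
            np.full(values.shape, np.nan)
            if a_crit is None
            else np.asarray(a_crit, dtype=float)
        )
        order = np.argsort(values, kind="stable")
        fits = [
            LandauFitResult(
                c1=np.nan, c2=np.nan, p_crit=float(p), beta=np.nan,
                a_crit=float(a), n_points=0,
            )
            for p, a in zip(p_crit[order], a_crit[order])
        ]
        triplet = {"d": 3.0, "gamma": 0.06, "l": 1.1}
        geoms = []
        for v in values[order]:
            t = dict(triplet)
            if param in t:
                t[param] = float(v)
            geoms.append(TubeGeometry(**t))
        return cls(
            param=param, values=values[order], fits=fits, geometries=geoms,
            ground_truth=[None] * values.size,
        )

    @property
    def p_crit(self) -> np.ndarray:
        """Signed critical pressures [Pa], one per sweep value."""
        return np.array([f.p_crit for f in self.fits])

    @property
    def a_crit(self) -> np.ndarray:
        """Critical areas (input normalization), one per sweep value."""
        return np.array([f.a_crit for f in self.fits])

    @property
    def n_converged(self) -> int:
        return sum(f.converged for f in self.fits)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                self.param: self.values,
                "p_crit_pa": self.p_crit,
                "a_crit": self.a_crit,
                "beta": [f.beta for f in self.fits],
                "c1": [f.c1 for f in self.fits],
                "c2": [f.c2 for f in self.fits],
                "rss": [f.rss for f in self.fits],
                "converged": [f.converged for f in self.fits],
            }
        )


def _infer_sweep_param(geoms: list[TubeGeometry]) -> str:
    varying = [
        name
        for name in ("d", "gamma", "l")
        if len({round(getattr(g, name), 12) for g in geoms}) > 1
    ]
    if len(varying) != 1:
        raise DomainError(
            f"cannot infer swept parameter (varying: {varying or 'none'}); "
            "pass param explicitly"
        )
    return varying[0]


def analyze_sweep(
    curves: list[TubeLawCurve],
    param: str | None = None,
    contact_area_threshold: float = 0.35,
    n_grid: int = 25,
) -> SweepResult:
    """Estimate the buckling point of every curve in a sweep.

    Requires at least 3 curves, each carrying its geometry.  Non-convergent
    fits are carried through with their flag, never dropped silently.
    The result is sorted by sweep value.
    """
    if len(curves) < 3:
        raise DomainError(f"a sweep needs >= 3 curves, got {len(curves)}")
    if any(c.geometry is None for c in curves):
        raise DomainError("every curve must carry its TubeGeometry")
    geoms = [c.geometry for c in curves]
    if param is None:
        param = _infer_sweep_param(geoms)
    if param not in ("d", "gamma", "l"):
        raise DomainError(f"unknown sweep parameter {param!r}")

    values = np.array([getattr(g, param) for g in geoms])
    order = np.argsort(values, kind="stable")
    fits = []
    for i in order:
        fits.append(
            estimate_from_curve(
                curves[i],
                contact_area_threshold=contact_area_threshold,
                n_grid=n_grid,
            )
        )
    return SweepResult(
        param=param,
        values=values[order],
        fits=fits,
        geometries=[geoms[i] for i in order],
        ground_truth=[curves[i].meta.get("ground_truth") for i in order],
    )


@dataclass(frozen=True)
class DependenceFit:
    """Fitted dependence law -p_crit(x) for one sweep.

    ``params``/``stderr`` hold A, B (and C where the law has one); the full
    covariance, residual sum of squares and a conditioning diagnostic (the
    A-C estimate correlation for the tanh law, whose plateau A + C is prone
    to cancellation) are kept for honest reporting.
    """

    equation: int
    params: dict
    stderr: dict
    cov: np.ndarray
    rss: float
    n_points: int
    degenerate: bool = False
    diagnostics: dict = field(default_factory=dict)

    def predict_neg_pcrit(self, x):
        """Evaluate the fitted -p_crit(x) [Pa] (positive magnitudes)."""
        x = np.asarray(x, dtype=float)
        p = self.params
        if self.equation == 11:
            out = p["A"] * x ** p["B"] + p["C"]
        elif self.equation == 12:
            out = p["A"] * x**3 + p["B"] * x
        else:
            out = p["A"] * np.tanh(p["B"] * x) + p["C"]
        return out if out.ndim else float(out)


def _model_d(x, A, B, C):
    return A * x**B + C


def _model_gamma(x, A, B):
    return A * x**3 + B * x


def _model_l(x, A, B, C):
    return A * np.tanh(B * x) + C


def _start_values(equation: int, x: np.ndarray, y: np.ndarray) -> list[float]:
    if equation == 11:
        c0 = 0.5 * float(y.min())
        resid = np.clip(y - c0, 1e-12, None)
        slope, intercept = np.polyfit(np.log(x), np.log(resid), 1)
        return [float(np.exp(intercept)), float(slope), c0]
    if equation == 12:
        coef, *_ = np.linalg.lstsq(
            np.column_stack([x**3, x]), y, rcond=None
        )
        return [float(coef[0]), float(coef[1])]
    # tanh law: amplitude from the observed spread, moderate rate, offset
    # from the large-l end
    return [float(y.max() - y.min() + 1e-3), 2.0, float(y.min())]


def fit_dependence(sweep: SweepResult, equation: int) -> DependenceFit:
    """Nonlinear least-squares fit of the dependence law matching the sweep.

    equation 11: -p_crit(d)     = A d^B + C
    equation 12: -p_crit(gamma) = A gamma^3 + B gamma
    equation 13: -p_crit(l)     = A tanh(B l) + C

    The sweep's parameter must match the equation.  Degenerate data (e.g.
    all-equal pressures) yield a fit flagged ``degenerate`` with a singular
    covariance rather than an error.
    """
    if equation not in PARAM_FOR_EQUATION:
        raise DomainError(f"unknown dependence equation {equation}")
    if PARAM_FOR_EQUATION[equation] != sweep.param:
        raise DomainError(
            f"equation {equation} fits a {PARAM_FOR_EQUATION[equation]}-sweep, "
            f"got a {sweep.param}-sweep"
        )
    x = np.asarray(sweep.values, dtype=float)
    y = -sweep.p_crit  # fit positive magnitudes
    model = {11: _model_d, 12: _model_gamma, 13: _model_l}[equation]
    names = ["A", "B"] if equation == 12 else ["A", "B", "C"]
    p0 = _start_values(equation, x, y)
    try:
        popt, pcov = curve_fit(model, x, y, p0=p0, maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise EstimationError(f"dependence fit failed: {exc}") from exc
    rss = float(np.sum((y - model(x, *popt)) ** 2))
    var = np.diag(pcov)
    degenerate = not np.all(np.isfinite(var))
    diagnostics = {}
    if equation == 13 and np.all(np.isfinite(var)) and np.all(var > 0):
        corr_ac = float(pcov[0, 2] / np.sqrt(var[0] * var[2]))
        diagnostics["corr_AC"] = corr_ac
        diagnostics["plateau_A_plus_C"] = float(popt[0] + popt[2])
    params = {n: float(v) for n, v in zip(names, popt)}
    stderr = {
        n: float(np.sqrt(v)) if np.isfinite(v) and v >= 0 else float("nan")
        for n, v in zip(names, var)
    }
    return DependenceFit(
        equation=equation,
        params=params,
        stderr=stderr,
        cov=pcov,
        rss=rss,
        n_points=x.size,
        degenerate=degenerate,
        diagnostics=diagnostics,
    )


def phase_boundary(fit: DependenceFit, grid) -> pd.DataFrame:
    """Evaluate a fitted dependence law on a parameter grid.

    Returns one row per grid value with the boundary pressure magnitude
    ``neg_p_crit_pa`` and the signed ``p_crit_pa``; intramural pressures
    below the boundary (more negative) put the tube in the buckled state.
    """
    param = PARAM_FOR_EQUATION[fit.equation]
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        return pd.DataFrame(columns=[param, "neg_p_crit_pa", "p_crit_pa"])
    neg = np.atleast_1d(fit.predict_neg_pcrit(grid))
    return pd.DataFrame(
        {param: grid, "neg_p_crit_pa": neg, "p_crit_pa": -neg}
    )


@dataclass(frozen=True)
class NondimensionalSummary:
    """Non-dimensional critical points of a set of analyzed tubes and their
    aggregate constants (mean +/- sd of each set)."""

    p_hat: np.ndarray
    a_hat: np.ndarray
    ddof: int = 0

    @property
    def n(self) -> int:
        return self.p_hat.size

    @property
    def p_hat_mean(self) -> float:
        return float(np.mean(self.p_hat))

    @property
    def p_hat_std(self) -> float:
        return float(np.std(self.p_hat, ddof=self.ddof))

    @property
    def a_hat_mean(self) -> float:
        return float(np.mean(self.a_hat))

    @property
    def a_hat_std(self) -> float:
        return float(np.std(self.a_hat, ddof=self.ddof))

    def to_dict(self) -> dict:
        return {
            "n": int(self.n),
            "p_hat_crit": list(map(float, self.p_hat)),
            "a_hat_crit": list(map(float, self.a_hat)),
            "p_hat_crit_mean": self.p_hat_mean,
            "p_hat_crit_std": self.p_hat_std,
            "a_hat_crit_mean": self.a_hat_mean,
            "a_hat_crit_std": self.a_hat_std,
            "ddof": int(self.ddof),
        }


def nondimensional_collapse(
    sweeps: list[SweepResult],
    mat: Material,
    ddof: int = 0,
    include_nonconverged: bool = False,
) -> NondimensionalSummary:
    """Pool the critical points of several sweeps in non-dimensional form.

    Each critical pressure is rescaled by (1 - nu^2)/E * l^-2 gamma^-1 d
    and each critical area by l/(pi r^2); fitted areas are normalized to
    the rest cross-section pi r^2 / l, under which the non-dimensional
    critical area equals the normalized one directly.  The summary reports
    the mean and standard deviation (population sd by default,
    ``ddof`` configurable) of both sets.
    """
    if not sweeps:
        raise DomainError("need at least one sweep to collapse")
    p_hat, a_hat = [], []
    for sweep in sweeps:
        for fit, geom in zip(sweep.fits, sweep.geometries):
            if geom is None:
                raise DomainError("every fit needs its geometry to collapse")
            if not fit.converged and not include_nonconverged:
                continue
            # fitted a_crit is normalized to the rest area pi r^2 / l, so the
            # absolute critical area is a_crit * pi r^2 / l
            area_abs = fit.a_crit * np.pi * geom.r**2 / geom.l
            ph, ah = nondimensionalize(fit.p_crit, area_abs, mat, geom)
            p_hat.append(ph)
            a_hat.append(ah)
    if not p_hat:
        raise EstimationError("no converged fits to collapse")
    return NondimensionalSummary(
        p_hat=np.array(p_hat), a_hat=np.array(a_hat), ddof=ddof
    )
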