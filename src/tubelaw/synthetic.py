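"""Synthetic tube-law generator emulating FEM collapse simulations.

A real tube-law run ramps the external pressure linearly in time and
records the central cross-section area at every time step.  The resulting
curve shows a stiff pre-buckling plateau, a continuous second-order knee at
the buckling pressure, a post-buckling area drop, and saturation once the
internal walls come into contact.  This module reproduces those features
from a known ground truth so that every downstream stage (preprocessing,
Landau fitting, sweep analysis, non-dimensional collapse) can be exercised
and its recovery accuracy measured without a finite-element solver.

Areas are generated in normalized units: the rest area of the central
cross-section after an incompressible axial pre-stretch is pi r^2 / l, and
areas are expressed relative to it, which makes them coincide with the
non-dimensional area A_hat = A l / (pi r^2).  The ground-truth knee area
defaults to the observed general value A_hat_crit = 0.924 and the plateau
amplitude c1 = 1 - A_hat_crit places the unloaded curve at A_hat ~ 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DomainError
from .landau import landau_area_model
from .models import (
    Material,
    TubeGeometry,
    predict_pcrit_d,
    predict_pcrit_gamma,
)

__all__ = [
    "RampSpec",
    "TubeLawCurve",
    "GeneratorConfig",
    "pressure_ramp",
    "noiseless_area",
    "generate_tubelaw",
    "generate_sweep_dataset",
    "default_generator_config",
    "DEFAULT_SWEEPS",
    "GENERAL_A_CRIT_HAT",
    "GENERAL_P_HAT_CRIT",
]

#: General non-dimensional buckling constants observed across geometries:
#: mean non-dimensional critical pressure and area.
GENERAL_P_HAT_CRIT = -0.07
GENERAL_A_CRIT_HAT = 0.924

#: Default sweep grids over the geometric parameters (7 + 5 + 8 = 20 tubes).
DEFAULT_SWEEPS = {
    "d": (3.0, 3.5, 4.0, 4.5, 5.0, 5.5, 6.0),
    "gamma": (0.05, 0.06, 0.07, 0.08, 0.09),
    "l": (1.1, 1.2, 1.3, 1.4, 1.5, 1.6, 1.7, 1.8),
}

#: Shared base triplet (d, gamma, l) of the default sweeps.
BASE_TRIPLET = {"d": 3.0, "gamma": 0.06, "l": 1.1}


@dataclass(frozen=True)
class RampSpec:
    """Linear external-pressure ramp p_ext(t) = p_max * t / tau sampled at a
    fixed time step; M = floor(tau / dt) samples at t_j = j dt, j = 1..M."""

    p_max: float = 8000.0  # [Pa]
    tau: float = 20.0  # [s]
    dt: float = 0.1  # [s]

    def __post_init__(self):
        if not self.p_max > 0:
            raise DomainError(f"p_max must be > 0, got {self.p_max}")
        if not self.tau > 0:
            raise DomainError(f"tau must be > 0, got {self.tau}")
        if not 0 < self.dt <= self.tau:
            raise DomainError(f"need 0 < dt <= tau, got dt={self.dt}")

    @property
    def n_samples(self) -> int:
        # guard against float round-off in tau/dt (e.g. 20/0.1 = 199.999...)
        return int(math.floor(self.tau / self.dt + 1e-9))

    @property
    def pressure_step(self) -> float:
        """Pressure resolution p_max * dt / tau [Pa]."""
        return self.p_max * self.dt / self.tau

    @property
    def rate(self) -> float:
        """Ramp rate p_max / tau [Pa/s]."""
        return self.p_max / self.tau


def pressure_ramp(spec: RampSpec):
    """Sample the linear ramp: returns (times [s], p_ext [Pa]) with
    constant increments p_max * dt / tau."""
    j = np.arange(1, spec.n_samples + 1)
    times = j * spec.dt
    return times, spec.p_max * times / spec.tau


@dataclass(frozen=True)
class TubeLawCurve:
    """One tube law: time-ordered (p_intr, A) samples plus provenance.

    In absence of flow the internal gauge pressure is zero and
    p_intr = -p_ext <= 0, non-increasing along the ramp.  ``normalized``
    flags whether areas are relative to the rest cross-section (True) or
    absolute [m^2].
    """

    time: np.ndarray
    p_intr: np.ndarray
    area: np.ndarray
    normalized: bool = True
    geometry: TubeGeometry | None = None
    material: Material | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        p = np.asarray(self.p_intr, dtype=float)
        a = np.asarray(self.area, dtype=float)
        if not (t.shape == p.shape == a.shape) or t.ndim != 1:
            raise DomainError("time, p_intr and area must be equal-length 1-D")
        if np.any(p > 0):
            raise DomainError("intramural pressures must be <= 0 (no flow)")
        if np.any(np.diff(p) > 1e-9):
            raise DomainError("p_intr must be non-increasing in time")
        if np.any(a <= 0):
            raise DomainError("areas must be positive")
        if self.normalized and np.any(a > 1.05):
            raise DomainError("normalized areas must lie in (0, 1.05]")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "p_intr", p)
        object.__setattr__(self, "area", a)

    @property
    def n_samples(self) -> int:
        return self.time.size


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground truth and sampling settings for one synthetic tube law.

    The knee follows the saturating Landau model with critical point
    (p_crit_true [Pa, negative], a_crit_hat) and shape (c1_true, c2_true,
    beta_true); the post-buckling branch saturates smoothly at the contact
    plateau a_contact_hat; Gaussian noise of sd sigma_a (normalized-area
    units) is added with the stated seed.
    """

    p_crit_true: float
    a_crit_hat: float = GENERAL_A_CRIT_HAT
    c1_true: float | None = None  # default 1 - a_crit_hat: unloaded area ~ 1
    c2_true: float = 1.5
    beta_true: float = 0.5
    a_contact_hat: float = 0.25
    blend_width: float = 0.02
    sigma_a: float = 0.002
    seed: int = 0
    ramp: RampSpec = field(default_factory=RampSpec)
    geometry: TubeGeometry = field(
        default_factory=lambda: TubeGeometry(d=3.0, gamma=0.06, l=1.1)
    )
    material: Material = field(default_factory=Material)

    def __post_init__(self):
        if not self.p_crit_true < 0:
            raise DomainError(
                f"p_crit_true must be negative (signed intramural pressure), "
                f"got {self.p_crit_true}"
            )
        if not self.beta_true > 0:
            raise DomainError("beta_true must be > 0")
        if not 0 < self.a_contact_hat < self.a_crit_hat:
            raise DomainError("need 0 < a_contact_hat < a_crit_hat")
        if self.sigma_a < 0:
            raise DomainError("sigma_a must be >= 0")
        if self.c2_true <= 0:
            raise DomainError("c2_true must be > 0")
        if self.blend_width < 0:
            raise DomainError("blend_width must be >= 0")
        if self.c1_true is not None and self.c1_true <= 0:
            raise DomainError("c1_true must be > 0")

    @property
    def c1(self) -> float:
        return self.c1_true if self.c1_true is not None else 1.0 - self.a_crit_hat

    @property
    def p_tilde_crit(self) -> float:
        return -self.p_crit_true


def default_generator_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Reference configuration: base triplet (d=3, gamma=0.06, l=1.1) with the
    knee pressure given by the d-dependence law at d=3."""
    cfg = GeneratorConfig(p_crit_true=predict_pcrit_d(3.0), seed=seed)
    return replace(cfg, **overrides) if overrides else cfg


def _smooth_max(a, floor, width):
    """Smooth lower saturation: max(a, floor) blended over ``width``."""
    if width == 0:
        return np.maximum(a, floor)
    return floor + width * np.logaddexp(0.0, (a - floor) / width)


def noiseless_area(cfg: GeneratorConfig, p_tilde):
    """Ground-truth normalized area at loading pressure p_tilde (> 0),
    before noise: the Landau knee saturated at the contact plateau."""
    p_tilde = np.asarray(p_tilde, dtype=float)
    smooth = landau_area_model(
        p_tilde, cfg.c1, cfg.c2_true, cfg.p_tilde_crit, cfg.beta_true,
        cfg.a_crit_hat,
    )
    out = _smooth_max(smooth, cfg.a_contact_hat, cfg.blend_width)
    return out if out.ndim else float(out)


def generate_tubelaw(cfg: GeneratorConfig) -> TubeLawCurve:
    """Generate one synthetic tube law from its ground-truth knee.

    Samples the pressure ramp, evaluates the noiseless curve at each
    loading pressure (samples with p_ext = 0 are skipped and counted in the
    output metadata: the knee variable is undefined there), and adds
    Gaussian area noise from a generator seeded with ``cfg.seed``.
    Deterministic for a fixed seed.
    """
    times, p_ext = pressure_ramp(cfg.ramp)
    keep = p_ext > 0
    n_skipped = int(np.sum(~keep))
    times, p_ext = times[keep], p_ext[keep]
    area = noiseless_area(cfg, p_ext)
    if cfg.sigma_a > 0:
        rng = np.random.default_rng(cfg.seed)
        area = area + rng.normal(0.0, cfg.sigma_a, size=area.size)
    return TubeLawCurve(
        time=times,
        p_intr=-p_ext,
        area=area,
        normalized=True,
        geometry=cfg.geometry,
        material=cfg.material,
        meta={
            "seed": int(cfg.seed),
            "n_skipped_zero_pressure": n_skipped,
            "ground_truth": {
                "p_crit_true": float(cfg.p_crit_true),
                "a_crit_hat": float(cfg.a_crit_hat),
                "c1_true": float(cfg.c1),
                "c2_true": float(cfg.c2_true),
                "beta_true": float(cfg.beta_true),
                "a_contact_hat": float(cfg.a_contact_hat),
                "sigma_a": float(cfg.sigma_a),
            },
        },
    )


def _child_seeds(base_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(int(base_seed))
    return [int(s) % 2**31 for s in ss.generate_state(n)]


def generate_sweep_dataset(
    param: str,
    values=None,
    *,
    base: dict | None = None,
    template: GeneratorConfig | None = None,
    knee_pressures=None,
    base_seed: int = 0,
) -> list[TubeLawCurve]:
    """Generate one synthetic tube law per value of a swept geometric
    parameter (``"d"``, ``"gamma"`` or ``"l"``).

    Ground-truth knee pressures come from the published dependence laws for
    the d- and gamma-sweeps.  For the l-sweep no well-conditioned published
    law exists (the printed tanh-law parameters cancel), so explicit
    ``knee_pressures`` (signed, one per value) are required.  The knee area
    is the general non-dimensional constant for every curve, and each
    curve's ground truth and derived seed are recorded in its metadata.
    """
    if param not in DEFAULT_SWEEPS:
        raise DomainError(f"unknown sweep parameter {param!r}")
    values = np.asarray(
        DEFAULT_SWEEPS[param] if values is None else values, dtype=float
    )
    if np.any(values <= 0):
        raise DomainError("sweep values must be positive")
    triplet = dict(BASE_TRIPLET)
    if base:
        triplet.update(base)
    if template is None:
        template = default_generator_config(seed=base_seed)

    if knee_pressures is None:
        if param == "d":
            knee_pressures = [predict_pcrit_d(v) for v in values]
        elif param == "gamma":
            knee_pressures = [predict_pcrit_gamma(v) for v in values]
        else:
            raise DomainError(
                "the l-sweep has no usable default knee law (the published "
                "tanh-law parameters cancel to rounding); supply explicit "
                "knee_pressures"
            )
    knee_pressures = np.asarray(knee_pressures, dtype=float)
    if knee_pressures.shape != values.shape:
        raise DomainError("knee_pressures must match sweep values in length")

    seeds = _child_seeds(base_seed, len(values))
    curves = []
    for value, p_crit, seed in zip(values, knee_pressures, seeds):
        t = dict(triplet)
        t[param] = float(value)
        geom = TubeGeometry(
            d=t["d"], gamma=t["gamma"], l=t["l"], r=template.geometry.r
        )
        cfg = replace(
            template,
            p_crit_true=float(p_crit),
            geometry=geom,
            seed=seed,
        )
        curve = generate_tubelaw(cfg)
        curve.meta["sweep"] = {"param": param, "value": float(value)}
        curves.append(curve)
    return curves
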