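"""Optional diagnostic plots (requires matplotlib).

Overlay tube laws, draw buckling phase diagrams, and show the
non-dimensional collapse.  All functions accept and return a matplotlib
``Axes`` so they compose into larger figures.
"""

from __future__ import annotations

import numpy as np

from .models import nondimensionalize


def _require_axes(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_tubelaws(curves, ax=None, labels=None):
    """Overlay (p_intr, area) tube laws."""
    ax = _require_axes(ax)
    for i, curve in enumerate(curves):
        label = labels[i] if labels else None
        ax.plot(curve.p_intr, curve.area, lw=1, label=label)
    ax.set_xlabel("intramural pressure [Pa]")
    ax.set_ylabel("normalized area")
    if labels:
        ax.legend(fontsize="small")
    return ax


def plot_phase_diagram(boundary, ax=None):
    """Draw the buckled/unbuckled boundary from a phase-boundary table."""
    ax = _require_axes(ax)
    param = boundary.columns[0]
    ax.plot(boundary[param], boundary["p_crit_pa"], "k-", lw=1.5)
    ax.fill_between(
        boundary[param],
        boundary["p_crit_pa"],
        boundary["p_crit_pa"].min() * 1.2,
        alpha=0.2,
        label="buckled",
    )
    ax.set_xlabel(param)
    ax.set_ylabel("intramural pressure [Pa]")
    ax.legend()
    return ax


def plot_collapse(curves, mat, ax=None):
    """Tube laws in non-dimensional variables; different geometries
    approximately fall on one curve."""
    ax = _require_axes(ax)
    for curve in curves:
        geom = curve.geometry
        area_abs = curve.area * np.pi * geom.r**2 / geom.l
        p_hat, a_hat = nondimensionalize(curve.p_intr, area_abs, mat, geom)
        ax.plot(p_hat, a_hat, lw=1)
    ax.set_xlabel("non-dimensional intramural pressure")
    ax.set_ylabel("non-dimensional area")
    return ax
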