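"""Plot helpers for psychometric functions and flow fields.

Every figure writer accepts an optional ``csv_path`` so the plotted numbers
always have a machine-readable twin.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .flowfield import FlowFieldSpec, screen_velocity_template
from .psychometrics import PsychometricData, PsychometricFit


def plot_psychometric(
    ax,
    data: PsychometricData,
    fit: PsychometricFit | None = None,
    color: str = "k",
    label: str | None = None,
):
    """Proportion-vs-level points with the fitted cumulative Gaussian."""
    ok = data.informative
    ax.plot(data.levels[ok], data.prop[ok], "o", color=color, label=label)
    if fit is not None and fit.converged:
        xs = np.linspace(data.levels[ok].min(), data.levels[ok].max(), 200)
        ax.plot(xs, fit.predict(xs), "-", color=color)
    ax.set_ylim(-0.02, 1.02)
    ax.axhline(0.5, lw=0.5, color="gray", ls=":")
    return ax


def plot_stim_comparison(
    ax,
    data_ctrl: PsychometricData,
    fit_ctrl: PsychometricFit,
    data_stim: PsychometricData,
    fit_stim: PsychometricFit,
    csv_path=None,
):
    """Control vs stimulated psychometric functions on one axis."""
    plot_psychometric(ax, data_ctrl, fit_ctrl, color="tab:green", label="control")
    plot_psychometric(ax, data_stim, fit_stim, color="tab:orange", label="stimulated")
    ax.legend(frameon=False)
    if csv_path is not None:
        rows = []
        for tag, d in (("ctrl", data_ctrl), ("stim", data_stim)):
            for lv, pr, n in zip(d.levels, d.prop, d.n):
                rows.append({"condition": tag, "level": lv, "prop": pr, "n": n})
        pd.DataFrame(rows).to_csv(csv_path, index=False)
    return ax


def plot_flow_template(ax, spec: FlowFieldSpec, grid: np.ndarray, color="tab:blue"):
    """Quiver plot of one spiral-space velocity template."""
    vf = screen_velocity_template(spec, grid)
    ax.quiver(
        vf.grid[:, 0], vf.grid[:, 1], vf.vectors[:, 0], vf.vectors[:, 1],
        color=color, angles="xy",
    )
    ax.set_aspect("equal")
    ax.set_xlabel("azimuth (deg)")
    ax.set_ylabel("elevation (deg)")
    return ax
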