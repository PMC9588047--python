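"""Diagnostic figures: field snapshots, error histograms, fit summaries.

All functions return the matplotlib Figure; pass ``path`` to save.
Plotting is optional and never required by the simulation pipeline.
"""

from __future__ import annotations

from typing import Dict, Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .architectures import ModelState  # noqa: E402

__all__ = ["snapshot_plot", "error_histogram", "fit_summary_bars"]


def snapshot_plot(model: ModelState, time: Optional[float] = None,
                  state: Optional[Dict[str, np.ndarray]] = None,
                  path=None):
    """One panel per field: activation (blue) and sigmoided output (red).

    2D fields are shown as images; 1D fields as activation profiles over
    feature space, mirroring the standard architecture-figure layout.
    """
    state = state or {n: f.u for n, f in model.fields.items()}
    names = list(model.fields)
    fig, axes = plt.subplots(len(names), 1, figsize=(6, 2.2 * len(names)))
    axes = np.atleast_1d(axes)
    for ax, name in zip(axes, names):
        f = model.fields[name]
        u = state[name]
        if u.ndim == 2:
            im = ax.imshow(u.T, origin="lower", aspect="auto",
                           extent=[0, 360, 0, 360], cmap="viridis")
            ax.set_ylabel(f"{name}\nhue (deg)")
            fig.colorbar(im, ax=ax, fraction=0.025)
        else:
            x = f.coords()
            ax.plot(x, u, color="tab:blue", lw=1.2, label="activation")
            out = 1.0 / (1.0 + np.exp(-f.sigmoid.beta * u))
            ax.plot(x, 10 * out - 5, color="tab:red", lw=0.9,
                    label="output (scaled)")
            ax.axhline(0.0, color="gray", lw=0.5, ls=":")
            ax.set_ylabel(name)
            ax.set_xlim(0, 360)
    axes[-1].set_xlabel("feature / space (deg)")
    title = f"{model.variant}" + (f" at t = {time:.0f} ms" if time is not None else "")
    fig.suptitle(title)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def error_histogram(errors, bins: int = 45, title: str = "", path=None):
    """Histogram of signed recall errors on (-180, 180]."""
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.hist(np.asarray(errors), bins=np.linspace(-180, 180, bins + 1),
            color="steelblue", edgecolor="white")
    ax.set_xlabel("signed error (deg)")
    ax.set_ylabel("trials")
    ax.set_title(title)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def fit_summary_bars(summary, reference=None, path=None):
    """Bar chart of mean mixture parameters per condition (with s.e.),
    optionally next to reference values."""
    params = ["mu", "sd", "p_m"]
    fig, axes = plt.subplots(1, 3, figsize=(11, 3))
    conds = list(summary.index)
    x = np.arange(len(conds))
    for ax, p in zip(axes, params):
        ax.bar(x - 0.2, summary[p], width=0.4, yerr=summary.get(f"{p}_se"),
               label="simulation", color="dimgray")
        if reference is not None:
            ref = reference.frame()
            vals = [ref.loc[c, p] if c in ref.index else np.nan for c in conds]
            ax.bar(x + 0.2, vals, width=0.4, label="reference",
                   color="lightgray", edgecolor="black")
        ax.set_xticks(x, conds, rotation=45)
        ax.set_title(p)
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
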