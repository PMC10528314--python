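"""Cosmetic plotting helpers (density panels, fitted-vs-empirical overlays).

Untested conveniences; matplotlib is imported lazily so headless library use
never touches a display backend.
"""

from __future__ import annotations

import numpy as np

from .regression import kaplan_meier
from .tlw import TLW

__all__ = ["plot_pdf_panel", "plot_fit", "plot_km_overlay"]


def _pyplot():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def plot_pdf_panel(param_list, out_path=None, n_grid=400):
    """Overlay TLW densities for a list of (theta, k, lam) triples."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(6, 4))
    for theta, k, lam in param_list:
        dist = TLW(theta, k, lam)
        hi = dist.ppf(0.995)
        xs = np.linspace(hi * 1e-3, hi, n_grid)
        ax.plot(xs, dist.pdf(xs),
                label=rf"$\theta$={theta:g}, k={k:g}, $\lambda$={lam:g}")
    ax.set_xlabel("x")
    ax.set_ylabel("density")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if out_path:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig


def plot_fit(x, fit_result, out_path=None, bins=20):
    """Histogram with the fitted TLW density and empirical vs fitted cdf."""
    plt = _pyplot()
    dist = TLW(*fit_result.params)
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    xs = np.linspace(min(x) * 0.9, max(x) * 1.05, 400)
    axes[0].hist(x, bins=bins, density=True, alpha=0.5)
    axes[0].plot(xs, dist.pdf(xs), "r-")
    axes[0].set_title("histogram and fitted density")
    xe = np.sort(np.asarray(x))
    axes[1].step(xe, np.arange(1, xe.size + 1) / xe.size, where="post",
                 label="empirical")
    axes[1].plot(xs, dist.cdf(xs), "r-", label="fitted")
    axes[1].legend()
    axes[1].set_title("cdf")
    fig.tight_layout()
    if out_path:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig


def plot_km_overlay(time, event, survival_curves, out_path=None):
    """Kaplan-Meier step function with model survival curves overlaid.

    ``survival_curves``: mapping label -> (xs, S(xs)).
    """
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(6, 4))
    km = kaplan_meier(time, event)[None]
    ax.step(km[0], km[1], where="post", label="Kaplan-Meier")
    for label, (xs, sf) in survival_curves.items():
        ax.plot(xs, sf, label=label)
    ax.set_xlabel("time")
    ax.set_ylabel("S(t)")
    ax.legend()
    fig.tight_layout()
    if out_path:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig
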