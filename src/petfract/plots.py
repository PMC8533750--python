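"""Figure writers: log-log box-count curves and D_q spectra."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .boxcount import BoxCountCurve, FractalFit
from .multifractal import MomentSpectrum

__all__ = ["plot_boxcount", "plot_spectrum"]


def plot_boxcount(
    curve: BoxCountCurve,
    fit: FractalFit | None,
    path: str | Path,
    normalized: bool = True,
    label: str | None = None,
) -> None:
    """Write the N(s) (or N(s)/N) vs s curve on double-logarithmic axes.

    Normalization by the per-scale total box count N only shifts the
    curve vertically scale-by-scale; the fitted exponent always comes
    from the unnormalized counts.
    """
    s = np.array(curve.sizes, dtype=float)
    y = np.array(curve.occupied, dtype=float)
    ylabel = "N(s)"
    if normalized:
        y = y / np.array(curve.total, dtype=float)
        ylabel = "N(s)/N"
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.loglog(s, y, "o-", label=label or "occupied boxes")
    if fit is not None:
        totals = dict(zip(curve.sizes, curve.total))
        xs = np.array(fit.fit_sizes, dtype=float)
        yfit = np.exp(fit.intercept) * xs ** (-fit.df)
        if normalized:
            yfit = yfit / np.array([totals[int(x)] for x in xs], dtype=float)
        ax.loglog(xs, yfit, "--", label=f"fit: Df = {fit.df:.4f}")
    ax.set_xlabel("box size s (voxels)")
    ax.set_ylabel(ylabel)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_spectrum(
    spectra: Mapping[str, MomentSpectrum], path: str | Path
) -> None:
    """Overlay D_q vs q curves (e.g. the three stages of one patient plus
    a healthy control)."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, spec in spectra.items():
        ax.plot(spec.q, spec.dq, "o-", markersize=3, label=label)
    ax.set_xlabel("moment order q")
    ax.set_ylabel(r"$D_q$")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
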