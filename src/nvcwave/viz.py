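"""Plots: aEEG panels (semi-log display), CWT spectrograms, coherence maps,
Bland-Altman and identity-scatter figures."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .aeeg import AEEGTrace, semilog_display
from .agreement import BlandAltmanResult, RegressionResult
from .coherence import CoherenceMap

__all__ = ["plot_aeeg", "plot_coherence", "plot_cwt_power", "plot_bland_altman", "plot_identity"]

_DISPLAY_TICKS = (0, 5, 10, 25, 50, 100)


def plot_aeeg(trace: AEEGTrace, path: str | Path | None = None):
    """Conventional aEEG panel: linear 0-10 µV, log 10-100 µV vertical axis."""
    fig, ax = plt.subplots(figsize=(10, 3))
    t_h = trace.uma.times / 3600.0
    ax.fill_between(
        t_h,
        semilog_display(trace.lma.values),
        semilog_display(trace.uma.values),
        color="tab:blue",
        alpha=0.6,
        lw=0,
    )
    ax.set_yticks([semilog_display(v) for v in _DISPLAY_TICKS], [str(v) for v in _DISPLAY_TICKS])
    ax.axhline(10.0, color="0.6", lw=0.5)
    ax.set_ylim(0, semilog_display(100.0))
    ax.set_xlabel("time (h)")
    ax.set_ylabel("amplitude (µV)")
    ax.set_title(f"aEEG margins — {trace.method}")
    return _finish(fig, path)


def plot_cwt_power(W: np.ndarray, scales_s: np.ndarray, times_s: np.ndarray, path=None):
    """Wavelet power spectrogram with a reciprocal mHz frequency axis."""
    fig, ax = plt.subplots(figsize=(10, 3.5))
    power = np.abs(W) ** 2
    mesh = ax.pcolormesh(times_s / 3600.0, 1000.0 / scales_s, power, shading="auto", cmap="viridis")
    ax.set_yscale("log")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("frequency (mHz)")
    fig.colorbar(mesh, ax=ax, label="wavelet power")
    return _finish(fig, path)


def plot_coherence(cmap: CoherenceMap, path: str | Path | None = None):
    """Time-scale R² map with significance contours and shaded COI."""
    fig, ax = plt.subplots(figsize=(10, 3.5))
    t_h = cmap.times_s / 3600.0
    mesh = ax.pcolormesh(t_h, cmap.scales_s, cmap.r2, vmin=0, vmax=1, shading="auto", cmap="jet")
    if cmap.sig_mask is not None:
        ax.contour(t_h, cmap.scales_s, cmap.sig_mask.astype(float), levels=[0.5], colors="k", linewidths=0.8)
    ax.contourf(t_h, cmap.scales_s, cmap.coi_mask.astype(float), levels=[0.5, 1.5], colors="none", hatches=["//"])
    ax.set_yscale("log")
    ax.invert_yaxis()
    ax.set_xlabel("time (h)")
    ax.set_ylabel("scale (s)")
    fig.colorbar(mesh, ax=ax, label="R²")
    return _finish(fig, path)


def plot_bland_altman(res: BlandAltmanResult, label: str = "", path=None):
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(res.means, res.diffs, s=25, color="k")
    for y, style in ((res.mean_diff, "-"), (res.upper_limit, "--"), (res.lower_limit, "--")):
        ax.axhline(y, color="tab:blue", ls=style, lw=1)
    ax.set_xlabel("mean of pair")
    ax.set_ylabel("difference")
    ax.set_title(label)
    return _finish(fig, path)


def plot_identity(a, b, fit: RegressionResult | None = None, label: str = "", path=None):
    fig, ax = plt.subplots(figsize=(5, 4))
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ax.scatter(a, b, s=25, color="k")
    lim = [min(a.min(), b.min()), max(a.max(), b.max())]
    ax.plot(lim, lim, color="tab:blue", lw=1, label="identity")
    if fit is not None:
        xs = np.linspace(*lim, 50)
        ax.plot(xs, fit.slope * xs + fit.intercept, color="tab:red", lw=1, label="regression")
    ax.legend(frameon=False)
    ax.set_title(label)
    return _finish(fig, path)


def _finish(fig, path):
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig
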