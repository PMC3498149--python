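"""Contour plots of wavelet power and coherence spectra.

Presentation mirrors the conventional layout: log-period y-axis, shaded
cone of influence, black contours around significant regions, and (for
coherence) phase arrows pointing right for in-phase fluctuation.
"""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .coherence import CoherenceSpectrum
from .wavelet import WaveletSpectrum

__all__ = ["plot_power", "plot_coherence"]


def _period_axis(ax, periods):
    ax.set_yscale("log", base=2)
    ax.set_ylim(periods[-1], periods[0])
    ax.set_ylabel("period (min)")


def _shade_coi(ax, times, coi, periods):
    ax.fill_between(times, coi, periods[-1], color="white", alpha=0.55, zorder=3)
    ax.plot(times, coi, "k", lw=1.5, zorder=4)


def plot_power(spec: WaveletSpectrum, path, title: str = "") -> None:
    """Scale-normalised local wavelet power with COI and significance contours."""
    fig, ax = plt.subplots(figsize=(9, 4))
    z = np.log2(np.maximum(spec.scale_normalised_power(), 1e-300))
    ax.contourf(spec.times, spec.fourier_periods, z, levels=32, cmap="jet")
    if spec.signif_mask is not None and spec.signif_mask.any():
        ax.contour(
            spec.times, spec.fourier_periods, spec.signif_mask.astype(float),
            levels=[0.5], colors="k", linewidths=1.2,
        )
    _shade_coi(ax, spec.times, spec.coi, spec.fourier_periods)
    _period_axis(ax, spec.fourier_periods)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_coherence(spec: CoherenceSpectrum, path, title: str = "", arrow_stride=(6, 24)) -> None:
    """Squared coherence with significance contours and phase arrows."""
    fig, ax = plt.subplots(figsize=(9, 4))
    ax.contourf(spec.times, spec.fourier_periods, spec.r2, levels=np.linspace(0, 1, 21), cmap="jet")
    if spec.signif_mask is not None and spec.signif_mask.any():
        ax.contour(
            spec.times, spec.fourier_periods, spec.signif_mask.astype(float),
            levels=[0.5], colors="k", linewidths=1.2,
        )
    js, ts = arrow_stride
    jj = np.arange(0, len(spec.fourier_periods), js)
    tt = np.arange(0, len(spec.times), ts)
    ph = np.radians(spec.phase[np.ix_(jj, tt)])
    ax.quiver(
        spec.times[tt], spec.fourier_periods[jj], np.cos(ph), np.sin(ph),
        scale=40, width=0.002, zorder=5,
    )
    _shade_coi(ax, spec.times, spec.coi, spec.fourier_periods)
    _period_axis(ax, spec.fourier_periods)
    ax.set_title(title or " vs ".join(spec.source))
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
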