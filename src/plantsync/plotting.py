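"""Rendering of wavelet-coherence maps.

Conventions: coherence from blue (none) to warm colours (perfect), period
increasing downward on a log2 axis, the cone of influence as a white dotted
line, phase arrows only where squared coherence exceeds a display threshold,
and optional red contours around significant regions.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .wavelet import WTCResult, phase_arrow_mask

__all__ = ["render_wtc_map", "render_average_map"]


def _period_axis(ax, periods: np.ndarray) -> None:
    ax.set_yscale("log", base=2)
    ax.set_ylim(periods[-1], periods[0])  # period increasing downward
    ax.set_ylabel("period (s)")


def render_wtc_map(
    result: WTCResult,
    path: str | Path,
    *,
    arrows: bool = True,
    coi: bool = True,
    sig_contours: np.ndarray | None = None,
    arrow_threshold: float = 0.5,
    arrow_step: int = 8,
    title: str | None = None,
) -> Path:
    """Render one dyad's coherence matrix to an image file.

    ``arrow_step`` decimates the phase-arrow field (every k-th cell in both
    directions) so dense maps stay legible.
    """
    if result.r2.size == 0:
        raise ValueError("empty coherence map")
    periods = 1.0 / result.freqs
    t = np.arange(result.r2.shape[1]) * result.dt

    fig, ax = plt.subplots(figsize=(8, 4.5))
    mesh = ax.pcolormesh(t, periods, result.r2, cmap="jet", vmin=0, vmax=1, shading="auto")
    _period_axis(ax, periods)
    ax.set_xlabel("time (s)")
    fig.colorbar(mesh, ax=ax, label="squared wavelet coherence")

    if arrows:
        mask = phase_arrow_mask(result, arrow_threshold)
        rows = np.arange(0, result.r2.shape[0], max(1, arrow_step // 2))
        cols = np.arange(0, result.r2.shape[1], max(1, arrow_step))
        sub = np.ix_(rows, cols)
        keep = mask[sub]
        if keep.any():
            tt, pp = np.meshgrid(t[cols], periods[rows])
            ax.quiver(
                tt[keep],
                pp[keep],
                np.cos(result.phase[sub])[keep],
                np.sin(result.phase[sub])[keep],
                pivot="mid",
                scale=40,
                width=0.002,
                color="black",
            )
    if coi:
        ax.plot(t, result.coi_period, "w:", linewidth=1.5)
    if sig_contours is not None and np.any(sig_contours):
        ax.contour(t, periods, sig_contours.astype(float), levels=[0.5], colors="red")
    if title:
        ax.set_title(title)
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def render_average_map(
    avg_map: np.ndarray,
    freqs: np.ndarray,
    path: str | Path,
    *,
    sig_contours: np.ndarray | None = None,
    coi_period: np.ndarray | None = None,
    title: str | None = None,
) -> Path:
    """Render a time-normalized average coherence map (x axis = % movement)."""
    if avg_map.size == 0:
        raise ValueError("empty coherence map")
    periods = 1.0 / np.asarray(freqs)
    pct = np.linspace(0.0, 100.0, avg_map.shape[1])

    fig, ax = plt.subplots(figsize=(8, 4.5))
    mesh = ax.pcolormesh(pct, periods, avg_map, cmap="jet", vmin=0, vmax=1, shading="auto")
    _period_axis(ax, periods)
    ax.set_xlabel("normalized movement time (%)")
    fig.colorbar(mesh, ax=ax, label="mean squared wavelet coherence")
    if sig_contours is not None and np.any(sig_contours):
        ax.contour(pct, periods, sig_contours.astype(float), levels=[0.5], colors="red")
    if coi_period is not None:
        ax.plot(np.linspace(0, 100, len(coi_period)), coi_period, "w:", linewidth=1.5)
    if title:
        ax.set_title(title)
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
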