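"""Diagnostic and result figures (PNG, headless backend).

Layout conventions follow the field's standard presentation: area-motion
plots with normalized cycle time horizontal and normalized tube length
vertical (inlet at the bottom); unrolled endocardial maps with the
circumferential angle horizontal (cut at the top of the tube) and the
inlet at the bottom.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .geometry import AreaMotionMatrix
from .hemo import UnrolledMap
from .sync import MMode, PhaseSchedule


def plot_mmode_pair(a: MMode, b: MMode, path: str,
                    titles=("longitudinal", "cross-sectional")) -> None:
    """Side-by-side pooled m-modes used for a phase alignment."""
    fig, axes = plt.subplots(1, 2, figsize=(8, 3), sharey=True)
    for ax, mm, title in zip(axes, (a, b), titles):
        ax.imshow(mm.matrix, aspect="auto", cmap="gray",
                  interpolation="nearest")
        ax.set_title(title)
        ax.set_xlabel("phase bin")
    axes[0].set_ylabel("pixel along line")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_cumulative_phase(schedule: PhaseSchedule, path: str) -> None:
    """Raw vs smoothed cumulative phase difference along the tube."""
    d = schedule.diagnostics
    fig, ax = plt.subplots(figsize=(5, 3.2))
    if "raw_cumulative" in d:
        ax.plot(d["raw_cumulative"], "o-", ms=3, label="measured")
    ax.plot(schedule.cumulative_curve, "-", label="smoothed")
    if "outlier_slices" in d and len(d["outlier_slices"]):
        out = np.asarray(d["outlier_slices"], dtype=int)
        ax.plot(out, np.asarray(d["raw_cumulative"])[out], "rx", ms=8,
                label="corrected")
    ax.set_xlabel("slice index (inlet to outlet)")
    ax.set_ylabel("cumulative phase (pooled frames)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_area_motion(matrix: AreaMotionMatrix, path: str,
                     period_s: float | None = None) -> None:
    """Color-coded cross-section areas: time horizontal, inlet at bottom."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    im = ax.imshow(matrix.values, aspect="auto", origin="lower",
                   cmap="viridis",
                   extent=(0.0, 1.0, 0.0, 1.0))
    ax.set_xlabel("normalized cardiac cycle")
    ax.set_ylabel("normalized tube length (inlet at bottom)")
    label = f"{matrix.layer} cross-sectional area (mm$^2$)"
    fig.colorbar(im, ax=ax, label=label)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_unrolled(m: UnrolledMap, path: str, label: str = "|WSS| (Pa)") -> None:
    """Unrolled endocardial surface: angle horizontal, inlet at bottom."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    im = ax.imshow(m.values, aspect="auto", origin="lower", cmap="inferno",
                   extent=(-180.0, 180.0, float(m.s_grid[0]),
                           float(m.s_grid[-1])))
    ax.set_xlabel("circumferential angle (deg, cut at the top)")
    ax.set_ylabel("normalized tube length (inlet at bottom)")
    fig.colorbar(im, ax=ax, label=label)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
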