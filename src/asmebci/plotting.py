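"""Figure export: grand-average ERP traces and signed-r² rasters."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .erp import EpochSet, SignedR2Map, grand_average, signed_r2_map

__all__ = ["plot_erp", "plot_signed_r2"]


def plot_erp(
    eps: EpochSet,
    channels: Sequence[str] = ("Cz", "Fz"),
    out: str | Path | None = None,
):
    """Grand-average target vs nontarget traces for selected channels."""
    picked = eps.pick_channels(channels)
    tgt = grand_average(picked, "label == 'target'")
    non = grand_average(picked, "label == 'nontarget'")
    fig, axes = plt.subplots(
        len(channels), 1, figsize=(7, 2.2 * len(channels)), sharex=True,
        squeeze=False,
    )
    for i, ch in enumerate(channels):
        ax = axes[i, 0]
        ax.plot(picked.times, tgt[i], label="target", color="crimson")
        ax.plot(picked.times, non[i], label="nontarget", color="steelblue")
        ax.axvline(0.0, color="k", lw=0.5)
        ax.set_ylabel(f"{ch} (µV)")
    axes[0, 0].legend(loc="upper right", frameon=False)
    axes[-1, 0].set_xlabel("time (s)")
    fig.tight_layout()
    if out is not None:
        fig.savefig(out)
        plt.close(fig)
    return fig


def plot_signed_r2(
    eps_or_map: EpochSet | SignedR2Map, out: str | Path | None = None
):
    """Channels x time raster of signed-r² discriminability."""
    r2 = eps_or_map if isinstance(eps_or_map, SignedR2Map) else signed_r2_map(eps_or_map)
    vmax = max(np.abs(r2.values).max(), 1e-12)
    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(
        r2.values,
        aspect="auto",
        origin="lower",
        extent=[r2.times[0], r2.times[-1], 0, len(r2.channels)],
        cmap="RdBu_r",
        vmin=-vmax,
        vmax=vmax,
    )
    step = max(1, len(r2.channels) // 16)
    ax.set_yticks(np.arange(0, len(r2.channels), step) + 0.5)
    ax.set_yticklabels(r2.channels[::step])
    ax.set_xlabel("time (s)")
    fig.colorbar(im, ax=ax, label="signed r²")
    fig.tight_layout()
    if out is not None:
        fig.savefig(out)
        plt.close(fig)
    return fig
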