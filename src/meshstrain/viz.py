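"""Overlay rendering: strain-coloured mesh segments and frequency maps."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.collections import LineCollection

__all__ = ["save_strain_overlay", "save_frequency_overlay"]


def save_strain_overlay(frame, tracks, graph, strain_table, t, path, *,
                        pixel_size=1.0, vmax=None, dpi=150):
    """Mesh segments over the frame, coloured red = tension, blue =
    compression on a diverging map centred at zero strain."""
    sub = strain_table[strain_table["frame"] == t]
    segs, vals = [], []
    for _, row in sub.iterrows():
        a, b = int(row["node_a"]), int(row["node_b"])
        pa = tracks.positions[t, a, :2] / pixel_size
        pb = tracks.positions[t, b, :2] / pixel_size
        segs.append([pa, pb])
        vals.append(row["epsilon"])
    vals = np.asarray(vals)
    if vmax is None:
        vmax = float(np.abs(vals).max()) if len(vals) else 1.0
        vmax = vmax or 1.0
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(frame, cmap="gray", origin="upper")
    lc = LineCollection(segs, cmap="bwr", linewidths=2)
    lc.set_array(vals)
    lc.set_clim(-vmax, vmax)
    ax.add_collection(lc)
    fig.colorbar(lc, ax=ax, label="engineering strain")
    ax.set_axis_off()
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)


def save_frequency_overlay(fmap, path, *, dpi=150):
    fig, ax = plt.subplots(figsize=(6, 6))
    im = ax.imshow(fmap.frequencies, cmap="viridis", origin="upper")
    fig.colorbar(im, ax=ax, label="dominant frequency (Hz)")
    ax.set_axis_off()
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
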