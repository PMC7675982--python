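"""Reading and writing image series and tabular outputs.

Image series travel as multi-page TIFF with ImageJ-style metadata (axes,
frame interval, z spacing) and the XY pixel size in the resolution tags;
tables are plain CSV with stable, documented headers.
"""

from __future__ import annotations

from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .simulate import ImageSeries

__all__ = ["read_series", "write_series", "nodes_to_csv", "nodesets_from_csv",
           "write_masks", "apply_edits_csv"]


def write_masks(masks: list, path) -> None:
    """Write per-frame binary mesh masks as an 8-bit multi-page TIFF."""
    stack = np.stack([np.asarray(m.mask, np.uint8) * 255 for m in masks])
    tifffile.imwrite(Path(path), stack, photometric="minisblack")


def apply_edits_csv(graph, path):
    """Apply manual node-pair corrections from a CSV with columns
    ``op`` (add | remove), ``node_a``, ``node_b``; returns the edited graph."""
    from .lattice import edit_pairs
    df = pd.read_csv(path)
    add = [(int(r.node_a), int(r.node_b)) for r in df.itertuples()
           if r.op == "add"]
    remove = [(int(r.node_a), int(r.node_b)) for r in df.itertuples()
              if r.op == "remove"]
    bad = set(df["op"]) - {"add", "remove"}
    if bad:
        raise ValueError(f"unknown edit op(s): {sorted(bad)}")
    return edit_pairs(graph, add=add, remove=remove)


def write_series(series: ImageSeries, path) -> None:
    """Write an ImageSeries as ImageJ-flavoured multi-page TIFF.

    Pixel size goes into the resolution tags (pixels per micrometre), the
    frame interval into ``finterval`` and the z step into ``spacing``.
    """
    path = Path(path)
    frames = np.asarray(series.frames, np.float32)
    axes = "TZYX" if frames.ndim == 4 else "TYX"
    meta = {"axes": axes, "unit": "um"}
    if series.dt > 0:
        meta["finterval"] = float(series.dt)
    if series.z_step:
        meta["spacing"] = float(series.z_step)
    res = 1.0 / series.pixel_size
    tifffile.imwrite(path, frames, imagej=True, resolution=(res, res),
                     metadata=meta)


def _pixel_size_from_tags(page, ij: dict) -> float | None:
    tag = page.tags.get("XResolution")
    if tag is None:
        return None
    unit_tag = page.tags.get("ResolutionUnit")
    calibrated = bool(ij.get("unit")) or (
        unit_tag is not None and getattr(unit_tag.value, "value",
                                         unit_tag.value) not in (1, "NONE"))
    if not calibrated:
        return None          # tifffile's (1, 1) placeholder, not physical
    num, den = tag.value
    if num == 0:
        return None
    return float(Fraction(den, num)) if den else None


def read_series(path, *, pixel_size: float | None = None,
                dt: float | None = None, axes: str | None = None) -> ImageSeries:
    """Read a TIFF/OME-TIFF stack as an ImageSeries, axes normalised to
    T(xZ)xYxX.

    Physical metadata are taken from the file when present; the
    ``pixel_size`` / ``dt`` overrides win when given.  Missing both for a
    required quantity is an error, as is an axis order that cannot be
    resolved (pass ``axes`` to disambiguate).
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        ser = tf.series[0]
        arr = ser.asarray()
        file_axes = ser.axes
        ij = tf.imagej_metadata or {}
        px_file = _pixel_size_from_tags(tf.pages[0], ij)
    ax = (axes or file_axes or "").upper().replace("S", "").replace("C", "")
    if "Q" in ax:      # tifffile's marker for an unidentified axis
        ax = ""
    arr = np.squeeze(arr)
    if arr.ndim == 2:
        ax = "YX"
    if not ax or len(ax) != arr.ndim:
        if arr.ndim == 3:
            raise ValueError(
                "ambiguous axis order for a 3D array without metadata; "
                "candidates: TYX (movie), ZYX (z-stack) — pass axes=...")
        raise ValueError(f"cannot interpret axes {file_axes!r} for shape {arr.shape}")

    z_step = None
    if ax == "YX":
        frames = arr[None]
    elif ax == "TYX":
        frames = arr
    elif ax == "ZYX":
        frames = arr[None]
        z_step = ij.get("spacing")
    elif ax == "TZYX":
        frames = arr
        z_step = ij.get("spacing")
    else:
        raise ValueError(f"unsupported axis order {ax!r}")

    px = pixel_size if pixel_size is not None else px_file
    if px is None:
        raise ValueError("pixel size missing from metadata and no override given")
    interval = dt if dt is not None else ij.get("finterval")
    if frames.shape[0] > 1 and (interval is None or interval <= 0):
        raise ValueError("frame interval missing from metadata and no override given")
    return ImageSeries(frames.astype(np.float32), float(px),
                       dt=float(interval) if interval else 0.0,
                       z_step=float(z_step) if z_step else None)


def nodes_to_csv(nodesets: list, path) -> None:
    """Write per-frame node detections (frame, node_id provisional, x_um,
    y_um[, z_um], score)."""
    rows = []
    for ns in nodesets:
        n = len(ns)
        rec = {"frame": np.full(n, ns.frame_index),
               "node_id": np.arange(n),
               "x_um": ns.positions[:, 0], "y_um": ns.positions[:, 1]}
        if ns.positions.shape[1] > 2:
            rec["z_um"] = ns.positions[:, 2]
        rec["score"] = ns.scores
        rows.append(pd.DataFrame(rec))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def nodesets_from_csv(path) -> list:
    """Inverse of :func:`nodes_to_csv` (node ids remain provisional)."""
    from .segment import NodeSet
    df = pd.read_csv(path)
    cols = ["x_um", "y_um"] + (["z_um"] if "z_um" in df else [])
    out = []
    for f, sub in df.groupby("frame"):
        out.append(NodeSet(int(f), sub[cols].to_numpy(),
                           sub["score"].to_numpy(),
                           np.ones(len(sub), int)))
    return out
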