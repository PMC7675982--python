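"""Strain, dilation, stress and stretch-ratio summaries from tracked meshes.

Two complementary strain descriptions are computed and reported side by
side, never conflated:

* **Per-segment engineering strain.**  Each node-to-node mesh segment is a
  one-dimensional strain gauge: with reference length ``l0`` and current
  length ``l`` (Euclidean, 2D or 3D), the engineering strain is
  ``eps = l/l0 - 1`` and the stretch ratio ``lam = l/l0``.  Positive strain
  is tension, negative compression.

* **Per-element finite strain.**  For every 4-node mesh cell a planar
  deformation gradient ``F`` is estimated by least squares over the four
  edge vectors (robust to a single mislocalised node, exact for affine
  deformation), from which the Green-Lagrange tensor
  ``E = (F^T F - I)/2``, the principal strains ``P1 >= P2`` with direction,
  and the dilation ``D = |det F|`` follow.  Green-Lagrange is rotation
  invariant: a rigid motion gives E = 0 exactly.

Stress is the linear estimate ``sigma = E_mod * eps`` for a supplied
elastic modulus; no constitutive fitting is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy import stats

from .lattice import LatticeGraph, NodeTracks, MISSING

__all__ = [
    "MacroscopicSeries", "segment_strain", "element_strain", "dilation",
    "fractional_shortening", "displacement_vectors", "stress_estimate",
    "stress_summary", "stretch_summary",
]


def shoelace_area(points: np.ndarray) -> float:
    """Signed polygon area; positive for counter-clockwise vertices."""
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class MacroscopicSeries:
    """Per-step macroscopic stretches from rig-level measurements.

    ``lambda1`` comes from fiducial-mark spacing along the pull axis,
    ``lambda2`` from the specimen width, ``lambda3`` from thickness
    (e.g. DIC); strains are ``eps_i = lambda_i - 1``.
    """

    frame: np.ndarray
    lambda3: np.ndarray
    lambda1: np.ndarray | None = None
    lambda2: np.ndarray | None = None

    def __post_init__(self):
        self.frame = np.asarray(self.frame, int)
        self.lambda3 = np.asarray(self.lambda3, float)
        for name in ("lambda1", "lambda2", "lambda3"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, float)
                setattr(self, name, v)
                if (v <= 0).any():
                    raise ValueError(f"{name} must be positive")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MacroscopicSeries":
        return cls(frame=df["frame"].to_numpy(),
                   lambda3=df["lambda3"].to_numpy(),
                   lambda1=df["lambda1"].to_numpy() if "lambda1" in df else None,
                   lambda2=df["lambda2"].to_numpy() if "lambda2" in df else None)

    def to_frame(self) -> pd.DataFrame:
        out = {"frame": self.frame}
        for name in ("lambda1", "lambda2", "lambda3"):
            v = getattr(self, name)
            if v is not None:
                out[name] = v
                out[name.replace("lambda", "epsilon")] = v - 1.0
        return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Segment (1D) strain
# ---------------------------------------------------------------------------

def segment_strain(tracks: NodeTracks, graph: LatticeGraph, *,
                   reference: int | None = None,
                   min_ref_length: float = 0.0) -> pd.DataFrame:
    """Per-segment, per-frame length, engineering strain and stretch ratio.

    One row per segment per frame where both endpoints have a position;
    segments whose reference length falls below ``min_ref_length``
    micrometres (localisation error would dominate) are excluded.
    """
    if reference is None:
        reference = tracks.reference
    ok = tracks.ok()
    rows = []
    for s in graph.segments:
        if not (ok[reference, s.a] and ok[reference, s.b]):
            continue
        pa = tracks.positions[:, s.a]
        pb = tracks.positions[:, s.b]
        l = np.linalg.norm(pb - pa, axis=1)
        l0 = float(l[reference])
        if l0 <= 0 or l0 < min_ref_length:
            continue
        both = ok[:, s.a] & ok[:, s.b]
        frames = np.flatnonzero(both)
        rows.append(pd.DataFrame({
            "frame": frames, "segment_id": s.id, "node_a": s.a, "node_b": s.b,
            "l_um": l[frames], "l0_um": l0, "epsilon": l[frames] / l0 - 1.0,
            "lambda": l[frames] / l0, "orientation": s.orientation,
        }))
    if not rows:
        return pd.DataFrame(columns=["frame", "segment_id", "node_a", "node_b",
                                     "l_um", "l0_um", "epsilon", "lambda",
                                     "orientation"])
    return pd.concat(rows, ignore_index=True).sort_values(
        ["frame", "segment_id"], ignore_index=True)


# ---------------------------------------------------------------------------
# Element (2D tensor) strain
# ---------------------------------------------------------------------------

def _cell_F(ref_pts: np.ndarray, cur_pts: np.ndarray) -> np.ndarray:
    """Planar deformation gradient mapping the 4 reference edge vectors to
    the 4 deformed edge vectors, least squares."""
    idx = [1, 2, 3, 0]
    R = ref_pts[idx] - ref_pts
    D = cur_pts[idx] - cur_pts
    sol, *_ = np.linalg.lstsq(R, D, rcond=None)
    return sol.T


def element_strain(tracks: NodeTracks, cells: list, *,
                   reference: int | None = None,
                   min_area: float = 1e-9) -> pd.DataFrame:
    """Per-cell deformation gradient, Green-Lagrange strain, principal
    strains/direction and dilation, relative to the reference frame.

    Planar (XY) coordinates are used.  The principal direction is the angle
    of the P1 eigenvector in degrees within [-90, 90).  Cells with a
    degenerate reference polygon are excluded.
    """
    if reference is None:
        reference = tracks.reference
    ok = tracks.ok()
    xy = tracks.positions[:, :, :2]
    rows = []
    for cid, quad in enumerate(cells):
        quad = list(quad)
        if not ok[reference, quad].all():
            continue
        ref_pts = xy[reference, quad]
        if abs(shoelace_area(ref_pts)) < min_area:
            continue
        for t in range(tracks.n_frames):
            if not ok[t, quad].all():
                continue
            F = _cell_F(ref_pts, xy[t, quad])
            E = 0.5 * (F.T @ F - np.eye(2))
            w, v = np.linalg.eigh(E)            # ascending
            p1, p2 = float(w[1]), float(w[0])
            vec = v[:, 1]
            theta = np.degrees(np.arctan2(vec[1], vec[0]))
            theta = (theta + 90.0) % 180.0 - 90.0
            rows.append((t, cid, F[0, 0], F[0, 1], F[1, 0], F[1, 1],
                         E[0, 0], E[1, 1], E[0, 1], p1, p2, theta,
                         abs(float(np.linalg.det(F)))))
    return pd.DataFrame(rows, columns=["frame", "cell_id", "Fxx", "Fxy", "Fyx",
                                       "Fyy", "Exx", "Eyy", "Exy", "P1", "P2",
                                       "theta_deg", "dilation"])


# ---------------------------------------------------------------------------
# Dilation & fractional shortening
# ---------------------------------------------------------------------------

def _polygon_simple(points: np.ndarray) -> bool:
    from shapely.geometry import Polygon
    return Polygon(points).is_valid


def dilation(tracks: NodeTracks, cells: list, *, reference: int | None = None,
             mode: str = "node_polygon", masks: list | None = None,
             pixel_size: float = 1.0, report: str = "ratio") -> pd.DataFrame:
    """Per-cell area ratio (1 = no change) through time.

    ``mode="node_polygon"`` takes the shoelace area of the 4 tracked nodes;
    ``mode="mask_projection"`` measures the enclosed hole of each mesh cell
    in the supplied binary masks, which also captures bowing of the mesh
    lines between nodes.  ``report="centered"`` returns ratio - 1 (the
    0-centred convention).  Self-intersecting polygons are flagged and get
    no value.
    """
    if reference is None:
        reference = tracks.reference
    if report not in ("ratio", "centered"):
        raise ValueError("report must be 'ratio' or 'centered'")
    ok = tracks.ok()
    xy = tracks.positions[:, :, :2]
    rows = []
    if mode == "node_polygon":
        for cid, quad in enumerate(cells):
            quad = list(quad)
            if not ok[reference, quad].all():
                continue
            ref_area = abs(shoelace_area(xy[reference, quad]))
            if ref_area <= 0:
                continue
            for t in range(tracks.n_frames):
                if not ok[t, quad].all():
                    continue
                pts = xy[t, quad]
                if not _polygon_simple(pts):
                    rows.append((t, cid, np.nan, np.nan, True))
                    continue
                area = abs(shoelace_area(pts))
                rows.append((t, cid, area, area / ref_area, False))
    elif mode == "mask_projection":
        if masks is None:
            raise ValueError("mask_projection mode needs the per-frame masks")
        hole_area = {}
        for t, mm in enumerate(masks):
            inv, _ = ndi.label(~np.asarray(mm.mask, bool))
            sizes = np.bincount(inv.ravel())
            hole_area[t] = (inv, sizes)
        for cid, quad in enumerate(cells):
            quad = list(quad)
            areas = {}
            for t in range(min(tracks.n_frames, len(masks))):
                if not ok[t, quad].all():
                    continue
                centroid = xy[t, quad].mean(axis=0) / pixel_size
                inv, sizes = hole_area[t]
                r, c = int(round(centroid[1])), int(round(centroid[0]))
                if not (0 <= r < inv.shape[0] and 0 <= c < inv.shape[1]):
                    continue
                lab = inv[r, c]
                if lab == 0:
                    continue          # centroid fell on the mesh itself
                areas[t] = sizes[lab] * pixel_size ** 2
            ref_area = areas.get(reference)
            if not ref_area:
                continue
            for t, area in sorted(areas.items()):
                rows.append((t, cid, area, area / ref_area, False))
    else:
        raise ValueError(f"unknown dilation mode {mode!r}")
    df = pd.DataFrame(rows, columns=["frame", "cell_id", "area_um2", "dilation",
                                     "flagged"])
    if report == "centered":
        df["dilation"] = df["dilation"] - 1.0
    return df


def fractional_shortening(dilation_table: pd.DataFrame, cells, *,
                          t_range: tuple | None = None) -> float:
    """Percent change in combined cell area between maximal relaxation and
    peak contraction: 100 * (max - min) / max of the summed region area."""
    cells = list(cells)
    if not cells:
        raise ValueError("empty region")
    sub = dilation_table[dilation_table["cell_id"].isin(cells)
                         & ~dilation_table["flagged"]]
    if t_range is not None:
        t0, t1 = t_range
        sub = sub[(sub["frame"] >= t0) & (sub["frame"] <= t1)]
    if sub.empty:
        raise ValueError("empty region / frame range")
    counts = sub.groupby("frame")["cell_id"].count()
    full = counts[counts == len(cells)].index
    combined = sub[sub["frame"].isin(full)].groupby("frame")["area_um2"].sum()
    if combined.empty:
        raise ValueError("region cells do not share any frame in range")
    amax, amin = float(combined.max()), float(combined.min())
    return 100.0 * (amax - amin) / amax


def displacement_vectors(tracks: NodeTracks, *,
                         reference: int | None = None) -> pd.DataFrame:
    """Per-node displacement from the reference frame, micrometres."""
    if reference is None:
        reference = tracks.reference
    ok = tracks.ok()
    base = tracks.positions[reference]
    rows = []
    axes = ["dx_um", "dy_um", "dz_um"][: tracks.dim]
    for t in range(tracks.n_frames):
        good = ok[t] & ok[reference]
        ids = np.flatnonzero(good)
        d = tracks.positions[t, ids] - base[ids]
        rec = {"frame": t, "node_id": ids}
        for k, name in enumerate(axes):
            rec[name] = d[:, k]
        rec["magnitude_um"] = np.linalg.norm(d, axis=1)
        rows.append(pd.DataFrame(rec))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Stress & stretch-ratio summaries
# ---------------------------------------------------------------------------

def stress_estimate(strain, modulus_pa: float):
    """Linear stress estimate sigma = E_mod * eps (Pa).

    ``strain`` may be a scalar, an array of engineering strains, or a
    segment-strain table (a ``sigma_pa`` column is appended to a copy).
    """
    if modulus_pa <= 0:
        raise ValueError("elastic modulus must be positive")
    if isinstance(strain, pd.DataFrame):
        out = strain.copy()
        out["sigma_pa"] = out["epsilon"] * modulus_pa
        return out
    arr = np.asarray(strain, float) * modulus_pa
    return float(arr) if arr.ndim == 0 else arr


def stress_summary(strain_table: pd.DataFrame, modulus_pa: float,
                   segment_ids=None) -> dict:
    """Mean +/- SD stress over a named segment set (all segments when None)."""
    df = strain_table
    if segment_ids is not None:
        df = df[df["segment_id"].isin(list(segment_ids))]
    sigma = df["epsilon"].to_numpy() * modulus_pa
    return {"mean_pa": float(sigma.mean()), "sd_pa": float(sigma.std(ddof=1))
            if len(sigma) > 1 else 0.0, "n": int(len(sigma))}


def stretch_summary(segment_table: pd.DataFrame,
                    macro: "MacroscopicSeries | pd.DataFrame"):
    """Per-step microscopic stretch ratios against the macroscopic series.

    lambda1 is the mean stretch of x-oriented segments, lambda2 of
    y-oriented segments; lambda3 comes from the auxiliary (thickness)
    series.  Returns ``(table, stats)`` where the table has per-step
    lambda1, lambda2, lambda3 and their product, and stats holds the
    Pearson correlation and least-squares slope of lambda3 on lambda2 plus
    (when the macroscopic series carries them) the correlations of
    microscopic vs macroscopic strain along both in-plane axes.
    """
    if isinstance(macro, pd.DataFrame):
        macro = MacroscopicSeries.from_frame(macro)
    lam = (segment_table.groupby(["frame", "orientation"])["lambda"]
           .mean().unstack("orientation"))
    if "x" not in lam or "y" not in lam:
        raise ValueError("segment table must contain both x- and y-oriented segments")
    table = pd.DataFrame({"frame": lam.index.to_numpy(),
                          "lambda1": lam["x"].to_numpy(),
                          "lambda2": lam["y"].to_numpy()})
    mtab = pd.DataFrame({"frame": macro.frame, "lambda3": macro.lambda3})
    table = table.merge(mtab, on="frame", how="inner")
    if len(table) < 3:
        raise ValueError("need at least 3 steps for correlation statistics")
    table["product"] = table["lambda1"] * table["lambda2"] * table["lambda3"]

    r23 = stats.pearsonr(table["lambda2"], table["lambda3"])
    slope, intercept = np.polyfit(table["lambda2"], table["lambda3"], 1)
    out = {"pearson_lambda23": float(r23.statistic),
           "slope_lambda3_on_lambda2": float(slope),
           "intercept_lambda3_on_lambda2": float(intercept)}
    if macro.lambda1 is not None:
        m = pd.DataFrame({"frame": macro.frame, "ml1": macro.lambda1})
        j = table.merge(m, on="frame")
        out["pearson_eps1"] = float(stats.pearsonr(j["lambda1"] - 1,
                                                   j["ml1"] - 1).statistic)
    if macro.lambda2 is not None:
        m = pd.DataFrame({"frame": macro.frame, "ml2": macro.lambda2})
        j = table.merge(m, on="frame")
        out["pearson_eps2"] = float(stats.pearsonr(j["lambda2"] - 1,
                                                   j["ml2"] - 1).statistic)
    return table, out
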