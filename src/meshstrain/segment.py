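"""Mesh segmentation: binarisation, skeletonisation and node detection.

Converts raw fluorescence frames of the fiducial mesh into a binary mask, a
unit-width skeleton, and subpixel detections of the lattice intersections
(nodes).  Junction candidates come from two complementary cues — skeleton
branch points (>= 3 neighbours) for T and X intersections, and a local
straightness test for the degree-2 corner bends at the mesh boundary — and
every candidate cluster is refined to subpixel accuracy by fitting the
incident line centrelines and intersecting them.  For z-stacks the frame is
max-projected for XY detection and the z coordinate recovered per node from
the stack, matching the projection-roadmap design of the analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as _field

import numpy as np
import scipy.ndimage as ndi
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.morphology import disk, skeletonize as _skimage_skeletonize

__all__ = ["MeshMask", "NodeSet", "binarize", "skeletonize", "detect_nodes"]

_EIGHT = np.ones((3, 3), int)


@dataclass
class MeshMask:
    """Binary mesh foreground with the threshold that produced it.

    ``skeleton`` (unit-width, 8-connected, a subset of the mask) is filled
    in by :func:`skeletonize`.
    """

    mask: np.ndarray
    threshold: float
    skeleton: np.ndarray | None = None

    def __post_init__(self):
        self.mask = np.asarray(self.mask, bool)
        if self.skeleton is not None:
            self.skeleton = np.asarray(self.skeleton, bool)

    @property
    def fraction(self) -> float:
        return float(self.mask.mean())


@dataclass
class NodeSet:
    """Subpixel lattice-intersection detections for one frame.

    ``positions`` holds (x, y[, z]) in micrometres; ``scores`` the
    distance-transform value at each detection (larger = deeper inside the
    junction); ``support`` the candidate-pixel count behind each detection.
    """

    frame_index: int
    positions: np.ndarray
    scores: np.ndarray
    support: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        if self.positions.size == 0:
            self.positions = self.positions.reshape(0, self.positions.shape[-1] or 2)
        self.scores = np.asarray(self.scores, float)
        self.support = np.asarray(self.support, int)

    def __len__(self) -> int:
        return self.positions.shape[0]

    @property
    def positions_px(self) -> np.ndarray:
        return self.positions[:, :2] / self.pixel_size


def _empty_nodeset(frame_index: int, pixel_size: float, dim: int = 2) -> NodeSet:
    return NodeSet(frame_index, np.zeros((0, dim)), np.zeros(0), np.zeros(0, int),
                   pixel_size)


# ---------------------------------------------------------------------------
# Binarisation / skeletonisation
# ---------------------------------------------------------------------------

def binarize(frame: np.ndarray, method: str = "otsu", *,
             background_subtract: bool = False, threshold: float | None = None,
             background_size: int = 51) -> MeshMask:
    """Threshold a fluorescence frame into a mesh foreground mask.

    ``background_subtract`` removes a rolling-ball-style background
    estimated by grey opening with a ``background_size`` window (choose it
    larger than the mesh line width so the lines survive).  ``method`` is
    ``"otsu"`` or ``"fixed"`` (requires ``threshold``); the threshold
    actually used is recorded on the returned mask for provenance.
    """
    frame = np.asarray(frame, float)
    if frame.size == 0:
        raise ValueError("no foreground: empty frame")
    if float(frame.max() - frame.min()) == 0.0:
        raise ValueError("no foreground: constant frame")
    work = frame
    if background_subtract:
        work = frame - ndi.grey_opening(frame, size=background_size)
    if method == "otsu":
        thr = float(threshold_otsu(work))
    elif method == "fixed":
        if threshold is None:
            raise ValueError("fixed thresholding requires a threshold value")
        thr = float(threshold)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    mask = work > thr
    if not mask.any() or mask.all():
        raise ValueError("no foreground: threshold separates nothing")
    return MeshMask(mask, thr)


def skeletonize(mask: MeshMask) -> MeshMask:
    """Thin the mask to a unit-width, topology-preserving centreline."""
    if not mask.mask.any():
        raise ValueError("cannot skeletonize an empty mask")
    skel = _skimage_skeletonize(mask.mask)
    return MeshMask(mask.mask, mask.threshold, skeleton=skel)


# ---------------------------------------------------------------------------
# Node detection
# ---------------------------------------------------------------------------

def _neighbor_count(skel: np.ndarray) -> np.ndarray:
    return ndi.convolve(skel.astype(np.uint8), _EIGHT, mode="constant") - skel


def _skel_neighbors(skel: np.ndarray, p):
    r, c = p
    out = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            rr, cc = r + dr, c + dc
            if 0 <= rr < skel.shape[0] and 0 <= cc < skel.shape[1] \
                    and skel[rr, cc]:
                out.append((rr, cc))
    return out


def _walk(skel: np.ndarray, start, first, steps: int):
    """Follow the skeleton ``steps`` pixels from ``start`` through ``first``;
    returns the end pixel (stops early at junctions or line ends)."""
    prev, cur = start, first
    for _ in range(steps - 1):
        nxt = [q for q in _skel_neighbors(skel, cur)
               if q != prev and q != start]
        if not nxt:
            break
        if len(nxt) > 1:   # prefer the least-backtracking continuation
            nxt.sort(key=lambda q: (q[0] - prev[0]) ** 2 + (q[1] - prev[1]) ** 2,
                     reverse=True)
            if len(nxt) > 2:
                break      # reached a junction
        prev, cur = cur, nxt[0]
    return cur


def _corner_candidates(skel: np.ndarray, coords: np.ndarray, tree: cKDTree,
                       nb: np.ndarray, radius: float,
                       anisotropy: float = 0.15,
                       max_turn_deg: float = 135.0) -> np.ndarray:
    """Degree-2 skeleton pixels where the centreline turns sharply.

    A cheap local-PCA anisotropy test (a straight centreline has a rank-1
    point cloud) preselects pixels near any bend or junction; each is then
    verified by walking the skeleton a few pixels in both directions and
    measuring the turn angle, which isolates the true corner bend from the
    straight run-up along its arms.  Returns a bool index into ``coords``.
    """
    deg2 = nb[tuple(coords.T)] == 2
    out = np.zeros(len(coords), bool)
    idx = np.flatnonzero(deg2)
    if idx.size == 0:
        return out
    steps = max(3, int(np.ceil(radius / 2)))
    cos_max = np.cos(np.deg2rad(max_turn_deg))
    neighborhoods = tree.query_ball_point(coords[idx], r=radius)
    for k, nbrs in zip(idx, neighborhoods):
        if len(nbrs) < 5:
            continue
        pts = coords[nbrs] - coords[k]
        cov = pts.T.astype(float) @ pts / len(nbrs)
        ev = np.linalg.eigvalsh(cov)
        if ev[1] <= 1e-12 or ev[0] / ev[1] <= anisotropy:
            continue
        q = tuple(coords[k])
        first = _skel_neighbors(skel, q)
        if len(first) != 2:
            continue
        e1 = np.asarray(_walk(skel, q, first[0], steps), float) - coords[k]
        e2 = np.asarray(_walk(skel, q, first[1], steps), float) - coords[k]
        n1, n2 = np.linalg.norm(e1), np.linalg.norm(e2)
        if min(n1, n2) < steps / 2:
            continue
        if e1 @ e2 / (n1 * n2) > cos_max:
            out[k] = True
    return out


def _cluster_candidates(cand: np.ndarray, dt_map: np.ndarray, merge_radius: float):
    """Merge nearby candidate pixels; peak = max distance transform,
    ties broken by lower (row, col)."""
    dil = ndi.binary_dilation(cand, structure=disk(max(1, int(np.ceil(merge_radius / 2)))))
    lab, n = ndi.label(dil, structure=_EIGHT)
    coords = np.argwhere(cand)
    labels = lab[tuple(coords.T)]
    peaks, scores, support = [], [], []
    for l in range(1, n + 1):
        members = coords[labels == l]
        if members.size == 0:
            continue
        vals = dt_map[tuple(members.T)]
        order = np.lexsort((members[:, 1], members[:, 0], -vals))
        peaks.append(members[order[0]])
        scores.append(float(vals[order[0]]))
        support.append(len(members))
    return np.asarray(peaks, float), np.asarray(scores), np.asarray(support, int)


def _split_by_angle(angles: np.ndarray, gap: float = np.deg2rad(25)):
    """Group undirected angles (mod pi) separated by circular gaps > ``gap``."""
    order = np.argsort(angles)
    a = angles[order]
    n = len(a)
    diffs = np.diff(np.concatenate([a, [a[0] + np.pi]]))
    start = int(np.argmax(diffs)) + 1  # rotate so the largest gap is the seam
    rotated = np.concatenate([order[start:], order[:start]])
    a_rot = angles[rotated]
    a_rot = np.where(a_rot < angles[rotated[0]] - 1e-12, a_rot + np.pi, a_rot)
    groups, current = [], [rotated[0]]
    for i in range(1, n):
        if a_rot[i] - a_rot[i - 1] > gap:
            groups.append(current)
            current = []
        current.append(rotated[i])
    groups.append(current)
    return groups


def _refine_junction(frame: np.ndarray, coords: np.ndarray, tree: cKDTree,
                     peak_rc: np.ndarray, halfw: float, reach: float,
                     r0: float | None = None):
    """Subpixel junction position from the incident line centrelines.

    Skeleton pixels in an annulus around the junction are grouped by arm
    direction; each arm pixel is re-centred perpendicular to the arm by an
    intensity-weighted centroid, a total-least-squares line is fitted per
    arm, and the junction is the least-squares intersection of the arm
    lines.  Returns (row, col) floats, or None when the local geometry is
    too sparse (caller falls back to the candidate peak).
    """
    if r0 is None:
        r0 = 1.5 * halfw + 1.0
    nbrs = tree.query_ball_point(peak_rc, r=reach)
    pts = coords[nbrs].astype(float)
    d = np.linalg.norm(pts - peak_rc, axis=1)
    pts = pts[d > r0]
    if len(pts) < 6:
        return None
    rel = pts - peak_rc
    angles = np.mod(np.arctan2(rel[:, 0], rel[:, 1]), np.pi)
    groups = _split_by_angle(angles)
    m = min(2.0 * halfw + 2.0, max(3.0, 0.9 * reach - halfw))
    us = np.linspace(-m, m, int(4 * m) + 1)
    normals, offsets = [], []
    for g in groups:
        arm = pts[g]
        if len(arm) < 3:
            continue
        c = arm.mean(axis=0)
        u, s, vt = np.linalg.svd(arm - c, full_matrices=False)
        direction = vt[0]
        normal = np.array([-direction[1], direction[0]])
        refined = []
        for p in arm[:: max(1, len(arm) // 12)]:
            samples = p[None, :] + us[:, None] * normal
            vals = ndi.map_coordinates(frame, samples.T, order=1, mode="nearest")
            w = vals - vals.min()
            tot = w.sum()
            if tot <= 0:
                refined.append(p)
                continue
            refined.append(p + (w @ us / tot) * normal)
        refined = np.asarray(refined)
        c = refined.mean(axis=0)
        _, _, vt = np.linalg.svd(refined - c, full_matrices=False)
        n2 = np.array([-vt[0][1], vt[0][0]])
        normals.append(n2)
        offsets.append(float(n2 @ c))
    if len(normals) < 2:
        return None
    N = np.asarray(normals)
    A = N.T @ N
    if np.linalg.cond(A) > 1e6:
        return None
    b = N.T @ np.asarray(offsets)
    sol = np.linalg.solve(A, b)
    if np.linalg.norm(sol - peak_rc) > 2.0 * halfw + 2.0:
        return None
    return sol


def detect_nodes(mask: MeshMask, frame: np.ndarray, *, pixel_size: float = 1.0,
                 pitch_hint: float | None = None, line_width: float | None = None,
                 frame_index: int = 0, stack: np.ndarray | None = None,
                 z_step: float = 1.0) -> NodeSet:
    """Detect lattice intersections at subpixel precision.

    Parameters
    ----------
    mask : MeshMask
        Binarised frame with its skeleton (see :func:`skeletonize`).
    frame : ndarray
        The intensity frame the mask came from (used for refinement).
    pixel_size : float
        Micrometres per pixel; detections are reported in micrometres.
    pitch_hint : float, optional
        Approximate node spacing in micrometres; detections closer than
        half of it are merged (higher score wins).  Estimated from the
        detections themselves when omitted.
    line_width : float, optional
        Mesh line width in micrometres; estimated from the distance
        transform when omitted.
    stack : ndarray, optional
        (Z, Y, X) intensity stack; when given, a z coordinate is recovered
        per node by an intensity-weighted centroid across slices.
    """
    if mask.skeleton is None:
        raise ValueError("detect_nodes needs a skeletonized mask")
    skel = mask.skeleton
    if not skel.any():
        warnings.warn("empty skeleton: no nodes detected", stacklevel=2)
        return _empty_nodeset(frame_index, pixel_size, 2 if stack is None else 3)
    frame = np.asarray(frame, float)
    dt_map = ndi.distance_transform_edt(mask.mask)
    coords = np.argwhere(skel)                   # (M, 2) as (row, col)
    tree = cKDTree(coords)
    if line_width is not None:
        halfw = 0.5 * line_width / pixel_size
    else:
        halfw = max(0.6, float(np.median(dt_map[skel])))
    nb = _neighbor_count(skel)
    pitch_px = pitch_hint / pixel_size if pitch_hint is not None else None

    cand = skel & (nb >= 3)
    corner_radius = 3.0 * halfw + 2.0
    merge_radius = 2.0 * halfw
    if pitch_px is not None:
        corner_radius = min(corner_radius, 0.45 * pitch_px)
        merge_radius = min(merge_radius, 0.4 * pitch_px)
    corner_idx = _corner_candidates(skel, coords, tree, nb, radius=corner_radius)
    cand = cand.copy()
    cand[tuple(coords[corner_idx].T)] = True
    if not cand.any():
        warnings.warn("no junction candidates found", stacklevel=2)
        return _empty_nodeset(frame_index, pixel_size, 2 if stack is None else 3)

    peaks, scores, support = _cluster_candidates(cand, dt_map, merge_radius=merge_radius)

    # enforce the minimum node separation (half the lattice pitch)
    if pitch_hint is not None:
        min_sep = 0.5 * pitch_hint / pixel_size
    elif len(peaks) > 1:
        nn = cKDTree(peaks).query(peaks, k=2)[0][:, 1]
        min_sep = 0.5 * float(np.median(nn))
    else:
        min_sep = 0.0
    if min_sep > 0 and len(peaks) > 1:
        order = np.lexsort((peaks[:, 1], peaks[:, 0], -scores))
        kept: list[int] = []
        for i in order:
            if all(np.linalg.norm(peaks[i] - peaks[j]) >= min_sep for j in kept):
                kept.append(i)
        kept = sorted(kept, key=lambda i: (peaks[i][0], peaks[i][1]))
        peaks, scores, support = peaks[kept], scores[kept], support[kept]

    reach = max(8.0, 5.0 * halfw)
    if pitch_hint is not None:
        reach = min(reach, 0.45 * pitch_hint / pixel_size)
    refined = []
    for p in peaks:
        # the cluster peak can sit several pixels along an arm (skeletons cut
        # corners); seed with the intensity centroid, then iterate the
        # centreline-intersection refinement to convergence
        est = _centroid_refine(frame, p, halfw)
        for _ in range(2):
            sol = _refine_junction(frame, coords, tree, est, halfw, reach)
            if sol is None:
                # tight meshes: too few arm pixels outside the junction blob
                sol = _refine_junction(frame, coords, tree, est, halfw, reach,
                                       r0=halfw + 0.5)
            if sol is None:
                break
            est = sol
        refined.append(est)
    refined = np.asarray(refined, float)         # (K, 2) as (row, col)

    positions = refined[:, ::-1] * pixel_size    # -> (x, y) micrometres
    if stack is not None:
        stack = np.asarray(stack, float)
        zs = []
        wr = max(1, int(round(2 * halfw)))
        z_idx = np.arange(stack.shape[0])
        for r, c in refined:
            r0, r1 = max(0, int(r) - wr), min(stack.shape[1], int(r) + wr + 1)
            c0, c1 = max(0, int(c) - wr), min(stack.shape[2], int(c) + wr + 1)
            prof = stack[:, r0:r1, c0:c1].sum(axis=(1, 2))
            prof = prof - prof.min()
            zs.append(float(prof @ z_idx / prof.sum()) * z_step
                      if prof.sum() > 0 else 0.0)
        positions = np.column_stack([positions, zs])

    order = _row_major_order(positions, pitch_hint)
    return NodeSet(frame_index, positions[order], scores[order], support[order],
                   pixel_size)


def _row_major_order(positions: np.ndarray, pitch_hint: float | None):
    """Stable row-major ordering: lattice rows (clustered by y, gaps larger
    than a fraction of the pitch) then x within each row."""
    y = positions[:, 1]
    if pitch_hint is None or len(positions) < 2:
        return np.lexsort((positions[:, 0], y))
    gap = 0.3 * pitch_hint
    by_y = np.argsort(y, kind="stable")
    row_id = np.zeros(len(y), int)
    rid, prev = 0, y[by_y[0]]
    for i in by_y[1:]:
        if y[i] - prev > gap:
            rid += 1
        prev = y[i]
        row_id[i] = rid
    return np.lexsort((positions[:, 0], row_id))


def _centroid_refine(frame: np.ndarray, peak_rc: np.ndarray, halfw: float):
    """Fallback: intensity-weighted centroid in a window around the peak."""
    wr = max(2, int(round(2 * halfw)))
    r, c = int(round(peak_rc[0])), int(round(peak_rc[1]))
    r0, r1 = max(0, r - wr), min(frame.shape[0], r + wr + 1)
    c0, c1 = max(0, c - wr), min(frame.shape[1], c + wr + 1)
    patch = frame[r0:r1, c0:c1]
    w = patch - patch.min()
    tot = w.sum()
    if tot <= 0:
        return peak_rc.astype(float)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    return np.array([float((w * rr).sum() / tot), float((w * cc).sum() / tot)])
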