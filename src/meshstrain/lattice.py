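"""Lattice graph assembly and node tracking through time.

Node detections are assembled into a rectangular lattice graph by walking
the skeleton: two nodes are paired iff a skeleton path connects them
without passing through a third node.  The graph carries segments (with an
x-like / y-like orientation label from the reference frame), 4-node cells,
and an edit log for manual pair corrections.  Node identities are carried
through time by greedy mutual-nearest-neighbour assignment within a
distance gate.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field as _field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy.spatial import cKDTree

from .segment import MeshMask, NodeSet

__all__ = ["Segment", "LatticeGraph", "NodeTracks", "build_lattice",
           "edit_pairs", "track_nodes", "TRACKED", "MISSING", "INTERPOLATED"]

MISSING, TRACKED, INTERPOLATED = 0, 1, 2

_EIGHT = np.ones((3, 3), int)


@dataclass(frozen=True)
class Segment:
    id: int
    a: int
    b: int
    orientation: str        # "x" or "y" in the reference frame
    ref_length: float


@dataclass
class LatticeGraph:
    """Reconstructed mesh: nodes, node-pair segments, and 4-node cells.

    ``ref_positions`` are the subpixel node coordinates (micrometres) at the
    reference frame; cells are listed counter-clockwise.  ``edit_log``
    records manual pair additions/removals, ``skipped`` the skeleton paths
    that could not be paired automatically.
    """

    ref_positions: np.ndarray
    segments: list = _field(default_factory=list)
    cells: list = _field(default_factory=list)
    edit_log: list = _field(default_factory=list)
    skipped: list = _field(default_factory=list)

    def __post_init__(self):
        self.ref_positions = np.asarray(self.ref_positions, float)
        pairs = [self._norm(s.a, s.b) for s in self.segments]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate segments in lattice graph")

    @staticmethod
    def _norm(a: int, b: int) -> tuple:
        return (a, b) if a < b else (b, a)

    @property
    def n_nodes(self) -> int:
        return self.ref_positions.shape[0]

    @property
    def pair_set(self) -> set:
        return {self._norm(s.a, s.b) for s in self.segments}

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, int)
        for s in self.segments:
            deg[s.a] += 1
            deg[s.b] += 1
        return deg

    def to_networkx(self):
        import networkx as nx
        g = nx.Graph()
        for i, p in enumerate(self.ref_positions):
            g.add_node(i, pos=tuple(p))
        for s in self.segments:
            g.add_edge(s.a, s.b, segment_id=s.id, orientation=s.orientation,
                       ref_length=s.ref_length)
        return g

    def segments_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "segment_id": [s.id for s in self.segments],
            "node_a": [s.a for s in self.segments],
            "node_b": [s.b for s in self.segments],
            "orientation": [s.orientation for s in self.segments],
            "ref_length_um": [s.ref_length for s in self.segments],
        })

    def cells_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cell_id": np.arange(len(self.cells)),
            "node_a": [c[0] for c in self.cells],
            "node_b": [c[1] for c in self.cells],
            "node_c": [c[2] for c in self.cells],
            "node_d": [c[3] for c in self.cells],
        })


def _segment_orientation(pa: np.ndarray, pb: np.ndarray) -> str:
    d = np.abs(pb[:2] - pa[:2])
    return "x" if d[0] >= d[1] else "y"


def enumerate_cells(ref_positions: np.ndarray, segments: list) -> list:
    """Unit squares of the lattice, counter-clockwise node ids.

    Uses the orientation labels: from each node follow its x-like segment
    towards +x and its y-like segment towards +y; a cell closes when the
    two paths commute.  Exact for (deformed) square lattices, deterministic.
    """
    right: dict[int, int] = {}
    down: dict[int, int] = {}
    for s in segments:
        a, b = s.a, s.b
        pa, pb = ref_positions[a], ref_positions[b]
        if s.orientation == "x":
            lo, hi = (a, b) if pa[0] <= pb[0] else (b, a)
            store = right
        else:
            lo, hi = (a, b) if pa[1] <= pb[1] else (b, a)
            store = down
        if lo in store:   # keep the nearer partner if ambiguous
            old = store[lo]
            if (np.linalg.norm(ref_positions[hi] - ref_positions[lo])
                    < np.linalg.norm(ref_positions[old] - ref_positions[lo])):
                store[lo] = hi
        else:
            store[lo] = hi
    cells = []
    for a in sorted(right):
        if a not in down:
            continue
        b, d = right[a], down[a]
        c1 = down.get(b)
        c2 = right.get(d)
        if c1 is not None and c1 == c2:
            cells.append((a, b, c1, d))
    return cells


def build_lattice(mask: MeshMask, nodes: NodeSet, *,
                  line_width: float | None = None,
                  node_radius: float | None = None) -> LatticeGraph:
    """Pair nodes connected by a clean skeleton path into a lattice graph.

    The skeleton is partitioned into node neighbourhoods (disks around each
    detection) and residual arcs; an arc touching exactly two node
    neighbourhoods becomes a segment.  Arcs touching fewer or more nodes
    (broken lines, loops through no node) are skipped and logged for manual
    editing via :func:`edit_pairs`.
    """
    if mask.skeleton is None:
        raise ValueError("build_lattice needs a skeletonized mask")
    if len(nodes) < 2:
        raise ValueError("need at least 2 nodes to build a lattice")
    skel = mask.skeleton
    px = nodes.positions_px                       # (N, 2) as (x, y)
    node_rc = px[:, ::-1]                         # (row, col)
    if node_radius is None:
        if line_width is not None:
            halfw = 0.5 * line_width / nodes.pixel_size
        else:
            dt_map = ndi.distance_transform_edt(mask.mask)
            halfw = max(0.6, float(np.median(dt_map[skel])))
        node_radius = max(2.0, 1.5 * halfw + 1.0)
    if len(nodes) > 1:
        nn = cKDTree(node_rc).query(node_rc, k=2)[0][:, 1]
        node_radius = min(node_radius, 0.35 * float(nn.min()))
        node_radius = max(node_radius, 1.5)

    coords = np.argwhere(skel)
    dist, idx = cKDTree(node_rc).query(coords)
    grid_id = np.full(skel.shape, -1, int)
    near = dist <= node_radius
    grid_id[tuple(coords[near].T)] = idx[near]

    resid = skel & (grid_id < 0)
    lab, n_lab = ndi.label(resid, structure=_EIGHT)
    segments: list[Segment] = []
    skipped: list[dict] = []
    seen_pairs: set = set()
    sid = 0
    pad_id = np.pad(grid_id, 1, constant_values=-1)
    for l in range(1, n_lab + 1):
        pix = np.argwhere(lab == l)
        touched: set[int] = set()
        for r, c in pix:
            nb = pad_id[r:r + 3, c:c + 3]
            touched.update(int(v) for v in np.unique(nb) if v >= 0)
        touched = sorted(touched)
        if len(touched) == 2:
            a, b = touched
            pair = (a, b)
            if pair in seen_pairs:
                skipped.append({"reason": "duplicate path", "nodes": pair,
                                "pixels": len(pix)})
                continue
            seen_pairs.add(pair)
            pa, pb = nodes.positions[a], nodes.positions[b]
            segments.append(Segment(sid, a, b, _segment_orientation(pa, pb),
                                    float(np.linalg.norm(pb - pa))))
            sid += 1
        else:
            skipped.append({"reason": "ambiguous path" if len(touched) > 2
                            else "dangling path", "nodes": tuple(touched),
                            "pixels": len(pix)})
    segments.sort(key=lambda s: (s.a, s.b))
    segments = [Segment(i, s.a, s.b, s.orientation, s.ref_length)
                for i, s in enumerate(segments)]
    graph = LatticeGraph(nodes.positions.copy(), segments,
                         cells=[], skipped=skipped)
    graph.cells = enumerate_cells(graph.ref_positions, segments)
    deg = graph.degrees()
    if (deg > 4).any():
        warnings.warn(f"{int((deg > 4).sum())} node(s) exceed degree 4; the "
                      "reconstruction may not be a square lattice", stacklevel=2)
    return graph


def edit_pairs(graph: LatticeGraph, add=(), remove=()) -> LatticeGraph:
    """Apply manual pair corrections; returns a new graph with the edit log
    extended and the cell enumeration refreshed."""
    g = LatticeGraph(graph.ref_positions.copy(), list(graph.segments),
                     list(graph.cells), list(graph.edit_log), list(graph.skipped))
    pairs = g.pair_set
    for a, b in remove:
        pair = g._norm(int(a), int(b))
        if pair not in pairs:
            raise ValueError(f"cannot remove non-existent pair {pair}")
        g.segments = [s for s in g.segments if g._norm(s.a, s.b) != pair]
        pairs.discard(pair)
        g.edit_log.append({"op": "remove", "pair": pair})
    for a, b in add:
        a, b = int(a), int(b)
        if not (0 <= a < g.n_nodes and 0 <= b < g.n_nodes):
            raise ValueError(f"cannot add pair ({a}, {b}): unknown node id")
        pair = g._norm(a, b)
        if pair in pairs:
            raise ValueError(f"cannot add duplicate pair {pair}")
        pa, pb = g.ref_positions[pair[0]], g.ref_positions[pair[1]]
        next_id = max((s.id for s in g.segments), default=-1) + 1
        g.segments.append(Segment(next_id, pair[0], pair[1],
                                  _segment_orientation(pa, pb),
                                  float(np.linalg.norm(pb - pa))))
        pairs.add(pair)
        g.edit_log.append({"op": "add", "pair": pair})
    g.cells = enumerate_cells(g.ref_positions, g.segments)
    return g


@dataclass
class NodeTracks:
    """Per-node positions through time with a tracked/missing/interpolated
    status flag; row t of ``positions`` is frame t, column i node id i."""

    positions: np.ndarray          # (T, N, dim), NaN where missing
    status: np.ndarray             # (T, N) in {MISSING, TRACKED, INTERPOLATED}
    reference: int = 0
    dt: float = 0.0

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.positions.shape[1]

    @property
    def dim(self) -> int:
        return self.positions.shape[2]

    def ok(self) -> np.ndarray:
        """(T, N) bool: position available (tracked or interpolated)."""
        return self.status != MISSING

    def to_frame(self) -> pd.DataFrame:
        T, N, dim = self.positions.shape
        frames = np.repeat(np.arange(T), N)
        ids = np.tile(np.arange(N), T)
        flat = self.positions.reshape(T * N, dim)
        status_names = np.array(["missing", "tracked", "interpolated"])
        out = {"frame": frames, "node_id": ids, "x_um": flat[:, 0],
               "y_um": flat[:, 1]}
        if dim > 2:
            out["z_um"] = flat[:, 2]
        out["status"] = status_names[self.status.reshape(-1)]
        return pd.DataFrame(out)


def _mutual_nn(ref: np.ndarray, det: np.ndarray, gate: float):
    """Greedy mutual nearest neighbours within ``gate``; returns index pairs."""
    if len(ref) == 0 or len(det) == 0:
        return np.zeros((0, 2), int)
    tree_det = cKDTree(det)
    d_rd, j_rd = tree_det.query(ref)
    tree_ref = cKDTree(ref)
    d_dr, i_dr = tree_ref.query(det)
    pairs = []
    for i, (d, j) in enumerate(zip(d_rd, j_rd)):
        if d <= gate and i_dr[j] == i:
            pairs.append((i, j))
    return np.asarray(pairs, int).reshape(-1, 2)


def track_nodes(nodesets: list, graph: LatticeGraph, *, gate: float,
                reference: int = 0, interpolate: bool = False,
                max_missing_frac: float = 0.5) -> NodeTracks:
    """Carry node identities through time.

    Frame-to-frame assignment is greedy mutual-nearest-neighbour between
    each detection set and the last known position of every identity,
    accepted only within ``gate`` micrometres.  Unmatched identities are
    flagged missing (optionally filled by linear interpolation between
    flanking tracked frames); unmatched detections are dropped.  A frame
    where more than ``max_missing_frac`` of the identities go unmatched
    raises a tracking failure.
    """
    if gate <= 0:
        raise ValueError("gate must be positive")
    T = len(nodesets)
    N = graph.n_nodes
    dim = graph.ref_positions.shape[1]
    positions = np.full((T, N, dim), np.nan)
    status = np.zeros((T, N), np.int8)

    ref_det = nodesets[reference].positions
    pairs = _mutual_nn(graph.ref_positions[:, :dim], ref_det, gate)
    if len(pairs) < N:
        raise ValueError(f"reference frame {reference}: only {len(pairs)} of "
                         f"{N} graph nodes matched by detections")
    for i, j in pairs:
        positions[reference, i] = ref_det[j]
        status[reference, i] = TRACKED

    order = list(range(reference + 1, T)) + list(range(reference - 1, -1, -1))
    last_known = positions[reference].copy()
    for t in order:
        if t == reference + 1 or t == reference - 1:
            last_known = positions[reference].copy()
        det = nodesets[t].positions
        have = ~np.isnan(last_known[:, 0])
        pairs = _mutual_nn(last_known[have], det, gate)
        have_idx = np.flatnonzero(have)
        matched = np.zeros(N, bool)
        for i_local, j in pairs:
            i = have_idx[i_local]
            positions[t, i] = det[j]
            status[t, i] = TRACKED
            matched[i] = True
        n_missing = N - int(matched.sum())
        if n_missing > max_missing_frac * N:
            raise ValueError(f"tracking failure at frame {t}: "
                             f"{n_missing}/{N} nodes unmatched")
        last_known = np.where(matched[:, None], positions[t], last_known)

    if interpolate:
        frames = np.arange(T)
        for i in range(N):
            good = status[:, i] == TRACKED
            if good.sum() < 2:
                continue
            gaps = ~good & (frames > frames[good].min()) & (frames < frames[good].max())
            for d in range(dim):
                positions[gaps, i, d] = np.interp(frames[gaps], frames[good],
                                                  positions[good, i, d])
            status[gaps, i] = INTERPOLATED

    return NodeTracks(positions, status, reference=reference,
                      dt=getattr(nodesets[reference], "dt", 0.0) or 0.0)
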