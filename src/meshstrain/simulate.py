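"""Synthetic rendering of fluorescent fiducial-mesh images with exact ground truth.

A square-lattice mesh of fluorescent lines, adhered to a deforming surface,
acts as a dense fiducial marker: every lattice intersection is a trackable
node and every node-to-node segment is a one-dimensional strain gauge.  This
module renders such meshes under parametric deformation fields so that the
whole downstream pipeline (segmentation, lattice tracking, strain and
frequency mapping) can be validated against known kinematics without any
microscopy data.

Coordinates are physical micrometres with the origin at the frame corner,
``x`` along the column axis and ``y`` along the row axis.  Deformation maps
operate in micrometres and are converted to pixels only at rasterisation.
The out-of-plane stretch ``lambda3`` is never rendered; it is emitted as an
auxiliary thickness table, the way thickness is measured macroscopically in
a tensile-test rig rather than imaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as _field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

__all__ = [
    "MeshSpec",
    "DeformationField",
    "IdentityField",
    "AffineField",
    "OscillatoryField",
    "SmoothWarpField",
    "uniaxial_field",
    "make_field",
    "ImageSeries",
    "GroundTruth",
    "render_frame",
    "make_uniaxial_series",
    "make_oscillatory_movie",
]


def _rotation(degrees: float) -> np.ndarray:
    th = np.deg2rad(degrees)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, -s], [s, c]])


def _shoelace(points: np.ndarray) -> float:
    """Signed polygon area (positive for counter-clockwise vertex order)."""
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


# ---------------------------------------------------------------------------
# Mesh geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeshSpec:
    """Geometry of a square-lattice fiducial mesh.

    Parameters
    ----------
    pitch : float
        Node-to-node spacing in micrometres.
    line_width : float
        Width of each fluorescent line in micrometres (must be < pitch).
    rows, cols : int
        Number of horizontal and vertical lattice lines (>= 2 each).
    origin : tuple of float
        Position of node (0, 0) in micrometres.
    orientation : float
        Rotation of the lattice about its origin, degrees.
    """

    pitch: float
    line_width: float
    rows: int = 5
    cols: int = 5
    origin: tuple = (0.0, 0.0)
    orientation: float = 0.0

    def __post_init__(self):
        if not (self.pitch > self.line_width > 0):
            raise ValueError("require pitch > line_width > 0")
        if self.rows < 2 or self.cols < 2:
            raise ValueError("require rows >= 2 and cols >= 2")

    @property
    def n_nodes(self) -> int:
        return self.rows * self.cols

    def node_id(self, i: int, j: int) -> int:
        return i * self.cols + j

    def node_grid(self) -> np.ndarray:
        """Reference node positions, shape (rows*cols, 2), row-major ids."""
        jj, ii = np.meshgrid(np.arange(self.cols), np.arange(self.rows))
        pts = np.stack([jj.ravel() * self.pitch, ii.ravel() * self.pitch], axis=1)
        pts = pts.astype(float) @ _rotation(self.orientation).T
        return pts + np.asarray(self.origin, float)

    def segment_pairs(self):
        """Lattice adjacency: list of ((a, b), orientation) with a < b."""
        out = []
        for i in range(self.rows):
            for j in range(self.cols - 1):
                out.append(((self.node_id(i, j), self.node_id(i, j + 1)), "x"))
        for i in range(self.rows - 1):
            for j in range(self.cols):
                out.append(((self.node_id(i, j), self.node_id(i + 1, j)), "y"))
        return out

    def cell_quads(self):
        """Unit squares as 4-tuples of node ids, counter-clockwise."""
        out = []
        for i in range(self.rows - 1):
            for j in range(self.cols - 1):
                out.append((self.node_id(i, j), self.node_id(i, j + 1),
                            self.node_id(i + 1, j + 1), self.node_id(i + 1, j)))
        return out

    def centerline_points(self, spacing: float) -> np.ndarray:
        """Dense samples along every lattice line centreline, micrometres."""
        lx = (self.cols - 1) * self.pitch
        ly = (self.rows - 1) * self.pitch
        nx = max(2, int(np.ceil(lx / spacing)) + 1)
        ny = max(2, int(np.ceil(ly / spacing)) + 1)
        xs = np.linspace(0.0, lx, nx)
        ys = np.linspace(0.0, ly, ny)
        pts = []
        for i in range(self.rows):          # horizontal lines
            pts.append(np.stack([xs, np.full_like(xs, i * self.pitch)], axis=1))
        for j in range(self.cols):          # vertical lines
            pts.append(np.stack([np.full_like(ys, j * self.pitch), ys], axis=1))
        pts = np.concatenate(pts, axis=0)
        return pts @ _rotation(self.orientation).T + np.asarray(self.origin, float)

    def center(self) -> np.ndarray:
        g = self.node_grid()
        return 0.5 * (g.min(axis=0) + g.max(axis=0))


# ---------------------------------------------------------------------------
# Deformation fields
# ---------------------------------------------------------------------------

class DeformationField:
    """Time-dependent planar map phi_t plus out-of-plane stretch lambda3(t).

    ``map(points, t)`` applies phi_t to (N, 2) micrometre coordinates.  The
    meaning of ``t`` (frame index for stepped series, seconds for movies) is
    fixed by the constructor of each concrete field.  phi_0 must be the
    identity so that frame 0 is the zero-strain reference.
    """

    kind = "identity"

    def map(self, points: np.ndarray, t) -> np.ndarray:
        return np.asarray(points, float).copy()

    def lambda3(self, t) -> float:
        return 1.0

    def planar_F(self, t):
        """2x2 deformation gradient if the map is affine, else None."""
        return np.eye(2)

    def check_valid(self, bounds, t, n: int = 15) -> None:
        """Reject fold-over: the map must be orientation-preserving on bounds."""
        F = self.planar_F(t)
        if F is not None:
            if np.linalg.det(F) <= 0:
                raise ValueError(f"fold-over: det F <= 0 at t={t}")
            return
        (x0, x1), (y0, y1) = bounds
        xs = np.linspace(x0, x1, n)
        ys = np.linspace(y0, y1, n)
        gx, gy = np.meshgrid(xs, ys)
        pts = np.stack([gx.ravel(), gy.ravel()], axis=1)
        h = 1e-3 * max(x1 - x0, y1 - y0, 1.0)
        dxp = self.map(pts + [h, 0], t) - self.map(pts - [h, 0], t)
        dyp = self.map(pts + [0, h], t) - self.map(pts - [0, h], t)
        det = (dxp[:, 0] * dyp[:, 1] - dxp[:, 1] * dyp[:, 0]) / (4 * h * h)
        if np.any(det <= 0):
            raise ValueError(f"fold-over: local Jacobian determinant <= 0 at t={t}")


class IdentityField(DeformationField):
    kind = "identity"


class AffineField(DeformationField):
    """phi_t(p) = F(t) (p - c) + c with a per-time 2x2 gradient F."""

    def __init__(self, F_of_t: Callable, lambda3_of_t: Callable | None = None,
                 center=(0.0, 0.0), kind: str = "affine"):
        self._F = F_of_t
        self._lam3 = lambda3_of_t
        self.center = np.asarray(center, float)
        self.kind = kind
        F0 = np.asarray(F_of_t(0), float)
        if not np.allclose(F0, np.eye(2), atol=1e-9):
            raise ValueError("phi_0 must be the identity (F(0) != I)")

    def planar_F(self, t):
        return np.asarray(self._F(t), float)

    def map(self, points, t):
        p = np.asarray(points, float)
        return (p - self.center) @ self.planar_F(t).T + self.center

    def lambda3(self, t):
        return 1.0 if self._lam3 is None else float(self._lam3(t))


def uniaxial_field(step: float | None = None, mode: str = "incompressible",
                   lambda1_of_t: Callable | None = None,
                   lateral_law: Callable | None = None,
                   thickness_law: Callable | None = None,
                   center=(0.0, 0.0)) -> AffineField:
    """Uniaxial stretch along x: frame k applies lambda1 = 1 + k*step.

    ``mode``:

    - ``"incompressible"`` (isotropic incompressible): lambda2 = lambda3 =
      lambda1**(-1/2), so lambda1*lambda2*lambda3 = 1 at every step.
    - ``"uniaxial"``: lateral direction held at lambda2 = 1.
    - ``"anisotropic"``: independent user laws k -> lambda2 and k -> lambda3
      (a compressible material; the stretch-ratio product drops below 1).
    """
    if lambda1_of_t is None:
        if step is None:
            raise ValueError("either step or lambda1_of_t is required")
        lambda1_of_t = lambda k: 1.0 + step * k
    lam1 = lambda1_of_t
    if mode in ("incompressible", "incompressible_uniaxial"):
        lam2 = lambda k: lam1(k) ** -0.5
        lam3 = lam2
        kind = "incompressible_uniaxial"
    elif mode == "uniaxial":
        lam2 = lambda k: 1.0
        lam3 = lambda k: 1.0
        kind = "uniaxial"
    elif mode in ("anisotropic", "anisotropic_compressible"):
        if lateral_law is None or thickness_law is None:
            raise ValueError("anisotropic mode needs lateral_law and thickness_law")
        lam2, lam3 = lateral_law, thickness_law
        kind = "anisotropic_compressible"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    F = lambda k: np.array([[lam1(k), 0.0], [0.0, lam2(k)]])
    return AffineField(F, lam3, center=center, kind=kind)


class OscillatoryField(DeformationField):
    """Sinusoidal rigid displacement, optionally different per x-region.

    ``components`` is a list of ``(xspan, period_s, amplitude_um)`` where
    ``xspan`` is ``None`` (whole extent) or an ``(x0, x1)`` micrometre
    interval.  Displacement is along ``direction`` (unit-normalised) and is
    a function of x only, blended across region boundaries over ``blend``
    micrometres so the map never folds.  ``t`` is in seconds.
    """

    kind = "oscillatory"

    def __init__(self, components: Sequence, direction=(1.0, 1.0), blend: float = 0.0):
        self.components = list(components)
        d = np.asarray(direction, float)
        nd = np.linalg.norm(d)
        if nd == 0:
            raise ValueError("direction must be non-zero")
        self.direction = d / nd
        self.blend = float(blend)
        for _, period, amp in self.components:
            if period <= 0:
                raise ValueError("period must be positive")
            if amp < 0:
                raise ValueError("amplitude must be non-negative")

    def _weight(self, x: np.ndarray, span) -> np.ndarray:
        if span is None:
            return np.ones_like(x)
        x0, x1 = span
        b = self.blend
        if b <= 0:
            return ((x >= x0) & (x < x1)).astype(float)
        w0 = np.clip((x - x0 + b / 2) / b, 0.0, 1.0)
        w1 = np.clip((x1 + b / 2 - x) / b, 0.0, 1.0)
        return w0 * w1

    def displacement(self, points: np.ndarray, t_s: float) -> np.ndarray:
        p = np.asarray(points, float)
        u = np.zeros(p.shape[0])
        for span, period, amp in self.components:
            u = u + self._weight(p[:, 0], span) * amp * np.sin(2 * np.pi * t_s / period)
        return u[:, None] * self.direction

    def map(self, points, t):
        return np.asarray(points, float) + self.displacement(points, t)

    def planar_F(self, t):
        return None


class SmoothWarpField(DeformationField):
    """Band-limited random displacement field, ramped up linearly in time.

    A sum of ``n_modes`` random plane-wave displacements of wavelength
    ``wavelength`` micrometres, scaled so the peak displacement at ramp(t)=1
    is ``amplitude`` micrometres.  Deterministic for a fixed seed.
    """

    kind = "smooth_warp"

    def __init__(self, amplitude: float, wavelength: float, seed: int,
                 n_modes: int = 4, ramp: Callable | None = None):
        rng = np.random.default_rng(seed)
        self.amplitude = float(amplitude)
        k = 2 * np.pi / wavelength
        ang = rng.uniform(0, 2 * np.pi, n_modes)
        self._kvec = k * np.stack([np.cos(ang), np.sin(ang)], axis=1)
        dang = rng.uniform(0, 2 * np.pi, n_modes)
        self._dvec = np.stack([np.cos(dang), np.sin(dang)], axis=1)
        self._phase = rng.uniform(0, 2 * np.pi, n_modes)
        self._amp = amplitude / n_modes
        self._ramp = ramp if ramp is not None else (lambda t: float(t))
        if abs(self._ramp(0)) > 1e-12:
            raise ValueError("ramp(0) must be 0 so that phi_0 is the identity")

    def _u(self, p: np.ndarray) -> np.ndarray:
        u = np.zeros_like(p)
        for kv, dv, ph in zip(self._kvec, self._dvec, self._phase):
            u = u + self._amp * np.sin(p @ kv + ph)[:, None] * dv
        return u

    def map(self, points, t):
        p = np.asarray(points, float)
        return p + self._ramp(t) * self._u(p)

    def planar_F(self, t):
        return None


_FIELD_KINDS = {
    "identity": lambda **kw: IdentityField(),
    "uniaxial": lambda **kw: uniaxial_field(mode="uniaxial", **kw),
    "incompressible_uniaxial": lambda **kw: uniaxial_field(mode="incompressible", **kw),
    "anisotropic_compressible": lambda **kw: uniaxial_field(mode="anisotropic", **kw),
    "oscillatory": lambda **kw: OscillatoryField(**kw),
    "region_map": lambda **kw: OscillatoryField(**kw),
    "smooth_warp": lambda **kw: SmoothWarpField(**kw),
}


def make_field(kind: str, **params) -> DeformationField:
    """Build a deformation field from a config-style kind + parameter dict."""
    try:
        factory = _FIELD_KINDS[kind]
    except KeyError:
        raise ValueError(f"unknown field kind {kind!r}; one of {sorted(_FIELD_KINDS)}")
    return factory(**params)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ImageSeries:
    """T(xZ)xYxX intensity stack with physical pixel size and frame interval.

    ``pixel_size`` is micrometres per pixel in XY; ``z_step`` (if a z-stack)
    in micrometres; ``dt`` is seconds per frame (must be > 0 for movies).
    """

    frames: np.ndarray
    pixel_size: float
    dt: float = 0.0
    z_step: float | None = None
    channel: str = ""

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim not in (3, 4):
            raise ValueError("frames must be (T, Y, X) or (T, Z, Y, X)")
        if min(self.frames.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.n_frames > 1 and self.dt <= 0:
            raise ValueError("dt must be positive for a multi-frame series")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def is_stack(self) -> bool:
        return self.frames.ndim == 4

    def frame(self, t: int) -> np.ndarray:
        """2D frame t (max-intensity projection over Z for stacks)."""
        f = self.frames[t]
        return f.max(axis=0) if f.ndim == 3 else f


@dataclass
class GroundTruth:
    """Exact kinematics of a rendered series, the oracle for recovery tests.

    Node positions are in frame-local micrometres (same coordinates the
    segmentation stage reports).  ``F`` holds the planar deformation
    gradient per frame for affine fields.  Construction asserts that the
    true cell-area ratio equals det F for affine fields.
    """

    node_positions: np.ndarray                 # (T, N, 2)
    segments: list                             # [(a, b)]
    segment_orientations: list                 # ["x" | "y"]
    cells: list                                # [(a, b, c, d)] CCW
    ref_lengths: np.ndarray                    # (n_segments,)
    F: np.ndarray | None = None                # (T, 2, 2) for affine fields
    lambda3: np.ndarray | None = None          # (T,)
    times: np.ndarray | None = None            # frame index or seconds
    dt: float = 0.0
    region_freqs: list | None = None           # [(bool mask (Y, X), freq Hz)]

    def __post_init__(self):
        T, N, _ = self.node_positions.shape
        if self.times is None:
            self.times = np.arange(T, dtype=float)
        l0 = self.segment_lengths(0)
        if not np.allclose(l0, self.ref_lengths, rtol=1e-8, atol=1e-8):
            raise AssertionError("frame-0 segment lengths disagree with reference geometry")
        if self.F is not None and self.cells:
            a0 = abs(_shoelace(self.node_positions[0][list(self.cells[0])]))
            for t in range(T):
                at = abs(_shoelace(self.node_positions[t][list(self.cells[0])]))
                det = abs(np.linalg.det(self.F[t]))
                if not np.isclose(at / a0, det, rtol=1e-6):
                    raise AssertionError(
                        f"cell-area ratio {at / a0:.6f} != |det F| {det:.6f} at frame {t}")

    @property
    def n_frames(self) -> int:
        return self.node_positions.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.node_positions.shape[1]

    def segment_lengths(self, t: int) -> np.ndarray:
        p = self.node_positions[t]
        ab = np.asarray(self.segments, int)
        return np.linalg.norm(p[ab[:, 1]] - p[ab[:, 0]], axis=1)

    def thickness_table(self) -> pd.DataFrame:
        """Auxiliary out-of-plane stretch table (mirrors DIC thickness data)."""
        if self.lambda3 is None:
            raise ValueError("this series carries no out-of-plane stretch")
        return pd.DataFrame({
            "frame": np.arange(self.n_frames),
            "lambda3": self.lambda3,
            "epsilon3": self.lambda3 - 1.0,
        })

    def macroscopic(self) -> pd.DataFrame:
        """Per-frame applied stretches (the macroscopic fiducial-mark view)."""
        if self.F is None:
            raise ValueError("macroscopic stretches are defined for affine series only")
        lam1 = np.linalg.norm(self.F[:, :, 0], axis=1)
        lam2 = np.linalg.norm(self.F[:, :, 1], axis=1)
        out = {"frame": np.arange(self.n_frames), "lambda1": lam1, "lambda2": lam2}
        if self.lambda3 is not None:
            out["lambda3"] = self.lambda3
        return pd.DataFrame(out)

    def nodes_table(self) -> pd.DataFrame:
        T, N, _ = self.node_positions.shape
        frames = np.repeat(np.arange(T), N)
        ids = np.tile(np.arange(N), T)
        xy = self.node_positions.reshape(T * N, 2)
        return pd.DataFrame({"frame": frames, "node_id": ids,
                             "x_um": xy[:, 0], "y_um": xy[:, 1]})

    def segments_table(self) -> pd.DataFrame:
        ab = np.asarray(self.segments, int)
        return pd.DataFrame({"segment_id": np.arange(len(ab)),
                             "node_a": ab[:, 0], "node_b": ab[:, 1],
                             "orientation": self.segment_orientations,
                             "ref_length_um": self.ref_lengths})

    def to_csv(self, outdir) -> None:
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.nodes_table().to_csv(outdir / "nodes.csv", index=False)
        self.segments_table().to_csv(outdir / "truth_segments.csv", index=False)
        if self.lambda3 is not None:
            self.thickness_table().to_csv(outdir / "thickness.csv", index=False)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _default_margin(mesh: MeshSpec, psf_sigma: float) -> float:
    return max(2.0 * mesh.line_width, 0.1 * mesh.pitch) + 4.0 * psf_sigma


def render_frame(mesh: MeshSpec, field: DeformationField, t, *,
                 pixel_size: float = 1.0, shape: tuple | None = None,
                 origin_um: tuple | None = None, psf_sigma: float | None = None,
                 noise_sigma: float = 0.0, poisson_photons: float | None = None,
                 rng: np.random.Generator | int | None = None,
                 margin: float | None = None, foreground: float = 1.0,
                 sample_spacing: float | None = None) -> np.ndarray:
    """Render one fluorescence frame of the deformed mesh.

    Pixels within ``line_width/2`` of a deformed lattice centreline carry
    the foreground intensity (with a half-pixel linear edge ramp), then the
    frame is blurred with a Gaussian PSF of ``psf_sigma`` micrometres
    (default half a pixel) and optionally corrupted with additive Gaussian
    and/or Poisson noise.  Deterministic for a fixed seed.

    ``shape``/``origin_um`` pin the pixel grid so that every frame of a
    series shares one coordinate system; when omitted they are derived from
    the deformed mesh bounding box plus ``margin`` micrometres.
    """
    if psf_sigma is None:
        psf_sigma = 0.5 * pixel_size
    spacing = sample_spacing if sample_spacing is not None else \
        min(0.25 * pixel_size, 0.5 * mesh.line_width)
    pts_ref = mesh.centerline_points(spacing)
    lo, hi = pts_ref.min(axis=0), pts_ref.max(axis=0)
    field.check_valid(((lo[0], hi[0]), (lo[1], hi[1])), t)
    pts = field.map(pts_ref, t)

    if margin is None:
        margin = _default_margin(mesh, psf_sigma)
    if origin_um is None:
        origin_um = pts.min(axis=0) - margin
    origin_um = np.asarray(origin_um, float)
    if shape is None:
        extent = pts.max(axis=0) - origin_um + margin
        shape = (int(np.ceil(extent[1] / pixel_size)) + 1,
                 int(np.ceil(extent[0] / pixel_size)) + 1)
    ny, nx = shape

    px = (pts - origin_um) / pixel_size        # columns: (x, y) in pixels
    if (px[:, 0].min() < -0.5 or px[:, 1].min() < -0.5
            or px[:, 0].max() > nx - 0.5 or px[:, 1].max() > ny - 0.5):
        raise ValueError(
            f"mesh out of frame at t={t}: deformed extent "
            f"x [{px[:, 0].min():.1f}, {px[:, 0].max():.1f}] px, "
            f"y [{px[:, 1].min():.1f}, {px[:, 1].max():.1f}] px "
            f"vs frame {nx} x {ny}")

    tree = cKDTree(px)
    cols, rows = np.meshgrid(np.arange(nx, dtype=float), np.arange(ny, dtype=float))
    centers = np.stack([cols.ravel(), rows.ravel()], axis=1)
    dist, _ = tree.query(centers, workers=-1)
    halfw = 0.5 * mesh.line_width / pixel_size
    img = np.clip(halfw + 0.5 - dist.reshape(ny, nx), 0.0, 1.0) * foreground

    if psf_sigma > 0:
        img = gaussian_filter(img, psf_sigma / pixel_size)
    if noise_sigma > 0 or poisson_photons is not None:
        if rng is None:
            raise ValueError("a seed (or Generator) is required when noise is enabled")
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        if noise_sigma > 0:
            img = img + rng.normal(0.0, noise_sigma * foreground, img.shape)
        if poisson_photons is not None:
            img = rng.poisson(np.clip(img, 0, None) * poisson_photons) / poisson_photons
    return np.clip(img, 0.0, None)


def _series_grid(mesh: MeshSpec, field: DeformationField, times, pixel_size: float,
                 psf_sigma: float, margin: float | None, pad_um: float = 0.0):
    """Common pixel grid covering the mesh at every time point."""
    if margin is None:
        margin = _default_margin(mesh, psf_sigma)
    corners = mesh.node_grid()
    lo = np.full(2, np.inf)
    hi = np.full(2, -np.inf)
    for t in times:
        p = field.map(corners, t)
        lo = np.minimum(lo, p.min(axis=0))
        hi = np.maximum(hi, p.max(axis=0))
    lo -= margin + pad_um + 0.5 * mesh.line_width
    hi += margin + pad_um + 0.5 * mesh.line_width
    origin = lo
    shape = (int(np.ceil((hi[1] - lo[1]) / pixel_size)) + 1,
             int(np.ceil((hi[0] - lo[0]) / pixel_size)) + 1)
    return shape, origin


def _truth_for(mesh: MeshSpec, field: DeformationField, times, origin, *,
               F=None, lambda3=None, dt=0.0, region_freqs=None) -> GroundTruth:
    grid = mesh.node_grid()
    pos = np.stack([field.map(grid, t) - origin for t in times])
    pairs = mesh.segment_pairs()
    segments = [p for p, _ in pairs]
    orients = [o for _, o in pairs]
    ab = np.asarray(segments, int)
    ref_lengths = np.linalg.norm(pos[0][ab[:, 1]] - pos[0][ab[:, 0]], axis=1)
    return GroundTruth(node_positions=pos, segments=segments,
                       segment_orientations=orients, cells=mesh.cell_quads(),
                       ref_lengths=ref_lengths, F=F, lambda3=lambda3,
                       times=np.asarray(times, float), dt=dt,
                       region_freqs=region_freqs)


def make_uniaxial_series(mesh: MeshSpec, max_strain: float, step: float, *,
                         mode: str = "incompressible",
                         lateral_law: Callable | None = None,
                         thickness_law: Callable | None = None,
                         pixel_size: float = 1.0, psf_sigma: float | None = None,
                         noise_sigma: float = 0.0, seed: int | None = None,
                         margin: float | None = None, dt: float = 1.0):
    """Stepped uniaxial stretch series: frame k applies lambda1 = 1 + k*step.

    Emulates loading a mesh-carrying tensile test strip in ``max_strain /
    step`` increments (e.g. 45 % in 3 % steps -> 16 frames including the
    reference).  Returns ``(ImageSeries, GroundTruth)``; the ground truth
    carries the lateral law per ``mode`` and the out-of-plane stretch series
    as an auxiliary thickness table.
    """
    if step <= 0 or step > max_strain:
        raise ValueError("require 0 < step <= max_strain")
    if psf_sigma is None:
        psf_sigma = 0.5 * pixel_size
    n_steps = int(round(max_strain / step))
    times = np.arange(n_steps + 1)
    field = uniaxial_field(step=step, mode=mode, lateral_law=lateral_law,
                           thickness_law=thickness_law, center=tuple(mesh.center()))
    shape, origin = _series_grid(mesh, field, times, pixel_size, psf_sigma, margin)
    rng = None
    if noise_sigma > 0:
        if seed is None:
            raise ValueError("a seed is required when noise is enabled")
        rng = np.random.default_rng(seed)
    frames = np.stack([
        render_frame(mesh, field, int(k), pixel_size=pixel_size, shape=shape,
                     origin_um=origin, psf_sigma=psf_sigma,
                     noise_sigma=noise_sigma, rng=rng)
        for k in times])
    F = np.stack([field.planar_F(int(k)) for k in times])
    lam3 = np.array([field.lambda3(int(k)) for k in times])
    truth = _truth_for(mesh, field, times, origin, F=F, lambda3=lam3, dt=dt)
    series = ImageSeries(frames.astype(np.float32), pixel_size, dt=dt)
    return series, truth


def make_oscillatory_movie(mesh: MeshSpec, periods: Sequence, duration: float,
                           fps: float, *, direction=(1.0, 1.0),
                           pixel_size: float = 1.0, psf_sigma: float | None = None,
                           noise_sigma: float = 0.0, seed: int | None = None,
                           margin: float | None = None, blend: float | None = None):
    """Movie of the mesh oscillating sinusoidally, region by region.

    ``periods`` is a list of ``(region, period_s, amplitude_um)`` where
    ``region`` is ``None`` (whole mesh) or an ``(x0, x1)`` micrometre span;
    regions must be disjoint.  Node displacement in each region is
    sinusoidal with its period, so the true contraction frequency is
    ``1/period``, stored per region together with a pixel mask.
    """
    if fps <= 0 or duration <= 0:
        raise ValueError("duration and fps must be positive")
    if psf_sigma is None:
        psf_sigma = 0.5 * pixel_size
    n_frames = int(round(duration * fps))
    dt = 1.0 / fps
    max_period = max(p for _, p, _ in periods)
    if duration < 2.0 * max_period:
        warnings.warn("fewer than 2 full cycles recorded; frequency resolution "
                      "is insufficient", stacklevel=2)
    for _, period, _ in periods:
        if fps < 2.0 / period:
            warnings.warn(f"sampling at {fps} fps aliases a {1.0 / period:.3g} Hz "
                          "oscillation (below Nyquist)", stacklevel=2)
    if blend is None:
        blend = 0.5 * mesh.pitch if len(periods) > 1 else 0.0
    field = OscillatoryField(periods, direction=direction, blend=blend)
    times = np.arange(n_frames) * dt
    max_amp = max(a for _, _, a in periods)
    shape, origin = _series_grid(mesh, field, [0.0], pixel_size, psf_sigma,
                                 margin, pad_um=max_amp)
    rng = None
    if noise_sigma > 0:
        if seed is None:
            raise ValueError("a seed is required when noise is enabled")
        rng = np.random.default_rng(seed)
    frames = np.stack([
        render_frame(mesh, field, float(t), pixel_size=pixel_size, shape=shape,
                     origin_um=origin, psf_sigma=psf_sigma,
                     noise_sigma=noise_sigma, rng=rng)
        for t in times])
    ny, nx = shape
    x_um = np.arange(nx) * pixel_size + origin[0]
    region_freqs = []
    for span, period, _ in periods:
        if span is None:
            col = np.ones(nx, bool)
        else:
            col = (x_um >= span[0]) & (x_um < span[1])
        region_freqs.append((np.tile(col, (ny, 1)), 1.0 / period))
    truth = _truth_for(mesh, field, times, origin, dt=dt, region_freqs=region_freqs)
    series = ImageSeries(frames.astype(np.float32), pixel_size, dt=dt)
    return series, truth
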