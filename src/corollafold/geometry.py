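"""Geometry synthesis and meshing for petal cross-sections.

Coordinate convention: x horizontal, y the proximodistal (base-to-tip) axis
with the base at y=0; all lengths in mm.

The module generates every geometry the analysis needs:

* the initial rectangular cross-section of the growth runs (0.1 x 0.8 mm by
  default, structured triangulation, exactly mirror-symmetric about the
  vertical midline so that symmetry-preservation tests are meaningful);
* synthetic stand-ins for image-traced folded cross-section outlines, built
  as a constant-width column whose midline carries sinusoidal folds
  (n_folds=2 emulates the doubly-folded "cup" phenotype);
* an unstructured conforming triangulation of arbitrary simple polygons,
  used to mesh traced or synthetic outlines for residual-stress mapping.

Outlines are read and written as plain CSV (header ``x_mm,y_mm``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import Delaunay
from shapely.geometry import Polygon as ShapelyPolygon

from .errors import FormatError, GeometryError

__all__ = [
    "Polygon2D",
    "TriMesh",
    "rectangle_mesh",
    "synthetic_folded_outline",
    "polygon_mesh",
    "read_outline",
    "write_outline",
]


@dataclass(frozen=True)
class Polygon2D:
    """Closed simple polygon, counter-clockwise after normalization."""

    vertices: np.ndarray  # (n, 2), mm
    closed: bool = True

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise GeometryError("vertices must be an (n, 2) array")
        if len(v) < 3:
            raise GeometryError(f"polygon needs >= 3 vertices, got {len(v)}")
        if not np.all(np.isfinite(v)):
            raise GeometryError("polygon vertices must be finite")
        sp = ShapelyPolygon(v)
        if not sp.is_valid or not sp.is_simple or sp.area <= 0:
            raise GeometryError("polygon is degenerate or self-intersecting")
        # normalize to counter-clockwise orientation
        if _shoelace(v) < 0:
            v = v[::-1].copy()
        object.__setattr__(self, "vertices", v)

    @property
    def area(self) -> float:
        """Analytic (shoelace) area, mm^2."""
        return _shoelace(self.vertices)

    def to_shapely(self) -> ShapelyPolygon:
        return ShapelyPolygon(self.vertices)


def _shoelace(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class TriMesh:
    """2D triangulated geometry with boundary tags and element metadata.

    Attributes
    ----------
    nodes : (N, 2) array, mm
    triangles : (M, 3) int array, counter-clockwise node triples
    boundary_edges : dict tag -> (m, 2) int array of boundary edges
    element_labels : (M,) int array, region label per triangle (0 = bulk)
    material_axes : (M, 2) array, unit principal-stiffness direction per
        triangle (defaults to the global vertical)
    node_sets : dict name -> int array of node indices (e.g. the "midline"
        column of a rectangle mesh, kept across growth steps because
        connectivity never changes)
    """

    nodes: np.ndarray
    triangles: np.ndarray
    boundary_edges: dict = field(default_factory=dict)
    element_labels: np.ndarray | None = None
    material_axes: np.ndarray | None = None
    node_sets: dict = field(default_factory=dict)

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.element_labels is None:
            self.element_labels = np.zeros(len(self.triangles), dtype=np.int64)
        if self.material_axes is None:
            ax = np.zeros((len(self.triangles), 2))
            ax[:, 1] = 1.0
            self.material_axes = ax
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        n, m = len(self.nodes), len(self.triangles)
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise GeometryError("triangles must be an (M, 3) index array")
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= n
        ):
            raise GeometryError("triangle node index out of range")
        t = self.triangles
        if np.any(
            (t[:, 0] == t[:, 1]) | (t[:, 1] == t[:, 2]) | (t[:, 0] == t[:, 2])
        ):
            raise GeometryError("triangle with repeated node index")
        areas = self.signed_areas()
        if np.any(areas <= 0):
            bad = int(np.argmin(areas))
            raise GeometryError(
                f"triangle {bad} has non-positive area {areas[bad]:.3e}"
            )
        if len(self.element_labels) != m or len(self.material_axes) != m:
            raise GeometryError("element metadata length mismatch")
        self._check_boundary_closed()

    def _check_boundary_closed(self) -> None:
        if not self.boundary_edges:
            return
        all_edges = np.vstack([e for e in self.boundary_edges.values()])
        deg = np.zeros(len(self.nodes), dtype=int)
        np.add.at(deg, all_edges.ravel(), 1)
        touched = deg > 0
        if np.any(deg[touched] != 2):
            raise GeometryError("boundary edges do not form closed loops")

    # -- derived quantities ---------------------------------------------
    def signed_areas(self) -> np.ndarray:
        p = self.nodes[self.triangles]
        return 0.5 * (
            (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
            - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
        )

    def centroids(self) -> np.ndarray:
        return self.nodes[self.triangles].mean(axis=1)

    @property
    def area(self) -> float:
        return float(self.signed_areas().sum())

    def boundary_nodes(self, tag: str | None = None) -> np.ndarray:
        """Sorted unique node indices on boundary edges (optionally one tag)."""
        if tag is None:
            edges = np.vstack([e for e in self.boundary_edges.values()])
        else:
            edges = self.boundary_edges[tag]
        return np.unique(edges)

    def with_nodes(self, new_nodes: np.ndarray) -> "TriMesh":
        """Same connectivity and metadata on displaced node coordinates."""
        return TriMesh(
            nodes=np.asarray(new_nodes, dtype=float),
            triangles=self.triangles,
            boundary_edges=self.boundary_edges,
            element_labels=self.element_labels.copy(),
            material_axes=self.material_axes.copy(),
            node_sets=dict(self.node_sets),
        )

    def min_angle_deg(self) -> float:
        """Smallest interior angle over all triangles, degrees."""
        p = self.nodes[self.triangles]
        angles = []
        for k in range(3):
            a = p[:, (k + 1) % 3] - p[:, k]
            b = p[:, (k + 2) % 3] - p[:, k]
            cosang = np.einsum("ij,ij->i", a, b) / (
                np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
            )
            angles.append(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
        return float(np.min(angles))


# ---------------------------------------------------------------------------
# structured rectangle mesh
# ---------------------------------------------------------------------------

def rectangle_mesh(width: float, height: float, nx: int, ny: int) -> TriMesh:
    """Structured triangulation of [0,width] x [0,height].

    (nx+1)*(ny+1) nodes, 2*nx*ny triangles.  Each grid quad is split along
    one diagonal, with the diagonal direction mirrored about the vertical
    midline so that for even nx the triangulation (not just the node set) is
    exactly mirror-symmetric under x -> width - x.  A single-direction split
    would itself bias the buckling direction of a growth run.

    Boundary tags: "base" (y=0), "top" (y=height), "left" (x=0),
    "right" (x=width).  For even nx, the node set "midline" holds the
    x = width/2 node column ordered base to tip.
    """
    if not (width > 0 and height > 0):
        raise GeometryError(f"width and height must be > 0, got {width}, {height}")
    if nx < 1 or ny < 1:
        raise GeometryError(f"nx and ny must be >= 1, got {nx}, {ny}")
    xs = np.linspace(0.0, width, nx + 1)
    ys = np.linspace(0.0, height, ny + 1)
    X, Y = np.meshgrid(xs, ys, indexing="xy")
    nodes = np.column_stack([X.ravel(), Y.ravel()])

    def nid(i, j):  # grid (column i, row j) -> node index
        return j * (nx + 1) + i

    tris = []
    half = nx / 2.0
    for j in range(ny):
        for i in range(nx):
            n00, n10 = nid(i, j), nid(i + 1, j)
            n01, n11 = nid(i, j + 1), nid(i + 1, j + 1)
            if i + 0.5 < half:  # left half: diagonal n00-n11
                tris.append((n00, n10, n11))
                tris.append((n00, n11, n01))
            else:  # right half: mirrored diagonal n10-n01
                tris.append((n00, n10, n01))
                tris.append((n10, n11, n01))
    triangles = np.array(tris, dtype=np.int64)

    boundary = {
        "base": np.array([[nid(i, 0), nid(i + 1, 0)] for i in range(nx)]),
        "top": np.array([[nid(i, ny), nid(i + 1, ny)] for i in range(nx)]),
        "left": np.array([[nid(0, j), nid(0, j + 1)] for j in range(ny)]),
        "right": np.array([[nid(nx, j), nid(nx, j + 1)] for j in range(ny)]),
    }
    node_sets = {}
    if nx % 2 == 0:
        node_sets["midline"] = np.array([nid(nx // 2, j) for j in range(ny + 1)])
    return TriMesh(nodes=nodes, triangles=triangles, boundary_edges=boundary,
                   node_sets=node_sets)


# ---------------------------------------------------------------------------
# synthetic folded outlines
# ---------------------------------------------------------------------------

def synthetic_folded_outline(
    height: float,
    width: float,
    n_folds: int,
    fold_depth: float,
    n_points: int = 100,
    seed: int = 0,
    jitter: float = 0.0,
) -> Polygon2D:
    """Stand-in for an image-traced folded petal cross-section outline.

    Builds a constant-width column whose midline deviates sinusoidally from
    the vertical: n_folds excursions of amplitude fold_depth*height.  The
    outline is the midline offset by +/- width/2 along the local normal,
    capped at base and tip.  n_folds=2 with a substantial fold_depth mimics
    the doubly folded "cup" corolla phenotype; n_folds=0 degenerates to a
    rectangle.

    ``seed`` only drives optional vertex jitter of relative amplitude
    ``jitter`` (fraction of width); jitter=0 gives the deterministic smooth
    outline regardless of seed.
    """
    if n_folds < 0:
        raise GeometryError("n_folds must be >= 0")
    if not (0.0 <= fold_depth < 0.5):
        raise GeometryError("fold_depth must lie in [0, 0.5)")
    if n_points < 20:
        raise GeometryError("n_points must be >= 20")
    if height <= 0 or width <= 0:
        raise GeometryError("height and width must be > 0")

    amp = fold_depth * height
    # curvature of the midline must stay below 2/width or the inner offset
    # curve self-intersects
    if n_folds > 0 and amp > 0:
        kmax = amp * (2.0 * np.pi * n_folds / height) ** 2
        if kmax * (width / 2.0) >= 1.0:
            raise GeometryError(
                f"fold {int(np.ceil(n_folds / 2))} too tight: offset curve "
                f"self-intersects (curvature*width/2 = {kmax * width / 2:.2f} >= 1)"
            )

    n_side = max(n_points // 2, 10)
    t = np.linspace(0.0, 1.0, n_side)
    y = t * height
    x = width / 2.0 + amp * np.sin(2.0 * np.pi * n_folds * t)
    dx = amp * 2.0 * np.pi * n_folds / height * np.cos(2.0 * np.pi * n_folds * t)
    # unit normal to midline tangent (dx, 1)/|.|, pointing to +x side
    norm = np.sqrt(1.0 + dx**2)
    nxv, nyv = 1.0 / norm, -dx / norm

    right = np.column_stack([x + width / 2 * nxv, y + width / 2 * nyv])
    left = np.column_stack([x - width / 2 * nxv, y - width / 2 * nyv])
    verts = np.vstack([right, left[::-1]])

    if jitter > 0:
        rng = np.random.default_rng(seed)
        verts = verts + rng.normal(scale=jitter * width, size=verts.shape)

    sp = ShapelyPolygon(verts)
    if not sp.is_valid or not sp.is_simple:
        raise GeometryError("generated outline self-intersects; reduce "
                            "fold_depth, n_folds or jitter")
    return Polygon2D(vertices=verts)


# ---------------------------------------------------------------------------
# unstructured polygon meshing
# ---------------------------------------------------------------------------

def _resample_boundary(poly: Polygon2D, h: float,
                       corner_deg: float = 20.0) -> np.ndarray:
    """Boundary points spaced ~h apart along the outline.

    Sharp corners (turning angle above corner_deg) are preserved exactly;
    the smooth chains between them are resampled uniformly by arclength so
    that densely traced outlines do not force sliver triangles.
    """
    v = poly.vertices
    n = len(v)
    prev = v - np.roll(v, 1, axis=0)
    nxt = np.roll(v, -1, axis=0) - v
    dp = prev / np.linalg.norm(prev, axis=1, keepdims=True)
    dn = nxt / np.linalg.norm(nxt, axis=1, keepdims=True)
    turn = np.degrees(np.arccos(np.clip(np.einsum("ij,ij->i", dp, dn), -1, 1)))
    corners = np.nonzero(turn > corner_deg)[0]
    if corners.size == 0:
        corners = np.array([0])
    pts = []
    for a, b in zip(corners, np.roll(corners, -1)):
        chain = v[a:b + 1] if b > a else np.vstack([v[a:], v[: b + 1]])
        seg = np.linalg.norm(np.diff(chain, axis=0), axis=1)
        arclen = np.concatenate([[0.0], np.cumsum(seg)])
        L = arclen[-1]
        m = max(int(round(L / h)), 1)
        s = np.linspace(0.0, L, m + 1)[:-1]  # next chain supplies endpoint
        pts.append(np.column_stack([
            np.interp(s, arclen, chain[:, 0]),
            np.interp(s, arclen, chain[:, 1]),
        ]))
    return np.vstack(pts)


def polygon_mesh(outline: Polygon2D, target_edge: float,
                 n_smooth: int = 4) -> TriMesh:
    """Conforming triangulation of a simple polygon interior.

    Strategy: resample the boundary at spacing target_edge, seed the
    interior with a staggered (triangular-lattice) grid of the same spacing
    kept clear of the boundary, Delaunay-triangulate, and discard triangles
    whose centroid falls outside the polygon.  A few Laplacian smoothing
    passes on the interior points (with re-triangulation) improve element
    quality.  Boundary edges are tagged "outline".
    """
    if target_edge <= 0:
        raise GeometryError("target_edge must be > 0")
    sp = outline.to_shapely()
    h = float(target_edge)
    bpts = _resample_boundary(outline, h)

    xmin, ymin, xmax, ymax = sp.bounds
    rows = []
    dy = h * np.sqrt(3) / 2
    j = 0
    yv = ymin + dy / 2
    while yv < ymax:
        off = (h / 2) if (j % 2) else 0.0
        xs = np.arange(xmin + off, xmax + h, h)
        rows.append(np.column_stack([xs, np.full_like(xs, yv)]))
        yv += dy
        j += 1
    ipts = np.vstack(rows) if rows else np.empty((0, 2))
    if len(ipts):
        inner = sp.buffer(-0.55 * h)
        keep = shapely.contains_xy(inner, ipts[:, 0], ipts[:, 1])
        ipts = ipts[keep]

    shapely.prepare(sp)

    def triangulate(points):
        tri = Delaunay(points)
        cent = points[tri.simplices].mean(axis=1)
        inside = shapely.contains_xy(sp, cent[:, 0], cent[:, 1])
        return tri.simplices[inside]

    pts = np.vstack([bpts, ipts])
    nb = len(bpts)
    simplices = triangulate(pts)
    for _ in range(n_smooth):
        if len(pts) <= nb:
            break
        # Laplacian: move each interior point to the mean of its neighbours
        nbr_sum = np.zeros_like(pts)
        nbr_cnt = np.zeros(len(pts))
        for k in range(3):
            i = simplices[:, k]
            for k2 in range(3):
                if k2 == k:
                    continue
                np.add.at(nbr_sum, i, pts[simplices[:, k2]])
                np.add.at(nbr_cnt, i, 1.0)
        movable = np.zeros(len(pts), dtype=bool)
        movable[nb:] = nbr_cnt[nb:] > 0
        new = pts.copy()
        new[movable] = nbr_sum[movable] / nbr_cnt[movable, None]
        ok = shapely.contains_xy(sp, new[nb:, 0], new[nb:, 1])
        new[nb:][~ok] = pts[nb:][~ok]
        pts = new
        simplices = triangulate(pts)

    # orient counter-clockwise
    p = pts[simplices]
    s = ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
         - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))
    flip = s < 0
    simplices[flip] = simplices[flip][:, [0, 2, 1]]
    degenerate = np.abs(s) < 1e-14 * sp.area
    simplices = simplices[~degenerate]

    used = np.unique(simplices)
    remap = -np.ones(len(pts), dtype=np.int64)
    remap[used] = np.arange(len(used))
    nodes = pts[used]
    triangles = remap[simplices]

    edges = np.sort(
        np.vstack([triangles[:, [0, 1]], triangles[:, [1, 2]], triangles[:, [2, 0]]]),
        axis=1,
    )
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    boundary = {"outline": uniq[counts == 1]}
    mesh = TriMesh(nodes=nodes, triangles=triangles, boundary_edges=boundary)
    if abs(mesh.area - outline.area) > 0.02 * outline.area:
        raise GeometryError(
            "triangulated area deviates from polygon area by more than 2%; "
            "reduce target_edge"
        )
    return mesh


# ---------------------------------------------------------------------------
# outline CSV I/O
# ---------------------------------------------------------------------------

_HEADER = "x_mm,y_mm"


def write_outline(polygon: Polygon2D, path) -> None:
    """Write the outline as CSV with header ``x_mm,y_mm``, one vertex/row."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_HEADER + "\n")
        for x, y in polygon.vertices:
            fh.write(f"{x:.12g},{y:.12g}\n")


def read_outline(path) -> Polygon2D:
    """Read an outline CSV (closure implied; round-trips write_outline)."""
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != _HEADER:
        raise FormatError(f"{path}: line 1: expected header '{_HEADER}'")
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise FormatError(f"{path}: line {ln}: expected two comma-separated fields")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError:
            raise FormatError(f"{path}: line {ln}: non-numeric field") from None
    if len(rows) < 3:
        raise FormatError(
            f"{path}: outline needs at least 3 vertices, found {len(rows)}"
        )
    return Polygon2D(vertices=np.array(rows))
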