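"""Incremental growth of a petal cross-section with one-sided friction.

The growth loop is the morphoelastic "inflate, equilibrate, release"
iteration: at each step the current rest shape is inflated by turgor
pressure (reduced to (1-eta)P inside the friction band), the linear elastic
equilibrium is solved, and the deformed configuration is adopted as the next
rest shape.  Adopting the deformed shape discards the elastic stress — the
incremental analogue of viscous relaxation of the tissue — while the
pre-release equilibrium stress of each step is kept as that step's record of
the stress the tissue experienced during development.

Friction with the outer organ reduces the turgor (hence growth) of the
labelled band elements on the contact side.  The band is Lagrangian: chosen
on the initial rectangle and carried with the material for the whole run.
The one-sided growth deficit makes the band a non-growing strip bonded to a
growing column, which bends the column at and below the band's lower edge —
the buckling-like fold.  With eta=0 there is no contact and a
mirror-symmetric mesh grows perfectly straight and stress-free.

The base is supported vertically (uy=0 along the basal edge, with the basal
midpoint also fixed horizontally to anchor the column) rather than fully
clamped: the receptacle prevents the corolla base from moving down or
sliding as a whole, but grows with it, so the base must be free to widen
with the tissue.  A full clamp would imprint a corner stress concentration
that grows with the accumulated widening and masks the friction-induced
stress the model is built to expose; with the vertical support the
friction-free control run is exactly stress-free uniform growth.  The full
clamp remains available (``base_bc="clamp"``).

An optional bilateral horizontal pin of the band's contact-side boundary
nodes (``pin_friction_boundary``) is off by default: the organ contact is
unilateral, and the buckling deflection moves the petal away from the
contact surface, so a bilateral pin would spuriously hold the column
straight.

Material anisotropy axes are convected: after each step every element's
principal-stiffness direction is mapped through the element deformation
gradient and renormalized, so "proximodistal" stiffness follows the tissue
as it folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .constitutive import ElasticParams, effective_pressure
from .errors import ConfigurationError, GeometryError
from .fem import BCSpec, deformation_gradients, solve_equilibrium
from .geometry import TriMesh, rectangle_mesh

__all__ = [
    "FrictionRegion",
    "band_edge_fractions",
    "GrowthConfig",
    "GrowthTrajectory",
    "label_friction_elements",
    "growth_step",
    "run_growth",
    "midline_deflection",
    "detect_buckling",
    "stress_summary",
    "default_initial_mesh",
]

log = logging.getLogger(__name__)

FRICTION_LABEL = 1


@dataclass(frozen=True)
class FrictionRegion:
    """Material friction band: one lateral side, a height interval and a
    depth into the tissue, both as fractions of the initial column.

    The depth is a width fraction (not an element count) so that the
    physical problem is independent of mesh resolution; the default 0.5
    covers the contact-side half of the cross-section.
    """

    side: str = "right"  # "left" or "right"
    height_interval: tuple = (0.70, 1.0)
    depth_fraction: float = 0.5

    def __post_init__(self):
        lo, hi = self.height_interval
        if not (0.0 <= lo < hi <= 1.0):
            raise ConfigurationError(
                f"friction height interval must be a non-empty sub-interval "
                f"of [0, 1], got {self.height_interval}"
            )
        if self.side not in ("left", "right"):
            raise ConfigurationError(f"side must be 'left' or 'right', got {self.side!r}")
        if not (0.0 < self.depth_fraction <= 1.0):
            raise ConfigurationError("depth_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class GrowthConfig:
    """Controls of one growth run.

    P: turgor pressure, Pa.  eta: friction parameter in [0, 1].  n_steps:
    number of inflate/release iterations.  friction_region: the material
    band in contact with the outer organ.  params: elastic constants.
    seed: drives optional initial node jitter only (0 = none); the model
    itself is deterministic.
    """

    P: float = 4.0e4
    eta: float = 0.0
    friction_region: FrictionRegion = FrictionRegion()
    n_steps: int = 200
    params: ElasticParams = ElasticParams()
    base_bc: str = "support"  # "support": uy=0 on base + midpoint ux=0; "clamp"
    pin_friction_boundary: bool = False
    seed: int = 0
    jitter: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.eta <= 1.0):
            raise ConfigurationError(f"eta must lie in [0, 1], got {self.eta}")
        if self.n_steps < 1:
            raise ConfigurationError("n_steps must be >= 1")
        if self.P < 0:
            raise ConfigurationError("P must be >= 0")
        if self.base_bc not in ("support", "clamp"):
            raise ConfigurationError(
                f"base_bc must be 'support' or 'clamp', got {self.base_bc!r}"
            )


@dataclass
class GrowthTrajectory:
    """Rest shapes and per-step stress records of a growth run.

    rest_meshes has n_steps+1 entries (step 0 = initial shape); fields has
    one pre-release FieldState per step.  summary is a list of per-step
    dicts (height, deflection, bend angle, peak von Mises and its element).
    """

    rest_meshes: list
    fields: list
    summary: list
    config: GrowthConfig

    def __post_init__(self):
        if len(self.rest_meshes) != len(self.fields) + 1:
            raise ValueError("expected n_steps+1 meshes for n_steps fields")

    @property
    def final_mesh(self) -> TriMesh:
        return self.rest_meshes[-1]


def default_initial_mesh(width: float = 0.1, height: float = 0.8,
                         nx: int = 4, ny: int = 32) -> TriMesh:
    """The standard initial cross-section: 0.1 x 0.8 mm rectangle."""
    return rectangle_mesh(width, height, nx, ny)


def label_friction_elements(mesh: TriMesh, region: FrictionRegion,
                            require_nonempty: bool = True) -> np.ndarray:
    """Label elements of the friction band on the initial rectangle.

    An element belongs to the band when its rest centroid lies within the
    height interval (fractions of the mesh height) and within
    depth_fraction of the width from the chosen lateral boundary.  Labels
    are material (Lagrangian): computed once on the rest mesh and reused
    all run.
    """
    cent = mesh.centroids()
    ymin, ymax = mesh.nodes[:, 1].min(), mesh.nodes[:, 1].max()
    height = ymax - ymin
    lo, hi = region.height_interval
    in_band_y = (cent[:, 1] >= ymin + lo * height) & (cent[:, 1] <= ymin + hi * height)

    xmin, xmax = mesh.nodes[:, 0].min(), mesh.nodes[:, 0].max()
    if xmax <= xmin:
        raise GeometryError("mesh has no lateral extent")
    depth = region.depth_fraction * (xmax - xmin)
    if region.side == "right":
        in_depth = cent[:, 0] >= xmax - depth
    else:
        in_depth = cent[:, 0] <= xmin + depth
    labels = np.where(in_band_y & in_depth, FRICTION_LABEL, 0).astype(np.int64)
    if require_nonempty and not labels.any():
        raise ConfigurationError("friction region selects no elements")
    return labels


def _pinned_boundary_nodes(mesh: TriMesh, region: FrictionRegion) -> np.ndarray:
    """Boundary nodes of the contact side inside the band height interval."""
    idx = mesh.boundary_nodes(region.side)
    y = mesh.nodes[idx, 1]
    ymin, ymax = mesh.nodes[:, 1].min(), mesh.nodes[:, 1].max()
    height = ymax - ymin
    lo, hi = region.height_interval
    sel = (y >= ymin + lo * height - 1e-12) & (y <= ymin + hi * height + 1e-12)
    return idx[sel]


def _base_bcs(mesh: TriMesh, base_bc: str, pin_nodes: tuple = ()) -> BCSpec:
    """Boundary conditions of a growth run on a rectangle-derived mesh."""
    if base_bc == "clamp":
        return BCSpec(clamped_tags=("base",), pin_x_nodes=pin_nodes)
    base_nodes = mesh.boundary_nodes("base")
    mid_x = mesh.nodes[base_nodes, 0].mean()
    anchor = base_nodes[int(np.argmin(np.abs(mesh.nodes[base_nodes, 0] - mid_x)))]
    prescribed = {int(i): (None, 0.0) for i in base_nodes}
    prescribed[int(anchor)] = (0.0, 0.0)
    return BCSpec(clamped_tags=(), pin_x_nodes=pin_nodes, prescribed=prescribed)


def growth_step(rest_mesh: TriMesh, labels: np.ndarray, config: GrowthConfig,
                bcs: BCSpec, step: int | None = None):
    """One inflate/equilibrate/release iteration.

    Returns (new rest mesh with convected material axes, FieldState of the
    pre-release equilibrium).
    """
    pressures = effective_pressure(config.P, config.eta, labels == FRICTION_LABEL)
    state = solve_equilibrium(rest_mesh, config.params, pressures, bcs)
    new_nodes = rest_mesh.nodes + state.displacement
    F = deformation_gradients(rest_mesh.nodes, new_nodes, rest_mesh.triangles,
                              step=step)
    deformed = rest_mesh.with_nodes(new_nodes)
    axes = np.einsum("mij,mj->mi", F, rest_mesh.material_axes)
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    deformed.material_axes = axes
    deformed.element_labels = labels.copy()
    return deformed, state


def run_growth(mesh0: TriMesh, config: GrowthConfig) -> GrowthTrajectory:
    """Run the full growth loop and collect the trajectory.

    Deterministic given the config: seed only drives optional initial node
    jitter of relative amplitude ``config.jitter`` (interior nodes only), a
    robustness device, and defaults to none.
    """
    mesh = mesh0
    if config.jitter > 0:
        rng = np.random.default_rng(config.seed)
        nodes = mesh0.nodes.copy()
        bnodes = mesh0.boundary_nodes()
        interior = np.setdiff1d(np.arange(len(nodes)), bnodes)
        scale = config.jitter * np.min(
            np.linalg.norm(
                nodes[mesh0.triangles[:, 1]] - nodes[mesh0.triangles[:, 0]], axis=1
            )
        )
        nodes[interior] += rng.normal(scale=scale, size=(len(interior), 2))
        mesh = mesh0.with_nodes(nodes)

    labels = label_friction_elements(mesh, config.friction_region,
                                     require_nonempty=config.eta > 0)
    pin_nodes: tuple = ()
    if config.eta > 0 and config.pin_friction_boundary:
        pin_nodes = tuple(_pinned_boundary_nodes(mesh, config.friction_region))
    bcs = _base_bcs(mesh, config.base_bc, pin_nodes)
    log.info(
        "growth run: P=%.3g Pa eta=%.3g n_steps=%d band=%s %s depth=%.2f "
        "pinned=%d seed=%d",
        config.P, config.eta, config.n_steps, config.friction_region.side,
        config.friction_region.height_interval,
        config.friction_region.depth_fraction, len(pin_nodes), config.seed,
    )

    mesh.element_labels = labels.copy()
    meshes = [mesh]
    states = []
    summary = []
    for step in range(config.n_steps):
        mesh, state = growth_step(mesh, labels, config, bcs, step=step)
        meshes.append(mesh)
        states.append(state)
        summary.append(_step_summary(step, mesh, state, labels))
    return GrowthTrajectory(rest_meshes=meshes, fields=states,
                            summary=summary, config=config)


def _step_summary(step, mesh, state, labels):
    peak = int(np.argmax(state.von_mises))
    entry = {
        "step": step,
        "height_mm": float(mesh.nodes[:, 1].max() - mesh.nodes[:, 1].min()),
        "peak_von_mises_Pa": float(state.von_mises[peak]),
        "peak_element": peak,
        "peak_in_band": bool(labels[peak] == FRICTION_LABEL),
    }
    if "midline" in mesh.node_sets:
        dev, arclen, bend = _midline_metrics(mesh)
        entry["max_deflection_mm"] = float(np.max(np.abs(dev)))
        entry["midline_length_mm"] = float(arclen[-1])
        entry["bend_angle_deg"] = float(np.degrees(bend))
    return entry


# ---------------------------------------------------------------------------
# midline diagnostics
# ---------------------------------------------------------------------------

def _midline_metrics(mesh: TriMesh):
    idx = mesh.node_sets["midline"]
    pts = mesh.nodes[idx]
    base = pts[0]
    dev = pts[:, 0] - base[0]
    seg = np.diff(pts, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seglen)])
    # bend angle: largest deviation of any segment direction from the basal
    # segment direction
    dirs = seg / seglen[:, None]
    cosang = np.clip(dirs @ dirs[0], -1.0, 1.0)
    bend = float(np.max(np.arccos(cosang)))
    return dev, arclen, bend


def midline_deflection(mesh: TriMesh):
    """Signed horizontal deviation of the midline vs arclength, plus bend angle.

    The midline is the node column that started at x = width/2 on the
    initial rectangle (tracked by index through the run).  Deviation is
    measured from the vertical line through the base midpoint.  The bend
    angle (radians) is the maximum angle any midline segment makes with the
    basal segment direction.
    """
    if "midline" not in mesh.node_sets:
        raise GeometryError(
            "mesh has no 'midline' node set; midline diagnostics require a "
            "rectangle-derived mesh"
        )
    dev, arclen, bend = _midline_metrics(mesh)
    return dev, arclen, bend


def detect_buckling(trajectory: GrowthTrajectory, threshold: float = 0.1):
    """Classify the final shape as buckled and locate the fold.

    Buckled iff max |midline deflection| / midline length exceeds
    ``threshold`` on the final rest shape.  The fold location is the
    arclength fraction of the vertex of maximum turning angle (discrete
    curvature) of the final midline polyline.  Returns
    (buckled, fold_fraction) with fold_fraction = nan when straight.
    """
    if not trajectory.rest_meshes:
        raise ValueError("empty trajectory")
    mesh = trajectory.final_mesh
    dev, arclen, _ = midline_deflection(mesh)
    length = arclen[-1]
    buckled = bool(np.max(np.abs(dev)) / length > threshold)
    if not buckled:
        return False, float("nan")
    pts = mesh.nodes[mesh.node_sets["midline"]]
    seg = np.diff(pts, axis=0)
    dirs = seg / np.linalg.norm(seg, axis=1, keepdims=True)
    cosang = np.clip(np.einsum("ij,ij->i", dirs[:-1], dirs[1:]), -1.0, 1.0)
    turning = np.arccos(cosang)  # at interior vertices 1..n-2
    k = int(np.argmax(turning))
    fold_fraction = float(arclen[k + 1] / length)
    return True, fold_fraction


def stress_summary(trajectory: GrowthTrajectory):
    """Peak von Mises per step with a region classification of the final peak.

    The final-step peak element is classified as "band" (labelled friction
    element), "band_edge" (shares a node with the band), "below_band"
    (centroid below the lowest band centroid) or "elsewhere".
    """
    rows = []
    labels = trajectory.final_mesh.element_labels
    for step, (state, mesh) in enumerate(
        zip(trajectory.fields, trajectory.rest_meshes[1:])
    ):
        peak = int(np.argmax(state.von_mises))
        rows.append(
            {
                "step": step,
                "peak_von_mises_Pa": float(state.von_mises[peak]),
                "peak_element": peak,
                "peak_centroid": mesh.centroids()[peak].tolist(),
            }
        )
    final = rows[-1]
    final["peak_region"] = _classify_element(
        trajectory.final_mesh, labels, final["peak_element"]
    )
    return rows


def band_edge_fractions(trajectory: GrowthTrajectory):
    """Final arclength fractions of the friction band's lower and upper edges.

    The band is material, so its edges are located by interpolating the
    band's initial height interval along the midline (tracked by node index)
    of the final rest shape.  Useful for asking whether a fold sits below
    the band's lower edge after differential growth has shifted the
    fractions.
    """
    mesh0 = trajectory.rest_meshes[0]
    mesh = trajectory.final_mesh
    if "midline" not in mesh.node_sets:
        raise GeometryError("trajectory mesh has no 'midline' node set")
    idx = mesh.node_sets["midline"]
    y0 = mesh0.nodes[idx, 1]
    h0 = y0[-1] - y0[0]
    pts = mesh.nodes[idx]
    arclen = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))]
    )
    lo, hi = trajectory.config.friction_region.height_interval
    fr = []
    for f in (lo, hi):
        fr.append(float(np.interp(y0[0] + f * h0, y0, arclen) / arclen[-1]))
    return tuple(fr)


def _classify_element(mesh: TriMesh, labels: np.ndarray, elem: int) -> str:
    if not labels.any():
        return "elsewhere"
    if labels[elem] == FRICTION_LABEL:
        band = labels == FRICTION_LABEL
        cent = mesh.centroids()
        rows = np.unique(np.round(cent[band, 1], 9))
        if cent[elem, 1] <= rows.min() + 1e-9:
            return "band_lower_edge"
        return "band"
    band_nodes = np.unique(mesh.triangles[labels == FRICTION_LABEL])
    if np.intersect1d(mesh.triangles[elem], band_nodes).size:
        return "band_edge"
    cent = mesh.centroids()
    band_low = cent[labels == FRICTION_LABEL][:, 1].min()
    if cent[elem, 1] < band_low:
        return "below_band"
    return "elsewhere"
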