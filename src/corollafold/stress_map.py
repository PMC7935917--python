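"""Residual-stress estimation on a traced or synthetic cross-section outline.

A folded cross-section outline (traced from an image, or generated by
:func:`corollafold.geometry.synthetic_folded_outline`) is meshed and loaded
with a downward force representing the residual stress accumulated during
development — by default a traction of magnitude 4P on the distal (top)
boundary segment, with the basal segment clamped.  The resulting per-element
von Mises field highlights where a folded geometry concentrates stress
relative to a straight column under the same load.
"""

from __future__ import annotations

import numpy as np

from .constitutive import ElasticParams
from .errors import ConfigurationError
from .fem import BCSpec, FieldState, solve_equilibrium
from .geometry import Polygon2D, TriMesh, polygon_mesh

__all__ = ["residual_stress_field"]


def _segment_nodes(mesh: TriMesh, frac: float, top: bool) -> np.ndarray:
    idx = mesh.boundary_nodes("outline")
    y = mesh.nodes[idx, 1]
    ymin, ymax = mesh.nodes[:, 1].min(), mesh.nodes[:, 1].max()
    span = ymax - ymin
    if top:
        sel = y >= ymax - frac * span + 1e-12 * span
    else:
        sel = y <= ymin + frac * span - 1e-12 * span
    # include boundary exactly on the cut
    if top:
        sel = y >= ymax - frac * span
    else:
        sel = y <= ymin + frac * span
    return idx[sel]


def residual_stress_field(
    outline: Polygon2D,
    params: ElasticParams = ElasticParams(),
    P: float = 4.0e4,
    force_multiple: float = 4.0,
    target_edge: float = 0.05,
    clamp_fraction: float = 0.05,
    load_fraction: float = 0.05,
    as_body_force: bool = False,
):
    """Mesh the outline, load it downward, and return (TriMesh, FieldState).

    The basal boundary segment (outline nodes in the lowest
    ``clamp_fraction`` of the height) is clamped; a downward traction of
    magnitude ``force_multiple * P`` (Pa) is applied on boundary edges of
    the distal segment (topmost ``load_fraction``).  With
    ``as_body_force=True`` the same total is instead distributed as a body
    force over the whole section (force density force_multiple*P/height per
    unit area).
    """
    if force_multiple < 0:
        raise ConfigurationError("force_multiple must be >= 0")
    mesh = polygon_mesh(outline, target_edge)
    clamp = _segment_nodes(mesh, clamp_fraction, top=False)
    if clamp.size == 0:
        raise ConfigurationError("basal clamp segment is empty; increase "
                                 "clamp_fraction")
    traction = force_multiple * P
    loads = np.zeros_like(mesh.nodes)
    if as_body_force:
        height = mesh.nodes[:, 1].max() - mesh.nodes[:, 1].min()
        dens = traction / height  # Pa/mm, downward per unit area
        areas = mesh.signed_areas()
        for k in range(3):
            np.add.at(loads[:, 1], mesh.triangles[:, k], -dens * areas / 3.0)
    else:
        top = _segment_nodes(mesh, load_fraction, top=True)
        if top.size == 0:
            raise ConfigurationError("distal load segment is empty; increase "
                                     "load_fraction")
        topset = set(int(i) for i in top)
        edges = mesh.boundary_edges["outline"]
        n_loaded = 0
        for a, b in edges:
            if int(a) in topset and int(b) in topset:
                # vertical traction weighted by the edge's horizontal
                # projection: side edges inside the strip carry no load and
                # the total equals traction * projected width
                w = abs(mesh.nodes[b, 0] - mesh.nodes[a, 0])
                if w == 0.0:
                    continue
                loads[a, 1] -= 0.5 * traction * w
                loads[b, 1] -= 0.5 * traction * w
                n_loaded += 1
        if n_loaded == 0:
            raise ConfigurationError(
                "no boundary edge lies entirely in the distal load segment; "
                "increase load_fraction or refine the mesh"
            )
    bcs = BCSpec(clamped_tags=(), prescribed={int(i): (0.0, 0.0) for i in clamp})
    state = solve_equilibrium(mesh, params, 0.0, bcs, node_loads=loads)
    return mesh, state
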