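"""Linear plane-stress finite elements on triangle meshes.

Discretization: linear (P1) triangles with single-point quadrature, so
strain and stress are constant per element — the element-wise quantities the
growth model reports.  Turgor pressure enters as a per-element isotropic
eigenstress: the element stress is ``C eps(u) - p I``, so an unconstrained
element inflated by pressure p expands isotropically with strain
``p (1-nu)/E`` (isotropic case).  The resulting linear system is symmetric
positive definite once the Dirichlet constraints remove the three rigid-body
modes, and is solved with a sparse direct factorization (deterministic, no
iterative tolerance).

Stress bookkeeping: strains are formed in the global frame from nodal
displacements, rotated into each element's material frame (per-element
principal-stiffness axis), and the constitutive law plus eigenstress applied
there.  ``FieldState.stress`` therefore holds material-frame components
(s11 along the principal axis), which is the frame the von Mises readout is
defined in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .constitutive import ElasticParams, stiffness_matrix, von_mises
from .errors import ConstraintError, ElementInversionError, NumericalError
from .geometry import TriMesh

__all__ = ["BCSpec", "FieldState", "solve_equilibrium", "element_kinematics",
           "deformation_gradients", "elastic_energy"]


@dataclass(frozen=True)
class BCSpec:
    """Dirichlet boundary conditions.

    clamped_tags: boundary tags whose nodes have both components fixed at 0
    (the basal attachment to the receptacle by default).
    pin_x_tags / pin_x_nodes: boundary tags or explicit node indices whose
    horizontal displacement is fixed at 0 (the "no horizontal movement by
    attachment to the outer organ" condition at the friction zone).
    prescribed: explicit node -> (ux, uy) values, either component may be
    None to leave it free; used e.g. for patch tests.
    """

    clamped_tags: tuple = ("base",)
    pin_x_tags: tuple = ()
    pin_x_nodes: tuple = ()
    prescribed: dict = field(default_factory=dict)

    def constraint_arrays(self, mesh: TriMesh):
        """Return (fixed_mask, fixed_values) over the 2N displacement dofs."""
        n = len(mesh.nodes)
        fixed = np.zeros(2 * n, dtype=bool)
        vals = np.zeros(2 * n)
        for tag in self.clamped_tags:
            idx = mesh.boundary_nodes(tag)
            fixed[2 * idx] = True
            fixed[2 * idx + 1] = True
        for tag in self.pin_x_tags:
            idx = mesh.boundary_nodes(tag)
            fixed[2 * idx] = True
        for i in self.pin_x_nodes:
            fixed[2 * int(i)] = True
        for i, (ux, uy) in self.prescribed.items():
            if ux is not None:
                fixed[2 * int(i)] = True
                vals[2 * int(i)] = ux
            if uy is not None:
                fixed[2 * int(i) + 1] = True
                vals[2 * int(i) + 1] = uy
        return fixed, vals


@dataclass
class FieldState:
    """One equilibrium solve: nodal displacement and element fields.

    displacement: (N, 2), mm.  strain: (M, 3) global-frame tensor components
    (exx, eyy, exy).  stress: (M, 3) material-frame components
    (s11, s22, s12), Pa.  von_mises: (M,), Pa.
    """

    displacement: np.ndarray
    strain: np.ndarray
    stress: np.ndarray
    von_mises: np.ndarray

    def __post_init__(self):
        m = len(self.strain)
        if not (len(self.stress) == len(self.von_mises) == m):
            raise ValueError("field array lengths do not match")


def _b_matrices(mesh: TriMesh):
    """Per-element strain-displacement matrices (engineering Voigt).

    Returns (B, areas) with B of shape (M, 3, 6); dof order
    (ux0, uy0, ux1, uy1, ux2, uy2), strain order (exx, eyy, gamma_xy).
    """
    p = mesh.nodes[mesh.triangles]
    x, y = p[..., 0], p[..., 1]
    areas = 0.5 * ((x[:, 1] - x[:, 0]) * (y[:, 2] - y[:, 0])
                   - (x[:, 2] - x[:, 0]) * (y[:, 1] - y[:, 0]))
    M = len(areas)
    B = np.zeros((M, 3, 6))
    for k in range(3):
        j, l = (k + 1) % 3, (k + 2) % 3
        bk = (y[:, j] - y[:, l]) / (2 * areas)
        ck = (x[:, l] - x[:, j]) / (2 * areas)
        B[:, 0, 2 * k] = bk
        B[:, 1, 2 * k + 1] = ck
        B[:, 2, 2 * k] = ck
        B[:, 2, 2 * k + 1] = bk
    return B, areas


def _material_rotation_voigt(axes: np.ndarray) -> np.ndarray:
    """Engineering-Voigt strain rotation T (global -> material) per element.

    axes: (M, 2) unit material-axis-1 vectors in the global frame.
    eps_mat_eng = T @ eps_glob_eng; the stiffness transforms as T^T D T.
    """
    c = axes[:, 0]
    s = axes[:, 1]
    # angle phi of material axis 1 from global x: cos=c, sin=s
    T = np.zeros((len(axes), 3, 3))
    T[:, 0, 0] = c**2
    T[:, 0, 1] = s**2
    T[:, 0, 2] = s * c
    T[:, 1, 0] = s**2
    T[:, 1, 1] = c**2
    T[:, 1, 2] = -s * c
    T[:, 2, 0] = -2 * s * c
    T[:, 2, 1] = 2 * s * c
    T[:, 2, 2] = c**2 - s**2
    return T


def _element_stiffness_global(params: ElasticParams, axes: np.ndarray) -> np.ndarray:
    """(M, 3, 3) engineering-strain stiffness rotated to the global frame."""
    C = stiffness_matrix(params)
    D_mat = C.copy()
    D_mat[2, 2] = C[2, 2] / 2.0  # tensor-shear law -> engineering-shear Voigt
    T = _material_rotation_voigt(axes)
    return np.einsum("mki,kl,mlj->mij", T, D_mat, T)


def assemble(mesh: TriMesh, params: ElasticParams,
             element_pressure: np.ndarray | float = 0.0,
             node_loads: np.ndarray | None = None):
    """Assemble the stiffness matrix K and load vector f.

    element_pressure: scalar or (M,) eigenstress pressures, Pa.
    node_loads: optional (N, 2) consistent nodal forces (traction/body-force
    contributions computed by the caller).
    """
    B, areas = _b_matrices(mesh)
    if np.any(areas <= 0):
        raise ElementInversionError(int(np.argmin(areas)))
    D = _element_stiffness_global(params, mesh.material_axes)
    Ke = np.einsum("m,mki,mkl,mlj->mij", areas, B, D, B)

    tri = mesh.triangles
    dof = np.empty((len(tri), 6), dtype=np.int64)
    dof[:, 0::2] = 2 * tri
    dof[:, 1::2] = 2 * tri + 1
    rows = np.repeat(dof, 6, axis=1).ravel()
    cols = np.tile(dof, (1, 6)).ravel()
    n2 = 2 * len(mesh.nodes)
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n2, n2)).tocsr()

    p = np.broadcast_to(np.asarray(element_pressure, dtype=float),
                        (len(tri),))
    # eigenstress -p*I: internal force moves to the rhs as A * B^T (p, p, 0)
    pv = np.zeros((len(tri), 3))
    pv[:, 0] = p
    pv[:, 1] = p
    fe = np.einsum("m,mki,mk->mi", areas, B, pv)
    f = np.zeros(n2)
    np.add.at(f, dof.ravel(), fe.ravel())
    if node_loads is not None:
        f += np.asarray(node_loads, dtype=float).ravel()
    return K, f, B, areas, D


def solve_equilibrium(mesh: TriMesh, params: ElasticParams,
                      element_pressure: np.ndarray | float = 0.0,
                      bcs: BCSpec = BCSpec(),
                      node_loads: np.ndarray | None = None) -> FieldState:
    """Solve the linear elastic equilibrium and return the field state.

    Dirichlet constraints are satisfied exactly (eliminated from the
    system); the reduced solve is checked to a relative residual of 1e-10.
    """
    K, f, B, areas, _ = assemble(mesh, params, element_pressure, node_loads)
    fixed, vals = bcs.constraint_arrays(mesh)
    free = ~fixed
    if free.sum() == 2 * len(mesh.nodes):
        raise ConstraintError("no Dirichlet constraints: rigid-body modes present")

    u = np.zeros(2 * len(mesh.nodes))
    u[fixed] = vals[fixed]
    Kff = K[free][:, free]
    rhs = f[free] - K[free][:, fixed] @ vals[fixed]
    try:
        uf = spla.spsolve(Kff.tocsc(), rhs)
    except RuntimeError as exc:  # pragma: no cover - singular factorization
        raise ConstraintError(f"singular stiffness matrix: {exc}") from exc
    if not np.all(np.isfinite(uf)):
        raise ConstraintError(
            "singular or under-constrained system (non-finite solution); "
            "check that boundary conditions remove all rigid-body modes"
        )
    u[free] = uf
    res = np.linalg.norm(Kff @ uf - rhs)
    scale = max(np.linalg.norm(rhs), np.linalg.norm(Kff @ uf), 1e-300)
    if scale > 0 and res / scale > 1e-10:
        raise NumericalError(f"linear solve residual {res / scale:.2e} > 1e-10")

    return _postprocess(mesh, params, element_pressure, u, B)


def _postprocess(mesh, params, element_pressure, u, B):
    tri = mesh.triangles
    dof = np.empty((len(tri), 6), dtype=np.int64)
    dof[:, 0::2] = 2 * tri
    dof[:, 1::2] = 2 * tri + 1
    ue = u[dof]
    eps_eng = np.einsum("mij,mj->mi", B, ue)  # (exx, eyy, gamma)
    strain = eps_eng.copy()
    strain[:, 2] /= 2.0  # tensor shear for reporting

    T = _material_rotation_voigt(mesh.material_axes)
    eps_mat_eng = np.einsum("mij,mj->mi", T, eps_eng)
    eps_mat = eps_mat_eng.copy()
    eps_mat[:, 2] /= 2.0
    C = stiffness_matrix(params)
    stress = eps_mat @ C.T
    p = np.broadcast_to(np.asarray(element_pressure, dtype=float), (len(tri),))
    stress = stress - np.column_stack([p, p, np.zeros_like(p)])
    vm = von_mises(stress[:, 0], stress[:, 1])
    return FieldState(displacement=u.reshape(-1, 2), strain=strain,
                      stress=stress, von_mises=vm)


def elastic_energy(mesh: TriMesh, params: ElasticParams,
                   displacement: np.ndarray) -> float:
    """Strain energy 1/2 u^T K u of a displacement field (no eigenstress)."""
    K, _, _, _, _ = assemble(mesh, params, 0.0)
    u = np.asarray(displacement, dtype=float).ravel()
    return 0.5 * float(u @ (K @ u))


def deformation_gradients(nodes_rest: np.ndarray, nodes_deformed: np.ndarray,
                          triangles: np.ndarray,
                          step: int | None = None) -> np.ndarray:
    """Per-element deformation gradient F mapping rest to deformed edges.

    Raises ElementInversionError (with the offending element index, and the
    growth step when given) if any element has det F <= 0.
    """
    p0 = np.asarray(nodes_rest)[triangles]
    p1 = np.asarray(nodes_deformed)[triangles]
    E0 = np.stack([p0[:, 1] - p0[:, 0], p0[:, 2] - p0[:, 0]], axis=-1)
    E1 = np.stack([p1[:, 1] - p1[:, 0], p1[:, 2] - p1[:, 0]], axis=-1)
    F = np.einsum("mij,mjk->mik", E1, np.linalg.inv(E0))
    det = np.linalg.det(F)
    if np.any(det <= 0):
        raise ElementInversionError(int(np.argmin(det)), step)
    return F


def element_kinematics(mesh_rest: TriMesh, mesh_deformed: TriMesh,
                       step: int | None = None) -> np.ndarray:
    """Per-element deformation gradient between two meshes sharing
    connectivity (see deformation_gradients)."""
    if not np.array_equal(mesh_rest.triangles, mesh_deformed.triangles):
        raise ValueError("meshes do not share connectivity")
    return deformation_gradients(mesh_rest.nodes, mesh_deformed.nodes,
                                 mesh_rest.triangles, step=step)
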