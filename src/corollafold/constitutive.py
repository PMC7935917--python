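"""Anisotropic plane-stress constitutive law for growing petal tissue.

The tissue is modelled as a linearly elastic, transversely anisotropic sheet
in plane stress.  With stress and strain expressed in the material frame
(axis 1 = principal stiffness direction, by default the proximodistal /
vertical axis), the law is

    (s11, s22, s12)^T = E/(1-nu^2) * M @ (e11, e22, e12)^T

with

    M = [[1+a,  nu*sqrt((1+a)(1-a)),  0       ],
         [nu*sqrt((1+a)(1-a)),  1-a,  0       ],
         [0,    0,                    b/(1+nu)]]

where ``E`` is the geometric-mean Young's modulus, ``nu`` the Poisson ratio,
``a`` (alpha) the stiffness anisotropy index and ``b`` (beta) the shear
factor.  Note the shear entry sits inside the E/(1-nu^2) prefactor and does
not reduce to the textbook isotropic shear modulus at beta=1; the law is
implemented in this form deliberately because it is the operative model.

Growth is driven by turgor pressure ``P`` entering as an isotropic
eigenstress: each element carries stress ``M@eps - p*I`` and therefore tends
to expand isotropically.  Organ-organ friction locally reduces the turgor to
``(1-eta)*P`` (eta=0: free growth, eta=1: no growth in the contact zone).

The scalar stress readout is a von Mises-type intensity computed per
triangle from the material-frame normal stresses only:

    MS = sqrt((s11 - s22)^2 / 2)

The shear component is deliberately not part of this readout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError

__all__ = [
    "ElasticParams",
    "StressTensor2D",
    "StrainTensor2D",
    "stiffness_matrix",
    "stress_from_strain",
    "von_mises",
    "effective_pressure",
]


@dataclass(frozen=True)
class ElasticParams:
    """Constitutive constants of the petal sheet.

    Parameters
    ----------
    E : float
        Geometric-mean Young's modulus, Pa.  Must be positive.
    nu : float
        Poisson ratio, in [0, 0.5).
    alpha : float
        Stiffness anisotropy index, in [0, 1).  The two in-plane moduli are
        E*(1+alpha) and E*(1-alpha); alpha=0 recovers isotropy.
    beta : float
        Dimensionless shear factor, > 0.
    swap_anisotropy_axes : bool
        If True the (1+alpha) and (1-alpha) diagonal entries are exchanged,
        i.e. the softer axis becomes the principal one.  Off by default; the
        default follows the stiffness matrix as written, which places
        (1+alpha) on the s11 row.
    """

    E: float = 3.0e6
    nu: float = 0.4
    alpha: float = 0.1
    beta: float = 0.9
    swap_anisotropy_axes: bool = False

    def __post_init__(self) -> None:
        if not (self.E > 0):
            raise ParameterError(f"E must be > 0, got {self.E}")
        if not (0.0 <= self.nu < 0.5):
            raise ParameterError(f"nu must satisfy 0 <= nu < 0.5, got {self.nu}")
        if not (0.0 <= self.alpha < 1.0):
            raise ParameterError(f"alpha must satisfy 0 <= alpha < 1, got {self.alpha}")
        if not (self.beta > 0):
            raise ParameterError(f"beta must be > 0, got {self.beta}")


@dataclass(frozen=True)
class StressTensor2D:
    """Symmetric 2D stress tensor (s12 == s21 stored once), Pa."""

    s11: float
    s22: float
    s12: float = 0.0


@dataclass(frozen=True)
class StrainTensor2D:
    """Symmetric 2D small-strain tensor (tensor shear e12, not engineering)."""

    e11: float
    e22: float
    e12: float = 0.0


def stiffness_matrix(params: ElasticParams) -> np.ndarray:
    """Return the 3x3 material-frame stiffness matrix (Pa).

    Maps (e11, e22, e12) -> (s11, s22, s12) with tensor (not engineering)
    shear strain.  Symmetric positive definite for all valid parameters.
    """
    E, nu, a, b = params.E, params.nu, params.alpha, params.beta
    if params.swap_anisotropy_axes:
        a = -a
    off = nu * np.sqrt((1.0 + a) * (1.0 - a))
    M = np.array(
        [
            [1.0 + a, off, 0.0],
            [off, 1.0 - a, 0.0],
            [0.0, 0.0, b / (1.0 + nu)],
        ]
    )
    return (E / (1.0 - nu**2)) * M


def _rotation(axis_angle: float) -> np.ndarray:
    """Material basis matrix R whose columns are the material axes.

    ``axis_angle`` is measured counter-clockwise from the global +y
    (proximodistal) direction, so axis_angle=0 means the principal stiffness
    axis is vertical:  e1 = (-sin t, cos t), e2 = (cos t, sin t) rotated to
    stay right-handed.
    """
    phi = axis_angle + np.pi / 2.0  # angle of material axis 1 from global +x
    c, s = np.cos(phi), np.sin(phi)
    return np.array([[c, -s], [s, c]])


def stress_from_strain(
    params: ElasticParams,
    strain: StrainTensor2D,
    axis_angle: float = 0.0,
) -> StressTensor2D:
    """Apply the constitutive law with the material axis at ``axis_angle``.

    The strain (given in the global frame) is rotated into the material
    frame, the stiffness matrix applied, and the stress rotated back to the
    global frame.  Linear in strain; axis_angle is measured from the global
    vertical.
    """
    if not np.isfinite(axis_angle):
        raise ParameterError("axis_angle must be finite")
    eps = np.array(
        [[strain.e11, strain.e12], [strain.e12, strain.e22]], dtype=float
    )
    if not np.all(np.isfinite(eps)):
        raise ParameterError("strain components must be finite")
    R = _rotation(axis_angle)
    eps_m = R.T @ eps @ R
    C = stiffness_matrix(params)
    sv = C @ np.array([eps_m[0, 0], eps_m[1, 1], eps_m[0, 1]])
    sig_m = np.array([[sv[0], sv[2]], [sv[2], sv[1]]])
    sig = R @ sig_m @ R.T
    return StressTensor2D(s11=sig[0, 0], s22=sig[1, 1], s12=sig[0, 1])


def von_mises(stress, s22=None):
    """Per-element von Mises stress intensity, MS = sqrt((s11-s22)^2/2).

    Accepts either a :class:`StressTensor2D` (or anything with s11/s22
    attributes) or two arrays/scalars of normal stresses.  The shear
    component does not enter this readout.
    """
    if s22 is None:
        s11, s22 = stress.s11, stress.s22
    else:
        s11 = stress
    return np.sqrt(np.square(np.asarray(s11) - np.asarray(s22)) / 2.0)


def effective_pressure(P, eta, in_friction_region):
    """Turgor pressure after friction-induced reduction.

    Returns ``P`` outside the friction region and ``(1-eta)*P`` inside it.
    eta=0 leaves growth unaffected; eta=1 suppresses it entirely in the
    contact zone.  Vectorized over ``in_friction_region``.
    """
    P = np.asarray(P, dtype=float)
    eta = float(eta)
    if not (0.0 <= eta <= 1.0):
        raise ParameterError(f"eta must lie in [0, 1], got {eta}")
    if np.any(P < 0):
        raise ParameterError("P must be >= 0")
    mask = np.asarray(in_friction_region, dtype=bool)
    out = np.where(mask, (1.0 - eta) * P, P)
    return out if out.ndim else float(out)
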