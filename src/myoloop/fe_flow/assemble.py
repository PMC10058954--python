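"""Element matrices and global assembly for the mixed formulation.

Velocity dofs are ordered component-blocked: all x-velocities first,
then all y-velocities, so every scalar operator (mass, viscous
stiffness, lagged convection) assembles once on the scalar space and is
expanded with a Kronecker product. The divergence block couples both
components to the pressure space.

All integrals use 3x3 Gauss quadrature, exact for the bilinear-mapped
biquadratic products involved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from ..errors import MeshError, ParameterError
from .mesh import CORNER_LOCALS, Mesh2D

__all__ = [
    "FluidProperties",
    "assemble_mass",
    "assemble_velocity_stiffness",
    "assemble_divergence",
]


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid: dynamic viscosity (Pa s) and density (kg/m^3)."""

    dynamic_viscosity: float
    density: float

    def __post_init__(self) -> None:
        if not (self.dynamic_viscosity > 0 and self.density > 0):
            raise ParameterError("viscosity and density must be > 0")


# ----- reference-element shape functions -----------------------------------

_GP = np.array([-np.sqrt(3.0 / 5.0), 0.0, np.sqrt(3.0 / 5.0)])
_GW = np.array([5.0 / 9.0, 8.0 / 9.0, 5.0 / 9.0])


def _shape1d_q2(x):
    n = np.array([x * (x - 1) / 2, 1 - x * x, x * (x + 1) / 2])
    dn = np.array([x - 0.5, -2 * x, x + 0.5])
    return n, dn


def _shape1d_q1(x):
    return np.array([(1 - x) / 2, (1 + x) / 2]), np.array([-0.5, 0.5])


def _tabulate():
    """Shape values/derivatives at the 9 quadrature points."""
    pts = [(xi, eta, wx * wy)
           for eta, wy in zip(_GP, _GW) for xi, wx in zip(_GP, _GW)]
    n9 = np.empty((9, 9))
    d9 = np.empty((9, 9, 2))
    n4 = np.empty((9, 4))
    for q, (xi, eta, _) in enumerate(pts):
        nx, dnx = _shape1d_q2(xi)
        ny, dny = _shape1d_q2(eta)
        for j in range(3):
            for i in range(3):
                k = 3 * j + i
                n9[q, k] = nx[i] * ny[j]
                d9[q, k] = (dnx[i] * ny[j], nx[i] * dny[j])
        lx, _ = _shape1d_q1(xi)
        ly, _ = _shape1d_q1(eta)
        for j in range(2):
            for i in range(2):
                n4[q, 2 * j + i] = lx[i] * ly[j]
    w = np.array([p[2] for p in pts])
    return n9, d9, n4, w


_N9, _D9, _N4, _W = _tabulate()


def _element_geometry(coords: np.ndarray, elem_id: int):
    """Jacobians, physical shape-function gradients and weighted measures.

    Returns (dn_xy with shape (9, 9, 2), wdet with shape (9,)).
    """
    # J[q] = d(x,y)/d(xi,eta): 2x2 per quadrature point
    j = np.einsum("qkd,ke->qde", _D9, coords)  # (9, 2, 2) with d=(xi,eta), e=(x,y)
    det = j[:, 0, 0] * j[:, 1, 1] - j[:, 0, 1] * j[:, 1, 0]
    if np.any(det <= 0):
        raise MeshError(
            f"non-positive Jacobian in element {elem_id} "
            f"(min det = {det.min():.3g}); the element is inverted or degenerate"
        )
    inv = np.empty_like(j)
    inv[:, 0, 0] = j[:, 1, 1] / det
    inv[:, 0, 1] = -j[:, 0, 1] / det
    inv[:, 1, 0] = -j[:, 1, 0] / det
    inv[:, 1, 1] = j[:, 0, 0] / det
    # physical gradient: dN/dx_e = sum_d dN/dxi_d * dxi_d/dx_e, and
    # dxi_d/dx_e = (J^{-1})^T[d, e] for J[d, e] = dx_e/dxi_d
    dn_xy = np.einsum("qkd,qed->qke", _D9, inv)
    return dn_xy, _W * det


def _scalar_to_vector(ms: sparse.spmatrix) -> sparse.csr_matrix:
    """Expand a scalar-space operator to the 2-component velocity space."""
    return sparse.kron(sparse.eye(2), ms, format="csr")


def assemble_mass(mesh: Mesh2D, props: FluidProperties) -> sparse.csr_matrix:
    """Consistent mass matrix M = rho * integral(N^T N), symmetric."""
    n = mesh.n_nodes
    ms = sparse.lil_matrix((n, n))
    for e, conn in enumerate(mesh.elements):
        _, wdet = _element_geometry(mesh.node_coords[conn], e)
        me = props.density * np.einsum("q,qa,qb->ab", wdet, _N9, _N9)
        ms[np.ix_(conn, conn)] += me
    return _scalar_to_vector(ms.tocsr())


def assemble_velocity_stiffness(
    mesh: Mesh2D,
    props: FluidProperties,
    v_lagged: np.ndarray | None = None,
) -> sparse.csr_matrix:
    """Viscous plus Picard-lagged convective stiffness on the velocity space.

    With ``v_lagged`` absent or zero this is the pure (symmetric) viscous
    operator mu * integral(grad N : grad N); otherwise the convective
    term rho * integral(N^T (u_lagged . grad) N) is added, with the
    advecting field interpolated from the previous iterate — the
    standard lagged-convection linearisation of the incremental-
    iterative scheme.
    """
    n = mesh.n_nodes
    if v_lagged is not None:
        v_lagged = np.asarray(v_lagged, float)
        if v_lagged.shape != (2 * n,):
            raise ParameterError(
                f"v_lagged has shape {v_lagged.shape}, expected ({2 * n},)"
            )
    ks = sparse.lil_matrix((n, n))
    for e, conn in enumerate(mesh.elements):
        dn_xy, wdet = _element_geometry(mesh.node_coords[conn], e)
        ke = props.dynamic_viscosity * np.einsum(
            "q,qae,qbe->ab", wdet, dn_xy, dn_xy
        )
        if v_lagged is not None:
            ux = _N9 @ v_lagged[conn]  # (9,) advecting velocity at q-points
            uy = _N9 @ v_lagged[n + conn]
            adv = ux[:, None] * dn_xy[:, :, 0] + uy[:, None] * dn_xy[:, :, 1]
            ke = ke + props.density * np.einsum("q,qa,qb->ab", wdet, _N9, adv)
        ks[np.ix_(conn, conn)] += ke
    return _scalar_to_vector(ks.tocsr())


def assemble_divergence(mesh: Mesh2D) -> sparse.csr_matrix:
    """Discrete divergence B mapping velocities to the pressure space.

    ``B[p, :] @ V = integral(N_p * div v)``; the momentum gradient block
    is exactly ``-B.T`` (the transpose relation of the mixed system).
    """
    n = mesh.n_nodes
    npres = mesh.n_pressure
    pelems = mesh.pressure_elements()
    b = sparse.lil_matrix((npres, 2 * n))
    for e, conn in enumerate(mesh.elements):
        dn_xy, wdet = _element_geometry(mesh.node_coords[conn], e)
        pconn = pelems[e]
        bx = np.einsum("q,qp,qa->pa", wdet, _N4, dn_xy[:, :, 0])
        by = np.einsum("q,qp,qa->pa", wdet, _N4, dn_xy[:, :, 1])
        b[np.ix_(pconn, conn)] += bx
        b[np.ix_(pconn, n + conn)] += by
    return b.tocsr()
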