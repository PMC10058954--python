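"""Incremental-iterative solution of the mixed system and boundary forces.

Each time step solves the saddle-point system

    [ M/dt + Kvv(V_lagged)   -B^T ] [V]   [F + M/dt V_old]
    [ B                        0  ] [P] = [0]

with the convective part of Kvv lagged at the previous iterate (Picard)
and iterated until the relative velocity change falls below tolerance.
Omitting ``dt`` solves the steady problem (the M/dt terms drop out).
Velocity Dirichlet conditions are eliminated row-and-column; when no
natural (traction) boundary fixes the pressure level, one pressure node
is pinned to zero.

After convergence, the momentum operator applied to (V; P) and
restricted to a tagged boundary yields the nodal reaction forces that a
loosely coupled structural solver receives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from ..errors import ConvergenceError, ParameterError
from .assemble import (
    FluidProperties,
    assemble_divergence,
    assemble_mass,
    assemble_velocity_stiffness,
)
from .mesh import Mesh2D

__all__ = ["FESystem", "BoundaryConditions", "BoundaryForce", "solve_time_step", "boundary_force"]


@dataclass
class BoundaryConditions:
    """Velocity Dirichlet constraints plus an optional pressure pin."""

    dirichlet: dict = field(default_factory=dict)  # (node, component) -> value
    pinned_pressure_node: int | None = None

    def set_velocity(self, mesh: Mesh2D, tag: str, vx=None, vy=None) -> "BoundaryConditions":
        """Prescribe velocity components on a tagged boundary.

        ``vx``/``vy`` may be constants or callables of (x, y); ``None``
        leaves that component free.
        """
        for node in mesh.boundary_nodes(tag):
            x, y = mesh.node_coords[node]
            for comp, v in ((0, vx), (1, vy)):
                if v is None:
                    continue
                self.dirichlet[(node, comp)] = float(v(x, y)) if callable(v) else float(v)
        return self

    def pin_pressure(self, node: int = 0) -> "BoundaryConditions":
        self.pinned_pressure_node = node
        return self


@dataclass
class BoundaryForce:
    """Per-node force vectors (N per unit depth) on a tagged boundary."""

    nodes: np.ndarray  # (k,)
    forces: np.ndarray  # (k, 2), global coordinates

    @property
    def total(self) -> np.ndarray:
        return self.forces.sum(axis=0)


class FESystem:
    """Assembled operators and current fields of the mixed FE problem."""

    def __init__(
        self,
        mesh: Mesh2D,
        props: FluidProperties,
        dt: float | None = None,
        include_convection: bool = True,
    ):
        if dt is not None and not dt > 0:
            raise ParameterError("dt must be positive (or None for steady)")
        self.mesh = mesh
        self.props = props
        self.dt = dt
        self.include_convection = include_convection
        self.mass = assemble_mass(mesh, props)
        self.divergence = assemble_divergence(mesh)
        self.v = np.zeros(2 * mesh.n_nodes)
        self.v_old = np.zeros(2 * mesh.n_nodes)
        self.p = np.zeros(mesh.n_pressure)
        self.f_ext = np.zeros(2 * mesh.n_nodes)
        self.iteration = 0

    def velocity_stiffness(self, v_lagged: np.ndarray | None) -> sparse.csr_matrix:
        return assemble_velocity_stiffness(
            self.mesh,
            self.props,
            v_lagged if self.include_convection else None,
        )

    def momentum_operator(self, v_lagged: np.ndarray | None) -> sparse.csr_matrix:
        """M/dt + Kvv(v_lagged); the transient part drops for steady solves."""
        k = self.velocity_stiffness(v_lagged)
        if self.dt is not None:
            k = k + self.mass / self.dt
        return k


def _solve_constrained(a, rhs, fixed: dict) -> np.ndarray:
    """Solve with Dirichlet dofs eliminated to a reduced system."""
    ndof = rhs.size
    idx = np.fromiter(fixed.keys(), dtype=int, count=len(fixed))
    vals = np.fromiter(fixed.values(), dtype=float, count=len(fixed))
    free = np.setdiff1d(np.arange(ndof), idx)
    acsc = a.tocsc()
    rhs_red = rhs[free] - acsc[:, idx][free] @ vals
    a_red = acsc[:, free][free]
    sol = np.empty(ndof)
    sol[free] = spsolve(a_red.tocsc(), rhs_red)
    sol[idx] = vals
    return sol


def solve_time_step(
    system: FESystem,
    bc: BoundaryConditions,
    tol: float = 1e-10,
    max_iter: int = 30,
):
    """Advance one (or the steady) step of the incremental-iterative solve.

    Returns ``(V, P, iterations)``. The convective operator is
    re-assembled from the previous iterate each pass; for Stokes flow
    (``include_convection=False``) a single pass is exact. Raises
    :class:`ConvergenceError` with the residual history if ``max_iter``
    is hit.
    """
    mesh = system.mesh
    n = mesh.n_nodes
    npres = mesh.n_pressure
    b = system.divergence

    fixed = {}
    for (node, comp), val in bc.dirichlet.items():
        fixed[comp * n + node] = val
    if bc.pinned_pressure_node is not None:
        pdof = mesh.pressure_map[bc.pinned_pressure_node]
        if pdof < 0:
            raise ParameterError(
                f"node {bc.pinned_pressure_node} carries no pressure dof"
            )
        fixed[2 * n + pdof] = 0.0

    v = system.v.copy()
    # seed Dirichlet values so the first lagged assembly sees them
    for dof, val in fixed.items():
        if dof < 2 * n:
            v[dof] = val

    rhs_mom = system.f_ext.copy()
    if system.dt is not None:
        rhs_mom = rhs_mom + system.mass @ system.v_old / system.dt

    history = []
    for it in range(1, max_iter + 1):
        a_vv = system.momentum_operator(v)
        a_full = sparse.bmat(
            [[a_vv, -b.T], [b, None]], format="csr"
        )
        rhs = np.concatenate([rhs_mom, np.zeros(npres)])
        sol = _solve_constrained(a_full, rhs, fixed)
        v_new, p_new = sol[: 2 * n], sol[2 * n :]
        dv = np.linalg.norm(v_new - v) / max(np.linalg.norm(v_new), 1e-300)
        history.append(dv)
        v = v_new
        if dv < tol or not system.include_convection:
            system.v, system.p, system.iteration = v, p_new, it
            return v, p_new, it
    raise ConvergenceError(
        f"Picard iteration did not reach tol={tol} in {max_iter} iterations "
        f"(last relative change {history[-1]:.3g})",
        residual_history=history,
    )


def divergence_residual(system: FESystem, v: np.ndarray) -> float:
    """Relative discrete divergence residual ||B V|| / ||V||."""
    return float(
        np.linalg.norm(system.divergence @ v) / max(np.linalg.norm(v), 1e-300)
    )


def boundary_force(
    system: FESystem,
    v: np.ndarray,
    p: np.ndarray,
    boundary_tag: str,
) -> BoundaryForce:
    """Nodal reaction forces on a tagged boundary from the converged fields.

    Applies the assembled momentum operator (including the transient
    term when a time step is set) to (V; P) minus the external load and
    restricts the residual to the boundary nodes. The result is the
    force the boundary exerts on the fluid, the vector handed to the
    structure in loose coupling.
    """
    mesh = system.mesh
    n = mesh.n_nodes
    nodes = mesh.boundary_nodes(boundary_tag)
    r = system.velocity_stiffness(v) @ v - system.divergence.T @ p - system.f_ext
    if system.dt is not None:
        r = r + system.mass @ (v - system.v_old) / system.dt
    forces = np.column_stack([r[nodes], r[n + nodes]])
    return BoundaryForce(nodes=nodes, forces=forces)
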