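"""Mixed FE kernel: assembly identities, analytic solutions, conservation."""

import numpy as np
import pytest

from myoloop import fe_flow as ff
from myoloop.errors import MeshError, ParameterError
from myoloop.fe_flow.assemble import (
    assemble_divergence,
    assemble_mass,
    assemble_velocity_stiffness,
)
from myoloop.fe_flow.solve import divergence_residual

from conftest import CHANNEL_HEIGHT, CHANNEL_LENGTH, MEAN_VELOCITY, channel_bcs, poiseuille_profile

PROPS = ff.FluidProperties(dynamic_viscosity=1.0, density=1.0)


def shoelace_area(corners):
    x, y = corners[:, 0], corners[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


class TestMassMatrix:
    def test_partition_of_unity_on_unit_square(self):
        mesh = ff.rect_mesh(1, 1, 1.0, 1.0)
        m = assemble_mass(mesh, PROPS)
        n = mesh.n_nodes
        assert m[:n, :n].sum() == pytest.approx(1.0, rel=1e-12)

    def test_symmetric_to_machine_precision(self):
        mesh = ff.rect_mesh(3, 2, 1.0, 0.5, distortion=0.03)
        m = assemble_mass(mesh, PROPS)
        assert abs(m - m.T).max() < 1e-15 * abs(m).max()

    def test_total_mass_matches_independent_area_oracle(self):
        """rho=2 on a 2x2 unit-square mesh: total mass per component is
        rho times the summed shoelace areas of the element corners."""
        mesh = ff.rect_mesh(2, 2, 1.0, 1.0)
        props = ff.FluidProperties(1.0, 2.0)
        m = assemble_mass(mesh, props)
        n = mesh.n_nodes
        area = sum(
            shoelace_area(mesh.node_coords[conn[[0, 2, 8, 6]]])
            for conn in mesh.elements
        )
        assert m[:n, :n].sum() == pytest.approx(2.0 * area, rel=1e-12)
        assert area == pytest.approx(1.0)

    def test_inverted_element_raises_naming_the_element(self):
        mesh = ff.rect_mesh(2, 1, 1.0, 1.0)
        bad = mesh.elements.copy()
        bad[1][[0, 2]] = bad[1][[2, 0]]  # swap two corners -> tangled element
        broken = ff.Mesh2D(mesh.node_coords, bad, mesh.boundary_tags)
        with pytest.raises(MeshError, match="element 1"):
            assemble_mass(broken, PROPS)


class TestVelocityStiffness:
    def test_without_lagged_velocity_it_is_the_symmetric_viscous_operator(self):
        mesh = ff.rect_mesh(2, 2, 1.0, 1.0, distortion=0.02)
        k = assemble_velocity_stiffness(mesh, PROPS, None)
        assert abs(k - k.T).max() < 1e-14

    def test_constant_field_in_viscous_null_space(self):
        mesh = ff.rect_mesh(3, 3, 1.0, 1.0, distortion=0.02)
        k = assemble_velocity_stiffness(mesh, PROPS, None)
        v = np.concatenate([np.full(mesh.n_nodes, 2.0), np.full(mesh.n_nodes, -1.0)])
        assert np.abs(k @ v).max() < 1e-12

    def test_matches_finite_difference_of_the_weak_form_energy(self):
        """K v equals the central finite-difference gradient of the viscous
        energy 1/2 mu int(grad v : grad v) on a distorted element."""
        mesh = ff.rect_mesh(1, 1, 1.0, 1.0, distortion=0.05)
        k = assemble_velocity_stiffness(mesh, PROPS, None).toarray()
        rng = np.random.default_rng(7)
        v = rng.normal(size=2 * mesh.n_nodes)

        def energy(vv):
            return 0.5 * vv @ k @ vv

        g = k @ v
        eps = 1e-6
        for i in range(0, v.size, 3):
            e = np.zeros_like(v)
            e[i] = eps
            fd = (energy(v + e) - energy(v - e)) / (2 * eps)
            assert fd == pytest.approx(g[i], rel=1e-6, abs=1e-9)

    def test_lagged_velocity_shape_mismatch_raises(self):
        mesh = ff.rect_mesh(2, 2, 1.0, 1.0)
        with pytest.raises(ParameterError):
            assemble_velocity_stiffness(mesh, PROPS, np.zeros(7))


class TestDivergence:
    def test_constant_velocity_has_zero_divergence(self):
        mesh = ff.rect_mesh(3, 2, 1.0, 0.5, distortion=0.03)
        b = assemble_divergence(mesh)
        n = mesh.n_nodes
        v = np.concatenate([np.ones(n), 3.0 * np.ones(n)])
        assert np.abs(b @ v).max() < 1e-13

    def test_solenoidal_linear_field_has_zero_divergence(self):
        mesh = ff.rect_mesh(3, 3, 1.0, 1.0, distortion=0.02)
        x, y = mesh.node_coords.T
        v = np.concatenate([x, -y])
        assert np.abs(assemble_divergence(mesh) @ v).max() < 1e-13

    def test_dilating_field_integrates_to_twice_the_area(self):
        mesh = ff.rect_mesh(3, 2, 1.0, 0.5, distortion=0.03)
        x, y = mesh.node_coords.T
        total = (assemble_divergence(mesh) @ np.concatenate([x, y])).sum()
        assert total == pytest.approx(2.0 * 0.5, rel=1e-12)


class TestChannelFlow:
    def test_poiseuille_centerline_velocity(self, poiseuille_solution):
        mesh, system, v, p = poiseuille_solution
        n = mesh.n_nodes
        center = np.isclose(mesh.node_coords[:, 1], CHANNEL_HEIGHT / 2)
        assert v[:n][center] == pytest.approx(1.5 * MEAN_VELOCITY, rel=1e-9)

    def test_outlet_profile_is_parabolic(self, poiseuille_solution):
        mesh, system, v, p = poiseuille_solution
        n = mesh.n_nodes
        outlet = mesh.boundary_nodes("right")
        exact = np.array([poiseuille_profile(x, y) for x, y in mesh.node_coords[outlet]])
        assert np.allclose(v[:n][outlet], exact, atol=1e-9)

    def test_discrete_incompressibility(self, poiseuille_solution):
        mesh, system, v, p = poiseuille_solution
        assert divergence_residual(system, v) < 1e-8

    def test_wall_traction_matches_plane_poiseuille(self, poiseuille_solution):
        """Tangential wall force per unit length is 6 mu U / h within 5%."""
        mesh, system, v, p = poiseuille_solution
        expected = 6.0 * 1.0 * MEAN_VELOCITY / CHANNEL_HEIGHT * CHANNEL_LENGTH
        for tag in ("bottom", "top"):
            force = ff.boundary_force(system, v, p, tag).total[0]
            assert abs(force) == pytest.approx(expected, rel=0.05)

    def test_global_force_balance_on_closed_boundary(self, poiseuille_solution):
        """Summed boundary forces vanish for the steady solution (momentum
        conservation: interior residuals are zero, convection vanishes for
        the fully developed profile)."""
        mesh, system, v, p = poiseuille_solution
        total = np.zeros(2)
        scale = 0.0
        for tag in ("left", "right", "top", "bottom"):
            bf = ff.boundary_force(system, v, p, tag)
            # shared corner nodes appear in two tags; sum unique nodes instead
            scale += np.abs(bf.forces).sum()
        allb = mesh.all_boundary_nodes()
        n = mesh.n_nodes
        r = (system.velocity_stiffness(v) @ v - system.divergence.T @ p)
        total = np.array([r[allb].sum(), r[n + allb].sum()])
        assert np.abs(total).max() < 1e-9 * max(scale, 1.0)

    def test_refinement_decreases_error_on_curved_meshes(self):
        errors = []
        for nx, ny in ((6, 4), (12, 8)):
            mesh = ff.rect_mesh(nx, ny, CHANNEL_LENGTH, CHANNEL_HEIGHT, distortion=0.02)
            system = ff.FESystem(mesh, PROPS, include_convection=False)
            v, p, _ = ff.solve_time_step(system, channel_bcs(mesh))
            n = mesh.n_nodes
            exact = np.array([poiseuille_profile(x, y) for x, y in mesh.node_coords])
            errors.append(np.linalg.norm(v[:n] - exact) / np.linalg.norm(exact))
        assert errors[1] < errors[0]

    def test_zero_inflow_gives_zero_flow(self):
        mesh = ff.rect_mesh(6, 4, 1.0, 0.2)
        system = ff.FESystem(mesh, PROPS)
        bc = ff.BoundaryConditions()
        for tag in ("left", "top", "bottom"):
            bc.set_velocity(mesh, tag, vx=0.0, vy=0.0)
        v, p, _ = ff.solve_time_step(system, bc)
        assert np.abs(v).max() < 1e-12


@pytest.fixture(scope="module")
def cavity():
    mesh = ff.rect_mesh(8, 8, 1.0, 1.0)
    system = ff.FESystem(mesh, ff.FluidProperties(1.0, 1.0))
    bc = ff.BoundaryConditions()
    for tag in ("left", "right", "bottom"):
        bc.set_velocity(mesh, tag, vx=0.0, vy=0.0)
    bc.set_velocity(mesh, "top", vx=1.0, vy=0.0)
    bc.pin_pressure(0)
    v, p, iters = ff.solve_time_step(system, bc)
    return mesh, system, v, p, iters


class TestLidDrivenCavity:
    def test_net_boundary_flux_vanishes(self, cavity):
        mesh, system, v, p, _ = cavity
        # total of all continuity rows is the net flux through the boundary
        assert abs((system.divergence @ v).sum()) < 1e-10

    def test_incompressibility(self, cavity):
        mesh, system, v, p, _ = cavity
        assert divergence_residual(system, v) < 1e-8

    def test_picard_converged(self, cavity):
        *_, iters = cavity
        assert iters < 30


class TestTransient:
    def test_impulsively_started_channel_approaches_steady_state(self):
        """Backward-Euler steps converge toward the steady Stokes profile."""
        mesh = ff.rect_mesh(6, 4, 1.0, 0.2)
        system = ff.FESystem(mesh, PROPS, dt=0.05, include_convection=False)
        bc = channel_bcs(mesh)
        for _ in range(40):
            v, p, _ = ff.solve_time_step(system, bc)
            system.v_old = v.copy()
        n = mesh.n_nodes
        exact = np.array([poiseuille_profile(x, y) for x, y in mesh.node_coords])
        assert np.linalg.norm(v[:n] - exact) / np.linalg.norm(exact) < 1e-6

    def test_unknown_boundary_tag_raises(self):
        mesh = ff.rect_mesh(2, 2, 1.0, 1.0)
        with pytest.raises(KeyError):
            mesh.boundary_nodes("lid")
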