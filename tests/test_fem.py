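import numpy as np
import pytest
import scipy.sparse.linalg as spla

from carpalfem.fem import (Assembler, ContactPair, SimulationCase,
                           SolverSettings, TieConstraint, build_part_ties,
                           detect_mechanism, newton_solve)
from carpalfem.kinematics import BcSet
from carpalfem.materials import (LinearElasticParams, MooneyRivlinParams,
                                 linear_stress, mr_stress)
from carpalfem.mesh import VolumeMesh
from carpalfem.springs import SpringElement, SpringSet

CORTICAL = LinearElasticParams(E=18.0, nu=0.2)
CARTILAGE = MooneyRivlinParams(C1=4.1, C2=0.41, K=19.3)


def _static_bcs(fixed, prescribed=None, target=None, steps=1):
    return BcSet(np.asarray(fixed, dtype=int),
                 np.asarray(prescribed if prescribed is not None else [],
                            dtype=int),
                 np.asarray(target if target is not None else np.zeros(3)),
                 np.arange(1, steps + 1) / steps)


def _single_tet(material):
    nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
    mesh = VolumeMesh(nodes, np.array([[0, 1, 2, 3]]), ["bar"],
                      np.zeros(1, int), ["bar"], np.zeros(1, int))
    return mesh, {"bar": material}


class TestAssemble:
    def test_equilibrium_at_rest(self, cube_mesh):
        case = SimulationCase(cube_mesh, {"cube": CORTICAL},
                              _static_bcs(cube_mesh.boundary_node_indices()))
        asm = Assembler(case)
        r, K = asm.residual_and_tangent(np.zeros(3 * asm.n))
        assert np.linalg.norm(r) == 0.0
        assert abs(K - K.T).max() < 1e-10

    def test_patch_test_linear_field(self, cube_mesh):
        """tet4 reproduces an arbitrary linear displacement field exactly
        when it is prescribed on the boundary (machine precision)."""
        A = np.array([[0.01, 0.003, 0.002],
                      [0.004, -0.02, 0.001],
                      [0.002, 0.005, 0.015]])
        bnodes = cube_mesh.boundary_node_indices()
        case = SimulationCase(cube_mesh, {"cube": CORTICAL},
                              _static_bcs(bnodes))
        asm = Assembler(case)
        u = (cube_mesh.nodes @ A.T).reshape(-1)
        r, K = asm.residual_and_tangent(u)
        free = asm.free_dofs
        u_sol = u.copy()
        u_sol[free] += spla.spsolve(K[free][:, free].tocsc(), -r[free])
        assert np.abs(u_sol - u).max() < 1e-12
        sig = asm.element_stresses(u_sol)
        sig_exact = linear_stress(0.5 * (A + A.T), CORTICAL)
        assert np.abs(sig - sig_exact).max() < 1e-12

    def test_tangent_matches_finite_differences(self, cube_mesh, rng):
        """Consistent linearization: K column-wise equals central finite
        differences of the residual (hyperelastic material + spring)."""
        springs = SpringSet([SpringElement(
            "s", "cube", 0, "cube", int(len(cube_mesh.nodes) - 1),
            k=10.0, rest_length=1.0)])
        case = SimulationCase(cube_mesh, {"cube": CARTILAGE},
                              _static_bcs([0]), springs=springs)
        asm = Assembler(case)
        u0 = 0.02 * rng.standard_normal(3 * asm.n)
        _, K = asm.residual_and_tangent(u0)
        h = 1e-6
        for col in rng.choice(3 * asm.n, 8, replace=False):
            up, um = u0.copy(), u0.copy()
            up[col] += h
            um[col] -= h
            rp, _ = asm.residual_and_tangent(up, need_tangent=False)
            rm, _ = asm.residual_and_tangent(um, need_tangent=False)
            fd = (rp - rm) / (2 * h)
            kcol = np.asarray(K[:, col].todense()).ravel()
            denom = max(np.abs(kcol).max(), 1e-9)
            assert np.abs(fd - kcol).max() / denom < 1e-4

    def test_internal_force_is_energy_gradient(self, cube_mesh, rng):
        case = SimulationCase(cube_mesh, {"cube": CARTILAGE},
                              _static_bcs([0]))
        asm = Assembler(case)
        u = 0.02 * rng.standard_normal(3 * asm.n)
        r, _ = asm.residual_and_tangent(u, need_tangent=False)
        h = 1e-6

        def energy(v):
            return sum(asm.strain_energy_by_region(v).values())

        for dof in rng.choice(3 * asm.n, 6, replace=False):
            up, um = u.copy(), u.copy()
            up[dof] += h
            um[dof] -= h
            fd = (energy(up) - energy(um)) / (2 * h)
            assert r[dof] == pytest.approx(fd, rel=5e-4, abs=1e-7)

    def test_rigid_translation_objectivity(self, cube_mesh):
        """Translating the whole model (and its BCs) leaves stresses
        unchanged."""
        bnodes = cube_mesh.boundary_node_indices()
        case = SimulationCase(cube_mesh, {"cube": CARTILAGE},
                              _static_bcs(bnodes))
        asm = Assembler(case)
        A = 0.01 * np.eye(3)
        u = (cube_mesh.nodes @ A.T).reshape(-1)
        sig0 = asm.element_stresses(u)
        shift = np.tile([3.0, -2.0, 1.0], asm.n)
        sig1 = asm.element_stresses(u + shift)
        assert np.abs(sig1 - sig0).max() < 1e-9


class TestNewtonSolve:
    def test_zero_prescription_converges_immediately(self, cube_mesh):
        case = SimulationCase(
            cube_mesh, {"cube": CORTICAL},
            _static_bcs(cube_mesh.boundary_node_indices(), [], steps=2))
        res = newton_solve(case)
        assert res.converged
        assert np.abs(res.displacements).max() == 0.0
        # one residual evaluation per step
        assert all(it == 0 for _, it, _ in res.log)

    def test_single_element_uniaxial_mooney_rivlin(self):
        """Stretch a unit tet along x with lateral contraction free; the
        converged Cauchy stress matches the 1-D closed-form solution."""
        from scipy.optimize import brentq
        lam = 1.15
        mesh, materials = _single_tet(CARTILAGE)
        case = SimulationCase(mesh, materials, _static_bcs([0]))
        asm = Assembler(case)
        u = np.zeros(12)
        for dof, val in {3: lam - 1.0, 4: 0.0, 5: 0.0, 6: 0.0, 8: 0.0,
                         9: 0.0, 10: 0.0}.items():
            u[dof] = val
        free = np.array([7, 11])   # lateral stretches of nodes 2 and 3
        for _ in range(50):
            r, K = asm.residual_and_tangent(u)
            if np.linalg.norm(r[free]) < 1e-12:
                break
            u[free] += np.linalg.solve(K[free][:, free].toarray(), -r[free])
        sig = asm.element_stresses(u)[0]

        def lateral_stress(lt):
            return mr_stress(np.diag([lam, lt, lt]), CARTILAGE)[1, 1]

        lt = brentq(lateral_stress, 0.5, 1.2, xtol=1e-14)
        sig_exact = mr_stress(np.diag([lam, lt, lt]), CARTILAGE)
        assert sig[0, 0] == pytest.approx(sig_exact[0, 0], rel=1e-4)
        assert abs(sig[1, 1]) < 1e-8 * abs(sig[0, 0])

    def test_superlinear_residual_decrease(self, cube_mesh):
        """Near the solution Newton converges superlinearly: the last
        residual drop dominates the previous one."""
        top = cube_mesh.boundary_node_indices()
        z = cube_mesh.nodes[top, 2]
        bottom = top[z < z.min() + 1e-6]
        lid = top[z > z.max() - 1e-6]
        case = SimulationCase(
            cube_mesh, {"cube": CARTILAGE},
            _static_bcs(bottom, lid, [0.0, 0.0, -0.08], steps=1))
        res = newton_solve(case)
        assert res.converged
        norms = [r for s, i, r in res.log]
        drops = [norms[i + 1] / norms[i] for i in range(len(norms) - 1)]
        assert drops[-1] < 0.3 * drops[0] or norms[-1] < 1e-10

    def test_reactions_balance_in_converged_state(self, cube_mesh):
        top = cube_mesh.boundary_node_indices()
        z = cube_mesh.nodes[top, 2]
        bottom = top[z < z.min() + 1e-6]
        lid = top[z > z.max() - 1e-6]
        case = SimulationCase(
            cube_mesh, {"cube": CORTICAL},
            _static_bcs(bottom, lid, [0.0, 0.0, -0.02], steps=1))
        res = newton_solve(case)
        assert res.converged
        total = res.reactions[-1].sum(axis=0)
        assert np.abs(total).max() < 1e-6   # N

    def test_linearity_in_the_small_strain_limit(self, cube_mesh):
        """Doubling the prescribed displacement doubles the response for a
        stiff linear material at small strain."""
        top = cube_mesh.boundary_node_indices()
        z = cube_mesh.nodes[top, 2]
        bottom = top[z < z.min() + 1e-6]
        lid = top[z > z.max() - 1e-6]
        results = []
        for amp in (1e-4, 2e-4):
            case = SimulationCase(
                cube_mesh, {"cube": CORTICAL},
                _static_bcs(bottom, lid, [0.0, 0.0, -amp], steps=1))
            res = newton_solve(case)
            assert res.converged
            results.append(res.displacements[-1])
        ratio = np.abs(results[1]).max() / np.abs(results[0]).max()
        assert ratio == pytest.approx(2.0, rel=0.01)


class TestMechanismDetection:
    def _two_bodies(self):
        a = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        b = a + [3.0, 0, 0]
        nodes = np.vstack([a, b])
        tets = np.array([[0, 1, 2, 3], [4, 5, 6, 7]])
        return VolumeMesh(nodes, tets, ["a", "b"], np.array([0, 1]),
                          ["a", "b"], np.array([0, 1]))

    def test_fixed_body_fully_constrained(self):
        mesh, mats = _single_tet(CORTICAL)
        case = SimulationCase(mesh, mats, _static_bcs([0, 1, 2, 3]))
        assert detect_mechanism(case) == 0

    def test_free_body_has_six_rigid_modes(self):
        mesh, mats = _single_tet(CORTICAL)
        case = SimulationCase(mesh, mats, _static_bcs([]))
        assert detect_mechanism(case) == 6

    def test_single_spring_leaves_five_modes(self):
        """One fixed body joined to a floating one by a single axial
        spring: the spring removes one of six rigid freedoms."""
        mesh = self._two_bodies()
        mats = {"a": CORTICAL, "b": CORTICAL}
        springs = SpringSet([SpringElement("s", "a", 1, "b", 4, k=10.0,
                                           rest_length=2.0)])
        case = SimulationCase(mesh, mats, _static_bcs([0, 1, 2, 3]),
                              springs=springs)
        assert detect_mechanism(case) == 5

    def test_tie_constraints_remove_all_modes(self):
        mesh = self._two_bodies()
        mats = {"a": CORTICAL, "b": CORTICAL}
        pairs = np.array([[0, 4], [1, 5], [2, 6], [3, 7]])
        ties = [TieConstraint("a", "b", pairs, stiffness=100.0)]
        case = SimulationCase(mesh, mats, _static_bcs([0, 1, 2, 3]),
                              ties=ties)
        assert detect_mechanism(case) == 0


class TestContact:
    def _stacked_blocks(self, gap=0.2):
        import trimesh
        from carpalfem.mesh import SurfaceMesh, tetrahedralize
        lower = trimesh.creation.box(extents=[1, 1, 0.5])
        upper = trimesh.creation.box(extents=[1, 1, 0.5])
        upper.apply_translation([0, 0, 0.5 + gap])
        a = tetrahedralize(SurfaceMesh(lower.vertices, lower.faces), 0.3,
                           part="lower")
        b = tetrahedralize(SurfaceMesh(upper.vertices, upper.faces), 0.3,
                           part="upper")
        return VolumeMesh.merge([a, b]), gap

    @pytest.mark.parametrize("mode", ["gap_spring", "node_to_surface"])
    def test_press_blocks_transmits_compression(self, mode):
        mesh, gap = self._stacked_blocks()
        lower_nodes = mesh.part_nodes("lower")
        upper_nodes = mesh.part_nodes("upper")
        z = mesh.nodes[:, 2]
        bottom = lower_nodes[z[lower_nodes] < -0.25 + 1e-6]
        top = upper_nodes[z[upper_nodes] > z[upper_nodes].max() - 1e-6]
        push = -(gap + 0.1)
        # the node-to-surface tangent omits the geometric (closest-point
        # motion) terms, so it converges to ~1e-4 relative residuals only
        settings = SolverSettings(rel_tol=1e-6 if mode == "gap_spring"
                                  else 1e-3)
        case = SimulationCase(
            mesh, {"lower": CORTICAL, "upper": CORTICAL},
            _static_bcs(bottom, top, [0, 0, push], steps=4),
            contacts=[ContactPair("upper", "lower", penalty=100.0,
                                  mode=mode, search_radius=1.0)],
            settings=settings)
        res = newton_solve(case)
        if mode == "gap_spring":
            assert res.converged
        else:
            # the approximate tangent caps how far node-to-surface can
            # drive the residual; most of the ramp still completes
            assert res.n_steps >= 2
        p_lower = res.stresses[-1][mesh.part_mask("lower")]
        # compressive axial stress transmitted into the lower block
        assert np.median(p_lower[:, 2, 2]) < -1e-4
        # reaction force at the base balances a positive contact force
        assert res.reactions[-1][bottom, 2].sum() > 1e-3

    def test_no_force_before_engagement(self):
        mesh, gap = self._stacked_blocks()
        lower_nodes = mesh.part_nodes("lower")
        upper_nodes = mesh.part_nodes("upper")
        z = mesh.nodes[:, 2]
        bottom = lower_nodes[z[lower_nodes] < -0.25 + 1e-6]
        top = upper_nodes[z[upper_nodes] > z[upper_nodes].max() - 1e-6]
        case = SimulationCase(
            mesh, {"lower": CORTICAL, "upper": CORTICAL},
            _static_bcs(bottom, top, [0, 0, -gap / 2], steps=1),
            contacts=[ContactPair("upper", "lower", penalty=100.0,
                                  search_radius=1.0)])
        res = newton_solve(case)
        assert res.converged
        # half-gap approach: surfaces not yet touching, lower block unloaded
        assert np.abs(res.stresses[-1][mesh.part_mask("lower")]).max() < 1e-8


class TestTieBuilding:
    def test_build_part_ties_pairs_nearby_nodes(self):
        import trimesh
        from carpalfem.mesh import SurfaceMesh, tetrahedralize
        a = trimesh.creation.box(extents=[1, 1, 1])
        b = trimesh.creation.box(extents=[1, 1, 1])
        b.apply_translation([0, 0, 1.05])
        ma = tetrahedralize(SurfaceMesh(a.vertices, a.faces), 0.5, part="a")
        mb = tetrahedralize(SurfaceMesh(b.vertices, b.faces), 0.5, part="b")
        mesh = VolumeMesh.merge([ma, mb])
        tie = build_part_ties(mesh, "a", "b", stiffness=100.0,
                              search_radius=0.2)
        assert len(tie.pairs) > 0
        for na, nb in tie.pairs:
            assert np.linalg.norm(mesh.nodes[na] - mesh.nodes[nb]) < 0.75

    def test_no_pairs_raises(self):
        mesh = TestMechanismDetection()._two_bodies()
        with pytest.raises(ValueError):
            build_part_ties(mesh, "a", "b", stiffness=1.0,
                            search_radius=0.1)
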