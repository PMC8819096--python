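"""Small implicit nonlinear finite-element solver for the carpal model.

Total-Lagrangian tet4 elements, Newton-Raphson with load stepping and step
bisection, direct sparse factorization.  Bone parts are small-strain linear
elastic; cartilage and the SLIL block are compressible Mooney-Rivlin, with
element tangents obtained by complex-step differentiation of the analytic
first Piola-Kirchhoff stress (exact to machine precision, so Newton keeps
its quadratic rate).

Part coupling:
* tied interfaces: node-pair penalty springs acting on the displacement
  difference (bone-cartilage, SLIL-bone),
* articulations: compression-only gap springs along the initial contact
  normal by default, with an optional node-to-triangle penalty contact.

A model without the SLIL is under-constrained: the assembled tangent has
near-zero-energy (mechanism) modes and Newton stalls.  That outcome is a
result here, not a crash: ``newton_solve`` returns a divergence record and
``detect_mechanism`` counts the mechanism modes by eigenvalue analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .kinematics import BcSet
from .materials import (LinearElasticParams, MaterialParams,
                        MooneyRivlinParams, linear_stress, mr_first_piola)
from .mesh import VolumeMesh
from .springs import SpringSet, spring_energy, spring_force, spring_tangent
from ._geometry import closest_point_on_triangles


# --------------------------------------------------------------------------
# case definition
# --------------------------------------------------------------------------

@dataclass
class SolverSettings:
    rel_tol: float = 1e-6
    abs_tol: float = 1e-9          # N
    max_iterations: int = 25
    max_bisections: int = 3


@dataclass
class TieConstraint:
    """Node-pair penalty ties enforcing equal displacement across an
    interface (pairs resolved at build time)."""

    part_a: str
    part_b: str
    pairs: np.ndarray              # (n, 2) global node indices
    stiffness: float               # N/mm per pair

    def __post_init__(self):
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        if self.stiffness <= 0:
            raise ValueError("tie stiffness must be positive")


@dataclass
class ContactPair:
    """Frictionless articulation between two part surfaces."""

    part_a: str                    # slave (nodes)
    part_b: str                    # master (faces / opposing nodes)
    penalty: float                 # N/mm (per pair or per node)
    mode: str = "gap_spring"       # "gap_spring" | "node_to_surface"
    search_radius: float = 2.5     # mm, gap-spring pair search
    smoothing: float = 0.05        # mm, C1 blend width at engagement

    def __post_init__(self):
        if self.penalty <= 0:
            raise ValueError("contact penalty must be positive")
        if self.mode not in ("gap_spring", "node_to_surface"):
            raise ValueError(f"unknown contact mode {self.mode!r}")
        if self.smoothing < 0:
            raise ValueError("smoothing width must be non-negative")


def _contact_force_law(pen: np.ndarray, penalty: float, w: float):
    """Penalty force magnitude and stiffness, C1-smoothed near pen = 0.

    Piecewise: zero for pen <= -w, quadratic blend on (-w, w), linear
    ``penalty * pen`` beyond; the blend removes the stiffness jump that
    makes Newton chatter on the contact active set.
    """
    pen = np.asarray(pen, dtype=float)
    if w <= 0:
        force = penalty * np.maximum(pen, 0.0)
        stiff = np.where(pen > 0, penalty, 0.0)
        return force, stiff
    force = np.where(
        pen <= -w, 0.0,
        np.where(pen >= w, penalty * pen,
                 penalty * (pen + w) ** 2 / (4 * w)))
    stiff = np.where(
        pen <= -w, 0.0,
        np.where(pen >= w, penalty, penalty * (pen + w) / (2 * w)))
    return force, stiff


@dataclass
class SimulationCase:
    mesh: VolumeMesh
    materials: dict[str, MaterialParams]     # region name -> params
    bcs: BcSet
    springs: SpringSet | None = None
    ties: list[TieConstraint] = field(default_factory=list)
    contacts: list[ContactPair] = field(default_factory=list)
    external_forces: np.ndarray | None = None   # (n_nodes, 3) N, constant
    settings: SolverSettings = field(default_factory=SolverSettings)

    def validate(self) -> None:
        for name in self.mesh.region_names:
            if name not in self.materials:
                raise ValueError(f"region {name!r} has no material")
        n = len(self.mesh.nodes)
        for arr in (self.bcs.fixed_nodes, self.bcs.prescribed_nodes):
            if len(arr) and (arr.min() < 0 or arr.max() >= n):
                raise ValueError("BC node index out of range")


@dataclass
class DivergenceRecord:
    """Structured non-convergence outcome (the no-SLIL observable)."""

    step: int
    ramp_fraction: float
    iterations: int
    residual_norms: list[float]
    reason: str


@dataclass
class FieldResult:
    displacements: np.ndarray        # (n_steps_done, n_nodes, 3) mm
    stresses: np.ndarray             # (n_steps_done, n_tets, 3, 3) MPa
    ramp: np.ndarray                 # fractions actually reached
    converged: bool
    divergence: DivergenceRecord | None
    log: list[tuple[int, int, float]]   # (step, iteration, residual norm)
    mesh: VolumeMesh
    reactions: np.ndarray | None = None  # (n_steps_done, n_nodes, 3) N

    @property
    def n_steps(self) -> int:
        return len(self.ramp)

    def log_text(self) -> str:
        lines = ["step\titeration\tresidual_N"]
        lines += [f"{s}\t{i}\t{r:.6e}" for s, i, r in self.log]
        return "\n".join(lines) + "\n"


class ElementInversionError(RuntimeError):
    def __init__(self, element_ids):
        self.element_ids = np.atleast_1d(element_ids)
        super().__init__(f"inverted elements: {self.element_ids[:10]}")


# --------------------------------------------------------------------------
# assembly
# --------------------------------------------------------------------------

def _shape_gradients(nodes: np.ndarray, tets: np.ndarray):
    """Constant shape-function gradients G (m,4,3) and volumes V0 (m,)."""
    x = nodes[tets]
    J = (x[:, 1:] - x[:, :1]).swapaxes(1, 2)   # (m,3,3), columns = edges
    detJ = np.linalg.det(J)
    if np.any(detJ <= 0):
        raise ValueError("mesh contains non-positively oriented tets")
    Jinv = np.linalg.inv(J)
    # dN/dX for N2..N4 are rows of J^{-1}; N1 = 1 - sum
    g = Jinv                                    # (m, 3(iso), 3(X))
    G = np.empty((len(tets), 4, 3))
    G[:, 1:] = g
    G[:, 0] = -g.sum(axis=1)
    return G, np.abs(detJ) / 6.0


def _hooke_matrix(p: LinearElasticParams) -> np.ndarray:
    lam, mu = p.lame
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2 * mu
    D[3:, 3:] = mu * np.eye(3)
    return D


class Assembler:
    """Precomputed element data + residual/tangent evaluation."""

    def __init__(self, case: SimulationCase):
        case.validate()
        self.case = case
        mesh = case.mesh
        self.n = len(mesh.nodes)
        self.G, self.V0 = _shape_gradients(mesh.nodes, mesh.tets)

        self.lin_groups: list[tuple[LinearElasticParams, np.ndarray]] = []
        self.mr_groups: list[tuple[MooneyRivlinParams, np.ndarray]] = []
        for rid, rname in enumerate(mesh.region_names):
            idx = np.flatnonzero(mesh.region_ids == rid)
            if not len(idx):
                continue
            p = case.materials[rname]
            if isinstance(p, LinearElasticParams):
                self.lin_groups.append((p, idx))
            else:
                self.mr_groups.append((p, idx))

        self.K_lin = self._assemble_linear()
        self.K_tie = self._assemble_ties()
        self._gap_pairs = self._build_gap_pairs()
        self.f_ext = np.zeros(3 * self.n)
        if case.external_forces is not None:
            self.f_ext = np.asarray(case.external_forces,
                                    dtype=float).reshape(-1)

        fixed = case.bcs.fixed_nodes
        presc = case.bcs.prescribed_nodes
        con = np.concatenate([fixed, presc])
        self.constrained_dofs = (3 * con[:, None]
                                 + np.arange(3)[None, :]).ravel()
        mask = np.ones(3 * self.n, dtype=bool)
        mask[self.constrained_dofs] = False
        self.free_dofs = np.flatnonzero(mask)

    # ---- constant pieces ------------------------------------------------
    def _element_dofs(self, idx: np.ndarray) -> np.ndarray:
        t = self.case.mesh.tets[idx]                       # (m,4)
        return (3 * t[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 12)

    def _assemble_linear(self) -> sp.csr_matrix:
        rows, cols, vals = [], [], []
        self._lin_Ke: list[tuple[np.ndarray, np.ndarray]] = []
        for p, idx in self.lin_groups:
            D = _hooke_matrix(p)
            G, V = self.G[idx], self.V0[idx]
            m = len(idx)
            B = np.zeros((m, 6, 12))
            for a in range(4):
                gx, gy, gz = G[:, a, 0], G[:, a, 1], G[:, a, 2]
                c = 3 * a
                B[:, 0, c] = gx
                B[:, 1, c + 1] = gy
                B[:, 2, c + 2] = gz
                B[:, 3, c] = gy
                B[:, 3, c + 1] = gx
                B[:, 4, c + 1] = gz
                B[:, 4, c + 2] = gy
                B[:, 5, c] = gz
                B[:, 5, c + 2] = gx
            Ke = np.einsum("mia,ij,mjb,m->mab", B, D, B, V, optimize=True)
            self._lin_Ke.append((idx, Ke))
            dofs = self._element_dofs(idx)
            rows.append(np.repeat(dofs, 12, axis=1).ravel())
            cols.append(np.tile(dofs, (1, 12)).ravel())
            vals.append(Ke.ravel())
        if not rows:
            return sp.csr_matrix((3 * self.n, 3 * self.n))
        K = sp.coo_matrix((np.concatenate(vals),
                           (np.concatenate(rows), np.concatenate(cols))),
                          shape=(3 * self.n, 3 * self.n)).tocsr()
        return K

    def _assemble_ties(self) -> sp.csr_matrix:
        rows, cols, vals = [], [], []
        for tie in self.case.ties:
            for (a, b) in tie.pairs:
                da = 3 * a + np.arange(3)
                db = 3 * b + np.arange(3)
                k = tie.stiffness
                for i in range(3):
                    rows += [da[i], db[i], da[i], db[i]]
                    cols += [da[i], db[i], db[i], da[i]]
                    vals += [k, k, -k, -k]
        if not rows:
            return sp.csr_matrix((3 * self.n, 3 * self.n))
        return sp.coo_matrix((vals, (rows, cols)),
                             shape=(3 * self.n, 3 * self.n)).tocsr()

    def _build_gap_pairs(self):
        """Gap-spring contact pairs: (slave node, master node, normal,
        engagement separation).

        Each slave boundary node within the search radius of the master
        surface pairs with its nearest master boundary node.  The pair
        engages when its separation along the initial pair direction drops
        below ``s0 - g0`` where s0 is the initial node distance and g0 the
        initial clearance from the slave node to the master *surface* -- so
        contact starts when the slave would cross the master surface, not
        when the two nodes meet.
        """
        out = []
        mesh = self.case.mesh
        for c in self.case.contacts:
            if c.mode != "gap_spring":
                continue
            sa = mesh.boundary_node_indices(c.part_a)
            sb = mesh.boundary_node_indices(c.part_b)
            xa = mesh.nodes[sa]
            xb = mesh.nodes[sb]
            faces_b, _ = mesh.boundary_faces(c.part_b)
            g0_all, _, _ = closest_point_on_triangles(
                xa, mesh.nodes[faces_b])
            d2 = ((xa[:, None, :] - xb[None, :, :]) ** 2).sum(-1)
            j = d2.argmin(axis=1)
            dmin = np.sqrt(d2[np.arange(len(sa)), j])
            keep = (g0_all <= c.search_radius) & (dmin > 1e-9)
            if not keep.any():
                continue
            a_idx = sa[keep]
            b_idx = sb[j[keep]]
            normal = (xb[j[keep]] - xa[keep]) / dmin[keep][:, None]
            engage = dmin[keep] - g0_all[keep]
            out.append((c, a_idx, b_idx, normal, engage))
        return out

    # ---- state-dependent assembly --------------------------------------
    def deformation_gradients(self, u: np.ndarray, idx: np.ndarray):
        ue = u.reshape(-1, 3)[self.case.mesh.tets[idx]]      # (m,4,3)
        F = np.eye(3) + np.einsum("maj,mak->mjk", ue, self.G[idx])
        return F

    def residual_and_tangent(self, u: np.ndarray, need_tangent: bool = True):
        """Internal - external force and (optionally) the tangent matrix."""
        mesh = self.case.mesh
        f = self.K_lin @ u + self.K_tie @ u
        K_parts = [self.K_lin, self.K_tie] if need_tangent else []
        rows, cols, vals = [], [], []

        # Mooney-Rivlin groups
        for p, idx in self.mr_groups:
            F = self.deformation_gradients(u, idx)
            J = np.linalg.det(F)
            if np.any(J <= 0):
                raise ElementInversionError(idx[J <= 0])
            P = mr_first_piola(F, p)
            fe = np.einsum("mij,maj,m->mai", P, self.G[idx], self.V0[idx])
            np.add.at(f.reshape(-1, 3), mesh.tets[idx], fe)
            if need_tangent:
                Ke = np.empty((len(idx), 12, 12))
                h = 1e-30
                Fc = F.astype(complex)
                for col in range(12):
                    a, kdir = divmod(col, 3)
                    dF = np.zeros_like(Fc)
                    dF[:, kdir, :] = 1j * h * self.G[idx][:, a, :]
                    dP = mr_first_piola(Fc + dF, p).imag / h
                    Ke[:, :, col] = np.einsum(
                        "mij,maj,m->mai", dP, self.G[idx],
                        self.V0[idx]).reshape(len(idx), 12)
                dofs = self._element_dofs(idx)
                rows.append(np.repeat(dofs, 12, axis=1).ravel())
                cols.append(np.tile(dofs, (1, 12)).ravel())
                vals.append(Ke.ravel())

        # springs
        x = mesh.nodes + u.reshape(-1, 3)
        if self.case.springs is not None:
            for s in self.case.springs.elements:
                fa, fb = spring_force(s, x[s.node_a], x[s.node_b])
                # internal force = -applied force
                f.reshape(-1, 3)[s.node_a] -= fa
                f.reshape(-1, 3)[s.node_b] -= fb
                if need_tangent:
                    Ks = spring_tangent(s, x[s.node_a], x[s.node_b])
                    dofs = np.concatenate([3 * s.node_a + np.arange(3),
                                           3 * s.node_b + np.arange(3)])
                    rows.append(np.repeat(dofs, 6))
                    cols.append(np.tile(dofs, 6))
                    vals.append(Ks.ravel())

        # gap springs (compression only, C1-smoothed at engagement)
        for c, a_idx, b_idx, n0, engage in self._gap_pairs:
            s_now = np.einsum("pj,pj->p", x[b_idx] - x[a_idx], n0)
            pen = engage - s_now                      # > 0 once crossed
            force, stiff = _contact_force_law(pen, c.penalty, c.smoothing)
            active = force > 0
            if active.any():
                # pen = engage - n0.(x_b - x_a): internal force +g*n0 at a,
                # -g*n0 at b (the pair is pushed apart)
                fa = force[active][:, None] * n0[active]
                np.add.at(f.reshape(-1, 3), a_idx[active], fa)
                np.add.at(f.reshape(-1, 3), b_idx[active], -fa)
            if need_tangent and (stiff > 0).any():
                sel = stiff > 0
                for ai, bi, nv, kc in zip(a_idx[sel], b_idx[sel],
                                          n0[sel], stiff[sel]):
                    nn = kc * np.outer(nv, nv)
                    dofs = np.concatenate([3 * ai + np.arange(3),
                                           3 * bi + np.arange(3)])
                    blk = np.block([[nn, -nn], [-nn, nn]])
                    rows.append(np.repeat(dofs, 6))
                    cols.append(np.tile(dofs, 6))
                    vals.append(blk.ravel())

        # node-to-surface penalty contact
        for c in self.case.contacts:
            if c.mode != "node_to_surface":
                continue
            self._node_to_surface(c, x, f, rows, cols, vals, need_tangent)

        f -= self.f_ext
        if not need_tangent:
            return f, None
        if rows:
            K_parts.append(sp.coo_matrix(
                (np.concatenate(vals),
                 (np.concatenate(rows), np.concatenate(cols))),
                shape=(3 * self.n, 3 * self.n)).tocsr())
        K = K_parts[0]
        for part in K_parts[1:]:
            K = K + part
        return f, K

    def _node_to_surface(self, c: ContactPair, x, f, rows, cols, vals,
                         need_tangent):
        mesh = self.case.mesh
        slaves = mesh.boundary_node_indices(c.part_a)
        faces, _ = mesh.boundary_faces(c.part_b)
        tri = x[faces]
        d, cp, idx = closest_point_on_triangles(x[slaves], tri)
        fnorm = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        fnorm /= np.linalg.norm(fnorm, axis=1, keepdims=True)
        nhat = fnorm[idx]
        gap = np.einsum("pj,pj->p", x[slaves] - cp, nhat)
        force_all, stiff_all = _contact_force_law(-gap, c.penalty,
                                                  c.smoothing)
        active = (force_all > 0) | (stiff_all > 0)
        for s_i in np.flatnonzero(active):
            node = slaves[s_i]
            face = faces[idx[s_i]]
            nv = nhat[s_i]
            # barycentric weights of the projection on the face
            a_, b_, c_ = x[face]
            T = np.stack([b_ - a_, c_ - a_], axis=1)
            uv, *_ = np.linalg.lstsq(T, cp[s_i] - a_, rcond=None)
            w = np.array([1 - uv.sum(), uv[0], uv[1]])
            # penalty on pen = -(x_s - cp).n ; the energy gradient gives
            # internal force -fmag*n at the slave (physically it is pushed
            # outward) and +w_j*fmag*n at the face nodes
            fmag = force_all[s_i]
            f.reshape(-1, 3)[node] += -fmag * nv
            for j in range(3):
                f.reshape(-1, 3)[face[j]] += w[j] * fmag * nv
            if need_tangent:
                nodes4 = np.array([node, *face])
                wts = np.array([-1.0, *w])
                nn = stiff_all[s_i] * np.outer(nv, nv)
                for i4, wi in enumerate(nodes4):
                    for j4, wj in enumerate(nodes4):
                        blk = wts[i4] * wts[j4] * nn
                        di = 3 * wi + np.arange(3)
                        dj = 3 * wj + np.arange(3)
                        rows.append(np.repeat(di, 3))
                        cols.append(np.tile(dj, 3))
                        vals.append(blk.ravel())

    # ---- energies -------------------------------------------------------
    def strain_energy_by_region(self, u: np.ndarray) -> dict[str, float]:
        """Element strain energy summed per region (tie/contact excluded)."""
        from .materials import mr_energy
        mesh = self.case.mesh
        out = {name: 0.0 for name in mesh.region_names}
        for (idx, Ke), (p, _) in zip(self._lin_Ke, self.lin_groups):
            ue = u.reshape(-1, 3)[mesh.tets[idx]].reshape(len(idx), 12)
            e = 0.5 * np.einsum("ma,mab,mb->m", ue, Ke, ue)
            for rid in np.unique(mesh.region_ids[idx]):
                name = mesh.region_names[rid]
                out[name] += float(e[mesh.region_ids[idx] == rid].sum())
        for p, idx in self.mr_groups:
            F = self.deformation_gradients(u, idx)
            W = mr_energy(F, p) * self.V0[idx]
            for rid in np.unique(mesh.region_ids[idx]):
                name = mesh.region_names[rid]
                out[name] += float(W[mesh.region_ids[idx] == rid].sum())
        return out

    def spring_strain_energy(self, u: np.ndarray) -> float:
        if self.case.springs is None:
            return 0.0
        x = self.case.mesh.nodes + u.reshape(-1, 3)
        return sum(spring_energy(s, x[s.node_a], x[s.node_b])
                   for s in self.case.springs.elements)

    # ---- stress recovery -------------------------------------------------
    def element_stresses(self, u: np.ndarray) -> np.ndarray:
        """Cauchy stress per tet (MPa)."""
        mesh = self.case.mesh
        sig = np.zeros((len(mesh.tets), 3, 3))
        for p, idx in self.lin_groups:
            ue = u.reshape(-1, 3)[mesh.tets[idx]]
            grad = np.einsum("maj,mak->mjk", ue, self.G[idx])
            eps = 0.5 * (grad + grad.swapaxes(1, 2))
            sig[idx] = linear_stress(eps, p)
        for p, idx in self.mr_groups:
            F = self.deformation_gradients(u, idx)
            P = mr_first_piola(F, p)
            J = np.linalg.det(F)
            s = P @ F.swapaxes(1, 2) / J[:, None, None]
            sig[idx] = 0.5 * (s + s.swapaxes(1, 2))
        return sig


# --------------------------------------------------------------------------
# Newton driver
# --------------------------------------------------------------------------

def _apply_prescribed(u: np.ndarray, bcs: BcSet, fraction: float):
    u3 = u.reshape(-1, 3)
    u3[bcs.fixed_nodes] = 0.0
    u3[bcs.prescribed_nodes] = fraction * bcs.target_displacement


def _solve_step(asm: Assembler, u: np.ndarray, fraction: float,
                step_index: int, log: list) -> tuple[bool, list[float], str]:
    """Newton-iterate at a fixed ramp fraction; u updated in place.

    Uses a backtracking line search on the residual norm: a full Newton
    update that raises the residual (or inverts an element) is halved up
    to 6 times before the step is declared failed.
    """
    st = asm.case.settings
    _apply_prescribed(u, asm.case.bcs, fraction)
    free = asm.free_dofs
    norms: list[float] = []
    ref = None
    try:
        r, K = asm.residual_and_tangent(u, need_tangent=True)
    except ElementInversionError as e:
        return False, norms, f"element inversion ({len(e.element_ids)})"
    for it in range(st.max_iterations):
        rn = float(np.linalg.norm(r[free]))
        norms.append(rn)
        log.append((step_index, it, rn))
        if not np.isfinite(rn):
            return False, norms, "non-finite residual"
        if ref is None:
            ref = rn
        if rn <= max(st.rel_tol * ref, st.abs_tol):
            return True, norms, ""
        Kff = K[free][:, free].tocsc()
        scale = float(np.abs(Kff.diagonal()).max()) or 1.0
        eye = sp.identity(Kff.shape[0], format="csc")
        accepted = False
        damping = 0.0
        for _ in range(8):            # damping escalations
            try:
                du = spla.spsolve(Kff + damping * scale * eye, -r[free])
            except Exception as exc:  # singular factorization
                return False, norms, f"linear solve failed: {exc}"
            if not np.all(np.isfinite(du)):
                return False, norms, "non-finite Newton update"
            alpha = 1.0
            for _ in range(7):        # backtracking line search
                u_try = u.copy()
                u_try[free] += alpha * du
                try:
                    # residual only here; tangent once accepted
                    r_try, _ = asm.residual_and_tangent(u_try,
                                                        need_tangent=False)
                except ElementInversionError:
                    alpha *= 0.5
                    continue
                rn_try = float(np.linalg.norm(r_try[free]))
                if np.isfinite(rn_try) and (rn_try < rn
                                            or rn_try <= max(
                                                st.rel_tol * ref,
                                                st.abs_tol)):
                    u[:] = u_try
                    r = r_try
                    _, K = asm.residual_and_tangent(u, need_tangent=True)
                    accepted = True
                    break
                alpha *= 0.5
            if accepted:
                break
            # stalled: damp the tangent (bounds the near-rigid soft modes)
            damping = 1e-8 if damping == 0.0 else 10.0 * damping
        if not accepted:
            return False, norms, "line search stalled"
    return False, norms, "iteration limit"


def newton_solve(case: SimulationCase) -> FieldResult:
    """Run the load-stepped Newton solve.

    Returns a FieldResult; if a step fails to converge even after
    ``max_bisections`` local step halvings, the result carries a
    DivergenceRecord and the fields computed so far.
    """
    asm = Assembler(case)
    n = asm.n
    u = np.zeros(3 * n)
    log: list[tuple[int, int, float]] = []
    disps, stresses, reactions, reached = [], [], [], []
    divergence = None

    t_prev = 0.0
    for step_index, t_target in enumerate(case.bcs.ramp):
        # adaptive substepping: halve the increment on failure (down to
        # 1/2^max_bisections of the step), grow it again after successes
        inc_full = float(t_target) - t_prev
        min_inc = inc_full / 2 ** case.settings.max_bisections
        inc = inc_full
        t_local = t_prev
        u_good = u.copy()
        failed = False
        last_norms: list[float] = []
        last_reason = ""
        while t_local < float(t_target) - 1e-12:
            t_try = min(t_local + inc, float(t_target))
            u_trial = u_good.copy()
            ok, norms, reason = _solve_step(asm, u_trial, t_try,
                                            step_index, log)
            if ok:
                u_good = u_trial
                t_local = t_try
                inc = min(2 * inc, inc_full)
                continue
            last_norms, last_reason = norms, reason
            inc *= 0.5
            if inc < min_inc * (1 - 1e-9):
                failed = True
                break
        if failed:
            divergence = DivergenceRecord(
                step=step_index, ramp_fraction=float(t_target),
                iterations=len(last_norms), residual_norms=last_norms,
                reason=last_reason or "did not converge")
            break
        u = u_good
        t_prev = float(t_target)
        disps.append(u.reshape(-1, 3).copy())
        stresses.append(asm.element_stresses(u))
        r, _ = asm.residual_and_tangent(u, need_tangent=False)
        rx = np.zeros((n, 3))
        rx.reshape(-1)[asm.constrained_dofs] = r[asm.constrained_dofs]
        reactions.append(rx)
        reached.append(float(t_target))

    return FieldResult(
        displacements=np.array(disps) if disps else np.zeros((0, n, 3)),
        stresses=(np.array(stresses) if stresses
                  else np.zeros((0, len(case.mesh.tets), 3, 3))),
        ramp=np.array(reached),
        converged=divergence is None,
        divergence=divergence,
        log=log,
        mesh=case.mesh,
        reactions=np.array(reactions) if reactions else None,
    )


def build_part_ties(mesh: VolumeMesh, part_a: str, part_b: str,
                    stiffness: float, search_radius: float = 1.5
                    ) -> TieConstraint:
    """Tie boundary nodes of part_a to their nearest part_b boundary node.

    Every part_a boundary node within ``search_radius`` mm of the part_b
    boundary surface is paired with its nearest part_b boundary node; the
    pair is penalized on its displacement difference, so the interface
    carries no force in the reference configuration regardless of any
    small geometric gap.
    """
    na = mesh.boundary_node_indices(part_a)
    faces_b, _ = mesh.boundary_faces(part_b)
    xa = mesh.nodes[na]
    d, _, _ = closest_point_on_triangles(xa, mesh.nodes[faces_b])
    close = d <= search_radius
    if not close.any():
        raise ValueError(f"no tie pairs between {part_a!r} and {part_b!r} "
                         f"within {search_radius} mm")
    nb = mesh.boundary_node_indices(part_b)
    xb = mesh.nodes[nb]
    sel = na[close]
    d2 = ((mesh.nodes[sel][:, None, :] - xb[None, :, :]) ** 2).sum(-1)
    partner = nb[d2.argmin(axis=1)]
    pairs = np.stack([sel, partner], axis=1)
    return TieConstraint(part_a, part_b, pairs, stiffness)


def run_reduced_radius_study(shape_config=None, target_edge: float = 2.5,
                             pressure_mpa: float = 1.0,
                             patch_radius: float = 2.5,
                             materials: dict[str, MaterialParams] | None = None,
                             steps: int = 5, seed: int = 0):
    """Distal-radius-only load study: is cancellous bone structurally needed?

    Builds the radius body (cortical shell, conforming cancellous core and
    conforming articular cartilage layer), fixes the proximal face, applies
    unit-magnitude pressure patches on the two articular fossae (where
    scaphoid and lunate seat) and solves.  Returns
    ``(FieldResult, energy_fractions, load_info)`` where
    ``energy_fractions`` maps region name to its share of the element
    strain energy at the final step.
    """
    from .anatomy import ShapeConfig, body_envelope, generate_reduced_wrist
    from .materials import default_library
    from .mesh import tetrahedralize

    cfg = shape_config or ShapeConfig()
    model = generate_reduced_wrist(cfg, seed=seed)
    lib = materials or default_library()

    env = body_envelope(model, "radius")
    mesh = tetrahedralize(
        env, target_edge, part="radius", base_region="radius_cortical",
        region_surfaces=[
            ("radius_cancellous", model.parts["radius_cancellous"]),
            ("radius_cartilage", model.parts["radius_cartilage"]),
        ])

    # fossa pressure patches on the distal cartilage surface
    c = cfg.scaled()
    x0 = 0.55 * c.radius_cartilage_semi[0]
    faces, _ = mesh.boundary_faces("radius_cartilage")
    tri = mesh.nodes[faces]
    cent = tri.mean(axis=1)
    nvec = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    area = 0.5 * np.linalg.norm(nvec, axis=1)
    nhat = nvec / (2 * area[:, None])
    on_top = nhat[:, 2] > 0.5
    in_patch = np.zeros(len(faces), dtype=bool)
    for sx in (-1.0, +1.0):
        r2 = (cent[:, 0] - sx * x0) ** 2 + cent[:, 1] ** 2
        in_patch |= r2 < patch_radius ** 2
    sel = on_top & in_patch
    if not sel.any():
        raise RuntimeError("no pressure-patch faces found on the cartilage")
    f_ext = np.zeros((len(mesh.nodes), 3))
    for fc, A, nh in zip(faces[sel], area[sel], nhat[sel]):
        np.add.at(f_ext, fc, -pressure_mpa * A * nh / 3.0)

    rnodes = mesh.part_nodes("radius")
    z = mesh.nodes[rnodes, 2]
    fixed = rnodes[z <= z.min() + 1.0]
    bcs = BcSet(fixed, np.array([], dtype=int), np.zeros(3),
                np.arange(1, steps + 1) / steps)

    mat = {"radius_cortical": lib["cortical"],
           "radius_cancellous": lib["cancellous"],
           "radius_cartilage": lib["cartilage"]}
    case = SimulationCase(mesh, mat, bcs, external_forces=f_ext)
    asm = Assembler(case)
    result = _solve_with_load_ramp(asm, case, f_ext)
    energy = asm.strain_energy_by_region(
        result.displacements[-1].reshape(-1)) if result.n_steps else {}
    total = sum(energy.values()) or 1.0
    fractions = {k: v / total for k, v in energy.items()}
    load_info = {"n_patch_faces": int(sel.sum()),
                 "patch_area_mm2": float(area[sel].sum()),
                 "pressure_MPa": pressure_mpa,
                 "patch_centers_x": [-x0, x0]}
    return result, fractions, load_info


def _solve_with_load_ramp(asm: Assembler, case: SimulationCase,
                          f_ext_full: np.ndarray) -> FieldResult:
    """Newton solve where the external force ramps with the step fraction."""
    n = asm.n
    u = np.zeros(3 * n)
    log: list[tuple[int, int, float]] = []
    disps, stresses, reactions, reached = [], [], [], []
    divergence = None
    for step_index, t in enumerate(case.bcs.ramp):
        asm.f_ext = float(t) * f_ext_full.reshape(-1)
        ok, norms, reason = _solve_step(asm, u, float(t), step_index, log)
        if not ok:
            divergence = DivergenceRecord(step_index, float(t), len(norms),
                                          norms, reason)
            break
        disps.append(u.reshape(-1, 3).copy())
        stresses.append(asm.element_stresses(u))
        r, _ = asm.residual_and_tangent(u, need_tangent=False)
        rx = np.zeros((n, 3))
        rx.reshape(-1)[asm.constrained_dofs] = r[asm.constrained_dofs]
        reactions.append(rx)
        reached.append(float(t))
    return FieldResult(
        displacements=np.array(disps) if disps else np.zeros((0, n, 3)),
        stresses=(np.array(stresses) if stresses
                  else np.zeros((0, len(case.mesh.tets), 3, 3))),
        ramp=np.array(reached), converged=divergence is None,
        divergence=divergence, log=log, mesh=case.mesh,
        reactions=np.array(reactions) if reactions else None)


def assemble(case: SimulationCase, u: np.ndarray | None = None):
    """Residual vector and tangent matrix at a given displacement state."""
    asm = Assembler(case)
    if u is None:
        u = np.zeros(3 * asm.n)
    return asm.residual_and_tangent(np.asarray(u, dtype=float).reshape(-1))


def detect_mechanism(case: SimulationCase, rel_tol: float = 1e-12,
                     n_probe: int = 16) -> int:
    """Count near-zero-energy modes of the constrained reference tangent.

    Returns the number of eigenvalues below ``rel_tol`` times the largest;
    0 means the assembly is fully constrained, >= 1 means it can move as a
    mechanism (the diagnosis for the SLIL-removed model).
    """
    asm = Assembler(case)
    _, K = asm.residual_and_tangent(np.zeros(3 * asm.n), need_tangent=True)
    free = asm.free_dofs
    Kff = K[free][:, free].tocsc()
    m = Kff.shape[0]
    if m == 0:
        return 0
    if m <= 600:
        w = np.linalg.eigvalsh(Kff.toarray())
        lam_max = w[-1]
        return int((w < rel_tol * lam_max).sum())
    lam_max = spla.eigsh(Kff, k=1, which="LA",
                         return_eigenvectors=False, tol=1e-4)[0]
    k = min(n_probe, m - 2)
    shift = -rel_tol * lam_max
    w = spla.eigsh(Kff, k=k, sigma=shift, which="LM",
                   return_eigenvectors=False)
    count = int((w < rel_tol * lam_max).sum())
    if count >= k:       # all probed modes were near zero; report >= k
        count = k
    return count
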