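"""Quasi-static axisymmetric finite-element solver.

Displacement-based total-Lagrangian formulation on six-node triangles with
three-point quadrature (the slight under-integration of the quadratic
element relieves volumetric locking at the model's near-incompressible
Poisson ratios of 0.48-0.49). The nonlinear equilibrium equations
div(sigma) = 0 with dead-load tractions are solved by Newton iteration with
backtracking line search, incremental loading and automatic step halving.
The linearized systems go through SuperLU (scipy sparse direct solve) with
its default deterministic ordering, so repeated runs are bit-identical.

Axisymmetric kinematics: with displacements (u_r, u_z) on the (r, z)
half-plane, the deformation gradient in the rotating frame is

    F = [[1 + du_r/dr, du_r/dz, 0 ], [du_z/dr, 1 + du_z/dz, 0],
         [0, 0, 1 + u_r/r]]

and every volume integral carries the revolution weight 2 pi r.
"""

from __future__ import annotations

from dataclasses import dataclass

import logging

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import AxisymMesh, REGIONS, REGION_NAMES
from .materials import (
    MaterialSpec,
    ViscoHistory,
    cauchy_from_pk1,
    neo_hookean_pk1,
    neo_hookean_pk2,
    svk_pk1,
    viscoelastic_multiplier,
)

__all__ = [
    "SolverSettings",
    "SolutionState",
    "AxisymOperator",
    "assemble",
    "solve_quasistatic",
    "solve_viscoelastic",
    "NonConvergenceError",
    "materials_as_elastic",
    "prolong_solution",
]

# quadrature rules on the reference triangle (weights sum to 1/2)
_QP3 = np.array([[1 / 6, 1 / 6], [2 / 3, 1 / 6], [1 / 6, 2 / 3]])
_QW3 = np.array([1 / 6, 1 / 6, 1 / 6])
_A6, _B6 = 0.445948490915965, 0.091576213509771
_QP6 = np.array(
    [[_A6, _A6], [1 - 2 * _A6, _A6], [_A6, 1 - 2 * _A6],
     [_B6, _B6], [1 - 2 * _B6, _B6], [_B6, 1 - 2 * _B6]]
)
_QW6 = np.array([0.111690794839005] * 3 + [0.054975871827661] * 3)
# default: 3-point (degree 2). Exact for the T6 stiffness would be degree 4
# (_QP6); the mild under-integration relieves near-incompressible locking.
_QP, _QW = _QP3, _QW3

# 5 active components of F in the axisymmetric frame
_IDX5 = ([0, 0, 1, 1, 2], [0, 1, 0, 1, 2])


logger = logging.getLogger("cellindent")


class NonConvergenceError(RuntimeError):
    """Newton iteration failed to converge after automatic step halving."""


class AssemblyError(RuntimeError):
    """Raised when an element inverts during assembly (carries element ids)."""


def _t3_shapes(xi: np.ndarray):
    """Linear (constant-strain) triangle shape functions at points xi."""
    x, y = xi[:, 0], xi[:, 1]
    z = 1.0 - x - y
    N = np.column_stack([z, x, y])
    ones, zeros = np.ones_like(x), np.zeros_like(x)
    dN = np.stack(
        [
            np.column_stack([-ones, ones, zeros]),
            np.column_stack([-ones, zeros, ones]),
        ],
        axis=-1,
    )
    return N, dN


def _t6_shapes(xi: np.ndarray):
    """T6 shape functions and reference-gradient at points xi (n, 2)."""
    x, y = xi[:, 0], xi[:, 1]
    z = 1.0 - x - y
    N = np.column_stack(
        [z * (2 * z - 1), x * (2 * x - 1), y * (2 * y - 1), 4 * z * x, 4 * x * y, 4 * y * z]
    )
    zeros = np.zeros_like(x)
    dN = np.stack(
        [
            np.column_stack([1 - 4 * z, 4 * x - 1, zeros, 4 * (z - x), 4 * y, -4 * y]),
            np.column_stack([1 - 4 * z, zeros, 4 * y - 1, -4 * x, 4 * x, 4 * (z - y)]),
        ],
        axis=-1,
    )  # (n, 6, 2): d/dxi, d/deta
    return N, dN


@dataclass
class SolverSettings:
    """Newton/incrementation controls. Tolerances are relative residuals."""

    n_load_steps: int = 8
    newton_tol: float = 1e-8
    max_newton_iters: int = 14
    max_damped_iters: int = 120
    line_search: bool = True
    max_halvings: int = 8
    element_order: int = 2
    quadrature: str = "reduced"
    dt: float = 0.25
    ramp_time: float = 1.0
    hold_time: float = 400.0
    ramp_steps: int = 8
    dt_growth: float = 1.4
    dt_max: float = 15.0
    steady_state_tol: float = 1e-4

    def __post_init__(self) -> None:
        if self.n_load_steps < 1:
            raise ValueError("n_load_steps must be >= 1")
        if not 0.0 < self.newton_tol < 1.0:
            raise ValueError("newton_tol must lie in (0, 1)")


@dataclass
class SolutionState:
    """Converged solution snapshot.

    Quadrature-point arrays are ordered element-major (element e owns rows
    3e..3e+2); ``qp_weights`` are the revolved reference quadrature weights
    (2 pi r detJ w), so volume integrals are plain weighted sums.
    """

    u: np.ndarray
    F: np.ndarray
    sigma: np.ndarray
    qp_elem: np.ndarray
    qp_weights: np.ndarray
    qp_pos: np.ndarray
    converged: bool = True
    residual_norm: float = 0.0
    lam: float = 1.0
    time: float = 0.0
    history: ViscoHistory | None = None
    n_newton: int = 0


class AxisymOperator:
    """Precomputed element data + residual/tangent evaluation for one mesh."""

    def __init__(
        self,
        mesh: AxisymMesh,
        materials: dict[str, MaterialSpec],
        quadrature: str = "reduced",
        element_order: int = 2,
    ):
        self.mesh = mesh
        self.materials = dict(materials)
        self.element_order = element_order
        qp, qw = (_QP3, _QW3) if quadrature == "reduced" else (_QP6, _QW6)
        nqp = len(qw)
        self.nqp_per_elem = nqp
        present = {REGION_NAMES[t] for t in np.unique(mesh.region)}
        missing = present - set(self.materials)
        if missing:
            raise ValueError(f"no material given for region(s) {sorted(missing)}")

        nodes = mesh.nodes
        elems = mesh.elems if element_order == 2 else mesh.elems[:, :3]
        ne = mesh.n_elems
        nen = elems.shape[1]
        self.nen = nen
        N, dN = (_t6_shapes if element_order == 2 else _t3_shapes)(qp)
        p0 = nodes[elems[:, 0]]
        J = np.stack(
            [nodes[elems[:, 1]] - p0, nodes[elems[:, 2]] - p0], axis=-1
        )  # (ne,2,2) columns are edge vectors
        detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
        if np.any(detJ <= 0):
            raise AssemblyError("negatively oriented element in mesh")
        Jinv = np.empty_like(J)
        Jinv[:, 0, 0] = J[:, 1, 1]
        Jinv[:, 0, 1] = -J[:, 0, 1]
        Jinv[:, 1, 0] = -J[:, 1, 0]
        Jinv[:, 1, 1] = J[:, 0, 0]
        Jinv /= detJ[:, None, None]
        # area-coordinate gradient wrt (xi,eta) maps through Jinv: dN/dx (ne,3,6,2)
        dNdx = np.einsum("qna,eab->eqnb", dN, Jinv, optimize=True)
        xq = np.einsum("qn,end->eqd", N, nodes[elems], optimize=True)  # (ne,3,2)
        rq = xq[..., 0]
        if np.any(rq <= 0):
            raise AssemblyError("quadrature point at r <= 0")
        w = detJ[:, None] * qw[None, :] * 2.0 * np.pi * rq  # (ne,nqp)

        # B: (ne, nqp, 5, 2*nen) mapping element dofs -> delta F (5 comps)
        B = np.zeros((ne, nqp, 5, 2 * nen))
        rcols = np.arange(0, 2 * nen, 2)
        zcols = np.arange(1, 2 * nen, 2)
        B[:, :, 0, rcols] = dNdx[..., 0]
        B[:, :, 1, rcols] = dNdx[..., 1]
        B[:, :, 2, zcols] = dNdx[..., 0]
        B[:, :, 3, zcols] = dNdx[..., 1]
        B[:, :, 4, rcols] = N[None, :, :] / rq[..., None]

        self.B = B
        self.w = w
        self.qp_pos = xq.reshape(-1, 2)
        self.qp_elem = np.repeat(np.arange(ne), nqp)
        self.n_qp = nqp * ne
        edofs = np.empty((ne, 2 * nen), dtype=int)
        edofs[:, 0::2] = 2 * elems
        edofs[:, 1::2] = 2 * elems + 1
        self.edofs = edofs
        self.ndof = 2 * mesh.n_nodes
        self._rows = np.repeat(edofs, 2 * nen, axis=1).ravel()
        self._cols = np.tile(edofs, (1, 2 * nen)).ravel()
        used = np.unique(elems)
        unused = np.setdiff1d(np.arange(mesh.n_nodes), used, assume_unique=False)
        # dofs of nodes not referenced by this element order (midside nodes
        # under P1): pinned so the reduced system stays nonsingular
        self.unused_dofs = np.concatenate([2 * unused, 2 * unused + 1])
        # element ids per region, in mesh order
        self.region_elems = {
            name: np.flatnonzero(mesh.region == tag)
            for name, tag in REGIONS.items()
            if np.any(mesh.region == tag)
        }

    # -- kinematics ---------------------------------------------------------

    def deformation_gradients(self, u: np.ndarray) -> np.ndarray:
        """F (n_qp, 3, 3) from the nodal displacement vector."""
        ue = u[self.edofs]  # (ne, 12)
        Fv = np.einsum("eqci,ei->eqc", self.B, ue, optimize=True)
        Fv = Fv.reshape(-1, 5) + np.array([1.0, 0.0, 0.0, 1.0, 1.0])
        F = np.zeros((self.n_qp, 3, 3))
        F[:, _IDX5[0], _IDX5[1]] = Fv
        return F

    # -- constitutive dispatch ---------------------------------------------

    def _qp_slice(self, region: str) -> np.ndarray:
        el = self.region_elems[region]
        nqp = self.nqp_per_elem
        return (nqp * el[:, None] + np.arange(nqp)[None, :]).ravel()

    def stress_and_tangent(
        self,
        F: np.ndarray,
        need_tangent: bool = True,
        dt: float | None = None,
        history: ViscoHistory | None = None,
    ):
        """PK1 stress (n_qp,3,3), tangent (n_qp,3,3,3,3) and the trial elastic
        PK2 stress of viscoelastic regions (for history commits)."""
        P = np.zeros((self.n_qp, 3, 3))
        A = np.zeros((self.n_qp, 3, 3, 3, 3)) if need_tangent else None
        Se_trial = None
        for region, spec in self.materials.items():
            if region not in self.region_elems:
                continue
            qs = self._qp_slice(region)
            Fr = F[qs]
            if spec.law in ("neo_hookean", "linear_elastic"):
                # "linear_elastic" = Hookean (E, nu) response carried by the
                # compressible Neo-Hookean kernel: identical small-strain
                # limit, but stable under the large local compression at the
                # contact (Saint Venant-Kirchhoff loses convexity there and
                # is only available as the explicit 'svk' law).
                lam, mu = spec.lame
                Pr, Ar = neo_hookean_pk1(Fr, lam, mu, tangent=need_tangent)
            elif spec.law == "svk":
                lam, mu = spec.lame
                Pr, Ar = svk_pk1(Fr, lam, mu, tangent=need_tangent)
            elif spec.law == "viscoelastic_prony":
                if dt is None or history is None:
                    raise ValueError(
                        "viscoelastic region requires dt and history (use solve_viscoelastic)"
                    )
                from .materials import lame_from_E_nu

                lam, mu = lame_from_E_nu(spec.E_instantaneous, spec.nu)
                Se, H = neo_hookean_pk2(Fr, lam, mu, tangent=need_tangent)
                m = viscoelastic_multiplier(dt, spec.prony)
                from .materials import _branch_coeffs

                coeffs = _branch_coeffs(dt, spec.prony)
                S_hist = sum(e * h[qs] for (e, _), h in zip(coeffs, history.branches))
                S_hist = S_hist - sum(b for _, b in coeffs) * history.stress_prev[qs]
                Sv = m * Se + S_hist
                Pr = Fr @ Sv
                Se_trial = (qs, Se)
                if need_tangent:
                    Ar = np.einsum("ik,...JL->...iJkL", np.eye(3), Sv, optimize=True)
                    Ar = Ar + m * np.einsum("...iM,...MJkL->...iJkL", Fr, H, optimize=True)
                else:
                    Ar = None
            else:  # pragma: no cover
                raise ValueError(f"unknown law {spec.law!r}")
            P[qs] = Pr
            if need_tangent:
                A[qs] = Ar
        return P, A, Se_trial

    # -- assembly -----------------------------------------------------------

    def internal_force(self, P: np.ndarray) -> np.ndarray:
        Pv = P[:, _IDX5[0], _IDX5[1]].reshape(-1, self.nqp_per_elem, 5)
        fe = np.einsum("eqci,eqc,eq->ei", self.B, Pv, self.w, optimize=True)
        f = np.zeros(self.ndof)
        np.add.at(f, self.edofs.ravel(), fe.ravel())
        return f

    def tangent_matrix(self, A: np.ndarray) -> sp.csr_matrix:
        A5 = A[:, _IDX5[0], _IDX5[1]][:, :, _IDX5[0], _IDX5[1]]
        A5 = A5.reshape(-1, self.nqp_per_elem, 5, 5)
        Ke = np.einsum(
            "eqci,eqcd,eqdj,eq->eij", self.B, A5, self.B, self.w, optimize=True
        )
        K = sp.coo_matrix(
            (Ke.ravel(), (self._rows, self._cols)), shape=(self.ndof, self.ndof)
        )
        return K.tocsr()


# ---------------------------------------------------------------------------
# boundary-condition reduction
# ---------------------------------------------------------------------------


class _Reduction:
    """Maps full dofs to reduced unknowns: fixed dofs eliminated, rigid-group
    slave dofs condensed onto one master unknown each."""

    def __init__(self, ndof: int, bcs, extra_fixed: np.ndarray | None = None) -> None:
        self.ndof = ndof
        fixed = np.asarray(bcs.fixed_dofs, dtype=int) if len(bcs.fixed_dofs) else np.empty(0, int)
        vals = np.asarray(bcs.fixed_values, dtype=float) if len(bcs.fixed_dofs) else np.empty(0)
        if extra_fixed is not None and len(extra_fixed):
            extra = np.setdiff1d(np.asarray(extra_fixed, int), fixed)
            fixed = np.concatenate([fixed, extra])
            vals = np.concatenate([vals, np.zeros(extra.size)])
        self.fixed_dofs, self.fixed_values = fixed, vals
        mapping = np.full(ndof, -2, dtype=int)  # -2 free (to number), -1 fixed
        mapping[fixed] = -1
        groups = list(getattr(bcs, "rigid_groups", []) or [])
        self.groups = groups
        nxt = 0
        # masters first so group forces have stable indices
        self.master_index = []
        for dofs, _force in groups:
            self.master_index.append(nxt)
            mapping[np.asarray(dofs, int)] = -3 - len(self.master_index) + 1  # placeholder
            nxt += 1
        free = np.flatnonzero(mapping == -2)
        mapping[free] = nxt + np.arange(free.size)
        for gi, (dofs, _force) in enumerate(groups):
            mapping[np.asarray(dofs, int)] = self.master_index[gi]
        self.map = mapping
        self.n_red = nxt + free.size
        self.free = free

    def apply_fixed(self, u: np.ndarray, lam: float) -> None:
        if self.fixed_dofs.size:
            u[self.fixed_dofs] = lam * self.fixed_values

    def reduce_vec(self, v: np.ndarray) -> np.ndarray:
        out = np.zeros(self.n_red)
        keep = self.map >= 0
        np.add.at(out, self.map[keep], v[keep])
        return out

    def group_force(self, lam: float) -> np.ndarray:
        out = np.zeros(self.n_red)
        for gi, (_dofs, force) in enumerate(self.groups):
            out[self.master_index[gi]] += lam * float(force)
        return out

    def reduce_mat(self, K: sp.csr_matrix) -> sp.csr_matrix:
        Kc = K.tocoo()
        r, c, v = self.map[Kc.row], self.map[Kc.col], Kc.data
        keep = (r >= 0) & (c >= 0)
        return sp.coo_matrix((v[keep], (r[keep], c[keep])), shape=(self.n_red, self.n_red)).tocsr()

    def expand(self, dq: np.ndarray) -> np.ndarray:
        du = np.zeros(self.ndof)
        keep = self.map >= 0
        du[keep] = dq[self.map[keep]]
        return du


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------


def prolong_solution(mesh_from, u_from: np.ndarray, mesh_to) -> np.ndarray:
    """Interpolate a nodal displacement field onto another mesh of the same
    geometry (grid sequencing: warm-starts a refined solve from a coarse
    solution). Linear scattered interpolation with nearest-point fallback."""
    from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator

    vals = u_from.reshape(-1, 2)
    lin = LinearNDInterpolator(mesh_from.nodes, vals)
    out = lin(mesh_to.nodes)
    bad = ~np.isfinite(out[:, 0])
    if np.any(bad):
        near = NearestNDInterpolator(mesh_from.nodes, vals)
        out[bad] = near(mesh_to.nodes[bad])
    return out.reshape(-1)


def materials_as_elastic(materials: dict[str, MaterialSpec], which: str = "equilibrium"):
    """Replace viscoelastic regions by their equilibrium or instantaneous
    Neo-Hookean backbone (for reference solves and initial guesses)."""
    out = {}
    for k, m in materials.items():
        if m.law == "viscoelastic_prony":
            E = m.E_equilibrium if which == "equilibrium" else m.E_instantaneous
            out[k] = MaterialSpec(law="neo_hookean", E=E, nu=m.nu)
        else:
            out[k] = m
    return out


def _resolve_fext(mesh: AxisymMesh, loadcase, element_order: int = 2) -> np.ndarray:
    if loadcase is None:
        return np.zeros(2 * mesh.n_nodes)
    if isinstance(loadcase, np.ndarray):
        return loadcase
    from .loading import build_load_case

    return build_load_case(mesh, loadcase, element_order=element_order)


def assemble(mesh, materials, state_u, loadcase=None, bcs=None, lam: float = 1.0):
    """Residual (internal - external force) and consistent tangent at a
    displacement vector. Elastic laws only; mainly a verification surface."""
    op = mesh if isinstance(mesh, AxisymOperator) else AxisymOperator(mesh, materials)
    u = np.asarray(state_u, dtype=float)
    F = op.deformation_gradients(u)
    P, A, _ = op.stress_and_tangent(F, need_tangent=True)
    fext = _resolve_fext(op.mesh, loadcase, op.element_order)
    R = op.internal_force(P) - lam * fext
    K = op.tangent_matrix(A)
    return R, K


def _newton(
    op: AxisymOperator,
    red: _Reduction,
    u: np.ndarray,
    fext: np.ndarray,
    lam: float,
    settings: SolverSettings,
    dt: float | None = None,
    history: ViscoHistory | None = None,
):
    """Newton solve at fixed load factor; returns (u, P, F, Se_trial, rnorm, iters)."""
    red.apply_fixed(u, lam)
    fext_red = red.reduce_vec(lam * fext) + red.group_force(lam)
    ref = np.linalg.norm(fext_red)
    if ref == 0.0:
        ref = 1.0

    def residual(uv):
        F = op.deformation_gradients(uv)
        P, A, Se = op.stress_and_tangent(F, need_tangent=True, dt=dt, history=history)
        R = red.reduce_vec(op.internal_force(P)) - fext_red
        return F, P, A, Se, R

    try:
        F, P, A, Se, R = residual(u)
    except FloatingPointError as err:
        raise NonConvergenceError(f"initial state invalid: {err}") from err
    rnorm = np.linalg.norm(R)
    damped = False
    alpha = 0.1  # Levenberg shift (kPa um) once the plain Newton path stalls
    it_budget = settings.max_newton_iters
    for it in range(it_budget + settings.max_damped_iters):
        if rnorm <= settings.newton_tol * ref:
            return u, P, F, Se, rnorm / ref, it
        if it >= it_budget and not damped:
            damped = True
        K = red.reduce_mat(op.tangent_matrix(A))
        if not damped:
            dq = spla.spsolve(K, -R)
            if not np.all(np.isfinite(dq)):
                damped = True
            else:
                du = red.expand(dq)
                step = 1.0
                accepted = False
                for _ in range(8):
                    try:
                        Ft, Pt, At, Set, Rt = residual(u + step * du)
                    except FloatingPointError:
                        step *= 0.5
                        continue
                    rt = np.linalg.norm(Rt)
                    if (
                        (not settings.line_search)
                        or rt < rnorm
                        or rt <= settings.newton_tol * ref
                    ):
                        accepted = True
                        break
                    step *= 0.5
                if accepted:
                    u = u + step * du
                    F, P, A, Se, R, rnorm = Ft, Pt, At, Set, Rt, rt
                    continue
                damped = True  # fall through to the damped update this iteration
        if damped:
            if settings.max_damped_iters == 0:
                raise NonConvergenceError("line search failed")
            I = sp.identity(red.n_red, format="csr")
            accepted = False
            for _ in range(30):
                dq = spla.spsolve(K + alpha * I, -R)
                if not np.all(np.isfinite(dq)):
                    alpha *= 5.0
                    continue
                try:
                    Ft, Pt, At, Set, Rt = residual(u + red.expand(dq))
                except FloatingPointError:
                    alpha *= 5.0
                    continue
                rt = np.linalg.norm(Rt)
                if rt < rnorm * 1.2:
                    u = u + red.expand(dq)
                    F, P, A, Se, R, rnorm = Ft, Pt, At, Set, Rt, rt
                    alpha = max(alpha * 0.4, 1e-4)
                    accepted = True
                    break
                alpha *= 5.0
            if not accepted or alpha > 1e7:
                raise NonConvergenceError(
                    f"damped Newton stalled at relative residual {rnorm / ref:.3e}"
                )
    if rnorm <= settings.newton_tol * ref:
        return u, P, F, Se, rnorm / ref, it_budget
    raise NonConvergenceError(f"Newton stalled at relative residual {rnorm / ref:.3e}")


def _make_state(op, u, P, F, lam, rnorm, time=0.0, history=None, n_newton=0):
    return SolutionState(
        u=u,
        F=F,
        sigma=cauchy_from_pk1(F, P),
        qp_elem=op.qp_elem,
        qp_weights=op.w.reshape(-1),
        qp_pos=op.qp_pos,
        converged=True,
        residual_norm=rnorm,
        lam=lam,
        time=time,
        history=history,
        n_newton=n_newton,
    )


def solve_quasistatic(
    mesh: AxisymMesh,
    materials: dict[str, MaterialSpec],
    loadcase,
    bcs,
    settings: SolverSettings | None = None,
    u0: np.ndarray | None = None,
) -> SolutionState:
    """Incremental Newton solve of the elastic problem at full load.

    ``loadcase`` may be a :class:`~cellindent.loading.LoadCase` or a raw
    external force vector. Viscoelastic materials are rejected here; use
    :func:`solve_viscoelastic`.
    """
    if any(m.law == "viscoelastic_prony" for m in materials.values()):
        raise ValueError("viscoelastic materials require solve_viscoelastic")
    settings = settings or SolverSettings()
    op = AxisymOperator(
        mesh, materials, quadrature=settings.quadrature, element_order=settings.element_order
    )
    red = _Reduction(op.ndof, bcs, extra_fixed=op.unused_dofs)
    fext = _resolve_fext(mesh, loadcase, op.element_order)

    if u0 is not None:
        # warm start (grid sequencing): try the full load directly
        try:
            u, P, F, _, rnorm, iters = _newton(op, red, u0.copy(), fext, 1.0, settings)
            return _make_state(op, u, P, F, 1.0, rnorm, n_newton=iters)
        except NonConvergenceError:
            logger.debug("warm start at full load failed; falling back to continuation")
    u = np.zeros(op.ndof)
    u_prev = None
    lam_done, lam_prev = 0.0, 0.0
    dlam = 1.0 / settings.n_load_steps
    dlam_min = dlam / 2**settings.max_halvings
    total_newton = 0
    P = F = None
    rnorm = 0.0
    while lam_done < 1.0 - 1e-12:
        lam_try = min(1.0, lam_done + dlam)
        # secant predictor along the load path, plain restart as fallback
        guesses = [u.copy()]
        if u_prev is not None and lam_done > lam_prev:
            pred = u + (lam_try - lam_done) / (lam_done - lam_prev) * (u - u_prev)
            guesses.insert(0, pred)
        for gi, u_guess in enumerate(guesses):
            try:
                u_new, P, F, _, rnorm, iters = _newton(
                    op, red, u_guess.copy(), fext, lam_try, settings
                )
                break
            except NonConvergenceError:
                if gi == len(guesses) - 1:
                    u_new = None
        if u_new is None:
            dlam *= 0.5
            if dlam < dlam_min:
                raise NonConvergenceError(
                    f"no convergence at load factor {lam_try:.4f}; "
                    f"increment underflow below {dlam_min:.2e}"
                )
            continue
        u_prev, lam_prev = u, lam_done
        u, lam_done = u_new, lam_try
        total_newton += iters
        logger.debug("load step to lam=%.4f in %d Newton iters", lam_done, iters)
        if iters <= 6:
            dlam = min(dlam * 1.5, 1.0 / settings.n_load_steps)
    if P is None:  # zero-step edge case (already at full load)
        u, P, F, _, rnorm, _ = _newton(op, red, u, fext, 1.0, settings)
    return _make_state(op, u, P, F, 1.0, rnorm, n_newton=total_newton)


def solve_viscoelastic(
    mesh: AxisymMesh,
    materials: dict[str, MaterialSpec],
    loadcase,
    bcs,
    settings: SolverSettings | None = None,
) -> list[SolutionState]:
    """Ramp-and-hold time stepping with the Prony-series cytoplasm.

    The load ramps linearly over ``settings.ramp_time`` (a near-instantaneous
    step when zero) and is then held; stepping stops when the per-step
    relative change of gel indentation depth falls below
    ``settings.steady_state_tol`` or ``hold_time`` is exhausted. Returns the
    list of converged states (one per accepted time step).
    """
    if not any(m.law == "viscoelastic_prony" for m in materials.values()):
        raise ValueError("no viscoelastic region; use solve_quasistatic")
    settings = settings or SolverSettings()
    op = AxisymOperator(
        mesh, materials, quadrature=settings.quadrature, element_order=settings.element_order
    )
    red = _Reduction(op.ndof, bcs, extra_fixed=op.unused_dofs)
    fext = _resolve_fext(mesh, loadcase, op.element_order)
    from .postprocess import indentation_depth

    hist = ViscoHistory.zeros(op.n_qp)
    u = np.zeros(op.ndof)
    states: list[SolutionState] = []
    t = 0.0
    ramp = max(settings.ramp_time, 0.0)
    t_end = ramp + settings.hold_time
    dt = ramp / settings.ramp_steps if ramp > 0 else 1e-6
    depth_prev = None
    halvings = 0
    while t < t_end - 1e-12:
        dt = min(dt, t_end - t)
        t_new = t + dt
        lam = min(1.0, t_new / ramp) if ramp > 0 else 1.0
        try:
            u_new, P, F, Se, rnorm, iters = _newton(
                op, red, u.copy(), fext, lam, settings, dt=dt, history=hist
            )
        except NonConvergenceError:
            halvings += 1
            if halvings > settings.max_halvings:
                raise NonConvergenceError(f"viscoelastic step at t={t_new:.3f}s failed")
            dt *= 0.5
            continue
        # commit history with the converged elastic trial stress
        qs, Se_arr = Se
        from .materials import viscoelastic_stress_update

        spec = next(m for m in materials.values() if m.law == "viscoelastic_prony")
        sub = ViscoHistory(
            branches=[b[qs] for b in hist.branches],
            stress_prev=hist.stress_prev[qs],
            time=hist.time,
        )
        _, sub_new = viscoelastic_stress_update(sub, dt, Se_arr, spec.prony)
        for b_old, b_new in zip(hist.branches, sub_new.branches):
            b_old[qs] = b_new
        hist.stress_prev[qs] = Se_arr
        hist.time += dt
        u, t = u_new, t_new
        st = _make_state(op, u, P, F, lam, rnorm, time=t, history=hist.copy(), n_newton=iters)
        states.append(st)
        if t >= ramp:  # steady-state check during hold
            depth = indentation_depth(st, mesh)
            if depth_prev is not None and depth > 0:
                if abs(depth - depth_prev) / depth <= settings.steady_state_tol:
                    break
            depth_prev = depth
            dt = min(dt * settings.dt_growth, settings.dt_max)
            dt = max(dt, settings.dt)
    return states
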