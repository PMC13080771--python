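"""Self-equilibrated load cases and displacement boundary conditions.

The cell loads itself: a downward central force routed through the top or
bottom third of the nucleus is balanced by upward-and-inward tractions on a
thin annular band at the cell-base perimeter, the resultant of which is
angled at 50 degrees to the gel surface (traction-force-microscopy
orientation). The net applied force is therefore zero and the gel reacts
only through the tied contact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import AxisymMesh
from .materials import MaterialSpec, PronyParams

__all__ = [
    "LoadCase",
    "BCSet",
    "decompose_perimeter_force",
    "build_load_case",
    "build_bcs",
    "default_materials",
]

_GAUSS3 = (
    np.array([-np.sqrt(3.0 / 5.0), 0.0, np.sqrt(3.0 / 5.0)]),
    np.array([5.0 / 9.0, 8.0 / 9.0, 5.0 / 9.0]),
)


@dataclass(frozen=True)
class LoadCase:
    """One force-application scenario.

    ``F_normal`` (nN) is both the magnitude of the downward central force and
    of the upward perimeter resultant. ``config`` selects whether the central
    force acts through the top or the bottom third of the nucleus. The
    ramp/hold protocol only matters for viscoelastic runs.
    """

    F_normal: float = 300.0
    config: str = "top"
    angle_deg: float = 50.0
    ramp_time: float = 1.0
    hold_time: float = 400.0

    def __post_init__(self) -> None:
        if self.F_normal <= 0:
            raise ValueError("F_normal must be positive")
        if self.config not in ("top", "bottom"):
            raise ValueError("config must be 'top' or 'bottom'")
        if not 0.0 < self.angle_deg < 90.0:
            raise ValueError("traction angle must lie strictly between 0 and 90 degrees")


@dataclass
class BCSet:
    """Homogeneous/inhomogeneous Dirichlet data plus optional rigid ties.

    ``rigid_groups`` is a list of (dof array, applied force); all dofs of a
    group share one unknown (used by the rigid flat-punch fixture).
    """

    fixed_dofs: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    fixed_values: np.ndarray = field(default_factory=lambda: np.empty(0))
    rigid_groups: list = field(default_factory=list)


def decompose_perimeter_force(F_normal: float, angle_deg: float):
    """Split the perimeter resultant into its vertical and in-plane parts.

    The total perimeter force is angled at ``angle_deg`` to the gel surface;
    its vertical (upward) resultant equals ``F_normal`` and the in-plane
    (inward) traction resultant is F_normal / tan(angle). Returns
    (F_up, F_traction) in nN.
    """
    if not 0.0 < angle_deg < 90.0:
        raise ValueError("degenerate decomposition: angle must lie in (0, 90) degrees")
    if F_normal <= 0:
        raise ValueError("F_normal must be positive")
    a = np.deg2rad(angle_deg)
    return F_normal, F_normal / np.tan(a)


def _edge_consistent_forces(mesh: AxisymMesh, edges: np.ndarray, traction: np.ndarray):
    """Consistent nodal forces for a constant traction (kPa) over revolved
    quadratic edges; returns (ndof,) force vector and the revolved band area."""
    f = np.zeros(2 * mesh.n_nodes)
    xi, wq = _GAUSS3
    # quadratic edge shape functions on [-1, 1], nodes (end, end, mid)
    N = np.column_stack([0.5 * xi * (xi - 1.0), 0.5 * xi * (xi + 1.0), 1.0 - xi**2])
    area = 0.0
    for a, b, m in edges:
        pts = mesh.nodes[[a, b, m]]
        # straight edge with midpoint mid-node: affine geometry
        dl = 0.5 * np.linalg.norm(mesh.nodes[b] - mesh.nodes[a])  # |dx/dxi|
        r = N @ pts[:, 0]
        wA = 2.0 * np.pi * r * dl * wq
        area += wA.sum()
        for k, node in enumerate((a, b, m)):
            f[2 * node] += np.sum(N[:, k] * wA) * traction[0]
            f[2 * node + 1] += np.sum(N[:, k] * wA) * traction[1]
    return f, area


def _body_force_consistent(
    mesh: AxisymMesh, elems: np.ndarray, density_force: np.ndarray, element_order: int = 2
):
    """Consistent nodal forces for a constant body-force density (nN/um^3)
    over the revolved volume of an element set."""
    from .solver import _t3_shapes, _t6_shapes, _QP, _QW

    f = np.zeros(2 * mesh.n_nodes)
    N, _ = (_t6_shapes if element_order == 2 else _t3_shapes)(_QP)
    for e in elems:
        conn = mesh.elems[e] if element_order == 2 else mesh.elems[e, :3]
        p = mesh.nodes[conn]
        J = np.stack([p[1] - p[0], p[2] - p[0]], axis=-1)
        detJ = J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0]
        r = N @ p[:, 0]
        w = np.abs(detJ) * _QW * 2.0 * np.pi * r
        for k, node in enumerate(conn):
            f[2 * node] += np.sum(N[:, k] * w) * density_force[0]
            f[2 * node + 1] += np.sum(N[:, k] * w) * density_force[1]
    return f


def build_load_case(mesh: AxisymMesh, lc: LoadCase, element_order: int = 2) -> np.ndarray:
    """Assemble the consistent external force vector of a load case.

    Perimeter: uniform body-force density (upward component with resultant
    F_normal, inward component with resultant F_normal/tan(angle)) over the
    annular band of cytoplasm elements hugging the base rim — force is
    carried by rim-adjacent cell volume, as in the reference configuration
    sketches. Centre: uniform downward body-force density over the chosen
    nucleus third. The assembled vertical resultant is zero to round-off.
    """
    if "perimeter_band" not in mesh.element_sets:
        raise ValueError("mesh lacks the perimeter_band element set")
    set_name = f"nucleus_{lc.config}_third"
    if set_name not in mesh.element_sets or len(mesh.element_sets[set_name]) == 0:
        raise ValueError(f"mesh lacks element set {set_name!r}")

    from .geometry import element_volumes

    vols = element_volumes(mesh)
    F_up, F_tr = decompose_perimeter_force(lc.F_normal, lc.angle_deg)
    band = mesh.element_sets["perimeter_band"]
    V_band = vols[band].sum()
    f_perim = _body_force_consistent(
        mesh, band, np.array([-F_tr / V_band, F_up / V_band]), element_order
    )

    third = mesh.element_sets[set_name]
    V = vols[third].sum()
    f_center = _body_force_consistent(
        mesh, third, np.array([0.0, -lc.F_normal / V]), element_order
    )

    f = f_perim + f_center
    net_z = f[1::2].sum()
    if abs(net_z) > 1e-9 * lc.F_normal:
        raise AssertionError(f"load case not self-equilibrated: net Fz = {net_z:.3e} nN")
    return f


def build_bcs(mesh: AxisymMesh) -> BCSet:
    """Fix the gel bottom and lateral faces (both components) and the radial
    displacement on the symmetry axis; every other surface is free."""
    fixed: set[int] = set()
    for name in ("gel_bottom", "gel_lateral"):
        if name in mesh.surface_sets:
            for n in mesh.surface_sets[name]:
                fixed.add(2 * int(n))
                fixed.add(2 * int(n) + 1)
    for n in mesh.surface_sets.get("axis", []):
        fixed.add(2 * int(n))
    dofs = np.asarray(sorted(fixed), dtype=int)
    return BCSet(fixed_dofs=dofs, fixed_values=np.zeros(dofs.size))


def default_materials(
    E_cyto: float = 0.8,
    E_nucleus: float = 2.0,
    nu_cell: float = 0.49,
    E_gel: float = 2.4,
    nu_gel: float = 0.48,
    cytoplasm_model: str = "elastic",
    prony: PronyParams | None = None,
    prony_mode: str = "equilibrium",
) -> dict[str, MaterialSpec]:
    """Region materials with the study's default constants.

    ``cytoplasm_model`` is 'elastic' (Neo-Hookean) or 'viscoelastic'
    (Prony-series quasi-linear viscoelasticity on a Neo-Hookean backbone).
    """
    if cytoplasm_model == "elastic":
        cyto = MaterialSpec(law="neo_hookean", E=E_cyto, nu=nu_cell)
    elif cytoplasm_model == "viscoelastic":
        cyto = MaterialSpec(
            law="viscoelastic_prony",
            E=E_cyto,
            nu=nu_cell,
            prony=prony or PronyParams(),
            prony_mode=prony_mode,
        )
    else:
        raise ValueError("cytoplasm_model must be 'elastic' or 'viscoelastic'")
    return {
        "cytoplasm": cyto,
        "nucleus": MaterialSpec(law="neo_hookean", E=E_nucleus, nu=nu_cell),
        "gel": MaterialSpec(law="linear_elastic", E=E_gel, nu=nu_gel),
    }
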