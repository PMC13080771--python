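"""Outcome metrics: indentation depth, region stress aggregates,
gel-transmitted stress, nucleus shape and top-vs-bottom percentage
differences.

All stresses are Cauchy stresses at quadrature points, aggregated with the
revolved reference quadrature weights; no nodal extrapolation is performed
(it would smooth the contact-edge concentration). The scalar reported for a
region is by default the volume mean; maxima and volume sums are available
since the aggregation statistic behind single-number "stress in the
nucleus/gel" summaries is a modelling choice.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .geometry import AxisymMesh
from .materials import total_stress, von_mises
from .solver import SolutionState

__all__ = [
    "ResultSummary",
    "indentation_depth",
    "region_stress_aggregate",
    "gel_transmitted_stress",
    "percent_difference",
    "nucleus_aspect_ratio",
    "average_effective_strain",
    "summarize",
]

_MEASURES = ("total", "von_mises")
_MODES = ("volume_mean", "max", "volume_sum")


@dataclass
class ResultSummary:
    """Scalar outcomes of one converged run (stresses in kPa, depth in um)."""

    indentation_depth: float
    nucleus_total_stress: float
    nucleus_vm_stress: float
    cytoplasm_total_stress: float
    cytoplasm_vm_stress: float
    gel_transmitted_stress: float
    nucleus_aspect_ratio: float
    avg_effective_strain_cell: float
    force_nN: float = np.nan
    E_cyto: float = np.nan
    config: str = ""
    material_model: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


def _check_converged(state: SolutionState) -> None:
    if not state.converged:
        raise ValueError("refusing to post-process an unconverged state")


def _qp_mask_for_elems(state: SolutionState, elem_ids: np.ndarray) -> np.ndarray:
    sel = np.zeros(state.qp_elem.max() + 1, dtype=bool)
    sel[elem_ids] = True
    return sel[state.qp_elem]


def indentation_depth(state: SolutionState, mesh: AxisymMesh) -> float:
    """Maximum downward vertical displacement of the gel top surface (um).

    The paper's primary invasiveness proxy; nonnegative by convention (zero
    if the surface nowhere moves down).
    """
    _check_converged(state)
    top = mesh.surface_sets["gel_top_free"]
    uz = state.u[2 * top + 1]
    return float(max(0.0, -(uz.min())))


def region_stress_aggregate(
    state: SolutionState,
    mesh: AxisymMesh,
    region: str,
    measure: str = "total",
    mode: str = "volume_mean",
) -> float:
    """Aggregate a pointwise stress measure over a region's revolved volume.

    ``measure``: 'total' (trace of Cauchy stress, the sum of the three
    directional stresses) or 'von_mises'. ``mode``: 'volume_mean' (default
    reported scalar), 'max' or 'volume_sum' (kPa*um^3). The 'max' of the
    signed total stress is the extremum by magnitude.
    """
    if measure not in _MEASURES:
        raise KeyError(f"unknown measure {measure!r}; expected one of {_MEASURES}")
    if mode not in _MODES:
        raise KeyError(f"unknown mode {mode!r}; expected one of {_MODES}")
    _check_converged(state)
    mask = _qp_mask_for_elems(state, mesh.region_elems(region))
    sig = state.sigma[mask]
    w = state.qp_weights[mask]
    vals = total_stress(sig) if measure == "total" else von_mises(sig)
    if mode == "volume_mean":
        return float(np.sum(vals * w) / np.sum(w))
    if mode == "volume_sum":
        return float(np.sum(vals * w))
    return float(vals[np.argmax(np.abs(vals))])


def gel_transmitted_stress(
    state: SolutionState, mesh: AxisymMesh, mode: str = "under_cell"
) -> float:
    """Stress transmitted by the cell to the gel (kPa).

    Default 'under_cell': volume-mean von Mises stress over gel quadrature
    points within 2 cell radii of the axis and of the surface — the region
    where the transmitted field localizes. Alternatives: 'column' (within 2
    cell radii of the axis, full gel depth), 'whole' (whole-gel mean) and
    'surface_peak' (max von Mises on the top gel element row).
    """
    _check_converged(state)
    mask = _qp_mask_for_elems(state, mesh.region_elems("gel"))
    r, z = state.qp_pos[:, 0], state.qp_pos[:, 1]
    R2 = 2.0 * mesh.params.cell_radius
    if mode == "under_cell":
        mask = mask & (r <= R2) & (z >= -R2)
    elif mode == "column":
        mask = mask & (r <= R2)
    elif mode == "surface_peak":
        zmax = z[mask].max()
        mask = mask & (z >= zmax - 1e-9) | (mask & (z > -mesh.params.cell_radius / 4))
    elif mode != "whole":
        raise KeyError(f"unknown gel-stress mode {mode!r}")
    vals = von_mises(state.sigma[mask])
    if mode == "surface_peak":
        return float(vals.max())
    w = state.qp_weights[mask]
    return float(np.sum(vals * w) / np.sum(w))


def percent_difference(top_value: float, bottom_value: float) -> float:
    """Signed percentage difference 100 (top - bottom) / bottom."""
    if bottom_value == 0:
        raise ZeroDivisionError("percent difference undefined for zero baseline")
    return 100.0 * (top_value - bottom_value) / bottom_value


def nucleus_aspect_ratio(state: SolutionState, mesh: AxisymMesh) -> float:
    """Deformed vertical / planar extent of the nucleus boundary.

    A rounding proxy: the undeformed value is the ratio of the two nucleus
    diameters (8/6 by default); compression towards 1 or below indicates the
    rounded-to-pestle shape transition.
    """
    _check_converged(state)
    nuc_nodes = np.unique(mesh.elems[mesh.region_elems("nucleus")][:, :3].ravel())
    r = mesh.nodes[nuc_nodes, 0] + state.u[2 * nuc_nodes]
    z = mesh.nodes[nuc_nodes, 1] + state.u[2 * nuc_nodes + 1]
    vertical = z.max() - z.min()
    planar = 2.0 * r.max()
    return float(vertical / planar)


def average_effective_strain(
    state: SolutionState, mesh: AxisymMesh, region: str = "cell"
) -> float:
    """Volume-mean effective (von Mises-equivalent) logarithmic strain.

    eps_eff = sqrt(2/3 dev(eps):dev(eps)) with eps = 1/2 ln(F F^T). The
    'cell' pseudo-region unions nucleus and cytoplasm.
    """
    _check_converged(state)
    if region == "cell":
        ids = np.concatenate([mesh.region_elems("nucleus"), mesh.region_elems("cytoplasm")])
    else:
        ids = mesh.region_elems(region)
    mask = _qp_mask_for_elems(state, ids)
    F = state.F[mask]
    B = F @ np.swapaxes(F, -1, -2)
    evals, _ = np.linalg.eigh(B)
    eps = 0.5 * np.log(evals)  # principal log strains
    dev = eps - eps.mean(axis=-1, keepdims=True)
    eff = np.sqrt(2.0 / 3.0 * np.sum(dev**2, axis=-1))
    w = state.qp_weights[mask]
    return float(np.sum(eff * w) / np.sum(w))


def summarize(
    state: SolutionState,
    mesh: AxisymMesh,
    force_nN: float = np.nan,
    E_cyto: float = np.nan,
    config: str = "",
    material_model: str = "",
    gel_mode: str = "under_cell",
) -> ResultSummary:
    """Bundle the standard scalar outcomes of one run."""
    return ResultSummary(
        indentation_depth=indentation_depth(state, mesh),
        nucleus_total_stress=region_stress_aggregate(state, mesh, "nucleus", "total"),
        nucleus_vm_stress=region_stress_aggregate(state, mesh, "nucleus", "von_mises"),
        cytoplasm_total_stress=region_stress_aggregate(state, mesh, "cytoplasm", "total"),
        cytoplasm_vm_stress=region_stress_aggregate(state, mesh, "cytoplasm", "von_mises"),
        gel_transmitted_stress=gel_transmitted_stress(state, mesh, gel_mode),
        nucleus_aspect_ratio=nucleus_aspect_ratio(state, mesh),
        avg_effective_strain_cell=average_effective_strain(state, mesh, "cell"),
        force_nN=force_nN,
        E_cyto=E_cyto,
        config=config,
        material_model=material_model,
    )
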