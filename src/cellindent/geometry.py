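"""Axisymmetric (r, z) mesh of the cell-on-gel indentation model.

The computational domain revolves around the symmetry axis r = 0:

* a gel cylinder (radius ``gel_radius``, height ``gel_thickness``) occupying
  z in [-gel_thickness, 0], fixed on its bottom and lateral faces;
* an initially hemispherical cell (radius ``cell_diameter``/2) sitting on the
  gel top surface, z >= 0;
* an ellipsoidal nucleus (planar/vertical semi-axes from the two nucleus
  diameters) embedded in the cytoplasm, separated from the gel by a thin
  cytoplasmic layer so that the central force is routed "through" the
  contact disc at the base of the cytoplasm.

All interfaces (cell base <-> gel top, nucleus <-> cytoplasm) share nodes:
a single conforming mesh is the exact discrete realization of a tied
(no-slip, no-separation) contact.

Elements are six-node (quadratic) triangles with straight edges; midside
nodes sit at edge midpoints, so geometric measures of the mesh coincide with
those of the underlying three-node triangulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeometryParams",
    "AxisymMesh",
    "build_domain",
    "build_gel_domain",
    "refine",
    "region_measure",
    "element_volumes",
    "write_vtk",
    "REGIONS",
]

REGIONS = {"nucleus": 0, "cytoplasm": 1, "gel": 2}
REGION_NAMES = {v: k for k, v in REGIONS.items()}

_MERGE_DECIMALS = 9


class MeshingError(RuntimeError):
    """Raised when the generated mesh is degenerate."""


@dataclass(frozen=True)
class GeometryParams:
    """Geometry of cell, nucleus and gel. All lengths in micrometres.

    ``nucleus_gap`` is the thickness of the cytoplasmic layer between the
    nucleus bottom pole and the gel surface; the nucleus centre sits at
    z = nucleus_gap + nucleus_diam_vertical / 2.
    """

    cell_diameter: float = 20.0
    nucleus_diam_planar: float = 6.0
    nucleus_diam_vertical: float = 8.0
    gel_radius: float = 225.0
    gel_thickness: float = 300.0
    contact_disc_diameter: float = 6.0
    nucleus_gap: float = 0.5
    perimeter_band_width: float = 1.0

    def __post_init__(self) -> None:
        vals = [
            self.cell_diameter,
            self.nucleus_diam_planar,
            self.nucleus_diam_vertical,
            self.gel_radius,
            self.gel_thickness,
            self.contact_disc_diameter,
            self.nucleus_gap,
            self.perimeter_band_width,
        ]
        if any(v <= 0 for v in vals):
            raise ValueError("all geometry parameters must be positive")
        if self.nucleus_diam_vertical / 2.0 >= self.cell_radius:
            raise ValueError("nucleus vertical semi-axis must be smaller than the cell radius")
        if self.nucleus_top > 0.99 * self.cell_radius:
            raise ValueError("nucleus (with its gap below) does not fit inside the cell")
        if self.nucleus_diam_planar / 2.0 >= self.cell_radius:
            raise ValueError("nucleus planar semi-axis must be smaller than the cell radius")
        if self.contact_disc_diameter > self.nucleus_diam_planar * (1.0 + 1e-9):
            raise ValueError("contact disc cannot exceed the nucleus planar diameter")
        if self.gel_radius < 10.0 * self.cell_radius:
            raise ValueError("gel radius must be at least 10x the cell radius (half-space proxy)")

    @property
    def cell_radius(self) -> float:
        return self.cell_diameter / 2.0

    @property
    def nucleus_a(self) -> float:
        """Planar (radial) semi-axis of the nucleus."""
        return self.nucleus_diam_planar / 2.0

    @property
    def nucleus_b(self) -> float:
        """Vertical semi-axis of the nucleus."""
        return self.nucleus_diam_vertical / 2.0

    @property
    def nucleus_center_z(self) -> float:
        return self.nucleus_gap + self.nucleus_b

    @property
    def nucleus_top(self) -> float:
        return self.nucleus_center_z + self.nucleus_b


@dataclass
class AxisymMesh:
    """Conforming quadratic-triangle mesh of the revolved (r, z) domain.

    ``elems`` is (n_elem, 6): corners 0-2 counter-clockwise, then midside
    nodes on edges (0,1), (1,2), (2,0). ``region`` holds one tag per element
    (see :data:`REGIONS`).
    """

    nodes: np.ndarray
    elems: np.ndarray
    region: np.ndarray
    surface_sets: dict[str, np.ndarray] = field(default_factory=dict)
    edge_sets: dict[str, np.ndarray] = field(default_factory=dict)
    element_sets: dict[str, np.ndarray] = field(default_factory=dict)
    params: GeometryParams | None = None
    resolution: int = 1

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elems(self) -> int:
        return self.elems.shape[0]

    def region_elems(self, region: str) -> np.ndarray:
        if region not in REGIONS:
            raise KeyError(f"unknown region {region!r}; expected one of {sorted(REGIONS)}")
        idx = np.flatnonzero(self.region == REGIONS[region])
        if idx.size == 0:
            raise KeyError(f"mesh contains no elements tagged {region!r}")
        return idx


# ---------------------------------------------------------------------------
# low-level builders
# ---------------------------------------------------------------------------


class _NodePool:
    """Merges coincident nodes across mesh blocks (conforming interfaces)."""

    def __init__(self) -> None:
        self._index: dict[tuple[float, float], int] = {}
        self.coords: list[tuple[float, float]] = []

    def add(self, r: float, z: float) -> int:
        if abs(r) < 1e-9:
            r = 0.0
        key = (round(r, _MERGE_DECIMALS), round(z, _MERGE_DECIMALS))
        idx = self._index.get(key)
        if idx is None:
            idx = len(self.coords)
            self._index[key] = idx
            self.coords.append((r, z))
        return idx

    def array(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)


def _geometric_levels(start: float, total: float, h0: float, ratio: float) -> np.ndarray:
    """Coordinates from `start` spanning `total`, first step h0, growth `ratio`."""
    steps = [h0]
    while sum(steps) < total:
        steps.append(steps[-1] * ratio)
    # rescale so the last level lands exactly on start + total
    steps = np.asarray(steps) * (total / sum(steps))
    return start + np.concatenate([[0.0], np.cumsum(steps)])


def _orient(tris: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    """Flip triangles so all signed areas are positive."""
    p = nodes[tris]
    area2 = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
        p[:, 2, 0] - p[:, 0, 0]
    ) * (p[:, 1, 1] - p[:, 0, 1])
    flip = area2 < 0
    tris = tris.copy()
    tris[flip] = tris[flip][:, [0, 2, 1]]
    if np.any(np.abs(area2) < 1e-12):
        raise MeshingError("degenerate (zero-area) element produced during meshing")
    return tris


def _quads_to_tris(quads: list[tuple[int, int, int, int]]) -> list[tuple[int, int, int]]:
    tris = []
    for a, b, c, d in quads:
        tris.append((a, b, c))
        tris.append((a, c, d))
    return tris


def _to_quadratic(nodes: np.ndarray, tris: np.ndarray):
    """Insert midside nodes (shared across elements) -> T6 connectivity."""
    midpoint: dict[tuple[int, int], int] = {}
    coords = [tuple(xy) for xy in nodes]
    elems = np.empty((tris.shape[0], 6), dtype=int)
    elems[:, :3] = tris
    edge_local = [(0, 1), (1, 2), (2, 0)]
    for e, tri in enumerate(tris):
        for k, (i, j) in enumerate(edge_local):
            a, b = int(tri[i]), int(tri[j])
            key = (a, b) if a < b else (b, a)
            m = midpoint.get(key)
            if m is None:
                m = len(coords)
                midpoint[key] = m
                coords.append(
                    (
                        0.5 * (nodes[a, 0] + nodes[b, 0]),
                        0.5 * (nodes[a, 1] + nodes[b, 1]),
                    )
                )
            elems[e, 3 + k] = m
    return np.asarray(coords, dtype=float), elems


# ---------------------------------------------------------------------------
# the full cell-on-gel domain
# ---------------------------------------------------------------------------


def _cell_blocks(params: GeometryParams, n: int, pool: _NodePool):
    """Nucleus fan + ray-blended cytoplasm shell.

    Both chains (inner: nucleus ellipse; outer: cell base + hemispherical arc)
    are star-shaped about the nucleus centre c = (0, zc), so nodes are laid on
    rays from c. Column j of the cytoplasm grid lies on the ray towards the
    j-th outer-boundary point; the rays at -90 and +90 degrees coincide with
    the symmetry-axis segments below and above the nucleus.
    """
    Rc = params.cell_radius
    a, b, zc = params.nucleus_a, params.nucleus_b, params.nucleus_center_z

    n_base = 6 * n
    n_arc = 8 * n
    n_t = 3 * n  # cytoplasm layers, nucleus boundary -> cell boundary
    n_m = 2 * n  # nucleus rings

    # outer chain: base (uniform in r) then arc (uniform in angle), corner shared
    base_r = np.linspace(0.0, Rc, n_base + 1)
    phi = np.linspace(0.0, np.pi / 2.0, n_arc + 1)[1:]
    outer = np.concatenate(
        [
            np.column_stack([base_r, np.zeros_like(base_r)]),
            np.column_stack([Rc * np.cos(phi), Rc * np.sin(phi)]),
        ]
    )
    alpha = np.arctan2(outer[:, 1] - zc, outer[:, 0])
    alpha[0] = -np.pi / 2.0
    alpha[-1] = np.pi / 2.0
    # ensure a ray at alpha = 0 so the nucleus equator (r = a) is a node
    if np.abs(alpha).min() > 1e-12:
        equator = np.array([np.sqrt(Rc**2 - zc**2), zc])
        k = int(np.searchsorted(alpha, 0.0))
        outer = np.insert(outer, k, equator, axis=0)
        alpha = np.insert(alpha, k, 0.0)
    if np.any(np.diff(alpha) <= 0):
        raise MeshingError("outer-chain ray angles are not monotone")

    d = np.column_stack([np.cos(alpha), np.sin(alpha)])
    t_in = 1.0 / np.sqrt((d[:, 0] / a) ** 2 + (d[:, 1] / b) ** 2)
    t_out = np.hypot(outer[:, 0], outer[:, 1] - zc)
    if np.any(t_out <= t_in):
        raise MeshingError("nucleus boundary reaches the cell boundary")

    n_s = outer.shape[0] - 1  # number of ray intervals

    # --- cytoplasm structured grid ---
    cy = np.empty((n_s + 1, n_t + 1), dtype=int)
    for j in range(n_s + 1):
        for k in range(n_t + 1):
            t = t_in[j] + (t_out[j] - t_in[j]) * k / n_t
            cy[j, k] = pool.add(t * d[j, 0], zc + t * d[j, 1])
    cyto_quads = [
        (cy[j, k], cy[j + 1, k], cy[j + 1, k + 1], cy[j, k + 1])
        for j in range(n_s)
        for k in range(n_t)
    ]
    cyto_tris = _quads_to_tris(cyto_quads)

    # --- nucleus polar fan ---
    center = pool.add(0.0, zc)
    rings = np.empty((n_m, n_s + 1), dtype=int)
    for m in range(1, n_m + 1):
        rho = m / n_m
        for j in range(n_s + 1):
            t = rho * t_in[j]
            rings[m - 1, j] = pool.add(t * d[j, 0], zc + t * d[j, 1])
    nuc_tris = [(center, rings[0, j], rings[0, j + 1]) for j in range(n_s)]
    nuc_tris += _quads_to_tris(
        [
            (rings[m, j], rings[m, j + 1], rings[m + 1, j + 1], rings[m + 1, j])
            for m in range(n_m - 1)
            for j in range(n_s)
        ]
    )

    base_nodes = [cy[j, n_t] for j in range(n_base + 1)]  # cell base, r = base_r
    return nuc_tris, cyto_tris, base_r, base_nodes


def _gel_block(
    params: GeometryParams,
    n: int,
    pool: _NodePool,
    inner_r: np.ndarray,
    h_surf: float | None = None,
    extra_r: np.ndarray | None = None,
):
    """Graded structured gel grid; top nodes at r in `inner_r` match the cell base."""
    Rg, H = params.gel_radius, params.gel_thickness
    growth = 1.35 ** (1.0 / n)
    h0 = h_surf if h_surf is not None else (inner_r[-1] - inner_r[-2])
    r_out = _geometric_levels(inner_r[-1], Rg - inner_r[-1], h0, growth)[1:]
    r_levels = np.concatenate([inner_r, r_out])
    if extra_r is not None:
        r_levels = np.unique(np.round(np.concatenate([r_levels, extra_r]), _MERGE_DECIMALS))
    z_levels = -(_geometric_levels(0.0, H, h0, growth))

    g = np.empty((len(r_levels), len(z_levels)), dtype=int)
    for i, r in enumerate(r_levels):
        for j, z in enumerate(z_levels):
            g[i, j] = pool.add(r, z)
    quads = [
        (g[i, j], g[i + 1, j], g[i + 1, j + 1], g[i, j + 1])
        for i in range(len(r_levels) - 1)
        for j in range(len(z_levels) - 1)
    ]
    return _quads_to_tris(quads), r_levels, z_levels


def build_domain(params: GeometryParams | None = None, resolution: int = 2) -> AxisymMesh:
    """Build the conforming nucleus/cytoplasm/gel mesh.

    ``resolution`` scales every subdivision count linearly, so element counts
    grow roughly quadratically with it.
    """
    if params is None:
        params = GeometryParams()
    if resolution < 1:
        raise ValueError("resolution must be >= 1")
    n = int(resolution)

    pool = _NodePool()
    nuc_tris, cyto_tris, base_r, _ = _cell_blocks(params, n, pool)
    gel_tris, _, _ = _gel_block(params, n, pool, base_r)

    tris = np.asarray(nuc_tris + cyto_tris + gel_tris, dtype=int)
    region = np.concatenate(
        [
            np.full(len(nuc_tris), REGIONS["nucleus"]),
            np.full(len(cyto_tris), REGIONS["cytoplasm"]),
            np.full(len(gel_tris), REGIONS["gel"]),
        ]
    )
    nodes3 = pool.array()
    tris = _orient(tris, nodes3)
    nodes, elems = _to_quadratic(nodes3, tris)

    mesh = AxisymMesh(
        nodes=nodes, elems=elems, region=region, params=params, resolution=n
    )
    _tag_sets(mesh)
    return mesh


def _tag_sets(mesh: AxisymMesh) -> None:
    p = mesh.params
    nodes, elems, region = mesh.nodes, mesh.elems, mesh.region
    r, z = nodes[:, 0], nodes[:, 1]
    tol = 1e-8

    gel_mask = region == REGIONS["gel"]
    gel_nodes = np.unique(elems[gel_mask].ravel()) if gel_mask.any() else np.array([], int)

    sets: dict[str, np.ndarray] = {}
    sets["axis"] = np.flatnonzero(r < tol)
    if gel_mask.any():
        sets["gel_bottom"] = gel_nodes[np.abs(z[gel_nodes] + p.gel_thickness) < tol]
        sets["gel_lateral"] = gel_nodes[np.abs(r[gel_nodes] - p.gel_radius) < tol]
        sets["gel_top_free"] = gel_nodes[np.abs(z[gel_nodes]) < tol]
    mesh.surface_sets.update(sets)

    cyto_mask = region == REGIONS["cytoplasm"]
    if not cyto_mask.any():
        return

    # perimeter band: cell-base edges (z = 0) whose midpoint lies within
    # `perimeter_band_width` of the cell rim; fall back to the outermost edge.
    band_edges = []
    edge_local = [(0, 1, 3), (1, 2, 4), (2, 0, 5)]
    for e in np.flatnonzero(cyto_mask):
        for i, j, m in edge_local:
            a, b, mid = elems[e, i], elems[e, j], elems[e, m]
            if abs(z[a]) < tol and abs(z[b]) < tol:
                band_edges.append((a, b, mid, 0.5 * (r[a] + r[b])))
    if not band_edges:
        raise MeshingError("no cell-base edges found for the perimeter band")
    band_edges.sort(key=lambda t: t[3])
    rmax = band_edges[-1][3]
    chosen = [t[:3] for t in band_edges if t[3] >= p.cell_radius - p.perimeter_band_width - tol]
    if not chosen:
        chosen = [band_edges[-1][:3]]
        rmax_edge = band_edges[-1]
        assert rmax_edge[3] == rmax
    mesh.edge_sets["perimeter_band"] = np.asarray(chosen, dtype=int)

    # volumetric perimeter band: cytoplasm elements hugging the base rim
    # (the loading scheme applies the perimeter push-pull over these)
    cyto_idx = np.flatnonzero(cyto_mask)
    cc = nodes[elems[cyto_idx, :3]].mean(axis=1)
    dist = np.hypot(cc[:, 0] - p.cell_radius, cc[:, 1])
    band = cyto_idx[dist <= p.perimeter_band_width + tol]
    if band.size == 0:
        band = cyto_idx[[int(np.argmin(dist))]]
    mesh.element_sets["perimeter_band"] = band

    # nucleus thirds by z-extent
    zc, b = p.nucleus_center_z, p.nucleus_b
    nuc_idx = np.flatnonzero(region == REGIONS["nucleus"])
    cz = nodes[elems[nuc_idx, :3], 1].mean(axis=1)
    mesh.element_sets["nucleus_top_third"] = nuc_idx[cz > zc + b / 3.0]
    mesh.element_sets["nucleus_bottom_third"] = nuc_idx[cz < zc - b / 3.0]

    # cytoplasm elements of the contact disc beneath the nucleus
    cyto_idx = np.flatnonzero(cyto_mask)
    cr = nodes[elems[cyto_idx, :3], 0].mean(axis=1)
    cz = nodes[elems[cyto_idx, :3], 1].mean(axis=1)
    a = p.contact_disc_diameter / 2.0
    under = np.where(
        cr < p.nucleus_a,
        cz < zc - b * np.sqrt(np.clip(1.0 - (cr / p.nucleus_a) ** 2, 0.0, 1.0)),
        False,
    )
    mesh.element_sets["center_contact_disc"] = cyto_idx[(cr <= a + tol) & under]


def build_gel_domain(
    params: GeometryParams | None = None,
    resolution: int = 2,
    punch_radius: float | None = None,
) -> AxisymMesh:
    """Gel-only mesh (verification fixtures: flat punch on a half-space).

    When ``punch_radius`` is given, the surface grid is clustered around the
    punch edge and a ``punch`` node set (top surface, r <= punch_radius) is
    added.
    """
    if params is None:
        params = GeometryParams()
    n = int(resolution)
    if n < 1:
        raise ValueError("resolution must be >= 1")
    a = punch_radius if punch_radius is not None else params.cell_radius
    pool = _NodePool()
    inner = np.linspace(0.0, a, 6 * n + 1)
    # extra ring of fine spacing just outside the punch edge (stress is singular there)
    h = inner[1] - inner[0]
    extra = a + h * np.arange(1, 2 * n + 1)
    gel_tris, _, _ = _gel_block(params, n, pool, inner, h_surf=h, extra_r=extra)
    nodes3 = pool.array()
    tris = _orient(np.asarray(gel_tris, dtype=int), nodes3)
    nodes, elems = _to_quadratic(nodes3, tris)
    mesh = AxisymMesh(
        nodes=nodes,
        elems=elems,
        region=np.full(tris.shape[0], REGIONS["gel"]),
        params=params,
        resolution=n,
    )
    _tag_sets(mesh)
    top = mesh.surface_sets["gel_top_free"]
    mesh.surface_sets["punch"] = top[nodes[top, 0] <= a + 1e-8]
    return mesh


def refine(mesh: AxisymMesh, factor: int) -> AxisymMesh:
    """Uniformly refined rebuild of the same geometry (factor x subdivisions)."""
    if factor == 1:
        return mesh
    if factor < 1:
        raise ValueError("refinement factor must be >= 1")
    if mesh.params is None:
        raise ValueError("mesh carries no geometry parameters; cannot rebuild")
    if "punch" in mesh.surface_sets:
        a = float(mesh.nodes[mesh.surface_sets["punch"], 0].max())
        return build_gel_domain(mesh.params, mesh.resolution * factor, punch_radius=a)
    return build_domain(mesh.params, mesh.resolution * factor)


# ---------------------------------------------------------------------------
# measures and export
# ---------------------------------------------------------------------------


def element_volumes(mesh: AxisymMesh) -> np.ndarray:
    """Revolved volume 2*pi*integral(r dA) per element (straight-sided T6)."""
    p = mesh.nodes[mesh.elems[:, :3]]
    area = 0.5 * np.abs(
        (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
        - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
    )
    r_cent = p[:, :, 0].mean(axis=1)
    return 2.0 * np.pi * area * r_cent


def region_measure(mesh: AxisymMesh, region: str) -> float:
    """Revolved volume of a tagged region, in cubic micrometres."""
    idx = mesh.region_elems(region)
    return float(element_volumes(mesh)[idx].sum())


def write_vtk(mesh: AxisymMesh, path, point_data=None, cell_data=None) -> None:
    """Write the mesh as a legacy-ASCII VTK unstructured grid.

    Nodes are embedded in 3D as (r, z, 0); elements are VTK quadratic
    triangles (type 22). Region tags are always included as cell data.
    """
    pd = dict(point_data or {})
    cd = {"region": mesh.region.astype(float)}
    cd.update(cell_data or {})
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\ncellindent mesh\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {mesh.n_nodes} double\n")
        for r, z in mesh.nodes:
            f.write(f"{r:.9g} {z:.9g} 0\n")
        f.write(f"CELLS {mesh.n_elems} {mesh.n_elems * 7}\n")
        for e in mesh.elems:
            f.write("6 " + " ".join(str(int(i)) for i in e) + "\n")
        f.write(f"CELL_TYPES {mesh.n_elems}\n")
        f.write("22\n" * mesh.n_elems)
        if pd:
            f.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, arr in pd.items():
                arr = np.asarray(arr)
                if arr.ndim == 1:
                    f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    f.writelines(f"{v:.9g}\n" for v in arr)
                else:
                    f.write(f"VECTORS {name} double\n")
                    for row in arr:
                        f.write(f"{row[0]:.9g} {row[1]:.9g} 0\n")
        f.write(f"CELL_DATA {mesh.n_elems}\n")
        for name, arr in cd.items():
            f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            f.writelines(f"{float(v):.9g}\n" for v in np.asarray(arr))
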