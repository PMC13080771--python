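"""Verification fixtures: benchmark problems with closed-form answers.

Every fixture carries its expected values computed *from the stated formula
at call time* (never a frozen constant), so the analytic oracle and the
numerical solution can never silently drift apart. The fixtures double as
the package's synthetic-data stand-in: no external dataset exists or is
needed — the model is fully parameterized by printed constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import AxisymMesh, GeometryParams, build_gel_domain
from .loading import BCSet, build_bcs
from .materials import MaterialSpec, PronyParams, lame_from_E_nu, reduced_relaxation

__all__ = [
    "Fixture",
    "flat_punch_fixture",
    "uniaxial_patch_fixture",
    "relaxation_fixture",
    "randomized_property_cases",
]


@dataclass
class Fixture:
    """A self-contained benchmark: inputs plus formula-derived expectations.

    ``expected`` maps quantity names to (value, relative tolerance);
    ``note`` names the closed form the expectations come from.
    """

    name: str
    expected: dict[str, tuple[float, float]]
    note: str
    mesh: AxisymMesh | None = None
    materials: dict[str, MaterialSpec] | None = None
    bcs: BCSet | None = None
    loadcase: object | None = None
    extra: dict = field(default_factory=dict)


def flat_punch_fixture(
    a: float = 3.0,
    E: float = 2.4,
    nu: float = 0.48,
    F: float = 10.0,
    resolution: int = 2,
    params: GeometryParams | None = None,
) -> Fixture:
    """Rigid flat circular punch on an elastic half-space (Boussinesq).

    Expected indentation depth d = F (1 - nu^2) / (2 a E). The half-space is
    approximated by the study's own gel cylinder (radius 75x the default
    punch), so the fixture doubles as a far-boundary-effect check. The punch
    is realized as a rigid tie: all surface nodes with r <= a share one
    vertical unknown carrying the force F.
    """
    params = params or GeometryParams()
    d = F * (1.0 - nu**2) / (2.0 * a * E)
    if d / a > 0.2:
        raise ValueError("punch force outside the small-indentation regime")
    mesh = build_gel_domain(params, resolution=resolution, punch_radius=a)
    bcs = build_bcs(mesh)
    punch_nodes = mesh.surface_sets["punch"]
    zdofs = 2 * punch_nodes + 1
    keep = ~np.isin(zdofs, bcs.fixed_dofs)
    bcs.rigid_groups.append((zdofs[keep], -F))
    mats = {"gel": MaterialSpec(law="linear_elastic", E=E, nu=nu)}
    return Fixture(
        name="flat_punch",
        expected={"depth": (d, 0.05)},
        note="Boussinesq rigid flat punch: d = F (1 - nu^2) / (2 a E)",
        mesh=mesh,
        materials=mats,
        bcs=bcs,
        loadcase=np.zeros(2 * mesh.n_nodes),
        extra={"a": a, "F": F, "punch_dof": zdofs[keep]},
    )


def uniaxial_patch_fixture(
    law: str = "neo_hookean", E: float = 1.0, nu: float = 0.3, stretch: float = 1.0001
) -> Fixture:
    """Homogeneous uniaxial-stretch state with the constitutive closed form.

    Builds the deformation gradient diag(lat, stretch, lat) with the lateral
    stretch solved so the transverse Cauchy stress vanishes, and evaluates
    the expected axial stress independently by central differencing of the
    stored-energy function (a path independent of the stress routines).
    """
    lam, mu = lame_from_E_nu(E, nu)

    def W(F):
        J = np.linalg.det(F)
        C = F.T @ F
        if law == "neo_hookean":
            return 0.5 * mu * (np.trace(C) - 3.0) - mu * np.log(J) + 0.5 * lam * np.log(J) ** 2
        if law in ("svk", "linear_elastic"):
            Egr = 0.5 * (C - np.eye(3))
            return 0.5 * lam * np.trace(Egr) ** 2 + mu * np.sum(Egr * Egr)
        raise ValueError(law)

    def axial_cauchy(lat):
        F = np.diag([lat, stretch, lat])
        h = 1e-6

        def dW(i):
            Fp, Fm = F.copy(), F.copy()
            Fp[i, i] += h
            Fm[i, i] -= h
            return (W(Fp) - W(Fm)) / (2 * h)

        J = np.linalg.det(F)
        P = np.array([dW(0), dW(1), dW(2)])
        sig = P * np.diag(F) / J  # diagonal Cauchy from diagonal PK1
        return sig

    from scipy.optimize import brentq

    if abs(stretch - 1.0) < 1e-12:
        lat = 1.0
    else:
        lat = brentq(lambda s: axial_cauchy(s)[0], 0.3, 3.0, xtol=1e-14)
    sig = axial_cauchy(lat)
    F = np.diag([lat, stretch, lat])
    tol = 1e-3 if abs(stretch - 1) < 1e-3 else 1e-6
    return Fixture(
        name="uniaxial_patch",
        expected={
            "sigma_axial": (float(sig[1]), tol),
            "sigma_lateral": (0.0, 1e-10),
        },
        note="uniaxial stress state; expected stress from central differences of W",
        extra={"F": F, "law": law, "lam": lam, "mu": mu, "stretch": stretch},
    )


def relaxation_fixture(
    prony: PronyParams | None = None, hold: float = 30.0, n_steps: int = 400
) -> Fixture:
    """Step-strain relaxation of a single material point.

    A constant elastic stress is switched on at t = 0+; the viscoelastic
    stress ratio must follow the reduced relaxation function
    g(t) = (G_inf + sum G_i e^{-t/tau_i}) / (G_inf + sum G_i).
    """
    if hold <= 0:
        raise ValueError("hold must be positive")
    prony = prony or PronyParams()
    times = np.linspace(0.0, hold, n_steps + 1)[1:]
    expected = {f"g({t:.4f})": (float(reduced_relaxation(t, prony)), 0.01) for t in times}
    expected["g_inf"] = (prony.g_inf, 1e-12)
    return Fixture(
        name="step_strain_relaxation",
        expected=expected,
        note="reduced relaxation g(t) = (G_inf + G1 e^-t/tau1 + G2 e^-t/tau2)/sum(G)",
        extra={"prony": prony, "times": times},
    )


def randomized_property_cases(seed: int = 20240301, n: int = 5) -> list[Fixture]:
    """Seeded random small problems for property tests (equilibrium,
    objectivity, tangent consistency). Same seed -> identical fixtures."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n):
        E = float(rng.uniform(0.5, 5.0))
        nu = float(rng.uniform(0.0, 0.49))
        F = float(rng.uniform(0.5, 5.0))
        a = float(rng.uniform(2.0, 6.0))
        params = GeometryParams()
        mesh = build_gel_domain(params, resolution=1, punch_radius=a)
        bcs = build_bcs(mesh)
        top = mesh.surface_sets["gel_top_free"]
        inside = top[mesh.nodes[top, 0] <= a + 1e-9]
        fext = np.zeros(2 * mesh.n_nodes)
        fext[2 * inside + 1] = -F / inside.size
        out.append(
            Fixture(
                name=f"random_case_{k}",
                expected={"net_force": (-F, 1e-8)},
                note="random gel patch under distributed surface load; reactions must balance",
                mesh=mesh,
                materials={"gel": MaterialSpec(law="neo_hookean", E=E, nu=nu)},
                bcs=bcs,
                loadcase=fext,
                extra={"seed": seed, "k": k, "F": F},
            )
        )
    return out
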