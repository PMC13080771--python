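"""Constitutive laws: compressible Neo-Hookean, Saint Venant-Kirchhoff
("linear elastic" assembled in the geometrically nonlinear framework) and a
quasi-linear viscoelastic (Prony-series) cytoplasm, plus the scalar stress
measures used in post-processing.

Units are fixed throughout the package: kPa for moduli and stresses, s for
time. 1 nN/um^2 = 1 kPa, so forces in nN and lengths in um are consistent.

Tensor conventions
------------------
The axisymmetric kinematics are carried as full 3x3 tensors in the rotating
(r, z, theta) frame, where the deformation gradient is block-diagonal::

    F = [[F_rr, F_rz, 0],
         [F_zr, F_zz, 0],
         [0,    0,    F_tt]]

Stress routines accept arrays of shape (..., 3, 3) and are vectorized over
leading axes (quadrature points).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MaterialSpec",
    "PronyParams",
    "lame_from_E_nu",
    "neo_hookean_stress",
    "neo_hookean_pk1",
    "svk_pk1",
    "reduced_relaxation",
    "viscoelastic_stress_update",
    "von_mises",
    "total_stress",
    "cauchy_from_pk1",
]

LAWS = ("neo_hookean", "linear_elastic", "svk", "viscoelastic_prony")

_I3 = np.eye(3)


@dataclass(frozen=True)
class PronyParams:
    """Two-branch Prony relaxation constants.

    ``G_inf``, ``G_1``, ``G_2`` are printed in kPa; whether they act as
    literal shear moduli or as relaxation weights is controlled by
    ``MaterialSpec.prony_mode``.
    """

    G_inf: float = 4.05
    G_1: float = 34.0
    G_2: float = 20.2
    tau_1: float = 0.58
    tau_2: float = 5.47

    def __post_init__(self) -> None:
        if min(self.G_inf, self.G_1, self.G_2, self.tau_1, self.tau_2) <= 0:
            raise ValueError("all Prony constants must be positive")

    @property
    def G_sum(self) -> float:
        return self.G_inf + self.G_1 + self.G_2

    @property
    def g_inf(self) -> float:
        """Long-time value of the reduced relaxation function."""
        return self.G_inf / self.G_sum

    @property
    def gammas(self) -> tuple[float, float]:
        """Normalized branch weights (gamma_1, gamma_2)."""
        return self.G_1 / self.G_sum, self.G_2 / self.G_sum

    @property
    def taus(self) -> tuple[float, float]:
        return self.tau_1, self.tau_2


@dataclass(frozen=True)
class MaterialSpec:
    """One region's material: law, elastic constants and optional Prony data.

    For ``viscoelastic_prony`` the elastic backbone is Neo-Hookean and the
    instantaneous stiffness depends on ``prony_mode``:

    * ``"equilibrium"`` — the long-time (relaxed) Young's modulus equals
      ``E``; the instantaneous modulus is ``E / g(inf)``. Elastic and
      viscoelastic runs then agree once the load is held to steady state.
    * ``"literal"`` — the printed Prony constants are taken as shear moduli
      in kPa: instantaneous shear modulus ``G_inf + G_1 + G_2``, relaxed
      shear modulus ``G_inf`` (``E`` is ignored for stiffness).
    """

    law: str = "neo_hookean"
    E: float = 1.0
    nu: float = 0.45
    prony: PronyParams | None = None
    prony_mode: str = "equilibrium"

    def __post_init__(self) -> None:
        if self.law not in LAWS:
            raise ValueError(f"unknown law {self.law!r}; expected one of {LAWS}")
        if self.E <= 0:
            raise ValueError("Young's modulus must be positive")
        if not 0.0 <= self.nu < 0.5:
            raise ValueError("Poisson ratio must lie in [0, 0.5)")
        if self.law == "viscoelastic_prony":
            if self.prony is None:
                object.__setattr__(self, "prony", PronyParams())
            if self.prony_mode not in ("equilibrium", "literal"):
                raise ValueError("prony_mode must be 'equilibrium' or 'literal'")

    @property
    def lame(self) -> tuple[float, float]:
        return lame_from_E_nu(self.E, self.nu)

    @property
    def E_instantaneous(self) -> float:
        """Instantaneous Young's modulus seen by the viscoelastic backbone."""
        if self.law != "viscoelastic_prony":
            return self.E
        if self.prony_mode == "literal":
            return 2.0 * (1.0 + self.nu) * self.prony.G_sum
        return self.E / self.prony.g_inf

    @property
    def E_equilibrium(self) -> float:
        if self.law != "viscoelastic_prony":
            return self.E
        return self.prony.g_inf * self.E_instantaneous


def lame_from_E_nu(E: float, nu: float) -> tuple[float, float]:
    """(lambda, mu) from Young's modulus and Poisson ratio.

    Raises for nu >= 0.5: the model uses near-incompressible 0.48/0.49 but
    never the incompressible limit itself.
    """
    if E <= 0:
        raise ValueError("E must be positive")
    if nu >= 0.5:
        raise ValueError("nu >= 0.5: incompressible limit not representable")
    mu = E / (2.0 * (1.0 + nu))
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    return lam, mu


# ---------------------------------------------------------------------------
# hyperelastic laws: Cauchy stress, PK1 and first elasticity tensor
# ---------------------------------------------------------------------------


def _det3(F: np.ndarray) -> np.ndarray:
    return np.linalg.det(F)


def neo_hookean_stress(F: np.ndarray, lam: float, mu: float) -> np.ndarray:
    """Cauchy stress of the compressible Neo-Hookean solid.

    W = mu/2 (I1 - 3) - mu ln J + lam/2 (ln J)^2, which gives
    sigma = (mu/J)(B - I) + (lam/J) ln(J) I.
    """
    F = np.asarray(F, dtype=float)
    J = _det3(F)
    if np.any(J <= 0.0):
        raise FloatingPointError("element inversion: det F <= 0")
    B = F @ np.swapaxes(F, -1, -2)
    Jb = J[..., None, None]
    return (mu / Jb) * (B - _I3) + (lam / Jb) * np.log(Jb) * _I3


def neo_hookean_pk1(F: np.ndarray, lam: float, mu: float, tangent: bool = True):
    """PK1 stress P = mu F + (lam ln J - mu) F^{-T} and (optionally) dP/dF."""
    F = np.asarray(F, dtype=float)
    J = _det3(F)
    if np.any(J <= 0.0):
        raise FloatingPointError("element inversion: det F <= 0")
    Finv = np.linalg.inv(F)
    FinvT = np.swapaxes(Finv, -1, -2)
    c = (lam * np.log(J) - mu)[..., None, None]
    P = mu * F + c * FinvT
    if not tangent:
        return P, None
    # A_{iJkL} = mu d_ik d_JL + lam F^-T_iJ F^-T_kL - c F^-1_Jk F^-1_Li
    sh = F.shape[:-2]
    A = mu * np.einsum("ik,JL->iJkL", _I3, _I3, optimize=True)
    A = np.broadcast_to(A, sh + (3, 3, 3, 3)).copy()
    A += lam * np.einsum("...iJ,...kL->...iJkL", FinvT, FinvT, optimize=True)
    A -= c[..., None, None] * np.einsum("...Jk,...Li->...iJkL", Finv, Finv, optimize=True)
    return P, A


def svk_stress_pk2(F: np.ndarray, lam: float, mu: float) -> np.ndarray:
    """PK2 stress of the Saint Venant-Kirchhoff law (Hooke in Green strain)."""
    F = np.asarray(F, dtype=float)
    C = np.swapaxes(F, -1, -2) @ F
    E = 0.5 * (C - _I3)
    trE = np.trace(E, axis1=-2, axis2=-1)[..., None, None]
    return lam * trE * _I3 + 2.0 * mu * E


def svk_pk1(F: np.ndarray, lam: float, mu: float, tangent: bool = True):
    """PK1 stress and tangent of the Saint Venant-Kirchhoff law."""
    F = np.asarray(F, dtype=float)
    S = svk_stress_pk2(F, lam, mu)
    P = F @ S
    if not tangent:
        return P, None
    B = F @ np.swapaxes(F, -1, -2)
    A = np.einsum("ik,...JL->...iJkL", _I3, S, optimize=True).copy()
    A += lam * np.einsum("...iJ,...kL->...iJkL", F, F, optimize=True)
    A += mu * np.einsum("...ik,JL->...iJkL", B, _I3, optimize=True)
    A += mu * np.einsum("...iL,...kJ->...iJkL", F, F, optimize=True)
    return P, A


# Neo-Hookean in PK2 form (used as the viscoelastic elastic backbone)


def neo_hookean_pk2(F: np.ndarray, lam: float, mu: float, tangent: bool = True):
    """S = mu (I - C^{-1}) + lam ln J C^{-1}, with optional dS/dF."""
    F = np.asarray(F, dtype=float)
    J = _det3(F)
    if np.any(J <= 0.0):
        raise FloatingPointError("element inversion: det F <= 0")
    Finv = np.linalg.inv(F)
    Cinv = Finv @ np.swapaxes(Finv, -1, -2)
    lnJ = np.log(J)[..., None, None]
    c = lam * lnJ - mu
    S = mu * _I3 + c * Cinv
    if not tangent:
        return S, None
    # dS_MN/dF_kL = lam Cinv_MN Finv_Lk - c (Cinv_ML Finv_Nk + Cinv_NL Finv_Mk)
    H = lam * np.einsum("...MN,...Lk->...MNkL", Cinv, Finv, optimize=True)
    H -= c[..., None, None] * (
        np.einsum("...ML,...Nk->...MNkL", Cinv, Finv, optimize=True)
        + np.einsum("...NL,...Mk->...MNkL", Cinv, Finv, optimize=True)
    )
    return S, H


def cauchy_from_pk1(F: np.ndarray, P: np.ndarray) -> np.ndarray:
    """sigma = (1/J) P F^T."""
    J = _det3(F)[..., None, None]
    return (P @ np.swapaxes(F, -1, -2)) / J


# ---------------------------------------------------------------------------
# quasi-linear viscoelasticity
# ---------------------------------------------------------------------------


def reduced_relaxation(t, prony: PronyParams) -> np.ndarray:
    """Normalized relaxation function g(t), g(0) = 1, g(inf) = G_inf/sum(G).

    g(t) = (G_inf + G_1 exp(-t/tau_1) + G_2 exp(-t/tau_2)) / (G_inf+G_1+G_2)
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("relaxation time argument must be nonnegative")
    g = (
        prony.G_inf
        + prony.G_1 * np.exp(-t / prony.tau_1)
        + prony.G_2 * np.exp(-t / prony.tau_2)
    ) / prony.G_sum
    return g


@dataclass
class ViscoHistory:
    """Per-quadrature internal state of the convolution recurrence.

    ``branches[i]`` carries the i-th exponential branch's tensorial state and
    ``stress_prev`` the elastic (backbone) stress at the previous converged
    step; both have shape (n_qp, 3, 3). Zero-initialized at t = 0.
    """

    branches: list[np.ndarray]
    stress_prev: np.ndarray
    time: float = 0.0

    @classmethod
    def zeros(cls, n_qp: int, n_branches: int = 2) -> "ViscoHistory":
        return cls(
            branches=[np.zeros((n_qp, 3, 3)) for _ in range(n_branches)],
            stress_prev=np.zeros((n_qp, 3, 3)),
            time=0.0,
        )

    def copy(self) -> "ViscoHistory":
        return ViscoHistory(
            branches=[b.copy() for b in self.branches],
            stress_prev=self.stress_prev.copy(),
            time=self.time,
        )


def _branch_coeffs(dt: float, prony: PronyParams):
    """Exponential-integrator recurrence coefficients per branch.

    For elastic stress varying linearly over the step,
    h^{n+1} = e^{-dt/tau} h^n + gamma (1 - e^{-dt/tau}) / (dt/tau) * dS_e.
    """
    gammas = prony.gammas
    out = []
    for gamma, tau in zip(gammas, prony.taus):
        x = dt / tau
        e = np.exp(-x)
        if x < 1e-8:
            beta = gamma * (1.0 - 0.5 * x)
        else:
            beta = gamma * (1.0 - e) / x
        out.append((e, beta))
    return out


def viscoelastic_multiplier(dt: float, prony: PronyParams) -> float:
    """Factor m such that S = m * S_e_new + (history terms)."""
    return prony.g_inf + sum(beta for _, beta in _branch_coeffs(dt, prony))


def viscoelastic_stress_update(
    history: ViscoHistory,
    dt: float,
    elastic_stress_new: np.ndarray,
    prony: PronyParams,
    commit: bool = True,
):
    """One step of the quasi-linear viscoelastic recurrence.

    sigma(t) = int g(t - s) dsigma_e(s); each Prony branch is integrated by
    the standard exponential recurrence assuming the elastic stress varies
    linearly across the step. Returns (stress, new_history); with
    ``commit=False`` the input history is left untouched (trial update inside
    Newton iterations).
    """
    if dt <= 0.0:
        raise ValueError("dt must be positive")
    Se = np.asarray(elastic_stress_new, dtype=float)
    dS = Se - history.stress_prev
    coeffs = _branch_coeffs(dt, prony)
    new_branches = [e * h + beta * dS for (e, beta), h in zip(coeffs, history.branches)]
    stress = prony.g_inf * Se + sum(new_branches)
    new_hist = ViscoHistory(
        branches=new_branches, stress_prev=Se.copy(), time=history.time + dt
    )
    if commit:
        return stress, new_hist
    return stress, new_hist


# ---------------------------------------------------------------------------
# scalar stress measures
# ---------------------------------------------------------------------------


def von_mises(sigma: np.ndarray) -> np.ndarray:
    """Effective (von Mises) stress sqrt(3/2 dev(s):dev(s))."""
    s = np.asarray(sigma, dtype=float)
    dev = s - np.trace(s, axis1=-2, axis2=-1)[..., None, None] / 3.0 * _I3
    return np.sqrt(1.5 * np.einsum("...ij,...ij->...", dev, dev))


def total_stress(sigma: np.ndarray) -> np.ndarray:
    """Sum of the three directional (normal) stresses: the trace of sigma."""
    return np.trace(np.asarray(sigma, dtype=float), axis1=-2, axis2=-1)
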