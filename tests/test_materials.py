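"""Constitutive-law unit and property tests: closed-form limits, frame
objectivity, tangent consistency and the Prony relaxation recurrence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cellindent.materials import (
    MaterialSpec,
    PronyParams,
    ViscoHistory,
    lame_from_E_nu,
    neo_hookean_pk1,
    neo_hookean_pk2,
    neo_hookean_stress,
    reduced_relaxation,
    svk_pk1,
    total_stress,
    viscoelastic_stress_update,
    von_mises,
)


class TestLame:
    @pytest.mark.parametrize(
        "E, nu, mu_exp, lam_exp",
        [
            (2.4, 0.48, 2.4 / (2 * 1.48), 2.4 * 0.48 / (1.48 * 0.04)),
            (2.0, 0.49, 2.0 / (2 * 1.49), 2.0 * 0.49 / (1.49 * 0.02)),
            (1.0, 0.0, 0.5, 0.0),
        ],
    )
    def test_closed_form(self, E, nu, mu_exp, lam_exp):
        lam, mu = lame_from_E_nu(E, nu)
        assert mu == pytest.approx(mu_exp, rel=1e-12)
        assert lam == pytest.approx(lam_exp, rel=1e-12)

    def test_gel_values(self):
        # gel constants: mu ~ 0.8108, lambda ~ 19.459 kPa
        lam, mu = lame_from_E_nu(2.4, 0.48)
        assert mu == pytest.approx(0.8108, abs=1e-4)
        assert lam == pytest.approx(19.459, abs=1e-3)

    def test_incompressible_rejected(self):
        with pytest.raises(ValueError):
            lame_from_E_nu(1.0, 0.5)


class TestNeoHookean:
    def test_reference_state_stress_free(self):
        sig = neo_hookean_stress(np.eye(3), 10.0, 1.0)
        assert np.allclose(sig, 0.0, atol=1e-14)

    @pytest.mark.parametrize("E, nu", [(0.8, 0.49), (2.4, 0.48), (1.0, 0.3)])
    def test_small_strain_uniaxial_limit(self, E, nu):
        """Axial stress/strain ratio tends to E in the uniaxial small-strain
        limit (lateral contraction solved for zero transverse stress)."""
        lam, mu = lame_from_E_nu(E, nu)
        eps = 1e-5
        lat = 1.0 - nu * eps  # first-order lateral contraction
        F = np.diag([lat, 1.0 + eps, lat])
        sig = neo_hookean_stress(F, lam, mu)
        assert sig[1, 1] / eps == pytest.approx(E, rel=1e-3)
        assert abs(sig[0, 0]) < 1e-3 * abs(sig[1, 1])

    @pytest.mark.parametrize("E, nu", [(0.8, 0.49), (2.4, 0.48)])
    def test_volumetric_bulk_limit(self, E, nu):
        lam, mu = lame_from_E_nu(E, nu)
        delta = 1e-5
        F = (1.0 + delta) * np.eye(3)
        sig = neo_hookean_stress(F, lam, mu)
        K = E / (3.0 * (1.0 - 2.0 * nu))
        pressure = np.trace(sig) / 3.0
        assert pressure / (3.0 * delta) == pytest.approx(K, rel=1e-3)

    def test_inversion_rejected(self):
        with pytest.raises(FloatingPointError):
            neo_hookean_stress(np.diag([1.0, -1.0, 1.0]), 1.0, 1.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_objectivity(self, seed):
        """sigma(R F) = R sigma(F) R^T for rigid rotations R."""
        rng = np.random.default_rng(seed)
        F = np.eye(3) + 0.3 * rng.standard_normal((3, 3))
        if np.linalg.det(F) < 0.2:
            F = np.eye(3) + 0.05 * rng.standard_normal((3, 3))
        theta = rng.uniform(0, 2 * np.pi)
        c, s = np.cos(theta), np.sin(theta)
        R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
        sig = neo_hookean_stress(F, 3.0, 1.2)
        sig_rot = neo_hookean_stress(R @ F, 3.0, 1.2)
        assert np.allclose(sig_rot, R @ sig @ R.T, atol=1e-10)

    @pytest.mark.parametrize("law", ["nh", "svk", "nh_pk2"])
    def test_tangent_matches_finite_differences(self, law, rng):
        lam_c, mu_c = 2.0, 0.7
        F = np.eye(3) + 0.2 * rng.standard_normal((3, 3))
        fun = {
            "nh": lambda X, tangent=True: neo_hookean_pk1(X, lam_c, mu_c, tangent),
            "svk": lambda X, tangent=True: svk_pk1(X, lam_c, mu_c, tangent),
            "nh_pk2": lambda X, tangent=True: neo_hookean_pk2(X, lam_c, mu_c, tangent),
        }[law]
        P0, A = fun(F)
        h = 1e-7
        for k in range(3):
            for L in range(3):
                Fp, Fm = F.copy(), F.copy()
                Fp[k, L] += h
                Fm[k, L] -= h
                dP = (fun(Fp, tangent=False)[0] - fun(Fm, tangent=False)[0]) / (2 * h)
                assert np.allclose(A[..., :, :, k, L], dP, rtol=2e-6, atol=2e-6)

    def test_svk_equals_nh_to_first_order(self):
        lam_c, mu_c = 5.0, 1.0
        F = np.eye(3) + 1e-6 * np.array([[1, 2, 0], [0, -1, 1], [1, 0, 3]])
        P_nh, _ = neo_hookean_pk1(F, lam_c, mu_c, tangent=False)
        P_svk, _ = svk_pk1(F, lam_c, mu_c, tangent=False)
        assert np.allclose(P_nh, P_svk, atol=1e-10)


class TestScalarMeasures:
    def test_von_mises_hydrostatic_is_zero(self):
        assert von_mises(3.7 * np.eye(3)) == pytest.approx(0.0, abs=1e-12)

    def test_von_mises_uniaxial(self):
        assert von_mises(np.diag([2.5, 0, 0])) == pytest.approx(2.5)

    def test_von_mises_pure_shear(self):
        s = np.zeros((3, 3))
        s[0, 1] = s[1, 0] = 1.3  # sigma_rz
        assert von_mises(s) == pytest.approx(np.sqrt(3) * 1.3, rel=1e-12)

    @pytest.mark.parametrize(
        "sig, expected",
        [
            (np.diag([1.0, 2.0, 3.0]), 6.0),
            (np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0.0]]), 0.0),
            (2.0 * np.eye(3), 6.0),
        ],
    )
    def test_total_stress_is_trace(self, sig, expected):
        assert total_stress(sig) == pytest.approx(expected)


class TestProny:
    def test_normalization_and_long_time_limit(self):
        pr = PronyParams()
        assert reduced_relaxation(0.0, pr) == pytest.approx(1.0)
        # printed constants: g(inf) = 4.05 / 58.25
        assert pr.g_inf == pytest.approx(4.05 / (4.05 + 34.0 + 20.2), rel=1e-12)
        assert reduced_relaxation(1e4, pr) == pytest.approx(pr.g_inf, rel=1e-9)
        assert pr.g_inf == pytest.approx(0.0695, abs=2e-4)

    def test_monotone_decay_within_bounds(self):
        pr = PronyParams()
        t = np.linspace(0, 40, 400)
        g = reduced_relaxation(t, pr)
        assert np.all(np.diff(g) < 0)
        assert np.all(g <= 1.0 + 1e-12)
        assert np.all(g >= pr.g_inf - 1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            reduced_relaxation(-0.1, PronyParams())

    def test_step_relaxation_matches_closed_form(self):
        """Recurrence under a stress step follows g(t) within 1%."""
        pr = PronyParams()
        hist = ViscoHistory.zeros(1)
        S = 2.0 * np.eye(3)[None]
        sig, hist = viscoelastic_stress_update(hist, 1e-9, S, pr)
        assert np.allclose(sig, S, rtol=1e-6)  # instantaneous response
        t, dt = 0.0, 0.01
        while t < 60.0:  # ~11 long relaxation times: g(t) within 1% of g_inf
            sig, hist = viscoelastic_stress_update(hist, dt, S, pr)
            t += dt
            g = reduced_relaxation(t, pr)
            assert sig[0, 0, 0] / 2.0 == pytest.approx(g, rel=0.01)
        assert sig[0, 0, 0] / 2.0 == pytest.approx(pr.g_inf, rel=0.01)

    def test_single_branch_closed_form(self):
        """With the second branch switched off the ratio follows
        (G_inf + G1 e^{-t/tau1})/(G_inf + G1) within 0.1%."""
        pr = PronyParams(G_inf=4.05, G_1=34.0, G_2=1e-12, tau_1=0.58, tau_2=5.47)
        hist = ViscoHistory.zeros(1)
        S = np.eye(3)[None]
        sig, hist = viscoelastic_stress_update(hist, 1e-10, S, pr)
        t, dt = 0.0, 0.002
        while t < 3.0:
            sig, hist = viscoelastic_stress_update(hist, dt, S, pr)
            t += dt
        expect = (4.05 + 34.0 * np.exp(-t / 0.58)) / (4.05 + 34.0)
        assert sig[0, 0, 0] == pytest.approx(expect, rel=1e-3)

    def test_zero_elastic_stress_stays_zero(self):
        pr = PronyParams()
        hist = ViscoHistory.zeros(4)
        Z = np.zeros((4, 3, 3))
        for _ in range(50):
            sig, hist = viscoelastic_stress_update(hist, 0.1, Z, pr)
        assert np.allclose(sig, 0.0)

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            viscoelastic_stress_update(ViscoHistory.zeros(1), 0.0, np.zeros((1, 3, 3)), PronyParams())


class TestMaterialSpec:
    def test_viscoelastic_modes(self):
        eq = MaterialSpec(law="viscoelastic_prony", E=0.8, nu=0.49, prony_mode="equilibrium")
        assert eq.E_equilibrium == pytest.approx(0.8, rel=1e-12)
        assert eq.E_instantaneous == pytest.approx(0.8 / eq.prony.g_inf, rel=1e-12)
        lit = MaterialSpec(law="viscoelastic_prony", E=0.8, nu=0.49, prony_mode="literal")
        assert lit.E_instantaneous == pytest.approx(2 * 1.49 * 58.25, rel=1e-12)
        assert lit.E_equilibrium == pytest.approx(2 * 1.49 * 4.05, rel=1e-12)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            MaterialSpec(law="bogus")
        with pytest.raises(ValueError):
            MaterialSpec(law="neo_hookean", E=-1.0)
        with pytest.raises(ValueError):
            MaterialSpec(law="neo_hookean", nu=0.5)
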