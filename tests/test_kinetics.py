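"""Rate laws, reaction-vector assembly, stoichiometric bookkeeping."""

import numpy as np
import pytest
import sympy
from hypothesis import given, strategies as st

import microreactor as mr
from microreactor.kinetics import (
    KineticsError,
    SEKinetics,
    Species,
    _exact_rank,
    _g6p_export_raw,
)

conc = st.floats(min_value=0.0, max_value=100.0, allow_nan=False)
frac = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


# ---------------------------------------------------------------------------
# individual rate laws
# ---------------------------------------------------------------------------

class TestInvertase:
    def test_hand_evaluated_value(self, hs_params):
        # lam=1, vmax=6.57e-5, [S]=50, KmS=0.9 -> vmax*50/50.9
        r = mr.rate_invertase(1.0, 50.0, hs_params)
        assert r == pytest.approx(6.57e-5 * 50.0 / 50.9, rel=1e-12)
        assert r == pytest.approx(6.4539e-5, rel=1e-4)

    @given(S=conc, lam=frac)
    def test_bounds_and_zero_cases(self, hs_params, S, lam):
        r = mr.rate_invertase(lam, S, hs_params)
        assert 0.0 <= r <= lam * hs_params.vmax_inv + 1e-30
        assert mr.rate_invertase(0.0, S, hs_params) == 0.0
        assert mr.rate_invertase(lam, 0.0, hs_params) == 0.0

    def test_monotone_in_substrate(self, hs_params):
        S = np.linspace(0.0, 100.0, 50)
        r = mr.rate_invertase(1.0, S, hs_params)
        assert np.all(np.diff(r) >= 0)

    def test_negative_concentration_rejected(self, hs_params):
        with pytest.raises(KineticsError):
            mr.rate_invertase(1.0, -1.0, hs_params)


class TestHexokinase:
    def test_hand_evaluated_value(self, hs_params):
        # HsHK2: [G]=1, [ATP]=10 -> vmax*10/(0.026+0.5+0.52+10)
        r = mr.rate_hexokinase(1.0, 1.0, 10.0, "G", hs_params)
        den = 0.052 * 0.5 + 0.5 * 1.0 + 0.052 * 10.0 + 1.0 * 10.0
        assert r == pytest.approx(10.62e-7 * 10.0 / den, rel=1e-12)
        assert r == pytest.approx(9.614e-7, rel=1e-4)

    def test_zero_substrate_and_saturation(self, hs_params):
        assert mr.rate_hexokinase(1.0, 0.0, 10.0, "G", hs_params) == 0.0
        r_inf = mr.rate_hexokinase(1.0, 1e9, 1e9, "F", hs_params)
        assert r_inf == pytest.approx(hs_params.vmax_hk, rel=1e-6)

    @given(X=conc, A=conc, lam=frac)
    def test_bounded_by_maximal_velocity(self, hs_params, X, A, lam):
        r = mr.rate_hexokinase(lam, X, A, "G", hs_params)
        assert 0.0 <= r <= lam * hs_params.vmax_hk + 1e-30

    def test_substrate_selects_km(self, sc_params):
        # ScHK2 KmF=0.33 != KmG=0.12 -> rates differ at equal concentrations
        rG = mr.rate_hexokinase(1.0, 0.2, 10.0, "G", sc_params)
        rF = mr.rate_hexokinase(1.0, 0.2, 10.0, "F", sc_params)
        assert rG > rF


class TestPgi:
    def test_reverse_only_value(self, hs_params):
        # [F6P]=0, [G6P]=0.5 -> -vmax_b*0.5/1.0
        r = mr.rate_pgi(1.0, 0.0, 0.5, hs_params)
        assert r == pytest.approx(-6.285e-6, rel=1e-12)

    def test_zero_and_symmetry(self, hs_params):
        assert mr.rate_pgi(1.0, 0.0, 0.0, hs_params) == 0.0
        # equal saturations with equal vmax -> exact cancellation
        p = hs_params
        f6p = 0.38  # saturation 2/3
        g6p = p.K_mG6P * (f6p / p.K_mF6P)  # same saturation fraction
        assert mr.rate_pgi(1.0, f6p, g6p, p) == pytest.approx(0.0, abs=1e-20)


class TestG6PExport:
    def test_zero_at_equilibrium(self, hs_params):
        p = hs_params
        # [G6P][Pi_e] = [G6P_e][Pi]/K_eq
        Pi = 2.0
        G6P = p.G6P_e * Pi / (p.K_eq * p.Pi_e)
        assert mr.rate_g6p_export(G6P, Pi, p) == pytest.approx(0.0, abs=1e-25)

    def test_sign_of_numerator(self, hs_params):
        # nothing inside -> nothing to antiport
        assert mr.rate_g6p_export(0.0, 0.0, hs_params) == 0.0
        # internal Pi only -> import direction (negative)
        assert mr.rate_g6p_export(0.0, 1.0, hs_params) < 0.0
        # internal G6P only -> export direction (positive)
        assert mr.rate_g6p_export(1.0, 0.0, hs_params) > 0.0

    def test_against_duplicate_formula(self, hs_params):
        """Independently hand-coded ping-pong expression, same constants."""
        p = hs_params
        G6P, Pi = 0.37, 1.21
        num = p.vmax_G6P_f * (G6P * p.Pi_e - p.G6P_e * Pi / p.K_eq)
        den = (G6P * p.Pi_e
               + p.K_mPie * G6P
               + p.K_mG6PT * p.Pi_e * (1 + Pi / p.K_iPi)
               + (p.vmax_G6P_f / p.vmax_G6P_b / p.K_eq)
               * (p.K_mPi * p.G6P_e * (1 + G6P / p.K_iG6P)
                  + Pi * (p.K_mG6Pe + p.G6P_e)))
        assert mr.rate_g6p_export(G6P, Pi, p) == pytest.approx(num / den,
                                                              rel=1e-14)


# ---------------------------------------------------------------------------
# assembled reaction vectors
# ---------------------------------------------------------------------------

class TestReactionVectors:
    def test_fresh_state_only_invertase(self, hs_params):
        lam = mr.Stoichiometry(0.25, 0.5, 0.25)
        R = mr.bead_flux_vector(np.zeros(5), lam, hs_params)
        r_inv = mr.rate_invertase(lam.inv, hs_params.S, hs_params)
        assert R[Species.G] == pytest.approx(r_inv, rel=1e-14)
        assert R[Species.F] == pytest.approx(r_inv, rel=1e-14)
        assert R[Species.F6P] == 0.0 and R[Species.PI] == 0.0
        assert R[Species.G6P] == 0.0

    def test_invertase_only_loading(self, hs_params):
        R = mr.bead_flux_vector(np.array([1.0, 1.0, 1.0, 0.5, 1.0]),
                                mr.Stoichiometry(1.0, 0.0, 0.0), hs_params)
        assert R[Species.F6P] == 0.0 and R[Species.G6P] == 0.0

    @given(y=st.lists(conc, min_size=5, max_size=5),
           l1=frac, l2=frac)
    def test_hexose_conservation_identity(self, hs_params, y, l1, l2):
        """R_G + R_F + R_F6P + R_G6P = 2 r_inv: cleavage of one sucrose
        yields two hexose units that are only interconverted downstream."""
        tot = l1 + l2
        if tot > 1.0:
            l1, l2 = l1 / tot, l2 / tot
        lam = mr.Stoichiometry(l1, l2, max(0.0, 1.0 - l1 - l2))
        y = np.asarray(y)
        R = mr.bead_flux_vector(y, lam, hs_params)
        r_inv = mr.rate_invertase(lam.inv, hs_params.S, hs_params)
        hexoses = R[Species.G] + R[Species.F] + R[Species.F6P] + R[Species.G6P]
        # abs floor: roundoff of the cancelling rate terms (vmax scale)
        assert hexoses == pytest.approx(2.0 * r_inv, rel=1e-14,
                                        abs=1e-14 * hs_params.vmax_inv)
        assert R[Species.PI] == 0.0

    def test_export_vector_antiport_conservation(self, hs_params):
        y = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        R = mr.export_flux_vector(y, hs_params)
        r = mr.rate_g6p_export(y[Species.G6P], y[Species.PI], hs_params)
        assert R[Species.G6P] == pytest.approx(-r, rel=1e-14)
        assert R[Species.PI] == pytest.approx(r, rel=1e-14)
        assert R[Species.G6P] + R[Species.PI] == pytest.approx(0.0, abs=1e-25)
        assert np.all(R[[Species.G, Species.F, Species.F6P]] == 0.0)

    def test_bulk_vector_scaling(self, hs_params):
        lam = mr.Stoichiometry.uniform()
        y = np.array([1.0, 0.5, 0.2, 0.1, 0.3])
        Rb = mr.bead_flux_vector(y, lam, hs_params)
        assert np.allclose(mr.bulk_reaction_vector(y, lam, hs_params, 0.0), 0.0)
        scale = np.pi * 1e-5 / (500e-6) ** 2
        np.testing.assert_allclose(
            mr.bulk_reaction_vector(y, lam, hs_params, scale), scale * Rb,
            rtol=1e-14)


class TestJacobians:
    def test_lambda_derivative_is_state_only(self, hs_params):
        y = np.array([0.3, 0.1, 0.05, 0.2, 0.4])
        for lam in (mr.Stoichiometry.uniform(), mr.Stoichiometry(0.6, 0.3, 0.1)):
            _, dRdlam, _ = mr.kinetics_jacobians(y, lam, hs_params)
            a_inv = hs_params.vmax_inv * hs_params.S / (hs_params.K_mS
                                                        + hs_params.S)
            assert dRdlam[Species.G, 0] == pytest.approx(a_inv, rel=1e-14)

    @pytest.mark.parametrize("variant", ["HsHK2", "ScHK2"])
    def test_jacobians_match_finite_differences(self, variant):
        p = mr.load_parameters(variant)
        lam = mr.Stoichiometry(0.2, 0.5, 0.3)
        rng = np.random.default_rng(42)
        mdl = SEKinetics(p, lam)
        for _ in range(20):
            y = rng.uniform(0.0, 5.0, 5)
            Jy, Jlam, Je = mr.kinetics_jacobians(y, lam, p)
            h = 1e-4 * np.maximum(y, 1.0)

            def fd4(f, j):
                """Fourth-order five-point difference in component j."""
                vals = []
                for c in (-2, -1, 1, 2):
                    yc = y.copy()
                    yc[j] += c * h[j]
                    vals.append(f(yc))
                return (vals[0] - 8 * vals[1] + 8 * vals[2] - vals[3]) / (12 * h[j])

            for j in range(5):
                fd_b = fd4(mdl.bead_rates, j)
                fd_e = fd4(mdl.export_rates, j)
                scale = max(np.abs(fd_b).max(), 1e-6 * p.vmax_inv)
                np.testing.assert_allclose(Jy[:, j], fd_b, atol=1e-6 * scale)
                scale_e = max(np.abs(fd_e).max(), 1e-6 * p.vmax_G6P_f)
                np.testing.assert_allclose(Je[:, j], fd_e, atol=1e-6 * scale_e)

    @given(alpha=st.floats(min_value=0.01, max_value=1.0))
    def test_rates_linear_in_stoichiometry(self, hs_params, alpha):
        """Scaling a lambda component scales its rates exactly linearly."""
        y = np.array([0.5, 0.4, 0.3, 0.2, 0.1])
        base = SEKinetics(hs_params, np.array([0.3, 0.5, 0.2]))
        scaled = SEKinetics(hs_params, alpha * np.array([0.3, 0.5, 0.2]))
        np.testing.assert_allclose(scaled.bead_rates(y),
                                   alpha * base.bead_rates(y), rtol=1e-14)


# ---------------------------------------------------------------------------
# stoichiometry vector, equal activity, vmax arithmetic
# ---------------------------------------------------------------------------

class TestStoichiometry:
    def test_simplex_validation(self):
        with pytest.raises(KineticsError):
            mr.Stoichiometry(0.5, 0.6, 0.1)
        with pytest.raises(KineticsError):
            mr.Stoichiometry(-0.1, 0.6, 0.5)
        lam = mr.Stoichiometry(0.2, 0.3, 0.5 + 5e-13)  # within tolerance
        assert lam.as_array().sum() == pytest.approx(1.0, abs=1e-15)

    def test_equal_activity_equalizes_activity(self, hs_params):
        lam = mr.equal_activity_stoichiometry(*hs_params.kcats)
        acts = hs_params.kcats * lam.as_array()
        assert np.ptp(acts) < 1e-12 * acts.max()
        assert lam.as_array().sum() == pytest.approx(1.0, abs=1e-14)

    def test_equal_kcats_give_uniform(self):
        lam = mr.equal_activity_stoichiometry(2.0, 2.0, 2.0)
        np.testing.assert_allclose(lam.as_array(), 1.0 / 3.0, rtol=1e-15)

    def test_published_equal_activity_components(self):
        lam_hs = mr.equal_activity_stoichiometry(3379.60, 54.63, 646.61)
        assert round(lam_hs.inv, 4) == 0.0147
        lam_sc = mr.equal_activity_stoichiometry(3379.60, 1.06, 646.61)
        assert tuple(np.round(lam_sc.as_array(), 4)) == (0.0003, 0.9981, 0.0016)

    def test_nonpositive_kcat_rejected(self):
        with pytest.raises(KineticsError):
            mr.equal_activity_stoichiometry(0.0, 1.0, 1.0)


class TestVmaxFromLoading:
    def test_published_full_loading_values(self):
        E = 1.94e-8
        assert mr.vmax_from_loading(3379.60, E) == pytest.approx(6.57e-5,
                                                                 rel=5e-3)
        assert mr.vmax_from_loading(54.63, E) == pytest.approx(10.62e-7,
                                                               rel=5e-3)
        assert mr.vmax_from_loading(646.61, E) == pytest.approx(12.57e-6,
                                                                rel=5e-3)

    def test_zero_loading_and_bead_division(self):
        assert mr.vmax_from_loading(100.0, 0.0) == 0.0
        full = mr.vmax_from_loading(100.0, 2e-8)
        assert mr.vmax_from_loading(100.0, 2e-8, 4) == pytest.approx(full / 4,
                                                                     rel=1e-15)

    def test_negative_loading_rejected(self):
        with pytest.raises(KineticsError):
            mr.vmax_from_loading(1.0, -1e-9)


# ---------------------------------------------------------------------------
# decoupling rank
# ---------------------------------------------------------------------------

def _sympy_rank(M):
    return sympy.Matrix(M.tolist()).rank()


class TestDecouplingRank:
    def test_full_network_has_six_coupled_species(self):
        S = mr.full_network_matrix()
        assert S.combined.shape == (11, 6)
        assert mr.coupled_species_count(S) == 6
        assert _sympy_rank(S.combined) == 6

    def test_se_network_has_full_rank(self):
        S = mr.se_network_matrix()
        assert S.combined.shape == (5, 5)
        assert mr.coupled_species_count(S) == 5
        assert _sympy_rank(S.combined) == 5

    def test_single_reaction_network(self):
        S = mr.kinetics.StoichiometricMatrix(
            ("A", "B"), ("r",), (), np.array([[-1], [1]]),
            np.zeros((2, 0), dtype=int))
        assert mr.coupled_species_count(S) == 1

    def test_exact_elimination_matches_sympy_on_random_int_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            M = rng.integers(-2, 3, size=(6, 4))
            assert _exact_rank(M) == _sympy_rank(M)


class TestParameterIO:
    def test_yaml_roundtrip(self, tmp_path, hs_params):
        path = tmp_path / "p.yaml"
        hs_params.to_yaml(path)
        back = mr.KineticParameters.from_yaml(path)
        assert back == hs_params

    def test_variant_selection(self, hs_params, sc_params):
        assert hs_params.K_mG == 0.052 and sc_params.K_mG == 0.12
        assert hs_params.kcat_hk == 54.63 and sc_params.kcat_hk == 1.06

    def test_unknown_variant_rejected(self):
        with pytest.raises(KineticsError):
            mr.load_parameters("XXHK9")
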