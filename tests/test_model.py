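"""Structural model, equilibrium algebra and family moments."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from twinfam import model as tfm
from twinfam.model import (
    FamilyConfiguration,
    InadmissibleParameterError,
    ModelError,
    build_model,
    family_moments,
    pair_covariance,
    solve_equilibrium,
    univariate_q_closed_form,
    variance_components,
)

from conftest import univariate_model


class TestBuildModel:
    def test_drop_fixes_matrix_to_zero_and_removes_freedom(self):
        m = build_model("ABDSTE", drop=("t_m", "t_f"))
        assert not np.any(m.matrices["t_m"])
        assert not any(p.target in ("t_m", "t_f") for p in m.params)
        # dropping both T matrices removes 6 lower-triangular cells
        assert m.n_free == build_model("ABDSTE").n_free - 6

    def test_abdfte_excludes_sibling_environment(self):
        m = build_model("ABDFTE")
        assert "s_m" not in m.matrices and "s_f" not in m.matrices
        assert {"v_fs", "v_fd", "v_ms", "v_md"} <= set(m.matrices)

    def test_homogamy_has_no_copaths_and_free_c(self):
        m = build_model("ABDCTE")
        assert "mu" not in m.matrices
        assert any(p.target == "c_m" for p in m.params)

    def test_unknown_matrix_rejected(self):
        with pytest.raises(ModelError):
            build_model("ABDSTE", drop=("c_m",))

    def test_negative_diagonal_fix_rejected(self):
        with pytest.raises(ModelError):
            build_model("ABDSTE", fix={"a_m[0,0]": -0.5})

    def test_equate_merges_parameter_groups(self):
        m = build_model("ABDSTE", equate=[["mu[0,1]", "mu[1,0]"]])
        assert m.n_free == build_model("ABDSTE").n_free - 1

    def test_s_and_f_never_jointly_active(self):
        m = build_model("ABDFTE")
        assert not any(p.target.startswith("s_") for p in m.params)


class TestEquilibrium:
    def test_random_mating_is_exact_identity(self, random_mating_model):
        eq = solve_equilibrium(random_mating_model)
        assert np.array_equal(eq.q, np.eye(2))
        assert not np.any(eq.gamma)
        assert not np.any(pair_covariance(random_mating_model, eq,
                                          "spouse", "m", "f"))

    @pytest.mark.parametrize("a2,mu", [(0.5, 0.2), (0.8, 0.1), (0.6, 0.3)])
    def test_univariate_fixed_point_matches_quadratic_root(self, a2, mu):
        model = univariate_model(a2, mu)
        eq = solve_equilibrium(model, tol=1e-14)
        assert eq.q[0, 0] == pytest.approx(univariate_q_closed_form(a2, mu),
                                           abs=1e-8)

    def test_closed_form_example(self):
        # a^2 mu = 0.1: smaller root of 0.1 q^2 - q + 1 = 0
        assert univariate_q_closed_form(0.5, 0.2) == pytest.approx(1.1270,
                                                                   abs=1e-4)

    def test_too_strong_assortment_is_inadmissible(self):
        model = univariate_model(0.9, 0.4)  # 4 a^2 mu > 1
        with pytest.raises(InadmissibleParameterError):
            solve_equilibrium(model, max_iter=3000)

    def test_q_symmetric_psd_and_stationarity_identity(self, truth_eq):
        q, gamma = truth_eq.q, truth_eq.gamma
        assert np.allclose(q, q.T)
        assert np.linalg.eigvalsh(q).min() > 0
        assert np.allclose(q, np.eye(2) + 0.5 * (gamma + gamma.T),
                           atol=1e-9)

    def test_mu_monotonicity_on_q_diagonal(self):
        prev = 1.0
        for mu in (0.0, 0.1, 0.2, 0.3):
            eq = solve_equilibrium(univariate_model(0.5, mu))
            assert eq.q[0, 0] >= prev - 1e-12
            prev = eq.q[0, 0]

    def test_q_constraint_reduces_parameter_count(self, truth):
        constrained = truth.copy()
        constrained.constraints.add("q_offdiag_zero")
        assert constrained.n_free == truth.n_free - 1

    def test_homogamy_equilibrium_is_random_mating(self):
        eq = solve_equilibrium(build_model("ABDCTE"))
        assert np.array_equal(eq.q, np.eye(2))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(a2=st.floats(0.2, 0.8), mu=st.floats(0.0, 0.25))
    def test_univariate_fixed_point_property(self, a2, mu):
        """Fixed point agrees with the closed form wherever 4 a^2 mu < 1."""
        if 4 * a2 * mu >= 0.98:
            return
        eq = solve_equilibrium(univariate_model(a2, mu), tol=1e-13)
        assert eq.q[0, 0] == pytest.approx(
            univariate_q_closed_form(a2, mu), abs=1e-8)


class TestPairCovariance:
    def test_classical_twin_identities_at_random_mating(
            self, random_mating_model):
        m = random_mating_model
        eq = solve_equilibrium(m)
        a, b = m.matrices["a_m"], m.matrices["b"]
        d, s = m.matrices["d_m"], m.matrices["s_m"]
        mz = pair_covariance(m, eq, "MZ", "m", "m")
        dz = pair_covariance(m, eq, "DZ", "m", "m")
        # DZ male genetic part is a q a'/2 + b b'/2 with q = I
        expected = 0.5 * (a @ a.T + b @ b.T) + 0.75 * (d @ d.T)
        assert np.allclose(mz - dz, expected, atol=1e-12)
        sib = pair_covariance(m, eq, "sib", "m", "m")
        t = m.matrices["t_m"]
        assert np.allclose(dz - sib, t @ t.T, atol=1e-12)

    def test_spouse_block_orientation_transposes(self, truth, truth_eq):
        hw = pair_covariance(truth, truth_eq, "spouse", "m", "f")
        wh = pair_covariance(truth, truth_eq, "spouse", "f", "m")
        assert np.allclose(hw, wh.T)
        assert np.allclose(hw, truth_eq.vp_m @ truth.matrices["mu"]
                           @ truth_eq.vp_f)

    def test_opposite_sex_attenuation(self, truth_eq, truth):
        model = truth.copy()
        model.scalars["r_D"] = 0.5
        eq = solve_equilibrium(model)
        full = model.copy()
        full.scalars["r_D"] = 1.0
        eq_full = solve_equilibrium(full)
        d_m, d_f = model.matrices["d_m"], model.matrices["d_f"]
        diff = (pair_covariance(full, eq_full, "sib", "m", "f")
                - pair_covariance(model, eq, "sib", "m", "f"))
        assert np.allclose(diff, 0.25 * 0.5 * d_m @ d_f.T, atol=1e-10)

    def test_mz_requires_same_sex(self, truth, truth_eq):
        with pytest.raises(ModelError):
            pair_covariance(truth, truth_eq, "MZ", "m", "f")

    def test_unknown_relationship(self, truth, truth_eq):
        with pytest.raises(ModelError):
            pair_covariance(truth, truth_eq, "cousin", "m", "m")

    def test_homogamy_spouse_block_is_shared_c(self):
        m = build_model("ABDCTE")
        eq = solve_equilibrium(m)
        c_m, c_f = m.matrices["c_m"], m.matrices["c_f"]
        assert np.allclose(pair_covariance(m, eq, "spouse", "m", "f"),
                           c_m @ c_f.T)


class TestFamilyMoments:
    def test_singleton_block_is_phenotypic_covariance(self, truth, truth_eq):
        cfg = FamilyConfiguration(members=(("sib1", "m"),))
        mean, cov = family_moments(truth, truth_eq, cfg)
        assert np.allclose(cov, truth_eq.vp_m)
        assert mean.shape == (2,)

    def test_twin_block_embeds_pair_covariance(self, truth, truth_eq):
        cfg = FamilyConfiguration(
            members=(("father", "m"), ("mother", "f"),
                     ("twin1", "f"), ("twin2", "f")), zygosity="MZ")
        _, cov = family_moments(truth, truth_eq, cfg)
        assert cov.shape == (8, 8)
        assert np.allclose(cov[4:6, 6:8],
                           pair_covariance(truth, truth_eq, "MZ", "f", "f"))
        assert np.allclose(cov, cov.T)

    def test_twin_label_swap_is_a_permutation(self, truth, truth_eq):
        cfg = FamilyConfiguration(
            members=(("twin1", "m"), ("twin2", "m"), ("sib1", "f")),
            zygosity="DZ")
        _, cov = family_moments(truth, truth_eq, cfg)
        perm = [2, 3, 0, 1, 4, 5]
        assert np.allclose(cov, cov[np.ix_(perm, perm)])

    def test_duplicate_roles_rejected(self):
        with pytest.raises(ModelError):
            FamilyConfiguration(members=(("sib1", "m"), ("sib1", "f")))

    def test_mz_sexes_must_match(self):
        with pytest.raises(ModelError):
            FamilyConfiguration(members=(("twin1", "m"), ("twin2", "f")),
                                zygosity="MZ")


class TestVarianceComponents:
    def test_no_inflation_under_random_mating(self, random_mating_model):
        eq = solve_equilibrium(random_mating_model)
        rep = variance_components(random_mating_model, eq)
        for sex in ("m", "f"):
            assert rep.inflation[sex]["trait1"] == pytest.approx(0.0)
            assert rep.inflation[sex]["cross"] == pytest.approx(0.0)

    def test_printed_inflation_arithmetic(self):
        assert tfm.inflation_percent(0.08, 0.03) == pytest.approx(
            166.7, abs=0.05)
        assert tfm.inflation_percent(0.15, 0.08) == pytest.approx(
            87.5, abs=0.05)

    def test_genetic_correlation_definition(self, truth, truth_eq):
        rep = variance_components(truth, truth_eq)
        va = rep.components["m"]["A"]
        assert rep.r_A["m"] == pytest.approx(
            va[0, 1] / np.sqrt(va[0, 0] * va[1, 1]))
        # worked numeric example: V_A = [[.5,.1],[.1,.4]] -> .1/sqrt(.2)
        assert 0.1 / np.sqrt(0.5 * 0.4) == pytest.approx(0.2236, abs=1e-4)

    def test_narrow_below_broad_heritability(self, truth, truth_eq):
        rep = variance_components(truth, truth_eq)
        for sex in ("m", "f"):
            assert np.all(rep.narrow_h2[sex] <= rep.broad_h2[sex] + 1e-12)
            assert np.all(rep.broad_h2[sex] <= 1.0)
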