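"""FIML likelihood, fitting machinery and likelihood-ratio tests."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from twinfam import fiml
from twinfam.model import (
    FamilyConfiguration,
    ModelError,
    build_model,
    family_moments,
    solve_equilibrium,
)
from twinfam.fiml import (
    FamilyData,
    aic,
    chi2_sf,
    fit,
    lrt,
    negloglik,
    read_family_table,
    submodel,
    write_family_table,
)


def _single_family(members, zygosity="", values=None):
    rows = []
    for i, (role, sex) in enumerate(members):
        v = values[i] if values is not None else (0.1 * i, -0.1 * i)
        rows.append({"family_id": 1, "role": role, "sex": sex,
                     "zygosity": zygosity, "age": 20.0, "sample": "LTS",
                     "trait1": v[0], "trait2": v[1]})
    return pd.DataFrame(rows)


class TestChi2Machinery:
    @pytest.mark.parametrize("stat,df,expected,digits", [
        (7.8, 6, 0.253, 3),
        (16.99, 6, 0.009, 3),
        (4.6, 1, 0.03, 2),
        (12.9, 2, 0.002, 3),
        (14.4, 1, 0.0001, 4),
        (1.46, 4, 0.83, 2),
        (0.0, 5, 1.0, 6),
    ])
    def test_tail_probabilities_to_printed_precision(self, stat, df,
                                                     expected, digits):
        assert round(chi2_sf(stat, df), digits) == expected

    def test_extreme_tail(self):
        assert chi2_sf(47.4, 3) == pytest.approx(2.8e-10, rel=0.03)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            chi2_sf(-1.0, 2)
        with pytest.raises(ValueError):
            chi2_sf(1.0, 0)


class TestNegloglik:
    def test_singleton_standard_normal_contribution(self):
        """A lone standardized observation with unit model variance and the
        observed value at the mean contributes exactly ln(2 pi)."""
        model = build_model("ABDSTE", free_means=False)
        # force unit phenotypic variance on trait1 for a male singleton
        model.matrices["mu"][:] = 0.0
        for name in ("b", "d_m", "d_f", "s_m", "s_f", "t_m", "t_f"):
            model.matrices[name][:] = 0.0
        model.matrices["a_m"][:] = [[0.6, 0.0], [0.0, 0.6]]
        model.matrices["e_m"][:] = [[0.8, 0.0], [0.0, 0.8]]
        table = _single_family([("sib1", "m")], values=[(0.0, np.nan)])
        val = negloglik(model, table)
        assert val == pytest.approx(np.log(2 * np.pi), abs=1e-12)

    def test_matches_dense_multivariate_normal(self, truth, truth_eq,
                                               small_table):
        data = FamilyData(small_table)
        ours = negloglik(truth, data, truth_eq)
        dense = 0.0
        for (config, mask), x in data.groups.items():
            mean, cov = family_moments(truth, truth_eq, config)
            idx = np.flatnonzero(mask)
            mvn = multivariate_normal(mean=mean[idx],
                                      cov=cov[np.ix_(idx, idx)])
            dense += float(-2.0 * mvn.logpdf(x).sum())
        assert ours == pytest.approx(dense, abs=1e-8)

    @pytest.mark.parametrize("drop_role", ["father", "mother", "twin2",
                                           "sib1"])
    def test_missing_member_equals_deleted_member(self, truth, truth_eq,
                                                  drop_role):
        members = [("father", "m"), ("mother", "f"), ("twin1", "f"),
                   ("twin2", "f"), ("sib1", "m")]
        fam = _single_family(members, zygosity="MZ")
        with_missing = fam.copy()
        with_missing.loc[with_missing.role == drop_role,
                         ["trait1", "trait2"]] = np.nan
        deleted = fam[fam.role != drop_role]
        assert negloglik(truth, with_missing, truth_eq) == pytest.approx(
            negloglik(truth, deleted, truth_eq), abs=1e-10)

    def test_all_missing_family_dropped_with_count(self, truth, truth_eq):
        fam = _single_family([("twin1", "m"), ("twin2", "m")], zygosity="DZ")
        empty = fam.copy()
        empty["family_id"] = 2
        empty[["trait1", "trait2"]] = np.nan
        both = pd.concat([fam, empty])
        data = FamilyData(both)
        assert data.n_families == 1
        assert data.n_dropped == 1
        assert negloglik(truth, data, truth_eq) == pytest.approx(
            negloglik(truth, fam, truth_eq))

    def test_grouping_independence(self, truth, truth_eq, small_table):
        """Likelihood is a sum over families: splitting the table in two
        and adding the parts reproduces the total."""
        ids = small_table["family_id"].unique()
        half = set(ids[:len(ids) // 2])
        first = small_table[small_table.family_id.isin(half)]
        second = small_table[~small_table.family_id.isin(half)]
        total = negloglik(truth, small_table, truth_eq)
        assert total == pytest.approx(
            negloglik(truth, first, truth_eq)
            + negloglik(truth, second, truth_eq), abs=1e-8)


class TestFit:
    @pytest.fixture(scope="class")
    def fitted(self, truth, small_table):
        start = truth.copy()
        rng = np.random.default_rng(1)
        start.set_free(truth.get_free() + 0.03 * rng.standard_normal(
            truth.n_free))
        data = FamilyData(small_table)
        return fit(start, data, n_starts=1, maxiter=250), data

    def test_refit_from_optimum_is_idempotent(self, fitted):
        res, data = fitted
        again = fit(res.estimates, data, n_starts=1, maxiter=250)
        assert again.minus2lnL == pytest.approx(res.minus2lnL, abs=1e-3)

    def test_nested_submodel_cannot_fit_better(self, fitted):
        res, data = fitted
        reduced = submodel(res, drop=("s_m", "s_f"))
        red = fit(reduced, data, n_starts=1, maxiter=250)
        assert red.minus2lnL >= res.minus2lnL - 1e-6
        assert red.k == res.k - 6

    def test_aic_identity(self, fitted):
        res, _ = fitted
        assert res.aic == pytest.approx(res.minus2lnL + 2 * res.k)

    def test_report_roundtrip(self, fitted):
        res, _ = fitted
        d = res.to_dict()
        assert d["k"] == res.k
        text = fiml.format_report(res)
        assert "minus2lnL" in text and "aic" in text


class TestLrt:
    def _fake_fit(self, m2ll, k):
        class Dummy:
            minus2lnL = m2ll
        dummy = Dummy()
        dummy.k = k
        return dummy

    def test_printed_example_values(self):
        full = self._fake_fit(1000.0, 30)
        t = lrt(full, self._fake_fit(1007.8, 24))
        assert (t.chi2, t.df) == (pytest.approx(7.8), 6)
        assert t.p == pytest.approx(0.253, abs=5e-4)
        assert not t.retained   # p > .10: the matrix can be dropped
        t2 = lrt(full, self._fake_fit(1016.99, 24))
        assert t2.p == pytest.approx(0.009, abs=5e-4)
        assert t2.retained

    def test_zero_statistic(self):
        t = lrt(self._fake_fit(10.0, 5), self._fake_fit(10.0, 3))
        assert t.p == 1.0

    def test_tiny_negative_clamped(self):
        t = lrt(self._fake_fit(10.0, 5), self._fake_fit(10.0 - 1e-8, 3))
        assert t.chi2 == 0.0 and t.clamped

    def test_large_negative_raises(self):
        with pytest.raises(ModelError):
            lrt(self._fake_fit(10.0, 5), self._fake_fit(5.0, 3))

    def test_non_nested_k_raises(self):
        with pytest.raises(ModelError):
            lrt(self._fake_fit(10.0, 3), self._fake_fit(11.0, 5))

    def test_aic_helper(self):
        assert aic(8200.0, k=20) == 8240.0
        # nested pair: AIC difference = chi2 - 2 df
        full, red = self._fake_fit(1000.0, 30), self._fake_fit(1007.8, 24)
        t = lrt(full, red)
        assert aic(red.minus2lnL, k=red.k) - aic(full.minus2lnL, k=full.k) \
            == pytest.approx(t.chi2 - 2 * t.df)


class TestSubmodel:
    def test_drop_t_removes_six_parameters(self, truth):
        full = build_model("ABDSTE")
        red = submodel(full, drop=("t_m", "t_f"))
        assert red.n_free == full.n_free - 6

    def test_equate_copaths_removes_one(self):
        full = build_model("ABDSTE")
        red = submodel(full, equate=[["mu[0,1]", "mu[1,0]"]])
        assert red.n_free == full.n_free - 1

    def test_zero_cross_paths_removes_two(self):
        full = build_model("ABDSTE")
        red = submodel(full, fix={"a_m[1,0]": 0.0, "a_f[1,0]": 0.0})
        assert red.n_free == full.n_free - 2

    def test_fix_cross_sex_correlation(self):
        full = build_model("ABDSTE")
        red = submodel(full, fix={"r_S": 1.0})
        assert red.scalars["r_S"] == 1.0
        assert red.n_free == full.n_free - 1

    def test_q_constraint_counts_as_one(self):
        full = build_model("ABDSTE")
        red = submodel(full, constraints=("q_offdiag_zero",))
        assert red.n_free == full.n_free - 1

    def test_unknown_matrix_rejected(self):
        with pytest.raises(ModelError):
            submodel(build_model("ABDSTE"), drop=("c_m",))


class TestIO:
    def test_family_table_roundtrip(self, raw_table, tmp_path):
        path = tmp_path / "fam.tsv"
        write_family_table(raw_table, path)
        back = read_family_table(path)
        assert len(back) == len(raw_table)
        assert set(back.columns) >= {"family_id", "role", "sex", "zygosity",
                                     "trait1", "trait2"}
        np.testing.assert_allclose(
            back["trait1"].to_numpy(), raw_table["trait1"].to_numpy(),
            rtol=1e-12)

    def test_na_values_roundtrip(self, tmp_path):
        fam = _single_family([("twin1", "m"), ("twin2", "m")], zygosity="DZ")
        fam.loc[0, "trait1"] = np.nan
        path = tmp_path / "na.tsv"
        write_family_table(fam, path)
        back = read_family_table(path)
        assert back["trait1"].isna().iloc[0]

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("family_id,role\n1,father\n")
        with pytest.raises(ModelError):
            read_family_table(path)
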