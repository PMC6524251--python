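"""Per-CpG association testing: OLS arm, exact signed-rank arm, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import dmrperm as dp
from dmrperm.ewas import (MassUnivariateOLS, PairedWilcoxon, _wilcoxon_exact_p,
                          inflation_lambda, nominal_loci, qq_points)
from dmrperm.qc import m_to_beta

from .oracles import ols_t_by_normal_equations, wilcoxon_two_sided_by_enumeration


def _design(n, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "exposure": (np.arange(n) < n // 3).astype(float),
        "age": rng.normal(48, 2, n),
        "sex": rng.integers(0, 2, n).astype(float),
    }, index=[f"s{i:02d}" for i in range(n)])


class TestRegression:
    def test_noiseless_effect_recovered_exactly(self):
        X = _design(30, seed=1)
        delta = -0.37
        m = 1.0 + delta * X["exposure"].to_numpy() + 0.02 * X["age"].to_numpy()
        Y = pd.DataFrame({"cg1": m, "cg2": m * 0.5}, index=X.index)
        est = MassUnivariateOLS().fit(X, Y)
        assert est.results_.loc["cg1", "effect"] == pytest.approx(delta, abs=1e-10)
        assert est.results_.loc["cg2", "effect"] == pytest.approx(delta / 2, abs=1e-10)

    def test_constant_exposure_rejected(self):
        X = _design(20, seed=2)
        X["exposure"] = 0.0
        Y = pd.DataFrame({"cg1": np.random.default_rng(0).normal(size=20)},
                         index=X.index)
        with pytest.raises(ValueError, match="no contrast"):
            MassUnivariateOLS().fit(X, Y)

    def test_rank_deficient_design_rejected(self):
        X = _design(20, seed=3)
        X["age2"] = X["age"]
        Y = pd.DataFrame({"cg1": np.zeros(20)}, index=X.index)
        with pytest.raises(ValueError, match="rank"):
            MassUnivariateOLS().fit(X, Y)

    def test_t_statistics_match_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        X = _design(40, seed=4)
        Y = pd.DataFrame(rng.normal(size=(40, 50)), index=X.index,
                         columns=[f"cg{i:02d}" for i in range(50)])
        est = MassUnivariateOLS().fit(X, Y)
        Xm = np.column_stack([np.ones(40), X.to_numpy(float)])
        for g, col in enumerate(Y.columns):
            t_oracle = ols_t_by_normal_equations(Xm, Y[col].to_numpy(), 1)
            assert est.t_[g] == pytest.approx(t_oracle, abs=1e-8)

    def test_p_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(8)
        X = _design(35, seed=5)
        Y = pd.DataFrame(rng.normal(size=(35, 5)), index=X.index,
                         columns=[f"cg{i}" for i in range(5)])
        est = MassUnivariateOLS().fit(X, Y)
        Xm = sm.add_constant(X.to_numpy(float))
        for g, col in enumerate(Y.columns):
            fit = sm.OLS(Y[col].to_numpy(), Xm).fit()
            assert est.results_["p"].iloc[g] == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_constant_probe_flagged(self):
        X = _design(20, seed=6)
        Y = pd.DataFrame({"flat": np.full(20, 1.5),
                          "ok": np.random.default_rng(1).normal(size=20)},
                         index=X.index)
        res = MassUnivariateOLS().fit(X, Y).results_
        assert res.loc["flat", "p"] == 1.0
        assert res.loc["flat", "effect"] == 0.0
        assert res.loc["flat", "flag"] == "constant"

    def test_direction_follows_delta_beta_sign(self):
        X = _design(30, seed=9)
        rng = np.random.default_rng(10)
        Y = pd.DataFrame(rng.normal(size=(30, 20)), index=X.index,
                         columns=[f"cg{i}" for i in range(20)])
        res = MassUnivariateOLS().fit(X, Y).results_
        assert (res.loc[res["delta_beta"] < 0, "direction"] == "hypo").all()
        assert (res.loc[res["delta_beta"] >= 0, "direction"] == "hyper").all()
        same_sign = np.sign(res["z"]) * np.sign(res["effect"])
        assert (same_sign[res["effect"] != 0] >= 0).all()


class TestPairedWilcoxon:
    def test_five_concordant_pairs_exact_floor(self):
        """All five differences in one direction: two-sided p = 2/2^5."""
        Xn = pd.DataFrame(np.zeros((5, 1)), columns=["cg1"])
        Xd = pd.DataFrame(np.full((5, 1), -1.0) + 0.01 * np.arange(5)[:, None],
                          columns=["cg1"])
        res = PairedWilcoxon().fit(Xn, Xd).results_
        assert res.loc["cg1", "p"] == pytest.approx(0.0625, abs=1e-12)
        assert res.loc["cg1", "direction"] == "hypo"

    def test_centered_statistic_gives_p_one(self):
        d = np.array([1.0, 2.0, -3.0])  # W+ = 3 = centre of the n=3 distribution
        Xn = pd.DataFrame(np.zeros((3, 1)), columns=["cg1"])
        Xd = pd.DataFrame(d[:, None], columns=["cg1"])
        res = PairedWilcoxon().fit(Xn, Xd).results_
        assert res.loc["cg1", "p"] == pytest.approx(1.0)

    def test_all_zero_differences_flagged(self):
        Xn = pd.DataFrame(np.ones((5, 1)), columns=["cg1"])
        res = PairedWilcoxon().fit(Xn, Xn.copy()).results_
        assert res.loc["cg1", "p"] == 1.0
        assert res.loc["cg1", "flag"] == "all_zero"

    @pytest.mark.parametrize("n", [4, 6, 8])
    def test_matches_full_sign_enumeration(self, n):
        rng = np.random.default_rng(100 + n)
        for _ in range(10):
            d = rng.normal(size=n)
            p_impl, _ = _wilcoxon_exact_p(d)
            assert p_impl == pytest.approx(wilcoxon_two_sided_by_enumeration(d),
                                           abs=1e-12)

    def test_ties_and_zeros_match_enumeration(self):
        cases = [
            np.array([1.0, 1.0, -1.0, 2.0, 3.0]),
            np.array([0.0, 1.0, -1.0, 2.0, 2.0, -2.0]),
            np.array([0.5, 0.5, 0.5, -0.5, 1.5]),
        ]
        for d in cases:
            p_impl, _ = _wilcoxon_exact_p(d)
            assert p_impl == pytest.approx(wilcoxon_two_sided_by_enumeration(d),
                                           abs=1e-12)

    def test_matches_scipy_exact_on_untied_data(self):
        rng = np.random.default_rng(77)
        for n in (5, 8, 12):
            d = rng.normal(size=n)
            p_impl, _ = _wilcoxon_exact_p(d)
            p_scipy = stats.wilcoxon(d, method="exact").pvalue
            assert p_impl == pytest.approx(p_scipy, abs=1e-12)

    def test_invariant_to_donor_level_shift(self):
        rng = np.random.default_rng(55)
        M = rng.normal(size=(5, 30))
        D = rng.normal(size=(5, 30))
        cols = [f"cg{i}" for i in range(30)]
        res1 = PairedWilcoxon().fit(pd.DataFrame(M, columns=cols),
                                    pd.DataFrame(M + D, columns=cols)).results_
        shift = rng.normal(size=(5, 1)) * 3.0
        res2 = PairedWilcoxon().fit(pd.DataFrame(M + shift, columns=cols),
                                    pd.DataFrame(M + D + shift, columns=cols)).results_
        np.testing.assert_allclose(res1["p"].to_numpy(), res2["p"].to_numpy(),
                                   atol=1e-12)

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(66)
        d = rng.normal(0.5, 1.0, size=40)
        p_impl, _ = _wilcoxon_exact_p(d)
        p_scipy = stats.wilcoxon(d, correction=True, method="approx").pvalue
        assert p_impl == pytest.approx(p_scipy, rel=1e-6)

    def test_effect_is_median_difference(self):
        Xn = pd.DataFrame(np.zeros((5, 1)), columns=["cg1"])
        d = np.array([-1.0, -2.0, -3.0, -4.0, -5.0])
        Xd = pd.DataFrame(d[:, None], columns=["cg1"])
        res = PairedWilcoxon().fit(Xn, Xd).results_
        assert res.loc["cg1", "effect"] == pytest.approx(-3.0)
        db = (m_to_beta(d) - m_to_beta(np.zeros(5))).mean()
        assert res.loc["cg1", "delta_beta"] == pytest.approx(db, abs=1e-12)

    def test_mismatched_pairing_rejected(self):
        Xn = pd.DataFrame(np.zeros((5, 2)), columns=["a", "b"])
        Xd = pd.DataFrame(np.zeros((5, 2)), columns=["a", "c"])
        with pytest.raises(ValueError):
            PairedWilcoxon().fit(Xn, Xd)


class TestDiagnostics:
    def test_nominal_loci_extremes(self, dense_map):
        from .conftest import make_assoc
        assoc = make_assoc(dense_map, np.linspace(-3, 3, 12))
        assert len(nominal_loci(assoc, alpha=1.0)) == len(assoc)
        assert len(nominal_loci(assoc, alpha=1e-12)) == 0
        sel = nominal_loci(assoc, alpha=0.05)
        assert (sel["p"] < 0.05).all()
        assert "direction" in sel.columns

    def test_lambda_is_one_on_uniform_grid(self):
        p = (np.arange(1, 1002) - 0.5) / 1001
        assoc = pd.DataFrame({"p": p})
        assert inflation_lambda(assoc) == pytest.approx(1.0, abs=1e-9)

    def test_lambda_increases_when_p_halved(self):
        p = (np.arange(1, 1002) - 0.5) / 1001
        lam0 = inflation_lambda(pd.DataFrame({"p": p}))
        lam1 = inflation_lambda(pd.DataFrame({"p": p / 2}))
        assert lam1 > lam0

    def test_qq_points_ordered_and_calibrated(self):
        p = (np.arange(1, 201) - 0.5) / 200
        pts = qq_points(pd.DataFrame({"p": p}))
        np.testing.assert_allclose(pts["expected"].to_numpy(),
                                   pts["observed"].to_numpy(), atol=1e-12)
        assert (np.diff(pts["expected"]) <= 0).all() or \
            (np.diff(pts["expected"]) >= 0).all()
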