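"""Factorability diagnostics, correlation PCA and the MDS selection chain."""

import numpy as np
import pandas as pd
import pytest
from sklearn.decomposition import PCA as SkPCA

from soilqualkit.sqi import (
    PCAModel,
    assign_groups,
    bartlett,
    bartlett_from_corr,
    kmo,
    kmo_from_corr,
    norm_values,
    prune_by_correlation,
    run_pca,
    select_high_norm,
    standardize,
)


def _random_table(n, p, seed, corr=0.0):
    rng = np.random.default_rng(seed)
    shared = rng.standard_normal((n, 1))
    X = np.sqrt(corr) * shared + np.sqrt(1 - corr) * rng.standard_normal((n, p))
    return pd.DataFrame(X, columns=[f"v{i}" for i in range(p)])


class TestStandardize:
    def test_three_point_column(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 9.0]})
        z = standardize(df)
        np.testing.assert_allclose(z["a"], [-1, 0, 1], atol=1e-12)
        assert abs(z.mean()).max() <= 1e-12
        np.testing.assert_allclose(z.std(ddof=1), 1.0, atol=1e-12)

    def test_constant_column_named(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="flat"):
            standardize(df)

    def test_needs_three_samples(self):
        with pytest.raises(ValueError, match="3 samples"):
            standardize(pd.DataFrame({"a": [1.0, 2.0]}))


def _partial_corr_by_regression(X, i, j):
    """Independent oracle: partial correlation of columns i, j given the rest,
    via least-squares residuals."""
    others = [k for k in range(X.shape[1]) if k not in (i, j)]
    Z = np.column_stack([np.ones(len(X)), X[:, others]])
    ri = X[:, i] - Z @ np.linalg.lstsq(Z, X[:, i], rcond=None)[0]
    rj = X[:, j] - Z @ np.linalg.lstsq(Z, X[:, j], rcond=None)[0]
    return np.corrcoef(ri, rj)[0, 1]


class TestKMO:
    @pytest.mark.parametrize("r", [0.3, -0.7, 0.95])
    def test_two_variables_always_half(self, r):
        # with p = 2 the partial correlation equals the correlation
        R = np.array([[1.0, r], [r, 1.0]])
        assert kmo_from_corr(R) == pytest.approx(0.5)

    def test_equicorrelated_three_variables(self):
        # partial corr of an equicorrelated triple is r/(1+r) = 1/3 at r=0.5,
        # so KMO = 6*(0.25) / (6*0.25 + 6*(1/9)) = 9/13
        R = np.full((3, 3), 0.5)
        np.fill_diagonal(R, 1.0)
        assert kmo_from_corr(R) == pytest.approx(9 / 13, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_regression_residual_oracle(self, seed):
        """KMO recomputed from regression-residual partial correlations."""
        df = _random_table(80, 5, seed, corr=0.4)
        X = df.to_numpy()
        R = np.corrcoef(X, rowvar=False)
        r2 = q2 = 0.0
        for i in range(5):
            for j in range(5):
                if i != j:
                    r2 += R[i, j] ** 2
                    q2 += _partial_corr_by_regression(X, i, j) ** 2
        assert kmo(df) == pytest.approx(r2 / (r2 + q2), abs=1e-10)
        assert 0.0 <= kmo(df) <= 1.0

    def test_singular_matrix_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0]})
        df["b"] = 2 * df["a"]
        df["c"] = [0.3, 1.2, 0.8, 0.1]
        with pytest.raises(ValueError, match="singular"):
            kmo(df)


class TestBartlett:
    def test_identity_correlation(self):
        chi2, df, p = bartlett_from_corr(np.eye(4), n=30)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 6
        assert p == pytest.approx(1.0)

    def test_direct_formula_two_variables(self):
        # chi2 = -(30 - 1 - (2*2+5)/6) ln(1 - 0.81), df = 1
        R = np.array([[1.0, 0.9], [0.9, 1.0]])
        chi2, df, p = bartlett_from_corr(R, n=30)
        assert chi2 == pytest.approx(-(30 - 1 - 9 / 6) * np.log(0.19))
        assert df == 1
        assert p < 0.01

    @pytest.mark.parametrize("p_vars", [3, 6, 10])
    def test_df_grows_as_p_choose_2(self, p_vars):
        df_table = _random_table(40, p_vars, 3, corr=0.3)
        _, df, _ = bartlett(df_table)
        assert df == p_vars * (p_vars - 1) // 2

    def test_warns_when_n_not_larger_than_p(self):
        df_table = _random_table(5, 6, 0)
        with pytest.warns(UserWarning, match="unreliable"):
            bartlett(df_table)


class TestRunPCA:
    def test_rank_one_pair(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 5.0]})
        df["b"] = 3 * df["a"] - 1  # perfectly correlated
        model = run_pca(standardize(df))
        assert model.n_components == 1
        np.testing.assert_allclose(model.eigenvalues, [2.0], atol=1e-12)
        np.testing.assert_allclose(np.abs(model.loadings.to_numpy().ravel()), 1.0,
                                   atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 5])
    def test_matches_sklearn_decomposition(self, seed):
        """Dual route: eigenvalues/loadings from the correlation matrix agree
        with sklearn's PCA on the standardized data (covariance of z-scores
        equals the correlation matrix)."""
        df = _random_table(60, 6, seed, corr=0.5)
        Z = standardize(df)
        model = run_pca(Z)
        sk = SkPCA().fit(Z.to_numpy())
        np.testing.assert_allclose(
            model.eigenvalues_full, sk.explained_variance_, atol=1e-8
        )
        for j in range(model.n_components):
            ours = model.loadings.iloc[:, j].to_numpy()
            theirs = sk.components_[j] * np.sqrt(sk.explained_variance_[j])
            assert np.allclose(ours, theirs, atol=1e-8) or np.allclose(
                ours, -theirs, atol=1e-8
            )

    def test_eigenvalue_conservation(self, study_table):
        model = run_pca(standardize(study_table.values))
        p = len(study_table.indicator_names)
        assert model.eigenvalues_full.sum() == pytest.approx(p, abs=1e-8)
        assert (model.eigenvalues_full / p * 100).sum() == pytest.approx(100.0, abs=1e-8)
        # retained spectrum is non-increasing and cumulative rates accumulate
        assert (np.diff(model.eigenvalues) <= 1e-12).all()
        np.testing.assert_allclose(
            model.cumulative_rate, np.cumsum(model.contribution_rate)
        )
        assert ((model.communalities >= 0) & (model.communalities <= 1 + 1e-12)).all()

    def test_sign_convention(self, study_table):
        model = run_pca(standardize(study_table.values))
        L = model.loadings.to_numpy()
        for j in range(L.shape[1]):
            assert L[np.argmax(np.abs(L[:, j])), j] > 0


class TestNormAndGrouping:
    def test_single_component_norm(self):
        model = PCAModel(
            indicators=["x"],
            eigenvalues=np.array([4.0]),
            loadings=pd.DataFrame({"PC1": [1.0]}, index=["x"]),
            n_total=1,
        )
        assert norm_values(model)["x"] == pytest.approx(2.0)

    def test_group_ties_break_to_lower_component(self):
        model = PCAModel(
            indicators=["x", "y"],
            eigenvalues=np.array([1.5, 1.5]),
            loadings=pd.DataFrame(
                {"PC1": [0.6, -0.7], "PC2": [-0.6, 0.2]}, index=["x", "y"]
            ),
            n_total=2,
        )
        groups = assign_groups(model)
        assert groups["x"] == 1  # exact tie -> lower index
        assert groups["y"] == 1

    def test_high_norm_band_inclusive(self):
        groups = pd.Series({"a": 1, "b": 1, "c": 1, "d": 2})
        norms = pd.Series({"a": 2.0, "b": 1.8, "c": 1.5, "d": 0.7})
        high = select_high_norm(groups, norms, band=0.10)
        assert high[1] == ["a", "b"]  # 1.8 == 0.9 * 2.0 retained (inclusive)
        assert high[2] == ["d"]  # singleton group keeps itself


class TestPrune:
    def test_greedy_pruning_and_audit(self):
        norms = pd.Series({"a": 2.0, "b": 1.9, "c": 1.85, "d": 0.7})
        groups = pd.Series({"a": 1, "b": 1, "c": 1, "d": 1})
        high = {1: ["a", "b", "c"]}
        facts = {
            frozenset(("a", "b")): (0.8, True),
            frozenset(("a", "c")): (0.1, False),
            frozenset(("b", "c")): (0.9, True),  # irrelevant: b already dropped
        }
        sel = prune_by_correlation(high, norms, facts, groups)
        assert sel.mds == ["a", "c"]
        assert "dropped-by-correlation" in sel.audit["b"]
        assert "below-10%-band" in sel.audit["d"]

    def test_no_significant_correlation_keeps_all(self):
        norms = pd.Series({"a": 1.0, "b": 0.95})
        high = {4: ["a", "b"]}
        facts = {frozenset(("a", "b")): (0.2, False)}
        sel = prune_by_correlation(high, norms, facts)
        assert sel.mds == ["a", "b"]

    def test_missing_fact_names_pair(self):
        norms = pd.Series({"a": 1.0, "b": 0.95})
        with pytest.raises(KeyError, match="a.*b|b.*a"):
            prune_by_correlation({1: ["a", "b"]}, norms, {})
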