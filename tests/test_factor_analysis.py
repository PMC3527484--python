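import numpy as np
import pytest

from traitnet.factor_analysis import (
    FactorAnalysisError,
    LoadingMatrix,
    MembershipTemplate,
    bartlett_sphericity,
    component_scores,
    forced_choice_template,
    kmo,
    pca_loadings,
    varimax_rotate,
)
from traitnet.scale_data import ScoreMatrix


def _scores(X, variables=None):
    X = np.asarray(X, dtype=float)
    variables = variables or [f"v{i}" for i in range(X.shape[1])]
    return ScoreMatrix([f"s{i}" for i in range(X.shape[0])], variables, X)


def _lm(L, variables=None):
    L = np.asarray(L, dtype=float)
    variables = variables or [f"v{i}" for i in range(L.shape[0])]
    ev = np.sort((L**2).sum(axis=0))[::-1]
    return LoadingMatrix(tuple(variables), L, ev, L.shape[0], rotated=True)


class TestPCA:
    def test_perfectly_correlated_pair_has_eigenvalues_two_and_zero(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        lm = pca_loadings(_scores(np.column_stack([x, 2 * x + 1])), 2)
        assert lm.eigenvalues == pytest.approx([2.0, 0.0], abs=1e-10)

    def test_trace_conservation(self):
        rng = np.random.default_rng(1)
        scores = _scores(rng.standard_normal((40, 6)))
        lm = pca_loadings(scores, 6)
        assert lm.eigenvalues.sum() == pytest.approx(6.0)
        assert lm.total_pct_variance == pytest.approx(100.0)

    def test_constant_column_rejected_by_name(self):
        X = np.ones((10, 3))
        X[:, 0] = np.arange(10)
        X[:, 2] = np.arange(10) ** 2
        with pytest.raises(FactorAnalysisError, match="v1"):
            pca_loadings(_scores(X), 2)

    def test_kaiser_near_boundary_flagged(self):
        rng = np.random.default_rng(2)
        # independent columns: all eigenvalues hover around 1
        scores = _scores(rng.standard_normal((500, 5)))
        with pytest.warns(UserWarning, match="Kaiser"):
            pca_loadings(scores, "kaiser")

    def test_planted_structure_yields_marked_eigenvalue_gap(self, small_planted):
        matrix, scale, _ = small_planted
        lm = pca_loadings(matrix.to_score_matrix(), matrix.n_variables)
        n_factors = len(scale.factors)
        assert np.all(lm.eigenvalues[:n_factors] > 1.5)
        assert np.all(lm.eigenvalues[n_factors:] < 1.5)

    def test_loading_sign_convention(self):
        rng = np.random.default_rng(3)
        lm = pca_loadings(_scores(rng.standard_normal((60, 4))), 3)
        for k in range(lm.n_components):
            col = lm.loadings[:, k]
            assert col[np.abs(col).argmax()] > 0


def _varimax_criterion(L):
    # variance of squared loadings within each column, summed
    sq = L**2
    return float(((sq - sq.mean(axis=0)) ** 2).sum())


class TestVarimax:
    def test_preserves_communalities(self, small_planted):
        matrix, scale, _ = small_planted
        lm = pca_loadings(matrix.to_score_matrix(), len(scale.factors))
        rot = varimax_rotate(lm)
        assert np.allclose(rot.communalities, lm.communalities, atol=1e-8)

    def test_simple_structure_is_fixed_point(self):
        L = np.array([[0.9, 0.0], [0.8, 0.0], [0.0, 0.85], [0.0, 0.75]])
        rot = varimax_rotate(_lm(L))
        # equal up to column order/sign, which the conventions normalize away
        assert np.allclose(np.sort(np.abs(rot.loadings), axis=None),
                           np.sort(np.abs(L), axis=None), atol=1e-6)

    def test_criterion_does_not_decrease(self):
        rng = np.random.default_rng(4)
        L = rng.uniform(-1, 1, size=(12, 3))
        rot = varimax_rotate(_lm(L), normalize=False)
        assert _varimax_criterion(rot.loadings) >= _varimax_criterion(L) - 1e-10

    def test_single_component_noop_with_warning(self):
        lm = _lm(np.array([[0.5], [0.6]]))
        with pytest.warns(UserWarning, match="single component"):
            out = varimax_rotate(lm)
        assert out is lm


class TestForcedChoice:
    def test_cross_loading_resolves_to_larger_absolute_loading(self):
        # a variable loading .592 on one factor and -.570 on another belongs
        # to the first: |.592| > |.570|
        L = np.zeros((5, 4))
        L[0, 0], L[0, 3] = 0.592, -0.570
        for i in range(1, 5):
            L[i, i % 4] = 0.8
        t = forced_choice_template(_lm(L, ["n2", "w", "x", "y", "z"]))
        assert t.assignment["n2"] == "F1"

    def test_cross_loading_can_prefer_later_factor(self):
        # .502 vs .527 on a later factor: the later factor wins
        L = np.zeros((7, 6))
        L[0, 2], L[0, 5] = 0.502, 0.527
        for i in range(1, 7):
            L[i, i % 6] = 0.9
        t = forced_choice_template(_lm(L, ["o4", "u", "v", "w", "x", "y", "z"]))
        assert t.assignment["o4"] == "F6"

    def test_covers_all_variables_even_below_cutoff(self):
        L = np.array([[0.2, 0.1], [0.9, 0.0], [0.0, 0.8]])
        t = forced_choice_template(_lm(L), cutoff=0.40)
        assert set(t.variables) == {"v0", "v1", "v2"}
        assert t.below_cutoff == {"v0"}
        assert t.assignment["v0"] == "F1"

    def test_exact_tie_breaks_to_lowest_factor_with_warning(self):
        L = np.array([[0.5, -0.5], [0.9, 0.0], [0.0, 0.8]])
        with pytest.warns(UserWarning, match="tie"):
            t = forced_choice_template(_lm(L))
        assert t.assignment["v0"] == "F1"

    def test_recovers_planted_membership(self, small_planted):
        matrix, scale, truth = small_planted
        lm = varimax_rotate(pca_loadings(matrix.to_score_matrix(), len(scale.factors)))
        t = forced_choice_template(lm)
        # template factor labels are arbitrary; compare the induced partition
        detected = {frozenset(t.members(f)) for f in t.factors}
        planted = {truth.factor_members(f) for f in scale.factors}
        assert detected == planted


class TestComponentScores:
    def test_mean_of_members(self):
        scores = _scores([[1, 3], [2, 4], [0, 0]], ["a", "b"])
        t = MembershipTemplate.from_mapping({"a": "F1", "b": "F1"})
        out = component_scores(scores, t)
        assert out.variables == ("F1",)
        assert out.scores[:, 0] == pytest.approx([2.0, 3.0, 0.0])

    def test_single_member_factor_copies_column(self):
        scores = _scores([[1, 3], [2, 4], [0, 0]], ["a", "b"])
        t = MembershipTemplate.from_mapping({"a": "F1", "b": "F2"})
        out = component_scores(scores, t)
        assert np.array_equal(out.column("F1"), scores.column("a"))


class TestAdequacy:
    def test_kmo_matches_closed_form_oracle(self):
        # 3 variables, all pairwise r = 0.7. Independent oracle: partial
        # correlation controlling the third variable is
        # (r - r^2) / (1 - r^2) = 0.21/0.51; KMO = 3 r^2 / (3 r^2 + 3 q^2).
        r = 0.7
        q = (r - r * r) / (1 - r * r)
        expected = (3 * 2 * r**2) / (3 * 2 * r**2 + 3 * 2 * q**2)
        R = np.full((3, 3), r)
        np.fill_diagonal(R, 1.0)
        assert kmo(R) == pytest.approx(expected)
        assert expected == pytest.approx(0.74293, abs=1e-5)

    def test_kmo_near_half_for_near_identity(self):
        R = np.full((4, 4), 0.01)
        np.fill_diagonal(R, 1.0)
        assert kmo(R) == pytest.approx(0.5, abs=0.02)

    def test_singular_matrix_rejected(self):
        R = np.ones((3, 3))  # perfect multicollinearity
        with pytest.raises(FactorAnalysisError, match="singular"):
            kmo(R)

    def test_bartlett_identity_matrix(self):
        chi2, df, p = bartlett_sphericity(np.eye(5), 100)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 10
        assert p == pytest.approx(1.0)

    def test_bartlett_df_formula(self):
        _, df30, _ = bartlett_sphericity(np.eye(30), 434)
        _, df240, _ = bartlett_sphericity(np.eye(240), 434)
        assert (df30, df240) == (435, 28680)

    def test_bartlett_detects_strong_correlation(self):
        R = np.full((6, 6), 0.5)
        np.fill_diagonal(R, 1.0)
        chi2, df, p = bartlett_sphericity(R, 200)
        assert chi2 > 0 and p < 1e-10
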