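"""Dichotomization, NIPALS PCA, OPLS-DA, marker selection, DBE contrasts."""
import numpy as np
import pytest

from aeronts import multivariate as mv
from aeronts.model import SampleRecord


def _sample(temp=10.0, weights=None):
    return SampleRecord("s", "2021-01-01", "2021-01-04", temp, False,
                        cluster_weights=weights or {})


class TestDichotomize:
    @pytest.mark.parametrize("temp,expected", [(16.0, 1.0), (14.9, -1.0),
                                               (15.1, 1.0)])
    def test_temperature_rule(self, temp, expected):
        assert mv.dichotomize([_sample(temp=temp)], "temperature")[0] == expected

    def test_boundary_goes_low_with_warning(self):
        with pytest.warns(UserWarning, match="15"):
            y = mv.dichotomize([_sample(temp=15.0)], "temperature")
        assert y[0] == -1.0

    def test_maritime_rule(self):
        y = mv.dichotomize([_sample(weights={1: 0.4, 2: 0.3, 3: 0.3}),
                            _sample(weights={3: 0.5, 5: 0.4, 1: 0.1})], "maritime")
        assert list(y) == [1.0, -1.0]

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            mv.dichotomize([_sample()], "altitude")


class TestNipalsPca:
    def test_rank_one_matrix_single_component(self):
        X = np.outer([1, 2, 3, 4], [0.5, 1.0, -0.2])
        res = mv.nipals_pca(X, n_components=2)
        assert res.explained[0] == pytest.approx(1.0)

    def test_scores_orthogonal(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(15, 8))
        res = mv.nipals_pca(X, n_components=3)
        t = res.scores
        for i in range(3):
            for j in range(i + 1, 3):
                cos = abs(t[:, i] @ t[:, j]) / (
                    np.linalg.norm(t[:, i]) * np.linalg.norm(t[:, j]))
                assert cos < 1e-8

    def test_agrees_with_svd_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 20))
        res = mv.nipals_pca(X, n_components=3)
        Xc = X - X.mean(axis=0)
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        for k in range(3):
            t_svd = U[:, k] * S[k]
            sign = np.sign(t_svd @ res.scores[:, k])
            assert np.allclose(res.scores[:, k], sign * t_svd, atol=1e-6)
            assert res.explained[k] == pytest.approx(S[k] ** 2 / (S ** 2).sum(),
                                                     abs=1e-8)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            mv.nipals_pca(np.ones((5, 4)))


def _toy_problem(seed=0, n=40, p=60):
    rng = np.random.default_rng(seed)
    y = np.array([1.0] * (n // 2) + [-1.0] * (n // 2))
    X = rng.normal(size=(n, p))
    X[:, 0] += y * 2
    return X, y


class TestOplsda:
    def test_duplicated_class_variable_attains_maximal_pcorr(self):
        # the class vector planted as a variable is maximally correlated
        # with the predictive scores (exactly 1 only when t is proportional
        # to y, so near-1 is asserted)
        X, y = _toy_problem()
        X = np.column_stack([X, y])
        m = mv.oplsda(X, y, n_ortho=1, cv_folds=5, seed=0)
        assert np.abs(m.pcorr).argmax() == X.shape[1] - 1
        assert abs(m.pcorr[-1]) == pytest.approx(1.0, abs=0.05)

    def test_orthogonal_scores_have_no_class_covariance(self):
        X, y = _toy_problem(3)
        m = mv.oplsda(X, y, n_ortho=2, cv_folds=5, seed=1)
        yc = y - y.mean()
        assert np.abs(m.t_ortho.T @ yc).max() < 1e-8

    def test_vip_mean_square_identity(self):
        X, y = _toy_problem(4)
        m = mv.oplsda(X, y, cv_folds=5, seed=2)
        assert (m.vip ** 2).mean() == pytest.approx(1.0, abs=1e-8)

    def test_q2_not_above_r2(self):
        for seed in (0, 1, 2):
            X, y = _toy_problem(seed)
            m = mv.oplsda(X, y, cv_folds=5, seed=seed)
            assert m.q2 <= m.r2 + 1e-12

    def test_label_swap_flips_pcorr_sign(self):
        X, y = _toy_problem(5)
        m1 = mv.oplsda(X, y, cv_folds=5, seed=3)
        m2 = mv.oplsda(X, -y, cv_folds=5, seed=3)
        assert np.allclose(m1.pcorr, -m2.pcorr, atol=1e-8)

    def test_single_class_rejected(self):
        X, _ = _toy_problem()
        with pytest.raises(ValueError):
            mv.oplsda(X, np.ones(X.shape[0]), cv_folds=5, seed=0)

    def test_permuted_labels_yield_nonpositive_median_q2(self):
        """Cross-validation sanity: pure-noise matrices with permuted class
        labels should not appear predictive."""
        rng = np.random.default_rng(9)
        n, p = 24, 40
        X = rng.normal(size=(n, p))
        y = np.array([1.0] * 12 + [-1.0] * 12)
        q2s = []
        for i in range(30):
            yp = rng.permutation(y)
            if np.unique(yp).size < 2:
                continue
            q2s.append(mv.oplsda(X, yp, cv_folds=4, seed=i).q2)
        assert np.median(q2s) <= 0

    def test_planted_variables_dominate_vip(self):
        """>= 18 of the 20 planted discriminating variables (effect 2 sigma,
        n = 80, p = 2000) appear in the top-20 VIP list."""
        from aeronts.synthetic import planted_contrast_matrix
        X, y, planted = planted_contrast_matrix(80, 2000, 20, 2.0, 1.0, seed=5)
        m = mv.oplsda(X, y, n_ortho=1, cv_folds=7, seed=5)
        top20 = set(np.argsort(-m.vip)[:20])
        assert len(top20 & set(planted)) >= 18


class TestMarkers:
    def _model(self, vip, pcorr):
        m = mv.OplsModel(t_pred=np.zeros(2), p_pred=np.zeros(2),
                         w_pred=np.zeros(2), q=0.0, t_ortho=np.zeros((2, 0)),
                         p_ortho=np.zeros((2, 0)), w_ortho=np.zeros((2, 0)),
                         r2=0, q2=0, vip=np.array(vip), pcorr=np.array(pcorr))
        return m

    def test_selection_rules_and_strict_boundaries(self):
        m = self._model([1.6, 1.6, 1.5, 2.0, 1.7],
                        [0.6, -0.4, 0.9, -0.8, 0.5])
        pos, neg = mv.select_markers(m)
        assert list(pos) == [0]          # vip 1.6, pcorr 0.6
        assert list(neg) == [3]          # vip 2.0, pcorr -0.8
        # vip exactly 1.5 (idx 2) and |pcorr| exactly 0.5 (idx 4) excluded


class TestContrast:
    def test_identical_distributions(self):
        s = mv.contrast_descriptors([4.0, 6.0, 5.0], [4.0, 6.0, 5.0])
        assert s.mean_dbe_a == s.mean_dbe_b
        assert s.p_value == pytest.approx(1.0)

    def test_mean_difference(self):
        s = mv.contrast_descriptors([4.0, 6.0], [2.0, 4.0])
        assert s.mean_dbe_a == 5.0 and s.mean_dbe_b == 3.0

    def test_planted_shift_recovered(self):
        rng = np.random.default_rng(7)
        a = list(np.clip(rng.normal(5.5, 1.5, 200), 0, None))
        b = list(np.clip(rng.normal(3.5, 1.5, 200), 0, None))
        s = mv.contrast_descriptors(a, b)
        assert s.mean_dbe_a - s.mean_dbe_b == pytest.approx(2.0, abs=0.3)
        assert s.p_value < 1e-6

    def test_empty_class_noted(self):
        s = mv.contrast_descriptors([4.0], [])
        assert s.p_value is None
        assert s.notes
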