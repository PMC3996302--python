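import numpy as np
import pytest

from blsom import som
from blsom.som import (
    Assignment,
    TrainConfig,
    assign,
    batch_update,
    fit_pca,
    map_queries,
    pca_init,
    size_map,
    train,
)


def gaussian_cloud(n, d, seed, scales=None):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    if scales is not None:
        X *= np.asarray(scales)
    return X


class TestFitPca:
    def test_projection_sd_equals_sigma(self):
        X = gaussian_cloud(2000, 5, 0, scales=[3, 2, 1, 0.5, 0.1])
        frame = fit_pca(X)
        proj1 = (X - frame.x_av) @ frame.b1
        assert proj1.std(ddof=1) == pytest.approx(frame.sigma1, rel=1e-10)
        assert frame.sigma1 >= frame.sigma2 >= 0

    def test_isotropic_cloud_has_similar_sigmas(self):
        frame = fit_pca(gaussian_cloud(10_000, 4, 1))
        assert frame.sigma2 / frame.sigma1 > 0.95

    def test_axes_are_orthonormal(self):
        frame = fit_pca(gaussian_cloud(200, 6, 2, scales=[4, 2, 1, 1, 1, 1]))
        assert np.linalg.norm(frame.b1) == pytest.approx(1.0)
        assert np.linalg.norm(frame.b2) == pytest.approx(1.0)
        assert frame.b1 @ frame.b2 == pytest.approx(0.0, abs=1e-10)

    def test_sign_convention_deterministic(self):
        X = gaussian_cloud(500, 3, 3, scales=[5, 2, 1])
        f1, f2 = fit_pca(X), fit_pca(-X)
        assert f1.b1[np.argmax(np.abs(f1.b1))] > 0
        assert f2.b1[np.argmax(np.abs(f2.b1))] > 0

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            fit_pca(np.zeros((2, 4)))

    def test_rank1_data_collapses_second_axis(self):
        t = np.linspace(0, 1, 50)
        X = np.outer(t, [1.0, 2.0])
        frame = fit_pca(X)
        assert frame.sigma2 == 0.0
        with pytest.warns(UserWarning):
            _, J = size_map(40, frame)
        assert J == 1

    def test_constant_data_rejected(self):
        with pytest.raises(ValueError):
            fit_pca(np.ones((10, 4)))


class FakeFrame:
    def __init__(self, sigma1, sigma2, d=4):
        self.sigma1, self.sigma2 = sigma1, sigma2
        self.x_av = np.zeros(d)
        self.b1 = np.eye(d)[0]
        self.b2 = np.eye(d)[1]


class TestSizeMap:
    def test_stated_formula_example(self):
        I, J = size_map(1000, FakeFrame(2.0, 1.0))  # rho = 0.5
        assert (I, J) == (22, 12)  # strictly-greater rule turns 11.0 into 12

    def test_per_neuron_target_met(self):
        I, J = size_map(1000, FakeFrame(2.0, 1.0))
        assert round(1000 / (I * J)) == 4

    def test_square_when_isotropic(self):
        I, J = size_map(16, FakeFrame(1.0, 1.0), per_neuron=4.0)
        assert abs(I - J) <= 1

    def test_degenerate_second_axis(self):
        with pytest.warns(UserWarning):
            I, J = size_map(100, FakeFrame(1.0, 0.0))
        assert J == 1


class TestPcaInit:
    def test_center_is_mean_when_indices_integral(self):
        frame = FakeFrame(2.0, 1.0)
        W = pca_init(frame, 10, 6)
        np.testing.assert_allclose(W[5, 3], frame.x_av, atol=1e-14)

    def test_first_axis_span_is_five_sigma(self):
        frame = FakeFrame(3.0, 1.0)
        I = 20
        W = pca_init(frame, I, 5)
        step = np.linalg.norm(W[1, 0] - W[0, 0])
        assert step * I / frame.sigma1 == pytest.approx(5.0)

    def test_planarity(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(50, 6)) * [3, 2, 1, 1, 1, 1]
        frame = fit_pca(X)
        W = pca_init(frame, 7, 4)
        resid = W - frame.x_av
        resid = resid - np.tensordot(resid, frame.b1, axes=(-1, 0))[..., None] * frame.b1
        resid = resid - np.tensordot(resid, frame.b2, axes=(-1, 0))[..., None] * frame.b2
        assert np.abs(resid).max() < 1e-12


def brute_force_assign(X, weights):
    """O(N * I * J) scalar-loop nearest-weight oracle with row-major tie-break."""
    I, J, d = weights.shape
    out = []
    for x in X:
        best, best_d = None, None
        for i in range(I):
            for j in range(J):
                dist = sum((x[t] - weights[i, j, t]) ** 2 for t in range(d))
                if best_d is None or dist < best_d:
                    best, best_d = (i, j), dist
        out.append(best)
    return out


class TestAssign:
    def test_exact_weight_match(self):
        rng = np.random.default_rng(0)
        W = rng.normal(size=(4, 3, 5))
        a = assign(W[2, 1][None, :], W)
        assert tuple(a.coords[0]) == (2, 1)
        assert a.distances[0] == 0.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        W = rng.normal(size=(5, 4, 3))
        X = rng.normal(size=(20, 3))
        a = assign(X, W)
        assert [tuple(c) for c in a.coords] == brute_force_assign(X, W)

    def test_tie_breaks_row_major(self):
        W = np.zeros((2, 2, 2))
        W[0, 0] = W[0, 1] = [1.0, 0.0]
        W[1, 0] = W[1, 1] = [5.0, 5.0]
        a = assign(np.array([[0.0, 0.0]]), W)  # (0,0) and (0,1) exactly tied
        assert tuple(a.coords[0]) == (0, 0)


def oracle_batch_update(weights, X, bmu_coords, alpha, beta, kernel="box"):
    """Slot-by-slot scalar reimplementation of the neighborhood-mean update."""
    I, J, d = weights.shape
    sigma = max(0.5, beta / 2.0)
    new = weights.copy()
    for i in range(I):
        for j in range(J):
            num, den = np.zeros(d), 0.0
            for n, (bi, bj) in enumerate(bmu_coords):
                di, dj = bi - i, bj - j
                if max(abs(di), abs(dj)) > beta:
                    continue
                w = 1.0 if kernel == "box" else np.exp(-(di**2 + dj**2) / (2 * sigma**2))
                num += w * X[n]
                den += w
            if den > 0:
                new[i, j] = weights[i, j] + alpha * (num / den - weights[i, j])
    return new


class TestBatchUpdate:
    def test_full_contraction_fixed_point(self):
        v = np.array([1.0, -2.0, 0.5])
        X = np.tile(v, (6, 1))
        W = np.random.default_rng(2).normal(size=(3, 3, 3))
        a = assign(X, W)
        new = batch_update(W, X, a, alpha=1.0, beta=10)
        np.testing.assert_allclose(new, np.broadcast_to(v, new.shape))

    def test_alpha_zero_is_identity(self):
        rng = np.random.default_rng(3)
        W = rng.normal(size=(3, 3, 2))
        X = rng.normal(size=(5, 2))
        new = batch_update(W, X, assign(X, W), alpha=0.0, beta=1)
        np.testing.assert_array_equal(new, W)

    @pytest.mark.parametrize("kernel", ["box", "gaussian"])
    @pytest.mark.parametrize("beta", [0, 1, 2])
    def test_matches_scalar_oracle(self, beta, kernel):
        rng = np.random.default_rng(4)
        W = rng.normal(size=(3, 3, 4))
        X = rng.normal(size=(5, 4))
        a = assign(X, W)
        new = batch_update(W, X, a, alpha=0.5, beta=beta, kernel=kernel)
        oracle = oracle_batch_update(W, X, [tuple(c) for c in a.coords], 0.5, beta, kernel)
        np.testing.assert_allclose(new, oracle, atol=1e-12)

    def test_empty_neighborhood_unchanged(self):
        W = np.zeros((3, 1, 2))
        W[:, 0, 0] = [0.0, 10.0, 20.0]
        X = np.array([[0.0, 0.0]])
        a = assign(X, W)
        new = batch_update(W, X, a, alpha=1.0, beta=0)
        np.testing.assert_array_equal(new[1:], W[1:])  # far points untouched


class TestTrain:
    def test_order_invariance_bitwise(self, panel_split):
        train_mat, _ = panel_split
        X = train_mat.matrix[:120]
        cfg = TrainConfig(epochs=30)
        m1, a1 = train(X, cfg)
        perm = np.random.default_rng(8).permutation(len(X))
        m2, a2 = train(X[perm], cfg)
        assert np.array_equal(m1.weights, m2.weights)
        assert np.array_equal(a1.bmu[perm], a2.bmu)

    def test_repeated_vector_collapses_to_one_lattice_point(self):
        # 18 exact copies of one vector (plus two distinct rows so the PCA
        # plane exists) all share a single best match, with vanishing error
        v = np.array([0.2, 0.4, 0.1, 0.3])
        X = np.vstack([np.tile(v, (18, 1)), [1.0, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 1.0]])
        m, a = train(X, TrainConfig(epochs=40), I=4, J=3)
        assert len(np.unique(a.bmu[:18])) == 1
        assert a.distances[:18].max() < 1e-6

    def test_quantization_error_settles(self, trained_map):
        m, _ = trained_map
        q = np.array(m.quantization_errors)
        diffs = np.diff(q[-10:])
        assert np.all(diffs <= 1e-9 * q[-10:-1])

    def test_nonempty_purity_on_divergent_panel(self, trained_map, panel_split):
        m, a = trained_map
        train_mat, _ = panel_split
        lattice = {}
        for b, cat in zip(a.bmu, train_mat.categories):
            lattice.setdefault(int(b), set()).add(cat)
        purity = np.mean([len(s) == 1 for s in lattice.values()])
        assert purity >= 0.95


class TestMapQueries:
    def test_training_rows_return_home(self, trained_map, panel_split):
        m, a = trained_map
        train_mat, _ = panel_split
        qa, preds = map_queries(m, train_mat)
        assert np.array_equal(qa.bmu, a.bmu)
        correct = np.mean([p == c for p, c in zip(preds, train_mat.categories)])
        assert correct >= 0.95

    def test_held_out_queries_classified(self, trained_map, panel_split):
        m, _ = trained_map
        _, query_mat = panel_split
        _, preds = map_queries(m, query_mat)
        acc = np.mean(
            [p == c for p, c in zip(preds, query_mat.categories) if p != "unassigned"]
        )
        assert acc >= 0.90

    def test_empty_lattice_point_is_unassigned(self):
        # hand-built 2x2 map: flat lattice id 3 received no training fragment
        weights = np.arange(8, dtype=float).reshape(2, 2, 2)
        frame = som.PcaFrame(
            x_av=np.zeros(2), b1=np.eye(2)[0], b2=np.eye(2)[1], sigma1=1.0, sigma2=1.0
        )
        m = som.SomMap(
            I=2, J=2, weights=weights, frame=frame,
            train_categories=["a", "a", "b"], train_bmus=np.array([0, 0, 1]),
        )
        _, preds = map_queries(m, weights[1, 1][None, :])
        assert preds[0] == "unassigned"

    def test_dimension_mismatch_rejected(self, trained_map):
        m, _ = trained_map
        with pytest.raises(ValueError):
            map_queries(m, np.zeros((2, 3)))


def test_save_load_roundtrip(tmp_path, trained_map):
    m, _ = trained_map
    m.save(tmp_path / "som")
    loaded = som.SomMap.load(tmp_path / "som")
    np.testing.assert_array_equal(loaded.weights, m.weights)
    assert loaded.I == m.I and loaded.J == m.J
    assert loaded.train_categories == m.train_categories
    np.testing.assert_array_equal(loaded.train_bmus, m.train_bmus)
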