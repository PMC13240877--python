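import numpy as np
import pytest
import scipy.sparse as sp

from sptraj.embedding import (Adam, EncoderConfig, LossWeights, dec_target,
                              encode_features, encode_graph_vgae,
                              finetune_with_clustering, init_params,
                              load_checkpoint, loss_and_grads, mask_expression,
                              normalized_propagation, pretrain,
                              save_checkpoint)
from sptraj.graph import SpatialGraph, build_alpha_adjacency
from sptraj.simulate import SimConfig, simulate


def _tiny_graph(n, edges):
    A = sp.lil_matrix((n, n))
    for i, j in edges:
        A[i, j] = A[j, i] = 1
    return SpatialGraph(A.tocsr(), radius_delta=1.0)


@pytest.fixture(scope="module")
def small_training():
    """Shared small training run (bifurcating, 120 cells)."""
    sim = simulate(SimConfig(n_cells=120, n_genes=48,
                             n_marker_genes_per_branch=5, seed=1))
    ds = sim.dataset
    from sptraj.graph import estimate_radius_delta

    G = build_alpha_adjacency(ds.coords, estimate_radius_delta(ds.coords))
    cfg = EncoderConfig(h=32, hf=8, hg=8, epochs_pretrain=60,
                        epochs_finetune=30, n_clusters=3, seed=2025)
    emb = pretrain(ds, G, cfg)
    return sim, ds, G, cfg, emb


class TestMasking:
    def test_mask_count(self):
        X = np.arange(8.0).reshape(4, 2)
        _, spec = mask_expression(X, 0.5, rng_seed=0)
        assert spec.mask_set.size == 2

    def test_same_seed_same_subset(self):
        X = np.random.default_rng(0).normal(size=(50, 4))
        _, s1 = mask_expression(X, 0.2, rng_seed=7)
        _, s2 = mask_expression(X, 0.2, rng_seed=7)
        np.testing.assert_array_equal(s1.mask_set, s2.mask_set)

    def test_unmasked_rows_bitwise_equal(self):
        X = np.random.default_rng(1).normal(size=(20, 5))
        Xp, spec = mask_expression(X, 0.3, rng_seed=0)
        keep = np.setdiff1d(np.arange(20), spec.mask_set)
        assert (Xp[keep] == X[keep]).all()
        assert not np.allclose(Xp[spec.mask_set], X[spec.mask_set])

    @pytest.mark.parametrize("frac", [0.001, 0.999])
    def test_degenerate_fraction_errors(self, frac):
        with pytest.raises(ValueError):
            mask_expression(np.ones((4, 2)), frac, rng_seed=0)


class TestFeatureEncoder:
    def test_zero_input_zero_output(self):
        params = init_params(3, 4, EncoderConfig(h=5, hf=2, hg=2))
        params["b1"][:] = 0
        params["b2"][:] = 0
        Zf = encode_features(np.zeros((3, 4)), params)
        assert (Zf == 0).all()

    def test_shape_and_nonnegativity(self):
        cfg = EncoderConfig(h=6, hf=3, hg=2)
        params = init_params(7, 10, cfg)
        Zf = encode_features(np.random.default_rng(0).normal(size=(7, 10)),
                             params)
        assert Zf.shape == (7, 3) and (Zf >= 0).all()

    def test_hand_computed_two_layer_forward(self):
        # 1 cell x 2 genes, hand-set 2x2 weights
        params = {"W1": np.array([[1.0, -1.0], [2.0, 0.5]]),
                  "b1": np.array([0.5, -0.25]),
                  "W2": np.array([[1.0, 2.0], [-1.0, 1.0]]),
                  "b2": np.array([0.0, -1.0])}
        x = np.array([[1.0, 2.0]])
        h1 = np.maximum(x @ params["W1"] + params["b1"], 0)   # [5.5, 0]
        expected = np.maximum(h1 @ params["W2"] + params["b2"], 0)
        np.testing.assert_allclose(encode_features(x, params), expected)
        np.testing.assert_allclose(expected, [[5.5, 10.0]])

    def test_nonfinite_input_errors(self):
        params = init_params(3, 4, EncoderConfig(h=5, hf=2, hg=2))
        with pytest.raises(ValueError, match="non-finite"):
            encode_features(np.full((3, 4), np.nan), params)

    def test_hf_must_be_small(self):
        with pytest.raises(ValueError, match="hf"):
            init_params(5, 4, EncoderConfig(h=5, hf=4, hg=2))


class TestGraphEncoder:
    def test_single_node_reduces_to_linear(self):
        g = _tiny_graph(1, [])
        params = init_params(1, 3, EncoderConfig(h=4, hf=2, hg=2))
        Zf = np.array([[0.3, 0.7]])
        mu, ls, Zg = encode_graph_vgae(Zf, g, params, sample=False)
        # A~ = [1], D~ = [1]: propagation is identity
        expected_mu = np.maximum(Zf @ params["W0"], 0) @ params["Wmu"]
        np.testing.assert_allclose(mu, expected_mu)
        np.testing.assert_array_equal(Zg, mu)

    def test_inference_mode_deterministic(self):
        g = _tiny_graph(4, [(0, 1), (1, 2), (2, 3)])
        params = init_params(4, 5, EncoderConfig(h=4, hf=3, hg=2))
        Zf = np.abs(np.random.default_rng(0).normal(size=(4, 3)))
        out1 = encode_graph_vgae(Zf, g, params, sample=False)[2]
        out2 = encode_graph_vgae(Zf, g, params, sample=False)[2]
        np.testing.assert_array_equal(out1, out2)

    def test_path_graph_hand_propagation(self):
        # 3-node path: D~ = diag(2,3,2); S = D^-1/2 (A+I) D^-1/2
        g = _tiny_graph(3, [(0, 1), (1, 2)])
        S = normalized_propagation(g.adjacency).todense()
        expected = np.array([
            [1 / 2, 1 / np.sqrt(6), 0],
            [1 / np.sqrt(6), 1 / 3, 1 / np.sqrt(6)],
            [0, 1 / np.sqrt(6), 1 / 2]])
        np.testing.assert_allclose(np.asarray(S), expected)

    def test_reparameterization_identity(self):
        g = _tiny_graph(3, [(0, 1), (1, 2)])
        params = init_params(3, 5, EncoderConfig(h=4, hf=3, hg=2))
        Zf = np.abs(np.random.default_rng(1).normal(size=(3, 3)))
        mu, ls, Zg0 = encode_graph_vgae(Zf, g, params, sample=True,
                                        eps=np.zeros((3, 2)))
        np.testing.assert_array_equal(Zg0, mu)
        eps = np.random.default_rng(2).normal(size=(3, 2))
        _, _, Zg = encode_graph_vgae(Zf, g, params, sample=True, eps=eps)
        np.testing.assert_allclose(Zg, mu + eps * np.exp(ls))


class TestGradients:
    """Analytic gradients vs central finite differences."""

    @pytest.mark.parametrize("stage", ["pretrain", "finetune"])
    def test_finite_difference(self, stage):
        rng = np.random.default_rng(0)
        n, m = 8, 5
        cfg = EncoderConfig(h=4, hf=3, hg=3, n_clusters=2)
        params = init_params(n, m, cfg)
        X = np.abs(rng.normal(size=(n, m)))
        g = _tiny_graph(n, [(i, i + 1) for i in range(n - 1)] + [(0, 4)])
        S = normalized_propagation(g.adjacency)
        At = np.asarray(g.adjacency.todense(), dtype=float)
        np.fill_diagonal(At, 1.0)
        pw = (n * n - At.sum()) / At.sum()
        eps_noise = rng.normal(size=(n, cfg.hg))
        w = LossWeights(lambda_rec=2.0, lambda_gcn=0.5, lambda_self=1.5,
                        lambda_cluster=0.7)
        kw = dict(use_mask=stage == "pretrain", sample=True)
        mask = np.array([1, 3])
        p_fixed = None
        if stage == "finetune":
            params["C"] = rng.normal(size=(2, cfg.hf + cfg.hg))
            # freeze the sharpened target so the objective is differentiable
            from sptraj.embedding import _student_q

            Zf = encode_features(X, params)
            _, _, Zg = encode_graph_vgae(Zf, g, params, sample=True,
                                         eps=eps_noise, S=S)
            q, _ = _student_q(np.concatenate([Zf, Zg], 1), params["C"])
            p_fixed = dec_target(q)

        def f(pr):
            t, _ = loss_and_grads(pr, X, mask, S, At, pw, w, eps_noise,
                                  stage=stage, cluster_p=p_fixed,
                                  centers=pr.get("C"), **kw)
            return t["total"]

        _, grads = loss_and_grads(params, X, mask, S, At, pw, w, eps_noise,
                                  stage=stage, cluster_p=p_fixed,
                                  centers=params.get("C"), **kw)
        h = 1e-6
        rngc = np.random.default_rng(42)
        for name in ("W1", "W2", "W0", "Wmu", "Wsg", "V1", "V2", "b1", "c2",
                     "T") + (("C",) if stage == "finetune" else ()):
            arr = params[name]
            for _ in range(3):
                idx = tuple(rngc.integers(0, s) for s in arr.shape)
                if name == "T" and idx[0] not in mask:
                    idx = (int(mask[0]),) + idx[1:]
                orig = arr[idx]
                arr[idx] = orig + h
                fp = f(params)
                arr[idx] = orig - h
                fm = f(params)
                arr[idx] = orig
                fd = (fp - fm) / (2 * h)
                an = grads[name][idx]
                assert an == pytest.approx(fd, rel=2e-4, abs=1e-8), \
                    f"{name}{idx}: analytic {an} vs fd {fd}"


class TestTraining:
    def test_pretrain_loss_decreases(self, small_training):
        _, _, _, _, emb = small_training
        first = emb.losses[0]["total"]
        last = emb.losses[-1]["total"]
        assert last < first

    def test_embedding_shapes_and_concat(self, small_training):
        _, ds, _, cfg, emb = small_training
        assert emb.Z.shape == (ds.n_cells, cfg.hf + cfg.hg)
        np.testing.assert_array_equal(
            emb.Z, np.concatenate([emb.Zf, emb.Zg], axis=1))
        assert (emb.Zf >= 0).all()

    def test_lambda_self_zero_reduces_objective(self):
        rng = np.random.default_rng(0)
        n, m = 6, 4
        cfg = EncoderConfig(h=3, hf=2, hg=2)
        params = init_params(n, m, cfg)
        X = np.abs(rng.normal(size=(n, m)))
        g = _tiny_graph(n, [(i, i + 1) for i in range(n - 1)])
        S = normalized_propagation(g.adjacency)
        At = np.asarray(g.adjacency.todense(), float)
        np.fill_diagonal(At, 1.0)
        pw = (n * n - At.sum()) / At.sum()
        eps = rng.normal(size=(n, 2))
        w0 = LossWeights(lambda_self=0.0)
        t, _ = loss_and_grads(params, X, np.array([0, 2]), S, At, pw, w0, eps,
                              stage="pretrain")
        assert t["total"] == pytest.approx(
            w0.lambda_rec * t["rec"] + w0.lambda_gcn * t["gcn"])

    def test_seeded_rerun_is_identical(self, small_training):
        sim, ds, G, cfg, emb = small_training
        emb2 = pretrain(ds, G, cfg)
        assert emb.losses[-1]["total"] == pytest.approx(
            emb2.losses[-1]["total"], abs=1e-6)
        np.testing.assert_allclose(emb.Z, emb2.Z, atol=1e-10)

    def test_finetune_removes_mask_adds_cluster(self, small_training):
        sim, ds, G, cfg, emb = small_training
        emb2 = finetune_with_clustering(emb, ds, G, cfg)
        ft = [rec for rec in emb2.losses if rec["stage"] == "finetune"]
        assert len(ft) == cfg.epochs_finetune
        assert all(rec["self"] == 0.0 for rec in ft)
        assert all(rec["cluster"] > 0.0 for rec in ft)
        assert emb2.Z.shape == emb.Z.shape

    def test_n_clusters_exceeding_n_errors(self, small_training):
        sim, ds, G, cfg, emb = small_training
        bad = EncoderConfig(**{**cfg.__dict__, "n_clusters": ds.n_cells + 1})
        with pytest.raises(ValueError, match="n_clusters"):
            finetune_with_clustering(emb, ds, G, bad)

    def test_checkpoint_roundtrip(self, small_training, tmp_path):
        _, _, _, cfg, emb = small_training
        path = str(tmp_path / "ckpt.npz")
        save_checkpoint(emb, path)
        params, cfg2 = load_checkpoint(path)
        assert cfg2.hf == cfg.hf and cfg2.seed == cfg.seed
        np.testing.assert_array_equal(params["W1"], emb.params["W1"])


def test_adam_moves_toward_minimum():
    params = {"x": np.array([5.0])}
    opt = Adam(params, lr=0.1)
    for _ in range(500):
        opt.step(params, {"x": 2 * params["x"]})   # d/dx x^2
    assert abs(params["x"][0]) < 1e-2
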