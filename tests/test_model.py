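"""Network components against independent straight-line and brute-force oracles."""

import numpy as np
import pytest
import scipy.sparse as sp

from cellformer import model as M
from cellformer.graph import CellGraph, normalize_adjacency


def _random_state(rng, n, d, heads, n_layers=1, seed=0):
    cfg = M.ModelConfig(d=d, n_heads=heads, n_layers=n_layers, seed=seed)
    params = M.init_params(cfg, d, 3)
    z = rng.normal(size=(n, d))
    return cfg, params, M.make_layer_state(z, params, cfg, 0)


def _brute_force_taylor(state, n):
    """Explicit double-sum of the linearised attention weights."""
    outs = []
    for qn, kn, v in zip(state.Q_hat, state.K_hat, state.V):
        out = np.zeros_like(v)
        for i in range(n):
            w = np.array([1.0 + qn[i] @ kn[j] for j in range(n)])
            w /= n + qn[i] @ kn.sum(axis=0)
            for j in range(n):
                out[i] += w[j] * v[j]
        outs.append(out)
    return np.concatenate(outs, axis=1)


# ------------------------------------------------------------------ embed


def test_embed_zero_input_zero_bias_gives_zero():
    cfg = M.ModelConfig(d=8, n_heads=2, seed=0)
    params = M.init_params(cfg, 5, 3)
    out = M.embed_cells(np.zeros((4, 5)), params, cfg)
    assert np.allclose(out, 0.0)


def test_embed_is_nonnegative_and_matches_straight_line_oracle():
    rng = np.random.default_rng(1)
    cfg = M.ModelConfig(d=6, n_heads=2, seed=1)
    params = M.init_params(cfg, 6, 3)
    x = rng.normal(size=(4, 6))
    out = M.embed_cells(x, params, cfg)
    assert (out >= 0).all()
    # independent straight-line evaluation
    h = x @ params.arrays["W1"].T + params.arrays["b1"]
    mu = h.mean(axis=1, keepdims=True)
    var = ((h - mu) ** 2).mean(axis=1, keepdims=True)
    ln = (h - mu) / np.sqrt(var + cfg.epsilon)
    expected = np.maximum(ln * params.arrays["ln0_g"] + params.arrays["ln0_b"], 0)
    assert np.allclose(out, expected)


def test_embed_shape_mismatch():
    cfg = M.ModelConfig(d=8, n_heads=2)
    params = M.init_params(cfg, 5, 3)
    with pytest.raises(ValueError, match="genes"):
        M.embed_cells(np.zeros((4, 7)), params, cfg)


# -------------------------------------------------- softmax reference oracle


def test_softmax_reference_single_cell_returns_value():
    rng = np.random.default_rng(2)
    cfg, params, state = _random_state(rng, 1, 8, 2)
    out = M.softmax_attention_reference(state)
    assert np.allclose(out, np.concatenate(state.V, axis=1))


def test_softmax_reference_identical_keys_average_values():
    rng = np.random.default_rng(3)
    cfg, params, state = _random_state(rng, 5, 8, 1)
    state.K[0] = np.ones_like(state.K[0])
    out = M.softmax_attention_reference(state)
    assert np.allclose(out, np.tile(state.V[0].mean(axis=0), (5, 1)))


def test_softmax_reference_weights_row_stochastic():
    rng = np.random.default_rng(4)
    cfg, params, state = _random_state(rng, 20, 4, 1)
    out = M.softmax_attention_reference(state)
    # constant-shift invariance of softmax: adding c to all V rows adds c to out
    shift = np.ones_like(state.V[0])
    state_shifted = M.LayerState(state.Z, state.Q, state.K, [state.V[0] + shift],
                                 state.Q_hat, state.K_hat)
    out2 = M.softmax_attention_reference(state_shifted)
    assert np.allclose(out2 - out, shift, atol=1e-12)


# ------------------------------------------------------------ linear attention


def test_linear_attention_single_cell_returns_value():
    rng = np.random.default_rng(5)
    cfg, params, state = _random_state(rng, 1, 8, 2)
    out = M.linear_attention(state)
    assert np.allclose(out, np.concatenate(state.V, axis=1), atol=1e-10)


def test_linear_attention_identical_embeddings_uniform_weights():
    cfg = M.ModelConfig(d=8, n_heads=2, seed=6)
    params = M.init_params(cfg, 8, 3)
    z = np.tile(np.random.default_rng(6).normal(size=8), (5, 1))
    state = M.make_layer_state(z, params, cfg, 0)
    out = M.linear_attention(state)
    assert np.allclose(out, np.concatenate(state.V, axis=1), atol=1e-8)


@pytest.mark.parametrize("n,d,heads", [(50, 8, 1), (50, 8, 2), (33, 16, 4)])
def test_linear_attention_matches_brute_force(n, d, heads):
    rng = np.random.default_rng(n + d + heads)
    cfg, params, state = _random_state(rng, n, d, heads)
    fast = M.linear_attention(state)
    slow = _brute_force_taylor(state, n)
    rel = np.abs(fast - slow).max() / np.abs(slow).max()
    assert rel <= 1e-5


def test_linear_attention_approaches_softmax_for_identical_embeddings():
    # when queries/keys coincide both schemes reduce to uniform averaging
    cfg = M.ModelConfig(d=8, n_heads=1, seed=7)
    params = M.init_params(cfg, 8, 3)
    z = np.tile(np.random.default_rng(7).normal(size=8), (6, 1))
    state = M.make_layer_state(z, params, cfg, 0)
    assert np.allclose(
        M.linear_attention(state), M.softmax_attention_reference(state), atol=1e-8
    )


def test_flop_count_grows_linearly_in_n():
    rng = np.random.default_rng(8)
    counts = {}
    for n in (500, 1000):
        cfg, params, state = _random_state(rng, n, 16, 2)
        M.flops.reset()
        M.linear_attention(state)
        counts[n] = M.flops.count
    assert 1.9 <= counts[1000] / counts[500] <= 2.1


# ------------------------------------------------------------------ gcn/fuse


def test_gcn_propagate_empty_graph_is_identity():
    rng = np.random.default_rng(9)
    z, v = rng.normal(size=(4, 6)), rng.normal(size=(4, 6))
    assert np.allclose(M.gcn_propagate(z, v, np.zeros((4, 4))), z)


def test_gcn_propagate_self_loop_adds_value():
    z, v = np.ones((1, 3)), np.full((1, 3), 2.0)
    assert np.allclose(M.gcn_propagate(z, v, np.array([[1.0]])), z + v)


def test_gcn_propagate_path_graph_matches_dense_oracle():
    rng = np.random.default_rng(10)
    a = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
    g = CellGraph(sp.csr_matrix(a))
    a_norm = normalize_adjacency(g)
    z, v = rng.normal(size=(3, 5)), rng.normal(size=(3, 5))
    d = np.diag(1 / np.sqrt([1, 2, 1]))
    assert np.allclose(M.gcn_propagate(z, v, a_norm), z + d @ a @ d @ v)


def test_fuse_endpoint_betas_drop_one_branch():
    rng = np.random.default_rng(11)
    cfg = M.ModelConfig(d=6, n_heads=2, seed=11)
    params = M.init_params(cfg, 6, 3)
    branch, z_prev, other = (rng.normal(size=(4, 6)) for _ in range(3))
    assert np.allclose(
        M.fuse_and_update(branch, z_prev, 0.0, cfg, params, 0),
        M.fuse_and_update(other, z_prev, 0.0, cfg, params, 0),
    )
    assert np.allclose(
        M.fuse_and_update(branch, z_prev, 1.0, cfg, params, 0),
        M.fuse_and_update(branch, other, 1.0, cfg, params, 0),
    )


def test_fuse_matches_direct_expression():
    rng = np.random.default_rng(12)
    cfg = M.ModelConfig(d=6, n_heads=2, seed=12)
    params = M.init_params(cfg, 6, 3)
    branch, z_prev = rng.normal(size=(4, 6)), rng.normal(size=(4, 6))
    mixed = 0.5 * branch + 0.5 * z_prev
    mu = mixed.mean(axis=1, keepdims=True)
    var = ((mixed - mu) ** 2).mean(axis=1, keepdims=True)
    ln = (mixed - mu) / np.sqrt(var + cfg.epsilon)
    expected = np.maximum(ln * params.arrays["layer0.ln_g"] + params.arrays["layer0.ln_b"], 0)
    assert np.allclose(M.fuse_and_update(branch, z_prev, 0.5, cfg, params, 0), expected)


def test_classify_identity_head_and_affine():
    cfg = M.ModelConfig(d=3, n_heads=1, seed=13)
    params = M.init_params(cfg, 3, 3)
    params.arrays["W_out"] = np.eye(3)
    params.arrays["b_out"] = np.zeros(3)
    z = np.random.default_rng(13).normal(size=(4, 3))
    assert np.allclose(M.classify(z, params), z)
    params.arrays["b_out"] = np.array([1.0, 2.0, 3.0])
    assert np.allclose(M.classify(np.zeros((2, 3)), params), [[1, 2, 3], [1, 2, 3]])


# ------------------------------------------------------------------ forward


def test_forward_permutation_equivariant():
    rng = np.random.default_rng(14)
    cfg = M.ModelConfig(d=16, n_heads=2, n_layers=2, seed=14)
    params = M.init_params(cfg, 10, 4)
    x = rng.normal(size=(25, 10)) ** 2
    perm = rng.permutation(25)
    out = M.forward(x, None, cfg, params)
    out_perm = M.forward(x[perm], None, cfg, params)
    assert np.allclose(out[perm], out_perm, atol=1e-8)


def test_forward_ignores_graph_when_disabled():
    rng = np.random.default_rng(15)
    cfg = M.ModelConfig(d=8, n_heads=2, use_graph=False, seed=15)
    params = M.init_params(cfg, 6, 3)
    x = rng.normal(size=(12, 6)) ** 2
    m = (rng.random((12, 12)) > 0.7).astype(float)
    g = CellGraph(sp.csr_matrix(np.maximum(m, m.T) * (1 - np.eye(12))))
    assert np.array_equal(M.forward(x, None, cfg, params), M.forward(x, g, cfg, params))


def test_forward_single_layer_matches_hand_composition():
    rng = np.random.default_rng(16)
    cfg = M.ModelConfig(d=8, n_heads=1, n_layers=1, beta=0.0, seed=16)
    params = M.init_params(cfg, 5, 3)
    x = rng.normal(size=(7, 5)) ** 2
    z0 = M.embed_cells(x, params, cfg)
    state = M.make_layer_state(z0, params, cfg, 0)
    z_attn = M.linear_attention(state, cfg.epsilon)
    z1 = M.fuse_and_update(z_attn, z0, cfg.beta, cfg, params, 0)
    expected = M.classify(z1, params)
    assert np.allclose(M.forward(x, None, cfg, params), expected, atol=1e-10)


def test_forward_graph_branch_changes_output():
    rng = np.random.default_rng(17)
    cfg = M.ModelConfig(d=8, n_heads=2, use_graph=True, beta=0.5, seed=17)
    params = M.init_params(cfg, 6, 3)
    x = rng.normal(size=(10, 6)) ** 2
    a = np.zeros((10, 10))
    a[0, 1] = a[1, 0] = a[2, 3] = a[3, 2] = 1
    g = CellGraph(sp.csr_matrix(a))
    assert not np.allclose(M.forward(x, g, cfg, params), M.forward(x, None, cfg, params))


# ---------------------------------------------------------------- attention map


def test_attention_map_single_cell():
    cfg = M.ModelConfig(d=8, n_heads=2, seed=18)
    params = M.init_params(cfg, 4, 3)
    amap = M.materialize_attention(np.ones((1, 4)), None, cfg, params, layer=0)
    assert np.allclose(amap.matrix, [[1.0]])


def test_attention_map_identical_cells_uniform():
    cfg = M.ModelConfig(d=8, n_heads=2, seed=19)
    params = M.init_params(cfg, 4, 3)
    x = np.tile(np.random.default_rng(19).random(4), (6, 1))
    amap = M.materialize_attention(x, None, cfg, params, layer=0)
    assert np.allclose(amap.matrix, 1 / 6, atol=1e-8)


def test_attention_map_rows_stochastic_and_consistent_with_output():
    rng = np.random.default_rng(20)
    cfg = M.ModelConfig(d=8, n_heads=1, n_layers=1, seed=20)
    params = M.init_params(cfg, 6, 3)
    x = rng.normal(size=(15, 6)) ** 2
    amap = M.materialize_attention(x, None, cfg, params, layer=0, head=0)
    assert (amap.matrix >= 0).all()
    assert np.allclose(amap.matrix.sum(axis=1), 1.0, atol=1e-6)
    # matrix · V reproduces the linear-attention output of that layer
    z0 = M.embed_cells(x, params, cfg)
    state = M.make_layer_state(z0, params, cfg, 0)
    assert np.allclose(
        amap.matrix @ state.V[0], M.linear_attention(state, cfg.epsilon), atol=1e-5
    )


def test_attention_map_guards():
    cfg = M.ModelConfig(d=8, n_heads=2, seed=21)
    params = M.init_params(cfg, 4, 3)
    x = np.ones((5, 4))
    with pytest.raises(ValueError, match="max_n"):
        M.materialize_attention(x, None, cfg, params, layer=0, max_n=3)
    with pytest.raises(ValueError, match="layer"):
        M.materialize_attention(x, None, cfg, params, layer=5)


# ---------------------------------------------------------------- checkpoint


def test_checkpoint_round_trip(tmp_path):
    cfg = M.ModelConfig(d=8, n_heads=2, seed=22)
    params = M.init_params(cfg, 6, 3)
    path = tmp_path / "model.ckpt"
    M.save_checkpoint(path, params, cfg, ["A", "B", "C"], np.array([0, 2, 4]))
    p2, c2, vocab, kept = M.load_checkpoint(path)
    assert c2 == cfg and vocab == ["A", "B", "C"]
    assert np.array_equal(kept, [0, 2, 4])
    for k in params.arrays:
        assert np.array_equal(params.arrays[k], p2.arrays[k])
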