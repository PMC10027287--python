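"""Encoder tower building blocks: positional encoding, Transformer layer,
GRU recurrence, full-tower gradients, discriminator."""

import numpy as np
import pytest

from ssplearn import autodiff as ad
from ssplearn.autodiff import Tensor
from ssplearn.nn import (Discriminator, EncoderTower, GruCell, ModelConfig,
                         discriminate, embed_with_positions, encode_view,
                         gru_step, sinusoidal_positions, transformer_encode)


def _tower(config, vocab=21, seed=0):
    return EncoderTower(vocab_size=vocab, config=config, rng=np.random.default_rng(seed))


# -- positional encoding -----------------------------------------------------
def test_position_zero_is_sin0_cos1(tiny_config):
    tower = _tower(tiny_config)
    tower.embedding.data[...] = 0.0
    rows = embed_with_positions(np.array([1, 2, 3]), tower)
    np.testing.assert_allclose(rows[0, 0::2], 0.0, atol=1e-12)  # sin(0)
    np.testing.assert_allclose(rows[0, 1::2], 1.0, atol=1e-12)  # cos(0)


def test_embedding_shape_contract(tiny_config):
    tower = _tower(tiny_config)
    for L in (1, 5, tiny_config.max_len):
        rows = embed_with_positions(np.ones(L, dtype=int), tower)
        assert rows.shape == (L, tiny_config.d_model)
    with pytest.raises(ValueError):
        embed_with_positions(np.ones(tiny_config.max_len + 1, dtype=int), tower)
    with pytest.raises(ValueError):
        embed_with_positions(np.array([99]), tower)


def test_positional_norm_difference_closed_form(tiny_config):
    d = tiny_config.d_model
    pe = sinusoidal_positions(10, d)
    i = np.arange(0, d, 2)
    angle1 = 1.0 / np.power(10000.0, i / d)  # position 1 angles
    expected = np.sum(np.sin(angle1) ** 2 + np.cos(angle1) ** 2)  # = d/2
    got = np.sum(pe[1] ** 2) - np.sum(pe[0] ** 2)
    # position 0 contributes d/2 (all cos(0)=1); both norms equal d/2 exactly
    assert np.sum(pe[0] ** 2) == pytest.approx(d / 2)
    assert got == pytest.approx(expected - d / 2, abs=1e-12)


# -- transformer encoder -----------------------------------------------------
def _zero_layer(layer):
    for block in (layer.attn.wo, layer.fc2):
        block.W.data[...] = 0.0
        block.b.data[...] = 0.0


def test_zero_weight_layer_is_identity(tiny_config, rng):
    tower = _tower(tiny_config)
    for layer in tower.layers:
        _zero_layer(layer)
    x = rng.normal(size=(6, tiny_config.d_model))
    out = transformer_encode(x, tower)
    np.testing.assert_allclose(out, x, atol=1e-12)


def _manual_pre_ln_layer(x, layer, n_heads):
    """Independent NumPy evaluation of one pre-LN encoder layer."""
    def ln(v, gamma, beta, eps=1e-5):
        mu = v.mean(-1, keepdims=True)
        var = ((v - mu) ** 2).mean(-1, keepdims=True)
        return (v - mu) / np.sqrt(var + eps) * gamma + beta

    L, D = x.shape
    dh = D // n_heads
    h = ln(x, layer.ln1.gamma.data, layer.ln1.beta.data)
    q = h @ layer.attn.wq.W.data + layer.attn.wq.b.data
    k = h @ layer.attn.wk.W.data + layer.attn.wk.b.data
    v = h @ layer.attn.wv.W.data + layer.attn.wv.b.data
    ctx = np.zeros_like(x)
    for head in range(n_heads):
        sl = slice(head * dh, (head + 1) * dh)
        scores = q[:, sl] @ k[:, sl].T / np.sqrt(dh)
        e = np.exp(scores - scores.max(-1, keepdims=True))
        attn = e / e.sum(-1, keepdims=True)
        ctx[:, sl] = attn @ v[:, sl]
    x = x + ctx @ layer.attn.wo.W.data + layer.attn.wo.b.data
    h = ln(x, layer.ln2.gamma.data, layer.ln2.beta.data)
    mlp = np.maximum(h @ layer.fc1.W.data + layer.fc1.b.data, 0.0)
    return x + mlp @ layer.fc2.W.data + layer.fc2.b.data


def test_single_layer_matches_manual_computation(rng):
    config = ModelConfig(d_model=4, n_encoder_layers=1, n_heads=2, gru_hidden=4,
                         proj_dim=4, dropout=0.0, max_len=8, seed=0)
    tower = _tower(config)
    x = rng.normal(size=(3, 4))
    got = transformer_encode(x, tower)
    want = _manual_pre_ln_layer(x, tower.layers[0], config.n_heads)
    np.testing.assert_allclose(got, want, rtol=1e-10, atol=1e-12)


def test_attention_is_permutation_equivariant(tiny_config, rng):
    """Without positional information, permuting the rows of the input permutes
    the encoder output identically (self-attention has no inherent order)."""
    tower = _tower(tiny_config)
    x = rng.normal(size=(5, tiny_config.d_model))
    perm = np.array([3, 1, 4, 0, 2])
    out = transformer_encode(x, tower)
    out_perm = transformer_encode(x[perm], tower)
    np.testing.assert_allclose(out_perm, out[perm], rtol=1e-9, atol=1e-11)


# -- GRU ---------------------------------------------------------------------
def _zero_cell(n_in=3, n_h=4):
    cell = GruCell(np.random.default_rng(0), n_in, n_h)
    for W in (cell.Wz, cell.Wr, cell.W):
        W.data[...] = 0.0
    return cell


def test_gru_zero_weights_halve_state():
    cell = _zero_cell()
    h_prev = np.array([1.0, -2.0, 0.5, 4.0])
    h = gru_step(np.zeros(3), h_prev, cell)
    np.testing.assert_allclose(h, 0.5 * h_prev)  # z=r=0.5, htilde=0
    np.testing.assert_allclose(gru_step(np.ones(3), np.zeros(4), cell), 0.0)


def _gru_scalar_loop(xs, h0, Wz, Wr, W):
    """Independent scalar-loop recurrence: z/r gates, candidate, convex update."""
    def sigma(v):
        return 1.0 / (1.0 + np.exp(-v))

    h = h0.copy()
    for x in xs:
        hx = np.concatenate([h, x])
        z = sigma(np.array([np.dot(hx, Wz[:, j]) for j in range(Wz.shape[1])]))
        r = sigma(np.array([np.dot(hx, Wr[:, j]) for j in range(Wr.shape[1])]))
        rh = np.concatenate([r * h, x])
        htil = np.tanh(np.array([np.dot(rh, W[:, j]) for j in range(W.shape[1])]))
        h = (1 - z) * h + z * htil
    return h


def test_gru_trajectory_matches_scalar_loop(rng):
    cell = GruCell(rng, input_size=3, hidden_size=4)
    xs = [rng.normal(size=3) for _ in range(3)]
    h = np.zeros(4)
    for x in xs:
        h = gru_step(x, h, cell)
    want = _gru_scalar_loop(xs, np.zeros(4), cell.Wz.data, cell.Wr.data, cell.W.data)
    np.testing.assert_allclose(h, want, atol=1e-6)


def test_gru_state_is_convex_combination(rng):
    cell = GruCell(rng, input_size=3, hidden_size=4)
    h_prev = rng.normal(size=4)
    x = rng.normal(size=3)
    with ad.no_grad():
        hx = ad.concat([Tensor(h_prev), Tensor(x)], axis=-1)
        z = ad.sigmoid(ad.matmul(hx, cell.Wz)).data
        rh = ad.concat([Tensor(ad.sigmoid(ad.matmul(hx, cell.Wr)).data * h_prev),
                        Tensor(x)], axis=-1)
        htilde = ad.tanh(ad.matmul(rh, cell.W)).data
    h = gru_step(x, h_prev, cell)
    lo = np.minimum(h_prev, htilde) - 1e-12
    hi = np.maximum(h_prev, htilde) + 1e-12
    assert np.all(h >= lo) and np.all(h <= hi)
    assert np.all((z > 0) & (z < 1))


# -- full tower --------------------------------------------------------------
def test_encode_view_shape_and_determinism(tiny_config, rng):
    tower = _tower(tiny_config)
    for L in (4, 11, 25):
        tokens = rng.integers(1, 21, size=L)
        v1 = encode_view(tokens, tower)
        v2 = encode_view(tokens, tower)
        assert v1.shape == (tiny_config.proj_dim,)
        np.testing.assert_array_equal(v1, v2)


def test_padding_does_not_leak_into_representation(tiny_config, rng):
    """A sequence encoded alone equals the same sequence inside a padded batch."""
    tower = _tower(tiny_config)
    short = rng.integers(1, 21, size=5)
    long = rng.integers(1, 21, size=12)
    with ad.no_grad():
        batch = np.zeros((2, 12), dtype=int)
        batch[0, :5] = short
        batch[1] = long
        both = tower.forward_batch(batch, np.array([5, 12])).data
    np.testing.assert_allclose(both[0], encode_view(short, tower), atol=1e-10)
    np.testing.assert_allclose(both[1], encode_view(long, tower), atol=1e-10)


def test_tower_gradients_match_finite_differences(tiny_config, rng):
    """d(‖v‖²)/dθ by autodiff vs central differences on a d_model=8 tower."""
    tower = _tower(tiny_config)
    tokens = rng.integers(1, 21, size=(1, 6))
    lengths = np.array([6])

    def loss_value():
        with ad.no_grad():
            v = tower.forward_batch(tokens, lengths)
        return float((v.data ** 2).sum())

    v = tower.forward_batch(tokens, lengths)
    loss = (v * v).sum()
    loss.backward()
    eps = 1e-5
    checked = 0
    for name, p in tower.named_parameters():
        flat = p.data.reshape(-1)
        gflat = p.grad.reshape(-1) if p.grad is not None else np.zeros_like(flat)
        for k in range(0, flat.size, max(1, flat.size // 3)):
            orig = flat[k]
            flat[k] = orig + eps
            hi = loss_value()
            flat[k] = orig - eps
            lo = loss_value()
            flat[k] = orig
            num = (hi - lo) / (2 * eps)
            denom = max(abs(num), abs(gflat[k]), 1e-6)
            assert abs(gflat[k] - num) / denom < 1e-3, f"{name}[{k}]"
            checked += 1
    assert checked > 30


# -- discriminator -----------------------------------------------------------
def test_discriminator_score_range(tiny_config, rng):
    disc = Discriminator(np.random.default_rng(0), tiny_config.proj_dim)
    for _ in range(5):
        v = rng.normal(scale=10.0, size=tiny_config.proj_dim)
        assert 0.0 <= discriminate(v, disc) <= 1.0


def test_zeroed_final_layer_scores_half(tiny_config, rng):
    disc = Discriminator(np.random.default_rng(0), tiny_config.proj_dim)
    disc.fc2.W.data[...] = 0.0
    disc.fc2.b.data[...] = 0.0
    score = discriminate(rng.normal(size=tiny_config.proj_dim), disc)
    assert score == 0.5
    assert int(score > 0.5) == 0  # strict inequality: 0.5 maps to non-SSP


def test_hand_set_linear_discriminator_sigmoid():
    disc = Discriminator(np.random.default_rng(0), 4, hidden=4)
    disc.fc1.W.data[...] = 0.0
    disc.fc1.b.data[...] = 0.0
    disc.fc1.W.data[0, 0] = 1.0  # pass v[0] through
    disc.fc2.W.data[...] = 0.0
    disc.fc2.b.data[...] = 0.0
    disc.fc2.W.data[0, 0] = 1.0
    v = np.array([3.0, 0.0, 0.0, 0.0])
    assert discriminate(v, disc) == pytest.approx(1 / (1 + np.exp(-3)), abs=1e-12)


def test_discriminator_dimension_mismatch(tiny_config):
    disc = Discriminator(np.random.default_rng(0), tiny_config.proj_dim)
    with pytest.raises(ValueError):
        discriminate(np.zeros(tiny_config.proj_dim + 1), disc)
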