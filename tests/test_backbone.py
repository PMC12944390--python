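"""Backbone network: embedding, positional encoding, encoder, density head."""

import math

import numpy as np
import pytest

from flockcast import MiniFormer, ModelConfig, Window
from flockcast.backbone import parameter_count_formula, positional_encoding, save_checkpoint, load_checkpoint
from flockcast.evaluation import mode_trajectories
from flockcast.training import wta_loss_tensors
from flockcast._autodiff import Tensor

from conftest import make_straight_window


TOY = ModelConfig(d_model=8, n_layers=1, n_heads=2, ffn_dim=16, head_hidden=16,
                  T_past=4, T_fut=2, K=2, dropout=0.0)


def toy_model(seed=0, **overrides):
    import dataclasses

    return MiniFormer(dataclasses.replace(TOY, **overrides), seed=seed)


# ---------------------------------------------------------------------------
# Positional encoding
# ---------------------------------------------------------------------------

def test_positional_encoding_values():
    pe = positional_encoding(4, 4)
    assert np.allclose(pe[0], [0, 1, 0, 1])                 # t = 0
    assert math.isclose(pe[1, 0], math.sin(1.0), rel_tol=1e-12)
    # independent scripted evaluation of the sinusoid table
    expected = np.array(
        [[math.sin(t / 10000 ** (2 * i / 4)) if c % 2 == 0 else
          math.cos(t / 10000 ** (2 * i / 4))
          for c in range(4) for i in [c // 2]][:4]
         for t in range(4)]
    )
    assert np.allclose(pe, expected, atol=1e-12)
    assert np.all(np.abs(pe) <= 1.0)
    with pytest.raises(ValueError):
        positional_encoding(4, 5)  # odd model width


# ---------------------------------------------------------------------------
# Embedding
# ---------------------------------------------------------------------------

def test_embedding_is_linear_plus_positional_encoding():
    m = toy_model()
    L = 3
    pe = positional_encoding(L, TOY.d_model)
    zero_rows = m.embed_displacements(np.zeros((L, 2)))
    bias_part = zero_rows - pe
    assert np.allclose(bias_part, m.embed.bias.data)  # W @ 0 + b
    dp = np.array([[1.0, -2.0], [0.5, 0.0], [0.0, 3.0]])
    rows = m.embed_displacements(dp)
    doubled = m.embed_displacements(2 * dp)
    # doubling the displacement doubles the pre-PE linear part
    assert np.allclose(doubled - pe, 2 * (rows - pe) - m.embed.bias.data)
    # explicit matrix-vector product
    manual = dp @ m.embed.weight.data + m.embed.bias.data + pe
    assert np.allclose(rows, manual, atol=1e-12)


def test_embedding_rejects_non_finite_input():
    with pytest.raises(ValueError):
        toy_model().embed_displacements(np.array([[np.nan, 0.0]]))


# ---------------------------------------------------------------------------
# Encoder
# ---------------------------------------------------------------------------

def test_encoder_deterministic_in_eval_mode():
    m = toy_model().eval()
    x = np.random.default_rng(0).standard_normal((3, TOY.d_model))
    a = m.encode_history(x).data
    b = m.encode_history(x).data
    assert np.array_equal(a, b)


def test_mean_pooling_of_identical_rows_returns_the_row():
    # pooling is the arithmetic mean of the encoder output rows
    m = toy_model()
    h = np.random.default_rng(1).standard_normal(TOY.d_model)
    pooled = Tensor(np.tile(h, (5, 1))).mean(axis=-2)
    assert np.allclose(pooled.data, h)


def test_pooling_invariant_to_output_row_permutation():
    rows = np.random.default_rng(2).standard_normal((1, 7, 16))
    perm = rows[:, np.random.default_rng(3).permutation(7)]
    assert np.allclose(rows.mean(axis=1), perm.mean(axis=1))


def test_single_head_attention_matches_hand_computation():
    # 1 layer, 1 head, d_model=2: verify the softmax-attention arithmetic
    m = toy_model(n_layers=1, n_heads=1, d_model=2, ffn_dim=4, head_hidden=4)
    layer = m.layers[0]
    x = np.array([[0.5, -1.0], [1.5, 0.25]])

    def ln(v, w, b):
        mu = v.mean(-1, keepdims=True)
        var = ((v - mu) ** 2).mean(-1, keepdims=True)
        return (v - mu) / np.sqrt(var + 1e-5) * w + b

    xn = ln(x, layer.norm1.weight.data, layer.norm1.bias.data)
    q = xn @ layer.attn.wq.weight.data + layer.attn.wq.bias.data
    k = xn @ layer.attn.wk.weight.data + layer.attn.wk.bias.data
    v = xn @ layer.attn.wv.weight.data + layer.attn.wv.bias.data
    s = q @ k.T / math.sqrt(2)
    a = np.exp(s - s.max(-1, keepdims=True))
    a /= a.sum(-1, keepdims=True)
    attn_out = (a @ v) @ layer.attn.wo.weight.data + layer.attn.wo.bias.data
    x1 = x + attn_out
    x1n = ln(x1, layer.norm2.weight.data, layer.norm2.bias.data)
    h = x1n @ layer.ffn1.weight.data + layer.ffn1.bias.data
    h = h * 0.5 * (1 + np.vectorize(math.erf)(h / math.sqrt(2)))
    expected = x1 + h @ layer.ffn2.weight.data + layer.ffn2.bias.data

    m.eval()
    got = layer(Tensor(x[None])).data[0]
    assert np.allclose(got, expected, atol=1e-10)


# ---------------------------------------------------------------------------
# Head
# ---------------------------------------------------------------------------

def test_raw_output_sizes():
    full = ModelConfig()  # K=5, T_fut=60 reference configuration
    assert full.K * full.raw_per_component == 5 * 242 == 1210
    g = ModelConfig(family="gaussian")
    assert g.K * g.raw_per_component == 241


def test_zero_initialized_head_predicts_standstill():
    m = toy_model(mu_init_std=0.0).eval()
    w = make_straight_window(T_past=TOY.T_past, T_fut=TOY.T_fut)
    mix = m.forward(w)
    for c in mix.components:
        assert np.array_equal(c.mu, np.zeros(2 * TOY.T_fut))
    modes = mode_trajectories(mix, w.last_observed, TOY.T_fut)
    assert np.allclose(modes, np.tile(w.last_observed, (mix.K, TOY.T_fut, 1)))


def test_forward_output_satisfies_mixture_invariants():
    m = toy_model(seed=5).eval()
    w = make_straight_window(T_past=TOY.T_past, T_fut=TOY.T_fut)
    mix = m.forward(w)
    assert mix.K == TOY.K and mix.d == 2 * TOY.T_fut
    assert abs(mix.weights.sum() - 1.0) < 1e-12
    for c in mix.components:
        assert np.all(c.scale_diag > 0) and c.nu > 2


def test_forward_rejects_mismatched_window():
    m = toy_model().eval()
    w = make_straight_window(T_past=6, T_fut=3)
    with pytest.raises(ValueError, match="does not"):
        m.forward(w)


def test_batched_forward_equals_single_sample_path():
    m = toy_model(seed=3).eval()
    rng = np.random.default_rng(4)
    ws = [make_straight_window(T_past=TOY.T_past, T_fut=TOY.T_fut,
                               velocity=rng.standard_normal(2)) for _ in range(4)]
    batch = m.predict_batch(ws)
    for w, bm in zip(ws, batch):
        sm = m.forward(w)
        assert np.array_equal(sm.weights, bm.weights)
        for a, b in zip(sm.components, bm.components):
            assert np.array_equal(a.mu, b.mu)
            assert np.array_equal(a.scale_diag, b.scale_diag)
            assert a.nu == b.nu


def test_end_to_end_toy_matches_scripted_composition():
    m = toy_model(seed=9).eval()
    w = make_straight_window(T_past=TOY.T_past, T_fut=TOY.T_fut, velocity=(0.3, -0.2))
    tokens = m.embed_displacements(w.past_displacements)
    h = m.encode_history(tokens)
    raw = m.mdn_head(h)
    direct = m.forward_raw(w.past_displacements[None])
    for key in raw:
        assert np.allclose(raw[key].data, direct[key].data, atol=1e-12)


# ---------------------------------------------------------------------------
# Parameter counting
# ---------------------------------------------------------------------------

def test_embedding_parameter_count_reference():
    c = ModelConfig()
    m = MiniFormer(c)
    emb = m.embed.weight.data.size + m.embed.bias.data.size
    assert emb == 2 * 96 + 96 == 288


def test_parameter_count_matches_hand_enumeration_on_toy():
    c = ModelConfig(d_model=4, n_layers=1, n_heads=1, ffn_dim=8, head_hidden=8,
                    head_depth=2, K=1, T_fut=1, T_past=3)
    m = MiniFormer(c)
    d = 2  # 2*T_fut
    hand = (
        (2 * 4 + 4)                        # embedding
        + 4 * (4 * 4 + 4)                  # q, k, v, o projections
        + (4 * 8 + 8) + (8 * 4 + 4)        # FFN
        + 2 * (4 + 4)                      # two layer norms
        + (4 + 4)                          # final norm
        + (4 * 8 + 8) + (8 * 8 + 8)        # head hidden layers
        + 8 * (1 * (1 + 2 * d + 1)) + (1 + 2 * d + 1)  # head output
    )
    assert m.count_parameters() == hand == parameter_count_formula(c)


def test_doubling_k_changes_only_head_output_count():
    import dataclasses

    c1 = ModelConfig(d_model=16, n_layers=1, n_heads=2, ffn_dim=32, head_hidden=32,
                     T_fut=4, K=2)
    c2 = dataclasses.replace(c1, K=4)
    diff = parameter_count_formula(c2) - parameter_count_formula(c1)
    predicted = (c1.head_hidden + 1) * (c2.K - c1.K) * c1.raw_per_component
    assert diff == predicted
    assert MiniFormer(c2).count_parameters() - MiniFormer(c1).count_parameters() == diff


def test_reference_configuration_count_is_documented_by_formula():
    c = ModelConfig()
    assert MiniFormer(c).count_parameters() == parameter_count_formula(c)


# ---------------------------------------------------------------------------
# Gradients and checkpointing
# ---------------------------------------------------------------------------

def test_gradient_reaches_every_parameter_under_wta():
    # the final layer starts at zero, which blocks upstream gradients on the
    # very first step; after one optimizer step every tensor must be live
    from flockcast import nn

    m = toy_model(seed=1)
    m.train()
    rng = np.random.default_rng(0)
    X = rng.standard_normal((8, TOY.T_past - 1, 2))
    Y = rng.standard_normal((8, 2 * TOY.T_fut))
    opt = nn.AdamW(m.parameters(), lr=1e-3)
    for _ in range(2):
        raw = m.forward_raw(X, rng)
        loss = wta_loss_tensors(Y, raw, family_has_nu=True)
        opt.zero_grad()
        loss.backward()
        opt.step()
    for name, p in m.named_parameters():
        assert p.grad is not None, name
        assert np.any(p.grad != 0.0), f"dead parameter: {name}"


def test_checkpoint_roundtrip_preserves_predictions(tmp_path):
    m = toy_model(seed=7).eval()
    w = make_straight_window(T_past=TOY.T_past, T_fut=TOY.T_fut)
    before = m.forward(w)
    save_checkpoint(m, tmp_path / "ck.zip", extra={"note": "toy"})
    loaded, meta = load_checkpoint(tmp_path / "ck.zip")
    after = loaded.forward(w)
    assert meta["extra"]["note"] == "toy"
    assert np.array_equal(before.weights, after.weights)
    for a, b in zip(before.components, after.components):
        assert np.array_equal(a.mu, b.mu)
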