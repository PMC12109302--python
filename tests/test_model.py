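"""Block-level checks of the staging network: shape arithmetic, SE
block semantics, the coupled state-space recurrence, and end-to-end
differentiability."""

import numpy as np
import pytest

from helpers import (finite_difference_max_rel_err,
                     reference_ssm_recurrence, tiny_model_config)
from sleepssm.autograd import Tensor
from sleepssm.model import (ModelConfig, MSCNNConfig, SEBlock, SSMConfig,
                            SSMCoupling, SleepStager, SsmOnlyClassifier,
                            build_model, conv_output_length)

RNG = np.random.default_rng(7)


# ---------------------------------------------------------------------------
# multi-scale convolution


def test_branch_length_arithmetic():
    """Both branch lengths from a 3000-sample epoch follow the
    convolution-arithmetic oracle."""
    cfg = MSCNNConfig()
    large, small = cfg.branch_lengths(3000)
    assert conv_output_length(3000, 50, 20) == 148
    assert conv_output_length(3000, 20, 5) == 597
    assert large[:2] == [148, 37]
    assert small[:2] == [597, 149]
    assert cfg.aligned_length(3000) == min(large[-1], small[-1])


def test_mscnn_zero_weights_give_zero_features():
    model = SleepStager(tiny_model_config(), seed=0)
    ms = model.mscnn[0]
    for t in ms.parameters().values():
        t.data[...] = 0.0
    x = Tensor(RNG.normal(size=(2, 1, 120)))
    assert np.all(ms.forward(x).data == 0.0)


def test_mscnn_output_shape():
    cfg = MSCNNConfig()
    model = SleepStager(ModelConfig(), seed=0)
    x = Tensor(RNG.normal(size=(3, 1, 3000)).astype(np.float32))
    out = model.mscnn[0].forward(x)
    assert out.shape == (3, cfg.out_channels, cfg.aligned_length(3000))


# ---------------------------------------------------------------------------
# squeeze-and-excitation


def test_se_squeeze_is_temporal_mean():
    se = SEBlock(4, 2, RNG, np.float64)
    u = Tensor(np.full((1, 4, 6), 3.5))
    np.testing.assert_allclose(se.squeeze(u).data, 3.5)
    u2 = Tensor(np.array([[[1.0, 2.0, 3.0, 4.0]]]))
    assert SEBlock(1, 1, RNG, np.float64).squeeze(u2).data[0, 0] == 2.5
    ur = Tensor(RNG.normal(size=(2, 4, 9)))
    loop = np.array([[ur.data[b, c].sum() / 9 for c in range(4)]
                     for b in range(2)])
    np.testing.assert_allclose(se.squeeze(ur).data, loop, atol=1e-12)


def test_se_excite_range_and_zero_weights():
    se = SEBlock(4, 2, RNG, np.float64)
    z = Tensor(RNG.normal(size=(3, 4)))
    s = se.excite(z).data
    assert np.all((s > 0) & (s < 1))
    se.w1.data[...] = 0.0
    np.testing.assert_allclose(se.excite(z).data, 0.5)


def test_se_excite_matches_scalar_loop():
    """4-channel, reduction-2 excitation against an explicit loop."""
    se = SEBlock(4, 2, RNG, np.float64)
    w1 = np.array([[0.1, -0.2], [0.3, 0.4], [-0.5, 0.6], [0.7, -0.8]])
    w2 = np.array([[0.2, -0.1, 0.05, 0.3], [-0.4, 0.25, 0.15, -0.2]])
    se.w1.data = w1
    se.w2.data = w2
    z = np.array([[1.0, -2.0, 0.5, 3.0]])
    hidden = [max(0.0, sum(z[0][c] * w1[c][h] for c in range(4)))
              for h in range(2)]
    expect = [1 / (1 + np.exp(-sum(hidden[h] * w2[h][c] for h in range(2))))
              for c in range(4)]
    np.testing.assert_allclose(se.excite(Tensor(z)).data[0], expect,
                               atol=1e-10)


def test_se_recalibrate_identity_annihilation_and_loop():
    u = Tensor(RNG.normal(size=(2, 4, 5)))
    ones = Tensor(np.ones((2, 4)))
    np.testing.assert_array_equal(SEBlock.recalibrate(u, ones).data, u.data)
    zeros = Tensor(np.zeros((2, 4)))
    assert np.all(SEBlock.recalibrate(u, zeros).data == 0)
    s = Tensor(RNG.random((2, 4)))
    out = SEBlock.recalibrate(u, s).data
    for b in range(2):
        for c in range(4):
            np.testing.assert_allclose(out[b, c], s.data[b, c] * u.data[b, c],
                                       atol=1e-12)
    assert out.shape == u.shape


def test_se_rejects_indivisible_reduction():
    with pytest.raises(ValueError, match="not divisible"):
        SEBlock(6, 4, RNG, np.float64)


# ---------------------------------------------------------------------------
# state-space coupling


def _coupling(m=2, h=3, d=4, seed=0, **kw):
    cfg = SSMConfig(hidden_dim=h, n_modalities=m, **kw)
    return SSMCoupling(cfg, d, np.random.default_rng(seed), np.float64)


def test_step_zero_fixed_point():
    c = _coupling()
    c.b_in.data[...] = 0.0
    h0 = [Tensor(np.zeros((2, 3))) for _ in range(2)]
    out = c.step(h0, Tensor(RNG.normal(size=(2, 4))))
    for h in out:
        np.testing.assert_array_equal(h.data, 0.0)


def test_step_without_cross_modal_term_is_shared_projection():
    """With all S_n = 0 and one shared input, every modality computes the
    same tanh(x·Bᵀ)."""
    c = _coupling()
    for s in c.s_mats:
        s.data[...] = 0.0
    x = Tensor(RNG.normal(size=(2, 4)))
    h0 = [Tensor(RNG.normal(size=(2, 3))) for _ in range(2)]
    out = c.step(h0, x)
    expect = np.tanh(x.data @ c.b_in.data)
    for h in out:
        np.testing.assert_allclose(h.data, expect, atol=1e-12)


@pytest.mark.parametrize("m", [1, 2, 3])
def test_attention_rows_sum_to_one(m):
    c = _coupling(m=m)
    h = [Tensor(RNG.normal(size=(4, 3))) for _ in range(m)]
    alpha = c.attention_weights(h).data
    assert alpha.shape == (4, m, m)
    np.testing.assert_allclose(alpha.sum(axis=2), 1.0, atol=1e-8)
    if m == 1:
        np.testing.assert_allclose(alpha, 1.0)


def test_attention_uniform_for_identical_states():
    c = _coupling(m=3)
    h0 = Tensor(RNG.normal(size=(2, 3)))
    alpha = c.attention_weights([h0, h0, h0]).data
    np.testing.assert_allclose(alpha, 1.0 / 3.0, atol=1e-8)


def test_attention_two_modality_closed_form():
    """M=2 with orthogonal unit states: softmax of [1/√H, 0] per row."""
    h1 = Tensor(np.array([[1.0, 0.0]]))
    h2 = Tensor(np.array([[0.0, 1.0]]))
    c = _coupling(m=2, h=2, d=2)
    alpha = c.attention_weights([h1, h2]).data[0]
    s = 1.0 / np.sqrt(2)
    e = np.exp([s, 0.0])
    np.testing.assert_allclose(alpha[0], e / e.sum(), atol=1e-10)
    np.testing.assert_allclose(alpha[1], e[::-1] / e.sum(), atol=1e-10)


@pytest.mark.parametrize("literal", [False, True])
def test_recurrence_matches_scalar_loop_reference(literal):
    """Hand-set T=3, M=2, H=2, D=2 recurrence equals the independent
    scalar-loop oracle within 1e-10, in both attention-history variants."""
    c = _coupling(m=2, h=2, d=2, literal_attention_state=literal)
    c.s_mats[0].data = np.array([[0.3, -0.2], [0.1, 0.4]])
    c.s_mats[1].data = np.array([[-0.1, 0.2], [0.5, -0.3]])
    c.b_in.data = np.array([[0.7, -0.5], [0.2, 0.9]])
    xs = RNG.normal(size=(3, 2, 2))  # T, M, D — already "normalised" input
    h = [Tensor(np.zeros((1, 2))), Tensor(np.zeros((1, 2)))]
    for t in range(3):
        h = c.step(h, [Tensor(xs[t, n][None, :]) for n in range(2)])
    ref = reference_ssm_recurrence(
        xs, [s.data for s in c.s_mats], c.b_in.data,
        np.zeros((2, 2)), literal=literal)
    for n in range(2):
        np.testing.assert_allclose(h[n].data[0], ref[n], atol=1e-10)


def test_hidden_states_bounded():
    c = _coupling()
    h = [Tensor(RNG.normal(size=(5, 3))) for _ in range(2)]
    out = c.step(h, Tensor(RNG.normal(size=(5, 4))))
    for hn in out:
        assert np.all(np.abs(hn.data) < 1.0)
    # extreme drive saturates but never escapes the tanh range
    big = c.step(h, Tensor(np.full((5, 4), 1e6)))
    for hn in big:
        assert np.all(np.abs(hn.data) <= 1.0)


def test_forward_single_modality_pass_through():
    """M=1, W=1, E=identity: the fused output is the final hidden state."""
    c = _coupling(m=1, h=3, d=3)
    c.e_out.data = np.eye(3)
    c.w_fuse[0].data = np.ones(())
    c.ln_gamma[0].data = np.ones(3)
    x = RNG.normal(size=(2, 4, 3))
    y = c.forward([Tensor(x)])
    # replicate: layernorm then recurrence, final h
    mu = x.mean(-1, keepdims=True)
    xhat = (x - mu) / np.sqrt(x.var(-1, keepdims=True) + 1e-5)
    h = np.zeros((2, 3))
    for t in range(4):
        h = np.tanh(h @ c.s_mats[0].data + xhat[:, t, :] @ c.b_in.data)
    np.testing.assert_allclose(y.data, h, atol=1e-10)


def test_forward_zero_fusion_weights_annihilate():
    c = _coupling()
    for w in c.w_fuse:
        w.data = np.zeros(())
    y = c.forward([Tensor(RNG.normal(size=(2, 3, 4))) for _ in range(2)])
    np.testing.assert_array_equal(y.data, 0.0)


def test_forward_rejects_mismatched_lengths():
    c = _coupling()
    with pytest.raises(ValueError, match="differ in length"):
        c.forward([Tensor(np.zeros((1, 3, 4))), Tensor(np.zeros((1, 5, 4)))])
    with pytest.raises(ValueError, match="expected 2"):
        c.forward([Tensor(np.zeros((1, 3, 4)))])


def test_modality_permutation_consistency():
    """Swapping the modalities together with their parameter blocks
    (S_1↔S_2, W_1↔W_2, layernorm affines) leaves the fused output
    unchanged."""
    c = _coupling(m=2, h=3, d=4, seed=3)
    xs = [Tensor(RNG.normal(size=(2, 3, 4))) for _ in range(2)]
    y = c.forward(xs).data.copy()
    c.s_mats[0].data, c.s_mats[1].data = (c.s_mats[1].data.copy(),
                                          c.s_mats[0].data.copy())
    c.w_fuse[0].data, c.w_fuse[1].data = (c.w_fuse[1].data.copy(),
                                          c.w_fuse[0].data.copy())
    for pair in (c.ln_gamma, c.ln_beta):
        pair[0].data, pair[1].data = pair[1].data.copy(), pair[0].data.copy()
    y_swapped = c.forward(xs[::-1]).data
    np.testing.assert_allclose(y_swapped, y, atol=1e-10)


# ---------------------------------------------------------------------------
# full model


def test_model_probabilities_normalised_and_deterministic():
    model = build_model("full", tiny_model_config("float32"), seed=0)
    x = np.tile(RNG.normal(size=(1, 2, 120)).astype(np.float32), (3, 1, 1))
    p = model.predict_proba(x)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
    assert np.all((p >= 0) & (p <= 1))
    # identical epochs -> identical rows (eval mode is deterministic)
    np.testing.assert_array_equal(p[0], p[1])
    np.testing.assert_array_equal(p[0], p[2])


def test_model_rejects_bad_shapes():
    model = build_model("full", tiny_model_config("float32"), seed=0)
    with pytest.raises(ValueError, match="expected epochs of 120"):
        model.forward(np.zeros((1, 2, 64)))
    with pytest.raises(ValueError, match=r"expected \(B, 2, L\)"):
        model.forward(np.zeros((1, 3, 120)))


@pytest.mark.parametrize("variant", ["full", "cnn_se", "ssm_only"])
def test_end_to_end_gradients(variant):
    """Finite-difference gradient check of the whole network (tiny
    configuration, float64) within 1e-4 relative error."""
    cfg = tiny_model_config()
    if variant == "ssm_only":
        model = SsmOnlyClassifier(cfg, seed=1, patch_len=30)
    else:
        model = build_model(variant, cfg, seed=1)
    x = np.random.default_rng(5).normal(size=(2, 2, 120))
    y = np.array([1, 4])
    assert finite_difference_max_rel_err(model, x, y) < 1e-4


def test_checkpoint_round_trip(tmp_path):
    model = build_model("full", tiny_model_config("float32"), seed=3)
    x = RNG.normal(size=(2, 2, 120)).astype(np.float32)
    p_before = model.predict_proba(x)
    model.save(tmp_path / "ckpt")
    from sleepssm.model import _BaseClassifier
    clone = _BaseClassifier.load(tmp_path / "ckpt")
    np.testing.assert_array_equal(clone.predict_proba(x), p_before)


def test_block_composition_matches_manual_pipeline():
    """The full forward equals manually chaining the individually tested
    blocks (MSCNN → SE → transpose → coupling → head)."""
    cfg = tiny_model_config()
    model = SleepStager(cfg, seed=2)
    x = np.random.default_rng(9).normal(size=(2, 2, 120))
    logits = model.forward(x).data
    seqs = []
    for n in range(2):
        xn = Tensor(x[:, n, :].reshape(2, 1, 120))
        feat = model.se[n].forward(model.mscnn[n].forward(xn))
        seqs.append(feat.transpose(0, 2, 1))
    manual = model.head.forward(model.coupling.forward(seqs)).data
    np.testing.assert_allclose(logits, manual, atol=1e-12)
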