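"""Modality-attention fusion algebra vs independent brute-force oracles."""

import numpy as np
import pytest

from modseg.autodiff import Parameter, Tensor
from modseg.fusion import (FeatureStack, FusionParameters,
                           ModalityAttentionFusion, ModalityWeights, SEBlock,
                           gap3d, modality_attention_fuse, modality_digits,
                           se_recalibrate, softmax_weights, sum_fuse,
                           weighted_fuse)

from conftest import numeric_gradient


# --- brute-force loop oracles (never vectorised) --------------------------

def oracle_sum(features):
    m = len(features)
    w, h, d, c = features[0].shape
    out = np.zeros((w, h, d, c))
    for mm in range(m):
        for i in range(w):
            for j in range(h):
                for k in range(d):
                    for cc in range(c):
                        out[i, j, k, cc] += features[mm][i, j, k, cc]
    return out


def oracle_gap(u):
    w, h, d, c = u.shape
    z = np.zeros(c)
    for cc in range(c):
        acc = 0.0
        for i in range(w):
            for j in range(h):
                for k in range(d):
                    acc += u[i, j, k, cc]
        z[cc] = acc / (w * h * d)
    return z


def oracle_digits(z, mats, biases):
    outs = []
    for a, b in zip(mats, biases):
        o = np.zeros(a.shape[1])
        for col in range(a.shape[1]):
            acc = b[col]
            for row in range(a.shape[0]):
                acc += z[row] * a[row, col]
            o[col] = acc
        outs.append(o)
    return outs


def oracle_softmax(digits):
    d = np.asarray(digits, dtype=np.float64)
    m, c = d.shape
    w = np.zeros((m, c))
    for cc in range(c):
        mx = max(d[mm, cc] for mm in range(m))
        denom = sum(np.exp(d[mm, cc] - mx) for mm in range(m))
        for mm in range(m):
            w[mm, cc] = np.exp(d[mm, cc] - mx) / denom
    return w


def oracle_weighted(features, w):
    m = len(features)
    wi, h, d, c = features[0].shape
    out = np.zeros((wi, h, d, c))
    for mm in range(m):
        for i in range(wi):
            for j in range(h):
                for k in range(d):
                    for cc in range(c):
                        out[i, j, k, cc] += w[mm, cc] * features[mm][i, j, k, cc]
    return out


def _random_stack(rng, m=None):
    m = m or int(rng.integers(1, 5))
    shape = tuple(rng.integers(1, 5, size=4))
    return FeatureStack([rng.normal(size=shape) for _ in range(m)])


def _random_params(rng, m, c):
    return FusionParameters([rng.normal(size=(c, c)) for _ in range(m)],
                            [rng.normal(size=c) for _ in range(m)])


@pytest.mark.parametrize("trial", range(12))
def test_each_fusion_step_matches_loop_oracle(rng, trial):
    stack = _random_stack(rng)
    u = sum_fuse(stack)
    assert np.allclose(u, oracle_sum(stack.features), atol=1e-6)
    z = gap3d(u)
    assert np.allclose(z, oracle_gap(u), atol=1e-6)
    params = _random_params(rng, stack.n_modalities, stack.n_channels)
    digits = modality_digits(z, params)
    assert np.allclose(digits, oracle_digits(z, params.weights, params.biases),
                       atol=1e-6)
    weights = softmax_weights(digits)
    assert np.allclose(weights.w, oracle_softmax(digits), atol=1e-6)
    fused = weighted_fuse(stack, weights)
    assert np.allclose(fused, oracle_weighted(stack.features, weights.w),
                       atol=1e-6)
    # composite equals the chained per-step oracles end-to-end
    fused2, w2 = modality_attention_fuse(stack, params)
    assert np.allclose(fused2, fused, atol=1e-5)
    assert np.allclose(w2.w, weights.w, atol=1e-6)


def test_simple_sum_fuse_identities(rng):
    x = rng.normal(size=(2, 2, 2, 3))
    assert np.allclose(sum_fuse(FeatureStack([x, np.zeros_like(x)])), x)
    assert np.allclose(sum_fuse(FeatureStack([x, x, x])), 3 * x)


def test_gap_closed_forms():
    const = np.full((3, 2, 2, 1), 5.0)
    assert np.allclose(gap3d(const), [5.0])
    seq = np.arange(1, 9, dtype=float).reshape(2, 2, 2, 1)
    assert np.allclose(gap3d(seq), [4.5])


def test_digit_generator_identities(rng):
    z = rng.normal(size=4)
    eye = FusionParameters([np.eye(4)] * 2, [np.zeros(4)] * 2)
    for zm in modality_digits(z, eye):
        assert np.allclose(zm, z)
    b = rng.normal(size=4)
    zero = FusionParameters([np.zeros((4, 4))], [b])
    assert np.allclose(modality_digits(z, zero)[0], b)


def test_softmax_closed_forms_and_overflow_safety():
    w = softmax_weights([np.full(3, 1.7)] * 4)
    assert np.allclose(w.w, 0.25)
    w2 = softmax_weights([np.array([np.log(2.0)]), np.array([0.0])])
    assert np.allclose(w2.w[:, 0], [2 / 3, 1 / 3])
    w3 = softmax_weights([np.array([1000.0]), np.array([0.0])])
    assert np.all(np.isfinite(w3.w))
    assert np.allclose(w3.w[:, 0], [1.0, 0.0])


def test_weight_normalization_invariant_under_fuzz(rng):
    """Σ_m w_c^m = 1 for every channel on 1000 fuzzed digit sets, including
    extreme magnitudes."""
    for trial in range(1000):
        m = int(rng.integers(1, 5))
        c = int(rng.integers(1, 8))
        scale = rng.choice([1.0, 10.0, 1000.0])
        digits = [rng.uniform(-scale, scale, size=c) for _ in range(m)]
        w = softmax_weights(digits).w
        assert np.all(np.isfinite(w))
        assert np.allclose(w.sum(axis=0), 1.0, atol=1e-6)
        assert np.all((w >= 0) & (w <= 1))


def test_weighted_fuse_selection_and_convexity(rng):
    x = rng.normal(size=(2, 3, 2, 4))
    y = rng.normal(size=(2, 3, 2, 4))
    stack = FeatureStack([x, y])
    pick_first = ModalityWeights(np.stack([np.ones(4), np.zeros(4)]))
    assert np.allclose(weighted_fuse(stack, pick_first), x)
    same = FeatureStack([x, x])
    anyw = softmax_weights([rng.normal(size=4), rng.normal(size=4)])
    assert np.allclose(weighted_fuse(same, anyw), x, atol=1e-9)
    fused = weighted_fuse(stack, anyw)
    lo = np.minimum(x, y)
    hi = np.maximum(x, y)
    assert np.all(fused >= lo - 1e-9) and np.all(fused <= hi + 1e-9)


def test_single_modality_is_identity(rng):
    x = rng.normal(size=(2, 2, 2, 3))
    params = _random_params(rng, 1, 3)
    fused, w = modality_attention_fuse(FeatureStack([x]), params)
    assert np.allclose(w.w, 1.0)
    assert np.allclose(fused, x)


def test_identical_modalities_and_params_give_uniform_weights(rng):
    x = rng.normal(size=(2, 2, 2, 3))
    a, b = rng.normal(size=(3, 3)), rng.normal(size=3)
    params = FusionParameters([a.copy(), a.copy()], [b.copy(), b.copy()])
    fused, w = modality_attention_fuse(FeatureStack([x, x.copy()]), params)
    assert np.allclose(w.w, 0.5)
    assert np.allclose(fused, x, atol=1e-9)


def test_digit_shift_invariance(rng):
    digits = [rng.normal(size=5) for _ in range(3)]
    shifted = [d + 17.3 for d in digits]
    assert np.allclose(softmax_weights(digits).w,
                       softmax_weights(shifted).w, atol=1e-12)


def test_permutation_consistency(rng):
    stack = _random_stack(rng, m=3)
    params = _random_params(rng, 3, stack.n_channels)
    fused, w = modality_attention_fuse(stack, params)
    perm = [2, 0, 1]
    pstack = FeatureStack([stack.features[i] for i in perm])
    pparams = FusionParameters([params.weights[i] for i in perm],
                               [params.biases[i] for i in perm])
    pfused, pw = modality_attention_fuse(pstack, pparams)
    assert np.allclose(pw.w, w.w[perm], atol=1e-12)
    assert np.allclose(pfused, fused, atol=1e-9)


# --- SE baseline ----------------------------------------------------------

def test_se_gate_saturation_limits(rng):
    u = rng.normal(size=(2, 2, 2, 4))
    fc1_w = rng.normal(size=(4, 2)) * 0.1
    fc1_b = np.zeros(2)
    fc2_w = np.zeros((2, 4))
    out_open = se_recalibrate(u, fc1_w, fc1_b, fc2_w, np.full(4, 30.0))
    assert np.allclose(out_open, u, atol=1e-6)
    out_closed = se_recalibrate(u, fc1_w, fc1_b, fc2_w, np.full(4, -30.0))
    assert np.allclose(out_closed, 0.0, atol=1e-6)


def test_se_matches_straight_line_reimplementation(rng):
    u = rng.normal(size=(3, 2, 2, 6))
    fc1_w = rng.normal(size=(6, 3))
    fc1_b = rng.normal(size=3)
    fc2_w = rng.normal(size=(3, 6))
    fc2_b = rng.normal(size=6)
    out = se_recalibrate(u, fc1_w, fc1_b, fc2_w, fc2_b)
    # independent reimplementation, scalar loops over channels
    z = np.array([u[..., c].mean() for c in range(6)])
    h = np.maximum(z @ fc1_w + fc1_b, 0)
    s = 1 / (1 + np.exp(-(h @ fc2_w + fc2_b)))
    for c in range(6):
        assert np.allclose(out[..., c], u[..., c] * s[c], atol=1e-6)


def test_se_rejects_degenerate_reduction(rng):
    u = rng.normal(size=(2, 2, 2, 4))
    with pytest.raises(ValueError):
        se_recalibrate(u, np.zeros((4, 0)), np.zeros(0), np.zeros((0, 4)),
                       np.zeros(4))
    rng_np = np.random.default_rng(0)
    with pytest.raises(ValueError):
        SEBlock(rng_np, channels=4, reduction=5)


# --- trainable module vs algebra and gradient flow ------------------------

def test_fusion_module_matches_numpy_composite(rng):
    """The autodiff fusion block equals the pure-numpy algebra when given
    the same parameters (layout adapted: module uses (N,C,D,H,W))."""
    m, c = 2, 4
    feats_cl = [rng.normal(size=(3, 2, 2, c)).astype(np.float32)
                for _ in range(m)]
    block = ModalityAttentionFusion(np.random.default_rng(0), m, c)
    mats = [rng.normal(size=(c, c)).astype(np.float32) * 0.3 for _ in range(m)]
    biases = [rng.normal(size=c).astype(np.float32) * 0.1 for _ in range(m)]
    for g, a, b in zip(block.generators, mats, biases):
        g.weight.data[...] = a
        g.bias.data[...] = b
    tensors = [Tensor(f.transpose(3, 0, 1, 2)[None]) for f in feats_cl]
    out = block(tensors)
    expected, w = modality_attention_fuse(
        FeatureStack(feats_cl), FusionParameters(mats, biases))
    assert np.allclose(out.data[0].transpose(1, 2, 3, 0), expected, atol=1e-5)
    assert np.allclose(block.last_weights, w.w, atol=1e-5)


def test_fusion_gradient_wrt_generator_parameters(rng):
    """Finite-difference vs analytic gradients of the fused output w.r.t.
    the digit-generator parameters on a 2×2×2×2, M=2 instance."""
    m, c = 2, 2
    feats = [rng.normal(size=(1, c, 2, 2, 2)).astype(np.float32)
             for _ in range(m)]
    target = rng.normal(size=(1, c, 2, 2, 2)).astype(np.float32)
    block = ModalityAttentionFusion(np.random.default_rng(3), m, c)
    for g in block.generators:           # non-degenerate operating point
        g.weight.data[...] = rng.normal(size=(c, c)).astype(np.float32) * 0.5
        g.bias.data[...] = rng.normal(size=c).astype(np.float32) * 0.2

    def loss_value():
        out = block([Tensor(f) for f in feats])
        d = out - Tensor(target)
        return float((d * d).sum().data)

    out = block([Tensor(f) for f in feats])
    d = out - Tensor(target)
    (d * d).sum().backward()
    for g in block.generators:
        for p in (g.weight, g.bias):
            ng = numeric_gradient(loss_value, p.data, eps=1e-2)
            denom = np.abs(ng).max() + 1e-6
            assert np.abs(p.grad - ng).max() / denom < 1e-3
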