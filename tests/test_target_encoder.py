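import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from gradta.featurize import encode_protein
from gradta.target_encoder import (
    AttentionParams,
    GRUWeights,
    TargetEncoder,
    bigru_encode,
    encode_target,
    gru_step,
    soft_attention,
)
from gradta.autodiff import Tensor


def zero_weights(in_dim, hidden):
    z = lambda shape: Tensor(np.zeros(shape), requires_grad=True)
    return GRUWeights(
        W_z=z((in_dim, hidden)), U_z=z((hidden, hidden)),
        W_r=z((in_dim, hidden)), U_r=z((hidden, hidden)),
        W_x=z((in_dim, hidden)), U_x=z((hidden, hidden)),
    )


class TestGruStep:
    def test_zero_weights_halve_previous_state(self, rng):
        # z = r = 0.5 and candidate 0, so h' = 0.5 h
        w = zero_weights(3, 4)
        h = rng.normal(size=4)
        out = gru_step(rng.normal(size=3), h, w)
        np.testing.assert_allclose(out.data, 0.5 * h)

    def test_zero_weights_zero_state_stays_zero(self):
        w = zero_weights(2, 2)
        out = gru_step(np.ones(2), np.zeros(2), w)
        np.testing.assert_array_equal(out.data, np.zeros(2))

    def test_scalar_case_against_hand_recurrence(self):
        import math

        w = GRUWeights(
            W_z=Tensor([[0.5]]), U_z=Tensor([[-0.3]]),
            W_r=Tensor([[0.2]]), U_r=Tensor([[0.7]]),
            W_x=Tensor([[1.1]]), U_x=Tensor([[-0.4]]),
        )
        x, h = 0.8, -0.6
        z = 1 / (1 + math.exp(-(x * 0.5 + h * -0.3)))
        r = 1 / (1 + math.exp(-(x * 0.2 + h * 0.7)))
        cand = math.tanh(x * 1.1 + r * h * -0.4)
        expected = (1 - z) * h + z * cand
        out = gru_step(np.array([x]), np.array([h]), w)
        assert out.data[0] == pytest.approx(expected, abs=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        w = GRUWeights.create(3, 4, rng)
        with pytest.raises(ValueError):
            gru_step(np.zeros(5), np.zeros(4), w)

    def test_matches_scalar_loop_oracle_on_random_instances(self, rng):
        for _ in range(100):
            d_in, d_h = int(rng.integers(1, 4)), int(rng.integers(1, 4))
            bias = bool(rng.integers(0, 2))
            w = GRUWeights.create(d_in, d_h, rng, bias=bias)
            x, h = rng.normal(size=d_in), rng.normal(size=d_h)
            args, kw = oracles.gru_weight_arrays(w)
            np.testing.assert_allclose(
                gru_step(x, h, w).data,
                oracles.gru_step_oracle(x, h, *args, **kw),
                atol=1e-10,
            )

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_output_bounded_by_state_and_unit_interval(self, seed):
        # h' is a convex mix of h_prev and a tanh value
        rng = np.random.default_rng(seed)
        w = GRUWeights.create(2, 3, rng)
        h = rng.normal(size=3)
        out = gru_step(rng.normal(size=2), h, w).data
        assert np.all(out <= np.maximum(h, 1.0) + 1e-12)
        assert np.all(out >= np.minimum(h, -1.0) - 1e-12)


class TestBigruEncode:
    def test_zero_weights_give_zero_states(self):
        w = zero_weights(2, 3)
        out = bigru_encode(np.ones((4, 2)), w, zero_weights(2, 3))
        np.testing.assert_array_equal(out.data, np.zeros((4, 6)))

    def test_direction_symmetry_under_input_reversal(self, rng):
        wf = GRUWeights.create(2, 3, rng)
        wb = GRUWeights.create(2, 3, rng)
        X = rng.normal(size=(5, 2))
        fwd = bigru_encode(X, wf, wb).data
        swapped = bigru_encode(X[::-1], wb, wf).data
        np.testing.assert_allclose(
            fwd, np.concatenate([swapped[::-1, 3:], swapped[::-1, :3]], axis=1),
            atol=1e-12,
        )

    def test_matches_compositional_oracle_small_instances(self, rng):
        for _ in range(100):
            L = int(rng.integers(1, 6))
            d_in, d_h = int(rng.integers(1, 4)), int(rng.integers(1, 4))
            layers = int(rng.integers(1, 3))
            fwd = [GRUWeights.create(d_in if k == 0 else 2 * d_h, d_h, rng)
                   for k in range(layers)]
            bwd = [GRUWeights.create(d_in if k == 0 else 2 * d_h, d_h, rng)
                   for k in range(layers)]
            X = rng.normal(size=(L, d_in))
            np.testing.assert_allclose(
                bigru_encode(X, fwd, bwd).data,
                oracles.bigru_oracle(X, fwd, bwd),
                atol=1e-10,
            )

    def test_empty_input_rejected(self, rng):
        w = GRUWeights.create(2, 2, rng)
        with pytest.raises(ValueError):
            bigru_encode(np.zeros((0, 2)), w, w)


class TestSoftAttention:
    def test_identical_rows_give_uniform_weights(self, rng):
        p = AttentionParams.create(4, 3, rng)
        v = rng.normal(size=4)
        H = np.tile(v, (6, 1))
        result = soft_attention(H, p)
        np.testing.assert_allclose(result.weights.data, np.full(6, 1 / 6))
        np.testing.assert_allclose(result.context.data, v)

    def test_weights_sum_to_one(self, rng):
        p = AttentionParams.create(5, 4, rng)
        for _ in range(20):
            result = soft_attention(rng.normal(size=(7, 5)), p)
            assert result.weights.data.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(result.weights.data >= 0)

    def test_dominant_score_selects_row(self):
        # parameters rigged so row 4's score is ~10 and others ~0
        H = np.zeros((4, 2))
        H[3] = [5.0, 0.0]
        p = AttentionParams(U_a=Tensor([10.0]), W_a=Tensor([[10.0, 0.0]]))
        result = soft_attention(H, p)
        np.testing.assert_allclose(result.context.data, H[3], atol=1e-3)

    def test_matches_explicit_exponential_oracle(self, rng):
        for _ in range(100):
            L, d2, ds_ = int(rng.integers(1, 6)), 4, 3
            p = AttentionParams.create(d2, ds_, rng)
            H = rng.normal(size=(L, d2))
            ctx, alpha = oracles.attention_oracle(H, p.W_a.data, p.U_a.data)
            result = soft_attention(H, p)
            np.testing.assert_allclose(result.context.data, ctx, atol=1e-10)
            np.testing.assert_allclose(result.weights.data, alpha, atol=1e-10)


class TestTargetEncoder:
    def test_default_output_length_128(self):
        enc = TargetEncoder(rng=np.random.default_rng(0))
        out = encode_target(encode_protein("ACDEFGHIKLMNPQRSTVWY"), enc)
        assert out.shape == (128,)

    def test_deterministic_repeated_encoding(self):
        enc = TargetEncoder(
            embed_dim=8, hidden_dim=8, repr_dim=16, rng=np.random.default_rng(1)
        )
        pe = encode_protein("MKTAYIAKQR")
        np.testing.assert_array_equal(encode_target(pe, enc), encode_target(pe, enc))

    def test_all_padding_input_is_finite(self):
        enc = TargetEncoder(
            embed_dim=4, hidden_dim=4, repr_dim=8, rng=np.random.default_rng(2)
        )
        out = encode_target(encode_protein(""), enc)
        assert np.all(np.isfinite(out))

    def test_batched_forward_matches_single_encoding(self, rng):
        # variable-length masking must not change per-sequence results
        enc = TargetEncoder(
            embed_dim=6, hidden_dim=5, layers=2, repr_dim=7, rng=rng
        )
        seqs = ["ACDEFGHIKL", "MKT", "WWWWAAAACCCCDDDD"]
        pes = [encode_protein(s) for s in seqs]
        rows = [p.indices[: p.effective_length] for p in pes]
        batched = enc.forward_batch(rows).data
        for i, pe in enumerate(pes):
            np.testing.assert_allclose(
                batched[i], encode_target(pe, enc), atol=1e-10
            )

    def test_mean_pool_variant_has_no_attention_parameters(self):
        enc = TargetEncoder(
            embed_dim=4, hidden_dim=4, use_attention=False,
            rng=np.random.default_rng(3),
        )
        assert enc.attention is None
        out = encode_target(encode_protein("ACDACD"), enc)
        assert np.all(np.isfinite(out))
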