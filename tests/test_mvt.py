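"""Multi-view transformer: tokenization, cross-view attention, encoder blocks."""

import numpy as np
import pytest

from ofml import CrossViewAttention, DataError, MultiViewTransformer, PatchEmbed, mvt_forward
from ofml.autodiff import Tensor
from ofml.mvt import AdjacentViewFusion, EncoderBlock


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestPatchEmbed:
    def test_token_count_is_grid_cells_plus_class_token(self):
        pe = PatchEmbed(224, 16, 32, _rng())
        out = pe(Tensor(np.zeros((1, 3, 224, 224), dtype=np.float32)))
        assert out.shape == (1, (224 // 16) ** 2 + 1, 32)
        assert out.shape[1] == 197

    def test_row_dimension_is_embed_dim(self):
        pe = PatchEmbed(32, 8, 24, _rng(1))
        out = pe(Tensor(np.zeros((2, 3, 32, 32), dtype=np.float32)))
        assert out.shape == (2, 17, 24)

    def test_positional_embedding_is_purely_additive(self):
        pe = PatchEmbed(32, 8, 16, _rng(2))
        x = Tensor(_rng(3).random((1, 3, 32, 32), dtype=np.float32))
        pe.pos_embed.data[...] = 0.0
        base = pe(x).data.copy()
        q = _rng(4).normal(size=pe.pos_embed.shape).astype(np.float32)
        pe.pos_embed.data[...] = q
        shifted = pe(x).data
        np.testing.assert_allclose(shifted - base, q, atol=1e-6)

    def test_indivisible_image_is_data_error(self):
        with pytest.raises(DataError):
            PatchEmbed(30, 16, 8, _rng())


class TestCrossViewAttention:
    def test_attention_rows_are_stochastic(self):
        cva = CrossViewAttention(8, _rng(5))
        x = Tensor(_rng(6).normal(size=(2, 5, 8)).astype(np.float32))
        y = Tensor(_rng(7).normal(size=(2, 9, 8)).astype(np.float32))
        weights = cva.attention_weights(x, y).data
        np.testing.assert_allclose(weights.sum(axis=-1), 1.0, atol=1e-5)
        assert (weights >= 0).all()

    def test_single_key_token_reduces_to_value_projection(self):
        cva = CrossViewAttention(4, _rng(8))
        x = Tensor(_rng(9).normal(size=(1, 3, 4)).astype(np.float32))
        y = Tensor(_rng(10).normal(size=(1, 1, 4)).astype(np.float32))
        out = cva(x, y).data
        zv_y = (y @ cva.z_v.weight).data
        np.testing.assert_allclose(out, np.repeat(zv_y, 3, axis=1), atol=1e-5)

    def test_two_token_hand_computed_softmax(self):
        """With identity projections the attention weights and output follow
        from plain softmax arithmetic."""
        cva = CrossViewAttention(2, _rng(11))
        eye = np.eye(2, dtype=np.float32)
        cva.z_q.weight.data[...] = eye
        cva.z_k.weight.data[...] = eye
        cva.z_v.weight.data[...] = eye
        x = Tensor(np.array([[[1.0, 0.0]]], dtype=np.float32))
        y = Tensor(np.array([[[1.0, 0.0], [0.0, 1.0]]], dtype=np.float32))
        scores = np.array([1.0, 0.0]) / np.sqrt(2.0)  # d_k = 2
        expected_w = np.exp(scores) / np.exp(scores).sum()
        weights = cva.attention_weights(x, y).data[0, 0]
        np.testing.assert_allclose(weights, expected_w, atol=1e-6)
        expected_out = expected_w @ y.data[0]
        np.testing.assert_allclose(cva(x, y).data[0, 0], expected_out, atol=1e-6)


class TestAdjacentViewFusion:
    def test_identity_projection_equals_plain_cva(self):
        fusion = AdjacentViewFusion(4, 4, _rng(12))
        fusion.z_proj.weight.data[...] = np.eye(4, dtype=np.float32)
        a_i = Tensor(_rng(13).normal(size=(1, 3, 4)).astype(np.float32))
        a_i1 = Tensor(_rng(14).normal(size=(1, 5, 4)).astype(np.float32))
        np.testing.assert_allclose(fusion(a_i, a_i1).data, fusion.cva(a_i, a_i1).data, atol=1e-6)

    def test_output_length_and_dim_follow_query_side(self):
        fusion = AdjacentViewFusion(2, 4, _rng(15))
        a_i = Tensor(_rng(16).normal(size=(2, 7, 2)).astype(np.float32))
        a_i1 = Tensor(_rng(17).normal(size=(2, 9, 4)).astype(np.float32))
        assert fusion(a_i, a_i1).shape == (2, 7, 2)

    def test_matches_by_hand_matrix_products(self):
        """Dims 4 -> 2 toy checked against an explicit float64 oracle."""
        fusion = AdjacentViewFusion(2, 4, _rng(18))
        a_i = _rng(19).normal(size=(1, 2, 2))
        a_i1 = _rng(20).normal(size=(1, 3, 4))
        out = fusion(Tensor(a_i.astype(np.float32)), Tensor(a_i1.astype(np.float32))).data

        proj = a_i1[0] @ fusion.z_proj.weight.data.astype(np.float64)
        q = a_i[0] @ fusion.cva.z_q.weight.data.astype(np.float64)
        k = proj @ fusion.cva.z_k.weight.data.astype(np.float64)
        v = proj @ fusion.cva.z_v.weight.data.astype(np.float64)
        scores = q @ k.T / np.sqrt(2.0)
        w = np.exp(scores - scores.max(axis=1, keepdims=True))
        w /= w.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(out[0], w @ v, atol=1e-5)


class TestEncoderBlock:
    def test_zeroed_sublayer_outputs_make_identity(self):
        block = EncoderBlock(6, 2, _rng(21))
        block.attn.out.weight.data[...] = 0.0
        block.attn.out.bias.data[...] = 0.0
        block.fc2.weight.data[...] = 0.0
        block.fc2.bias.data[...] = 0.0
        x = Tensor(_rng(22).normal(size=(2, 5, 6)).astype(np.float32))
        np.testing.assert_allclose(block(x).data, x.data, atol=1e-6)

    def test_shape_preserved(self):
        block = EncoderBlock(8, 2, _rng(23))
        x = Tensor(np.zeros((3, 10, 8), dtype=np.float32))
        assert block(x).shape == (3, 10, 8)

    def test_matches_by_hand_prenorm_oracle(self):
        """Single-head (2, 2) toy reproduced step by step in float64."""
        block = EncoderBlock(2, 1, _rng(24), mlp_ratio=2.0)
        x64 = _rng(25).normal(size=(1, 2, 2))
        out = block(Tensor(x64.astype(np.float32))).data

        def layernorm(a, w, b):
            mu = a.mean(-1, keepdims=True)
            var = a.var(-1, keepdims=True)
            return (a - mu) / np.sqrt(var + 1e-5) * w + b

        def gelu(a):
            from scipy.special import erf

            return a * 0.5 * (1 + erf(a / np.sqrt(2)))

        h = layernorm(x64[0], block.norm1.weight.data, block.norm1.bias.data)
        qkv = h @ block.attn.qkv.weight.data.astype(np.float64) + block.attn.qkv.bias.data
        q, k, v = qkv[:, 0:2], qkv[:, 2:4], qkv[:, 4:6]
        scores = q @ k.T / np.sqrt(2.0)
        w = np.exp(scores - scores.max(axis=1, keepdims=True))
        w /= w.sum(axis=1, keepdims=True)
        att = (w @ v) @ block.attn.out.weight.data.astype(np.float64) + block.attn.out.bias.data
        y = att + x64[0]
        h2 = layernorm(y, block.norm2.weight.data, block.norm2.bias.data)
        mlp = gelu(h2 @ block.fc1.weight.data.astype(np.float64) + block.fc1.bias.data)
        mlp = mlp @ block.fc2.weight.data.astype(np.float64) + block.fc2.bias.data
        np.testing.assert_allclose(out[0], mlp + y, atol=5e-5)


@pytest.fixture(scope="module")
def tiny_mvt():
    return MultiViewTransformer(
        4, 32, _rng(26), patch_size=8, view_dims=(8, 12, 16),
        layers_per_view=1, global_dim=16, global_depth=3, heads=2, tap_layer=3,
    )


class TestMultiViewForward:

    def test_feature_map_is_square_grid_of_patch_tokens(self, tiny_mvt):
        tiny_mvt.eval()
        out = mvt_forward(tiny_mvt, np.zeros((2, 3, 32, 32), dtype=np.float32))
        assert out.feature_map.shape == (2, 16, 4, 4)
        assert out.logits.shape == (2, 4)

    def test_batch_independence_under_permutation(self, tiny_mvt):
        tiny_mvt.eval()
        batch = _rng(27).random((2, 3, 32, 32), dtype=np.float32)
        fwd = mvt_forward(tiny_mvt, batch).logits.data
        swapped = mvt_forward(tiny_mvt, batch[::-1].copy()).logits.data
        np.testing.assert_allclose(swapped, fwd[::-1], atol=1e-5)

    def test_gradients_reach_embedding_projections_and_zproj(self, tiny_mvt):
        tiny_mvt.train()
        out = tiny_mvt(Tensor(_rng(28).random((1, 3, 32, 32), dtype=np.float32)))
        (out.logits**2).sum().backward()
        probes = {
            "patch projection E": tiny_mvt.patch_embed.proj.weight,
            "positional embedding q": tiny_mvt.patch_embed.pos_embed,
            "class token": tiny_mvt.patch_embed.class_token,
            "Z_proj": tiny_mvt.fusions[0].z_proj.weight,
            "CVA Z_Q": tiny_mvt.fusions[0].cva.z_q.weight,
        }
        for name, p in probes.items():
            assert p.grad is not None and np.abs(p.grad).sum() > 0, f"no gradient at {name}"

    def test_single_view_degrades_to_plain_transformer(self):
        mvt = MultiViewTransformer(
            3, 32, _rng(29), patch_size=8, view_dims=(16,),
            layers_per_view=1, global_dim=16, global_depth=3, heads=2,
        )
        mvt.eval()
        out = mvt_forward(mvt, np.zeros((1, 3, 32, 32), dtype=np.float32))
        assert len(mvt.fusions) == 0
        assert out.logits.shape == (1, 3)
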