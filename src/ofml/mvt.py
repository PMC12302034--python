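"""Multi-view transformer global-context branch.

The image is embedded into a token sequence (patch tokens + a learnable
class token + a learnable positional embedding).  Several view-specific
encoder stacks with *different hidden widths* process the sequence in
parallel; adjacent views are then fused by cross-view attention (CVA) —
attention whose queries come from view i while keys/values come from view
i+1 after a learnable dimension-matching projection.  The adjacent pairs
are chained from the deepest view down, so the final fused sequence (at
view 1's width) aggregates every view; it enters a global pre-norm
transformer encoder, whose
class token feeds the classification head and whose tapped layer provides
the spatial feature map handed to the fusion classifier (class token
dropped, patch tokens reshaped to a square grid).
"""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor, concat, nn
from .cnn import BranchOutput
from .exceptions import ConfigurationError, DataError


class PatchEmbed(nn.Module):
    """Tokenize an image: split into Q x Q patches, project linearly to
    dimension d, prepend a class token and add a learnable positional
    embedding.  N = (H/Q) * (W/Q) patches."""

    def __init__(self, image_size: int, patch_size: int, dim: int, rng: np.random.Generator):
        super().__init__()
        if image_size % patch_size:
            raise DataError(f"image size {image_size} not divisible by patch size {patch_size}")
        self.patch_size = patch_size
        self.image_size = image_size
        self.dim = dim
        self.n_patches = (image_size // patch_size) ** 2
        self.proj = nn.Linear(patch_size * patch_size * 3, dim, rng)
        self.class_token = nn.Parameter(rng.normal(0, 0.02, size=(1, 1, dim)).astype(np.float32))
        self.pos_embed = nn.Parameter(rng.normal(0, 0.02, size=(1, self.n_patches + 1, dim)).astype(np.float32))

    def forward(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        q = self.patch_size
        if h % q or w % q:
            raise DataError(f"input {h}x{w} not divisible by patch size {q}")
        gh, gw = h // q, w // q
        patches = (
            x.reshape(b, c, gh, q, gw, q)
            .transpose(0, 2, 4, 3, 5, 1)  # (B, gh, gw, q, q, C)
            .reshape(b, gh * gw, q * q * c)
        )
        tokens = self.proj(patches)  # (B, N, d)
        cls = self.class_token + Tensor(np.zeros((b, 1, self.dim), dtype=np.float32))
        sequence = concat([cls, tokens], axis=1)
        return sequence + self.pos_embed


class MultiHeadSelfAttention(nn.Module):
    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % heads:
            raise ConfigurationError(f"dim {dim} not divisible by heads {heads}")
        self.heads = heads
        self.head_dim = dim // heads
        self.qkv = nn.Linear(dim, 3 * dim, rng)
        self.out = nn.Linear(dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        b, n, d = x.shape
        qkv = self.qkv(x)  # (B, N, 3d)
        qkv = qkv.reshape(b, n, 3, self.heads, self.head_dim).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]  # (B, h, N, dh)
        scale = 1.0 / math.sqrt(self.head_dim)
        attn = ((q @ k.swapaxes(-1, -2)) * scale).softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(b, n, d)
        return self.out(out)


class EncoderBlock(nn.Module):
    """Pre-norm residual transformer block:
    y = MSA(LN(x)) + x;  out = MLP(LN(y)) + y, with a GELU between the two
    linear maps of the MLP."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator, mlp_ratio: float = 2.0):
        super().__init__()
        hidden = int(dim * mlp_ratio)
        self.norm1 = nn.LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, heads, rng)
        self.norm2 = nn.LayerNorm(dim)
        self.fc1 = nn.Linear(dim, hidden, rng)
        self.fc2 = nn.Linear(hidden, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        y = self.attn(self.norm1(x)) + x
        out = self.fc2(self.fc1(self.norm2(y)).gelu()) + y
        return out


class CrossViewAttention(nn.Module):
    """Single-head attention where queries come from sequence x and
    keys/values from sequence y:  softmax(Z_Q x (Z_K y)^T / sqrt(d_k)) Z_V y."""

    def __init__(self, dim: int, rng: np.random.Generator, d_k: int | None = None):
        super().__init__()
        self.d_k = d_k or dim
        self.z_q = nn.Linear(dim, self.d_k, rng, bias=False)
        self.z_k = nn.Linear(dim, self.d_k, rng, bias=False)
        self.z_v = nn.Linear(dim, dim, rng, bias=False)

    def attention_weights(self, x: Tensor, y: Tensor) -> Tensor:
        if x.shape[-1] != y.shape[-1]:
            raise ConfigurationError(f"CVA dim mismatch: {x.shape[-1]} vs {y.shape[-1]}")
        scores = (self.z_q(x) @ self.z_k(y).swapaxes(-1, -2)) * (1.0 / math.sqrt(self.d_k))
        return scores.softmax(axis=-1)

    def forward(self, x: Tensor, y: Tensor) -> Tensor:
        return self.attention_weights(x, y) @ self.z_v(y)


class ViewEncoder(nn.Module):
    """One view: an input width-projection followed by L encoder layers."""

    def __init__(self, in_dim: int, dim: int, layers: int, heads: int, rng):
        super().__init__()
        self.project = None if in_dim == dim else nn.Linear(in_dim, dim, rng)
        self.blocks = nn.ModuleList([EncoderBlock(dim, heads, rng) for _ in range(layers)])

    def forward(self, x: Tensor) -> Tensor:
        if self.project is not None:
            x = self.project(x)
        for block in self.blocks:
            x = block(x)
        return x


class AdjacentViewFusion(nn.Module):
    """Fuse view i with view i+1:  CVA(A_i, Z_proj A_{i+1}), where Z_proj is
    the learnable map matching view (i+1)'s width to view i's."""

    def __init__(self, dim_i: int, dim_i1: int, rng):
        super().__init__()
        self.z_proj = nn.Linear(dim_i1, dim_i, rng, bias=False)
        self.cva = CrossViewAttention(dim_i, rng)

    def forward(self, a_i: Tensor, a_i1: Tensor) -> Tensor:
        return self.cva(a_i, self.z_proj(a_i1))


class MultiViewTransformer(nn.Module):
    """The full global branch.

    Parameters default to three views of widths (256, 384, 512) with 4
    layers each, an 8-head global encoder of depth 4 and width 512, patch
    size 16 and tap layer 3 — giving the (512, 14, 14) tapped map at
    224 px input.  ``view_dims`` of length 1 degrades gracefully to a plain
    single-view transformer (no cross-view fusion), which the ablation
    variants use.
    """

    def __init__(
        self,
        num_classes: int,
        image_size: int,
        rng: np.random.Generator,
        patch_size: int = 16,
        view_dims: tuple[int, ...] = (256, 384, 512),
        layers_per_view: int = 4,
        global_dim: int = 512,
        global_depth: int = 4,
        heads: int = 8,
        tap_layer: int = 3,
    ):
        super().__init__()
        if not 1 <= tap_layer <= global_depth:
            raise ConfigurationError(f"tap_layer {tap_layer} deeper than global encoder depth {global_depth}")
        self.view_dims = tuple(view_dims)
        self.tap_layer = tap_layer
        self.global_dim = global_dim
        embed_dim = view_dims[0]
        self.patch_embed = PatchEmbed(image_size, patch_size, embed_dim, rng)
        self.views = nn.ModuleList(
            [ViewEncoder(embed_dim, d, layers_per_view, heads, rng) for d in view_dims]
        )
        self.fusions = nn.ModuleList(
            [AdjacentViewFusion(view_dims[i], view_dims[i + 1], rng) for i in range(len(view_dims) - 1)]
        )
        last_dim = view_dims[0]
        self.to_global = None if last_dim == global_dim else nn.Linear(last_dim, global_dim, rng)
        self.global_blocks = nn.ModuleList([EncoderBlock(global_dim, heads, rng) for _ in range(global_depth)])
        self.norm = nn.LayerNorm(global_dim)
        self.head = nn.Linear(global_dim, num_classes, rng)

    def forward(self, x: Tensor) -> BranchOutput:
        tokens = self.patch_embed(x)
        encoded = [view(tokens) for view in self.views]
        # chain adjacent-view fusion from the deepest view down: the running
        # sequence carries view (i+1) information into CVA at view i, so every
        # view and every Z_proj contributes to the fused output (dim = view 1)
        seq = encoded[-1]
        for i in range(len(self.fusions) - 1, -1, -1):
            seq = self.fusions[i](encoded[i], seq)
        if self.to_global is not None:
            seq = self.to_global(seq)
        tapped = None
        for layer_idx, block in enumerate(self.global_blocks, start=1):
            seq = block(seq)
            if layer_idx == self.tap_layer:
                tapped = seq
        cls = self.norm(seq[:, 0])
        logits = self.head(cls)
        patch_tokens = tapped[:, 1:]  # drop the class token before the spatial reshape
        b, n, d = patch_tokens.shape
        side = int(round(math.sqrt(n)))
        feature_map = patch_tokens.transpose(0, 2, 1).reshape(b, d, side, side)
        return BranchOutput(logits=logits, feature_map=feature_map)


def mvt_forward(model: MultiViewTransformer, batch) -> BranchOutput:
    """Run the transformer branch on a (B, 3, H, W) batch."""
    if not isinstance(batch, Tensor):
        batch = Tensor(batch)
    return model(batch)
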