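"""Per-branch transformer encoders and the cross-attention fusion module.

The cross-attention fusion module (CAFM) exchanges information between the
two modality branches through their class tokens only: the MRI class token
queries the PET patch tokens and vice versa.  Because a single query row is
used per head, the attention map has h*(N+1) entries — linear rather than
quadratic in the number of patch tokens.
"""

from __future__ import annotations

import numpy as np

from .nn import LayerNorm, Linear, Module, Tensor, concat
from .types import TokenSequence

__all__ = [
    "MultiHeadSelfAttention", "MultiHeadCrossAttention", "FeedForward",
    "EncoderBlock", "CafmSubBlock", "CAFM",
]


def _split_heads(x: Tensor, h: int) -> Tensor:
    """(L, D) -> (h, L, D/h)."""
    L, d = x.shape
    return x.reshape(L, h, d // h).transpose(1, 0, 2)


def _merge_heads(x: Tensor) -> Tensor:
    """(h, L, D/h) -> (L, D)."""
    h, L, dh = x.shape
    return x.transpose(1, 0, 2).reshape(L, h * dh)


class MultiHeadSelfAttention(Module):
    """Standard multi-head self-attention over a token sequence.

    The last attention map is kept (as a plain array) on ``last_attn`` with
    shape (h, L, L) for inspection of cost and normalization properties.
    """

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % heads:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        self.heads = heads
        self.scale = 1.0 / np.sqrt(dim // heads)
        self.q_proj = Linear(dim, dim, rng)
        self.k_proj = Linear(dim, dim, rng)
        self.v_proj = Linear(dim, dim, rng)
        self.out_proj = Linear(dim, dim, rng)
        self.last_attn: np.ndarray | None = None

    def forward(self, x: Tensor) -> Tensor:
        q = _split_heads(self.q_proj(x), self.heads)
        k = _split_heads(self.k_proj(x), self.heads)
        v = _split_heads(self.v_proj(x), self.heads)
        attn = ((q @ k.transpose(0, 2, 1)) * self.scale).softmax(axis=-1)
        self.last_attn = attn.data
        return self.out_proj(_merge_heads(attn @ v))


class MultiHeadCrossAttention(Module):
    """MCA: a class token queries [cls || other-branch patches].

    q is built from the class token alone; k and v from the concatenated
    sequence, so the per-head attention map is a single row of length N+1.
    Heads are concatenated and output-projected.
    """

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % heads:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        self.heads = heads
        self.scale = 1.0 / np.sqrt(dim // heads)
        self.q_proj = Linear(dim, dim, rng)
        self.k_proj = Linear(dim, dim, rng)
        self.v_proj = Linear(dim, dim, rng)
        self.out_proj = Linear(dim, dim, rng)
        self.last_attn: np.ndarray | None = None

    def forward(self, cls: Tensor, other_patches: Tensor) -> Tensor:
        if cls.shape[1] != other_patches.shape[1]:
            raise ValueError(
                f"branch dimensions differ: class token D={cls.shape[1]}, "
                f"other-branch patches D={other_patches.shape[1]}")
        x = concat([cls, other_patches], axis=0)          # (N+1, D)
        q = _split_heads(self.q_proj(cls), self.heads)    # (h, 1, D/h)
        k = _split_heads(self.k_proj(x), self.heads)
        v = _split_heads(self.v_proj(x), self.heads)
        attn = ((q @ k.transpose(0, 2, 1)) * self.scale).softmax(axis=-1)
        self.last_attn = attn.data                        # (h, 1, N+1)
        return self.out_proj(_merge_heads(attn @ v))      # (1, D)


class FeedForward(Module):
    """Two linear layers with a nonlinearity, widening each token by
    ``ffn_mult`` before projecting back."""

    def __init__(self, dim: int, ffn_mult: int, rng: np.random.Generator,
                 activation: str = "gelu"):
        super().__init__()
        self.fc1 = Linear(dim, ffn_mult * dim, rng)
        self.fc2 = Linear(ffn_mult * dim, dim, rng)
        self.activation = activation

    def forward(self, x: Tensor) -> Tensor:
        h = self.fc1(x)
        h = h.gelu() if self.activation == "gelu" else h.relu()
        return self.fc2(h)


class EncoderBlock(Module):
    """Conventional pre-norm transformer encoder: MHSA + FFN with residuals."""

    def __init__(self, dim: int, heads: int, ffn_mult: int,
                 rng: np.random.Generator, activation: str = "gelu"):
        super().__init__()
        self.norm1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, heads, rng)
        self.norm2 = LayerNorm(dim)
        self.ffn = FeedForward(dim, ffn_mult, rng, activation)

    def forward(self, seq: TokenSequence) -> TokenSequence:
        x = seq.tokens
        x = x + self.attn(self.norm1(x))
        x = x + self.ffn(self.norm2(x))
        return TokenSequence(x)


class CafmSubBlock(Module):
    """One direction of CAFM: own class token attends over the other
    branch's patches, then an FFN stage refines the recombined sequence.

    The attention stage touches only the class token — own patch tokens are
    concatenated back unchanged.  The FFN stage applies
    ``LN(FFN(LN(z)) + z)`` literally (inner pre-norm, outer norm on the
    residual sum); set ``conventional_prenorm`` for the standard
    ``z + FFN(LN(z))`` form instead.
    """

    def __init__(self, dim: int, heads: int, ffn_mult: int,
                 rng: np.random.Generator, activation: str = "gelu",
                 conventional_prenorm: bool = False):
        super().__init__()
        self.mca = MultiHeadCrossAttention(dim, heads, rng)
        self.norm_inner = LayerNorm(dim)
        self.ffn = FeedForward(dim, ffn_mult, rng, activation)
        self.norm_outer = LayerNorm(dim)
        self.conventional_prenorm = conventional_prenorm

    def attention_stage(self, own: TokenSequence,
                        other: TokenSequence) -> Tensor:
        """y_cls = cls + MCA(cls, other patches); z = [y_cls || own patches]."""
        y_cls = own.cls + self.mca(own.cls, other.patches)
        return concat([y_cls, own.patches], axis=0)

    def forward(self, own: TokenSequence, other: TokenSequence) -> TokenSequence:
        z = self.attention_stage(own, other)
        if self.conventional_prenorm:
            out = z + self.ffn(self.norm_inner(z))
        else:
            out = self.norm_outer(self.ffn(self.norm_inner(z)) + z)
        return TokenSequence(out)


class CAFM(Module):
    """Symmetric cross-attention fusion: one sub-block per direction.

    Both directions read the *input* sequences, so the module has no order
    dependence between branches.
    """

    def __init__(self, dim: int, heads: int, ffn_mult: int,
                 rng: np.random.Generator, activation: str = "gelu",
                 conventional_prenorm: bool = False):
        super().__init__()
        self.mri_block = CafmSubBlock(dim, heads, ffn_mult, rng, activation,
                                      conventional_prenorm)
        self.pet_block = CafmSubBlock(dim, heads, ffn_mult, rng, activation,
                                      conventional_prenorm)

    def forward(self, mri_seq: TokenSequence,
                pet_seq: TokenSequence) -> tuple[TokenSequence, TokenSequence]:
        mri_out = self.mri_block(mri_seq, pet_seq)
        pet_out = self.pet_block(pet_seq, mri_seq)
        return mri_out, pet_out
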