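"""Reshape-Pooling-Reshape (RPR): graph-based token pruning.

Patch tokens are recast as a graph whose adjacency links token pairs whose
Euclidean distance falls below the mean pairwise distance (tokens-to-graph,
T2G).  Vertices are scored two ways — a one-layer graph convolution over
the structure (SBLM) and a per-vertex feature scorer (FBLM) — and the two
scores are combined (SFLM).  A graph-attention layer fuses neighborhood
features over the *full* graph before any vertex is discarded, the top-k
vertices by combined score are retained (k = max(1, floor(r*N))), and the
surviving features are reassembled into a token sequence with the carried
class token and a fresh positional encoding (graph-to-tokens, G2T).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .nn import (BatchNorm1d, Linear, Module, Tensor, concat, trunc_normal)
from .types import TokenSequence

__all__ = [
    "TokenGraph", "PooledGraph", "tokens_to_graph", "top_k_pool",
    "graph_to_tokens", "SBLM", "FBLM", "SFLM", "GATFusion", "RPR",
    "pooled_size",
]


def pooled_size(n: int, r: float) -> int:
    """Number of vertices kept from n at pooling rate r."""
    return max(1, int(np.floor(r * n)))


@dataclass
class TokenGraph:
    """Vertex features plus binary adjacency built from patch tokens."""

    features: Tensor          # (N, D)
    adjacency: np.ndarray     # (N, N) in {0, 1}
    mean_distance: float = 0.0

    @property
    def n_vertices(self) -> int:
        return self.features.shape[0]


@dataclass
class PooledGraph:
    """Top-k subgraph: surviving vertices in ascending original order."""

    kept_indices: np.ndarray  # (k,) strictly increasing
    features: Tensor          # (k, D), post-fusion rows
    adjacency: np.ndarray     # (k, k) submatrix


def tokens_to_graph(patches: Tensor | np.ndarray) -> TokenGraph:
    """Build the thresholded-distance graph over patch tokens.

    dist_ij is the l2 distance between token rows; the threshold mu is the
    mean over all N^2 entries of the distance matrix (the zero diagonal
    included); A_ij = 1 iff dist_ij < mu (strict).  When every token is
    identical mu = 0 and no edge passes the threshold; the adjacency falls
    back to the identity so that downstream stages stay well-defined.
    """
    feats = patches if isinstance(patches, Tensor) else Tensor(patches)
    n = feats.shape[0]
    if n < 2:
        raise ValueError(f"need at least 2 patch tokens to build a graph, got {n}")
    x = feats.data
    dist = cdist(x, x)
    mu = dist.mean()
    if mu > 0:
        adj = (dist < mu).astype(np.int64)
    else:
        adj = np.eye(n, dtype=np.int64)
    return TokenGraph(features=feats, adjacency=adj, mean_distance=float(mu))


class SBLM(Module):
    """Structure-based scorer: sigmoid of a symmetric-normalized one-layer
    graph convolution, s1 = sigmoid(Deg^{-1/2} A Deg^{-1/2} X w).

    Thresholding already puts self-loops on the adjacency whenever mu > 0;
    ``add_self_loops`` forces them in any case.  Degrees of isolated
    vertices are clamped to 1 before inversion.
    """

    def __init__(self, dim: int, rng: np.random.Generator,
                 add_self_loops: bool = False):
        super().__init__()
        self.weight = Tensor(trunc_normal(rng, (dim, 1)), requires_grad=True)
        self.add_self_loops = add_self_loops

    def propagation_matrix(self, adjacency: np.ndarray) -> np.ndarray:
        a = adjacency.astype(np.float64)
        if self.add_self_loops:
            np.fill_diagonal(a, 1.0)
        deg = np.maximum(a.sum(axis=1), 1.0)
        inv_sqrt = 1.0 / np.sqrt(deg)
        return inv_sqrt[:, None] * a * inv_sqrt[None, :]

    def forward(self, graph: TokenGraph) -> Tensor:
        prop = Tensor(self.propagation_matrix(graph.adjacency))
        s1 = (prop @ graph.features @ self.weight).sigmoid()
        return s1.reshape(-1)


class FBLM(Module):
    """Feature-based scorer.

    The default ("conv") form is the 1-D convolution over the feature axis
    — one learned D-kernel mapping each vertex feature vector to a scalar —
    followed by batch normalization over vertices and a sigmoid.  The
    "mlp" variant (the FBLM* ablation arm) scores each vertex with a
    two-layer perceptron instead.
    """

    def __init__(self, dim: int, rng: np.random.Generator,
                 variant: str = "conv"):
        super().__init__()
        if variant not in ("conv", "mlp"):
            raise ValueError(f"unknown FBLM variant {variant!r}")
        self.variant = variant
        if variant == "conv":
            self.conv = Linear(dim, 1, rng)
            self.bn = BatchNorm1d(1)
        else:
            hidden = max(dim // 4, 4)
            self.fc1 = Linear(dim, hidden, rng)
            self.fc2 = Linear(hidden, 1, rng)

    def forward(self, features: Tensor) -> Tensor:
        if self.variant == "conv":
            s2 = self.bn(self.conv(features)).sigmoid()
        else:
            s2 = self.fc2(self.fc1(features).gelu()).sigmoid()
        return s2.reshape(-1)


class SFLM(Module):
    """Score combiner: s = BN(Conv(s1 + s2)).

    The 1-D convolution acts per vertex (kernel size 1) so the combined
    score stays permutation-equivariant.  The "linear" variant (SFLM*)
    replaces it with a learned weighted sum alpha*s1 + beta*s2.  No final
    nonlinearity is applied — ranking uses the raw combined score.
    """

    def __init__(self, rng: np.random.Generator, variant: str = "conv"):
        super().__init__()
        if variant not in ("conv", "linear"):
            raise ValueError(f"unknown SFLM variant {variant!r}")
        self.variant = variant
        if variant == "conv":
            self.conv = Linear(1, 1, rng, std=0.5)
            self.bn = BatchNorm1d(1)
        else:
            self.alpha = Tensor(np.array([0.5]), requires_grad=True)
            self.beta = Tensor(np.array([0.5]), requires_grad=True)

    def forward(self, s1: Tensor, s2: Tensor) -> Tensor:
        if s1.shape != s2.shape:
            raise ValueError(f"score length mismatch: {s1.shape} vs {s2.shape}")
        if self.variant == "conv":
            coarse = (s1 + s2).reshape(-1, 1)
            return self.bn(self.conv(coarse)).reshape(-1)
        return self.alpha * s1 + self.beta * s2


class GATFusion(Module):
    """Multi-head graph-attention feature fusion over the full graph.

    Per head: e_ij = LeakyReLU(a_src.Wh_i + a_dst.Wh_j) masked to the
    neighborhood given by the adjacency (self included), softmax-normalized
    per vertex; outputs are head-averaged and passed through the
    nonlinearity.  Applied to all vertices *before* pooling, so vertices
    that will be discarded still contribute to their neighbors.
    """

    NEG_INF = -1e9

    def __init__(self, dim: int, heads: int, rng: np.random.Generator,
                 negative_slope: float = 0.2, activation: str = "gelu"):
        super().__init__()
        self.heads = heads
        self.negative_slope = negative_slope
        self.activation = activation
        self.w = [Linear(dim, dim, rng, bias=False) for _ in range(heads)]
        for i, lin in enumerate(self.w):
            self._modules[f"w{i}"] = lin
        self.a_src = Tensor(trunc_normal(rng, (heads, dim)), requires_grad=True)
        self.a_dst = Tensor(trunc_normal(rng, (heads, dim)), requires_grad=True)
        self.last_attn: np.ndarray | None = None

    def attention_coefficients(self, graph: TokenGraph) -> list[Tensor]:
        """Per-head (N, N) neighborhood-normalized attention matrices."""
        adj = graph.adjacency.copy()
        np.fill_diagonal(adj, 1)  # every vertex attends at least to itself
        mask = np.where(adj > 0, 0.0, self.NEG_INF)
        coeffs = []
        for k in range(self.heads):
            h = self.w[k](graph.features)                     # (N, D)
            s = h @ self.a_src[k].reshape(-1, 1)              # (N, 1)
            t = h @ self.a_dst[k].reshape(-1, 1)              # (N, 1)
            logits = (s + t.transpose()).leaky_relu(self.negative_slope)
            coeffs.append((logits + Tensor(mask)).softmax(axis=-1))
        return coeffs

    def forward(self, graph: TokenGraph) -> Tensor:
        coeffs = self.attention_coefficients(graph)
        self.last_attn = np.stack([c.data for c in coeffs])
        agg = None
        for k, alpha in enumerate(coeffs):
            out = alpha @ self.w[k](graph.features)
            agg = out if agg is None else agg + out
        agg = agg * (1.0 / self.heads)
        return agg.gelu() if self.activation == "gelu" else agg.relu()


def top_k_pool(graph: TokenGraph, scores: np.ndarray | Tensor, r: float,
               fused_features: Tensor | None = None) -> PooledGraph:
    """Retain the k = max(1, floor(r*N)) highest-scoring vertices.

    Ties break toward the lower original index; kept indices are returned
    in ascending original order so the raster order of surviving tokens is
    preserved.  ``fused_features`` (post-fusion rows) are selected if
    given, otherwise the graph's own features.
    """
    if not 0.0 < r <= 1.0:
        raise ValueError(f"pooling rate r must be in (0, 1], got {r}")
    s = scores.data if isinstance(scores, Tensor) else np.asarray(scores)
    n = graph.n_vertices
    if s.shape != (n,):
        raise ValueError(f"scores shape {s.shape} does not match {n} vertices")
    k = pooled_size(n, r)
    order = np.argsort(-s, kind="stable")   # stable: ties keep lower index first
    kept = np.sort(order[:k])
    feats = fused_features if fused_features is not None else graph.features
    return PooledGraph(
        kept_indices=kept,
        features=feats[kept],
        adjacency=graph.adjacency[np.ix_(kept, kept)],
    )


def graph_to_tokens(pooled: PooledGraph, cls: Tensor,
                    pos_embed: Tensor) -> TokenSequence:
    """Reassemble [cls || X'] + PE into a (k+1, D) token sequence.

    The class token is the one carried around the pooling stage unchanged —
    it never enters the graph.
    """
    k, d = pooled.features.shape
    if pos_embed.shape != (k + 1, d):
        raise ValueError(f"positional encoding shape {pos_embed.shape} "
                         f"does not match pooled sequence ({k + 1}, {d})")
    if cls.shape != (1, d):
        raise ValueError(f"class token shape {cls.shape} != (1, {d})")
    seq = concat([cls, pooled.features], axis=0) + pos_embed
    return TokenSequence(seq)


class RPR(Module):
    """One full Reshape-Pooling-Reshape stage for a known input length.

    The number of surviving tokens is fixed by the deterministic schedule
    (it depends only on the input length and r), so the stage owns a
    learned positional encoding of exactly that size.
    """

    def __init__(self, dim: int, n_patches_in: int, r: float,
                 rng: np.random.Generator, gat_heads: int = 2,
                 fblm_variant: str = "conv", sflm_variant: str = "conv",
                 add_self_loops: bool = False, activation: str = "gelu"):
        super().__init__()
        self.r = r
        self.n_patches_in = n_patches_in
        self.n_patches_out = pooled_size(n_patches_in, r)
        self.sblm = SBLM(dim, rng, add_self_loops=add_self_loops)
        self.fblm = FBLM(dim, rng, variant=fblm_variant)
        self.sflm = SFLM(rng, variant=sflm_variant)
        self.fusion = GATFusion(dim, gat_heads, rng, activation=activation)
        self.pos_embed = Tensor(
            trunc_normal(rng, (self.n_patches_out + 1, dim)),
            requires_grad=True)

    def forward(self, seq: TokenSequence) -> TokenSequence:
        if seq.length < 3:
            raise ValueError(
                f"RPR needs a class token plus >= 2 patches, got length {seq.length}")
        if seq.length - 1 != self.n_patches_in:
            raise ValueError(
                f"RPR built for {self.n_patches_in} patches, got {seq.length - 1}")
        graph = tokens_to_graph(seq.patches)
        s1 = self.sblm(graph)
        s2 = self.fblm(graph.features)
        scores = self.sflm(s1, s2)
        fused = self.fusion(graph)
        pooled = top_k_pool(graph, scores, self.r, fused_features=fused)
        return graph_to_tokens(pooled, seq.cls, self.pos_embed)
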