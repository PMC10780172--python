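"""Neural building blocks: view encoders and the cascade attention classifier.

Each view encoder is a graph autoencoder whose encoder stacks three
GCN-MLP blocks,

    H_l = ReLU( norm @ H_{l-1} @ W_gcn  +  H_{l-1} @ W_mlp + b ),

where ``norm`` is the renormalized propagation matrix of the view. The
parallel fully-connected branch counteracts over-smoothing: even if repeated
graph convolution drives node features together, the MLP path preserves
per-node information. The decoder scores every node pair by the inner
product of its latent embeddings, ``sigmoid(Z Z^T)``, and the autoencoder is
trained to reconstruct the view adjacency under mean binary cross-entropy.

The classifier consumes a per-pair feature vector

    F = concat( z_mdm[i],  (z_local[i] (+) z_local[j]) + (z_global[i] (+) z_global[j]),  z_dmd[j] ),

where ``(+)`` is concatenation of the miRNA and disease node embeddings and
the local and global pair blocks are summed elementwise. F passes through a
tapering stack of fully-connected layers whose intermediate activations are
projected to a common width, fused by a layer attention (softmax-normalized
mixing across the three hierarchy levels) and refined by a gate-structured
feature attention, before a sigmoid prediction head.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, bce, bce_with_logits, concat, parameter, stack, tensor

__all__ = [
    "glorot",
    "GCNMLPBlock",
    "ViewEncoder",
    "decode_inner_product",
    "reconstruction_loss",
    "assemble_pair_features",
    "CascadeClassifier",
]


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> Tensor:
    """Glorot/Xavier-uniform initialized parameter matrix."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return parameter(rng.uniform(-limit, limit, size=(fan_in, fan_out)))


class GCNMLPBlock:
    """One GCN-MLP block: ReLU(norm @ H @ W_gcn + H @ W_mlp + b).

    The MLP branch is a single fully-connected layer with the same output
    width as the graph-convolution branch, so the two terms sum elementwise.
    """

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W_gcn = glorot(rng, d_in, d_out)
        self.W_mlp = glorot(rng, d_in, d_out)
        self.b = parameter(np.zeros(d_out))

    def __call__(self, norm, H):
        norm = tensor(norm)
        H = tensor(H)
        if H.shape[-1] != self.W_gcn.shape[0]:
            raise ValueError(
                f"feature width {H.shape[-1]} does not match block input "
                f"width {self.W_gcn.shape[0]}"
            )
        return ((norm @ H) @ self.W_gcn + H @ self.W_mlp + self.b).relu()

    def parameters(self):
        return [self.W_gcn, self.W_mlp, self.b]


class ViewEncoder:
    """Three stacked GCN-MLP blocks producing latent embeddings Z."""

    n_blocks = 3

    def __init__(self, d_in: int, latent_dim: int, rng: np.random.Generator):
        self.latent_dim = latent_dim
        dims = [d_in] + [latent_dim] * self.n_blocks
        self.blocks = [
            GCNMLPBlock(dims[i], dims[i + 1], rng) for i in range(self.n_blocks)
        ]

    def __call__(self, norm, X0) -> Tensor:
        H = tensor(X0)
        for block in self.blocks:
            H = block(norm, H)
        return H

    def parameters(self):
        return [p for b in self.blocks for p in b.parameters()]


def decode_inner_product(Z) -> Tensor:
    """Pairwise association probabilities ``sigmoid(Z Z^T)``."""
    Z = tensor(Z)
    return (Z @ Z.T).sigmoid()


def reconstruction_loss(A_target: np.ndarray, A_hat) -> Tensor:
    """Mean binary cross-entropy between a binary target and probabilities."""
    A_target = np.asarray(A_target, dtype=np.float64)
    A_hat = tensor(A_hat)
    if A_target.shape != A_hat.shape:
        raise ValueError(
            f"shape mismatch: target {A_target.shape} vs prediction {A_hat.shape}"
        )
    return bce(A_hat, A_target)


def _recon_loss_from_logits(A_target: np.ndarray, Z: Tensor) -> Tensor:
    """Numerically stable reconstruction loss computed from Z Z^T logits."""
    return bce_with_logits(Z @ Z.T, np.asarray(A_target, dtype=np.float64))


def assemble_pair_features(
    z_local, z_global, z_mdm, z_dmd, pairs, m: int | None = None
) -> Tensor:
    """Per-pair feature vectors F (width 4 * latent_dim with all views on).

    ``z_local``/``z_global`` are joint-node embedding tables (miRNAs first),
    ``z_mdm`` is the miRNA semantic table, ``z_dmd`` the disease semantic
    table. Any table may be ``None`` (view ablation); at least one block must
    remain. ``pairs`` is a sequence of (miRNA index, disease index). ``m``
    (the miRNA count) locates the disease rows of the joint tables; it is
    inferred from ``z_mdm`` when omitted.
    """
    pairs = np.asarray(pairs, dtype=np.intp)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (i, j) tuples")
    mi, dj = pairs[:, 0], pairs[:, 1]
    if m is None:
        if z_mdm is None:
            raise ValueError("m must be given when z_mdm is absent")
        m = z_mdm.shape[0]

    blocks = []
    if z_mdm is not None:
        blocks.append(tensor(z_mdm)[mi])
    pair_block = None
    for table in (z_local, z_global):
        if table is None:
            continue
        table = tensor(table)
        part = concat([table[mi], table[m + dj]], axis=1)
        pair_block = part if pair_block is None else pair_block + part
    if pair_block is not None:
        blocks.append(pair_block)
    if z_dmd is not None:
        blocks.append(tensor(z_dmd)[dj])
    if not blocks:
        raise ValueError("at least one view embedding table is required")
    return concat(blocks, axis=1)


class CascadeClassifier:
    """Hierarchical projections + layer attention + feature attention + head.

    Three fully-connected layers taper the pair feature F into hierarchical
    features H0, H1, H2; each is projected to a common width ``d_h``. With
    attention enabled the three projections are stacked into ``h`` of shape
    (batch, 3, d_h), mixed by a softmax layer-attention (``W_in`` maps d_h to
    3 layer scores; rows of the 3x3 attention matrix sum to 1), flattened and
    mapped by ``W_out`` back to width d_h, then refined by a gate-structured
    feature attention whose (d_h x d_h) score matrix is built from two
    low-rank maps ``W1, W2`` of shape (1, attn_rank) applied to h~ as a
    column of features. Without attention the three projections are simply
    concatenated into the head (the ablation baseline).
    """

    n_levels = 3

    def __init__(
        self,
        d_in: int,
        rng: np.random.Generator,
        hidden_widths: tuple[int, int, int] = (256, 128, 64),
        d_h: int = 64,
        attn_rank: int = 16,
        use_attention: bool = True,
    ):
        self.d_in = d_in
        self.hidden_widths = tuple(hidden_widths)
        self.d_h = d_h
        self.use_attention = use_attention
        dims = [d_in, *self.hidden_widths]
        self.W_hier = [glorot(rng, dims[i], dims[i + 1]) for i in range(3)]
        self.b_hier = [parameter(np.zeros(dims[i + 1])) for i in range(3)]
        self.W_proj = [glorot(rng, w, d_h) for w in self.hidden_widths]
        self.b_proj = [parameter(np.zeros(d_h)) for _ in range(3)]
        self.W_in = glorot(rng, d_h, self.n_levels)
        self.W_out = glorot(rng, self.n_levels * d_h, d_h)
        self.W1 = glorot(rng, 1, attn_rank)
        self.W2 = glorot(rng, 1, attn_rank)
        head_in = d_h if use_attention else self.n_levels * d_h
        # zero-initialized head: the untrained classifier outputs exactly 0.5
        # and the first-epoch loss on balanced labels is ln 2
        self.W_head = parameter(np.zeros((head_in, 1)))
        self.b_head = parameter(np.zeros(1))

    # -- stages, exposed separately for testing -------------------------------

    def hierarchical_projections(self, F) -> tuple[Tensor, Tensor, Tensor]:
        """Sequential hierarchy H0 <- F, H1 <- H0, H2 <- H1, each projected to d_h."""
        F = tensor(F)
        if F.shape[-1] != self.d_in:
            raise ValueError(
                f"pair feature width {F.shape[-1]} != classifier input {self.d_in}"
            )
        hs = []
        H = F
        for Wh, bh, Wp, bp in zip(self.W_hier, self.b_hier, self.W_proj, self.b_proj):
            H = (H @ Wh + bh).relu()
            hs.append((H @ Wp + bp).relu())
        return tuple(hs)

    def layer_attention_fuse(self, h0, h1, h2) -> Tensor:
        """Softmax-normalized mixing across the three hierarchy levels."""
        h = stack([tensor(h0), tensor(h1), tensor(h2)], axis=-2)  # (..., 3, d_h)
        attn = (h @ self.W_in).softmax(axis=-1)  # (..., 3, 3), rows sum to 1
        mixed = h + attn @ h  # residual layer mixing
        flat = mixed.reshape(*mixed.shape[:-2], self.n_levels * self.d_h)
        return flat @ self.W_out  # (..., d_h)

    def feature_attention_refine(self, h_tilde) -> Tensor:
        """Gate-structured attention across the d_h feature elements."""
        h_tilde = tensor(h_tilde)
        col = h_tilde.reshape(*h_tilde.shape, 1)  # (..., d_h, 1)
        scores = (col @ self.W1) @ (col @ self.W2).T  # (..., d_h, d_h)
        attn = scores.softmax(axis=-1)  # rows sum to 1
        row = h_tilde.reshape(*h_tilde.shape[:-1], 1, h_tilde.shape[-1])
        mixed = (row @ attn).reshape(*h_tilde.shape)
        return h_tilde + mixed

    def head_logits(self, features) -> Tensor:
        return tensor(features) @ self.W_head + self.b_head

    # -- full forward ---------------------------------------------------------

    def forward_logits(self, F) -> Tensor:
        h0, h1, h2 = self.hierarchical_projections(F)
        if self.use_attention:
            fused = self.layer_attention_fuse(h0, h1, h2)
            refined = self.feature_attention_refine(fused)
        else:
            refined = concat([h0, h1, h2], axis=-1)
        return self.head_logits(refined).reshape(-1)

    def predict_proba(self, F) -> Tensor:
        """Association probabilities in (0, 1) for a pair-feature batch."""
        return self.forward_logits(F).sigmoid()

    def parameters(self):
        return (
            self.W_hier
            + self.b_hier
            + self.W_proj
            + self.b_proj
            + [self.W_in, self.W_out, self.W1, self.W2, self.W_head, self.b_head]
        )
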