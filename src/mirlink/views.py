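"""Graph views over the joint miRNA-disease node set.

Three kinds of view feed the encoders:

* **local** — the bipartite association graph in block form over the joint
  node set: ``[[I_m, A], [A^T, I_n]]``. Message passing only reaches
  first-order association neighbours.
* **global** — a fully connected graph (all-ones adjacency) over the joint
  node set; propagation is a (nearly uniform) mean over all nodes and
  supplies non-local context.
* **semantic** — homogeneous networks induced by the metapaths
  miRNA-disease-miRNA and disease-miRNA-disease: two miRNAs are linked iff
  they share at least one disease, and dually for diseases. ``A A^T`` counts
  shared diseases; by default the networks are binarized (presence of at
  least one metapath instance), with path-count weighting available.

All views use the renormalized propagation matrix
``D^{-1/2} (adj + I) D^{-1/2}`` where ``D`` is the degree matrix of
``adj + I`` — the self-loop guarantees positive degrees.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

__all__ = [
    "ViewGraph",
    "build_local_adjacency",
    "build_global_adjacency",
    "build_metapath_networks",
    "normalize_adjacency",
    "global_mean_propagate",
]


def normalize_adjacency(adj: np.ndarray) -> np.ndarray:
    """Symmetric renormalization ``D^{-1/2} (adj + I) D^{-1/2}``.

    ``D`` is the diagonal degree matrix of ``adj + I``; adding the self-loop
    makes every degree >= 1 so the result is always finite.
    """
    adj = np.asarray(adj, dtype=np.float64)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(adj, adj.T):
        raise ValueError("adjacency must be symmetric")
    a_tilde = adj + np.eye(adj.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(a_tilde.sum(axis=1))
    return a_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


@dataclass
class ViewGraph:
    """A square symmetric adjacency plus its renormalized propagation matrix."""

    adj: np.ndarray
    view_kind: str  # local | global | semantic_mm | semantic_dd

    def __post_init__(self):
        self.adj = np.asarray(self.adj, dtype=np.float64)
        if self.adj.ndim != 2 or self.adj.shape[0] != self.adj.shape[1]:
            raise ValueError("adjacency must be square")

    @property
    def n_nodes(self) -> int:
        return self.adj.shape[0]

    @cached_property
    def adj_selfloop(self) -> np.ndarray:
        return self.adj + np.eye(self.n_nodes)

    @cached_property
    def norm(self) -> np.ndarray:
        return normalize_adjacency(self.adj)


def build_local_adjacency(A: np.ndarray) -> ViewGraph:
    """Block adjacency ``[[I_m, A], [A^T, I_n]]`` over the joint node set."""
    A = np.asarray(A)
    m, n = A.shape
    adj = np.zeros((m + n, m + n), dtype=np.float64)
    adj[:m, :m] = np.eye(m)
    adj[m:, m:] = np.eye(n)
    adj[:m, m:] = A
    adj[m:, :m] = A.T
    return ViewGraph(adj, "local")


def build_global_adjacency(m: int, n: int) -> ViewGraph:
    """All-ones adjacency over the joint node set (fully connected view)."""
    if m + n < 1:
        raise ValueError("need at least one node")
    return ViewGraph(np.ones((m + n, m + n)), "global")


def global_mean_propagate(H: np.ndarray) -> np.ndarray:
    """Closed-form ``norm @ H`` for the all-ones view without materializing it.

    With an all-ones adjacency plus self-loop every degree is ``N + 1``, so
    the propagation matrix is ``(ones + I) / (N + 1)`` and
    ``norm @ H = (colsum(H) + H) / (N + 1)`` — a rank-one update. Used when
    the dense matrix would be wasteful; tests pin its equality to the dense
    product.
    """
    H = np.asarray(H, dtype=np.float64)
    N = H.shape[0]
    return (H.sum(axis=0, keepdims=True) + H) / (N + 1)


def build_metapath_networks(
    A: np.ndarray, weighting: str = "binary"
) -> tuple[ViewGraph, ViewGraph]:
    """Metapath-induced homogeneous networks.

    ``(A A^T)[i, k]`` counts diseases shared by miRNAs i and k (instances of
    the miRNA-disease-miRNA metapath); ``(A^T A)[j, l]`` counts miRNAs shared
    by diseases j and l. With ``weighting="binary"`` (default) entries are
    thresholded to presence/absence; ``"count"`` keeps the path counts.
    """
    if weighting not in ("binary", "count"):
        raise ValueError(f"unknown metapath weighting: {weighting!r}")
    A = np.asarray(A, dtype=np.float64)
    mm = A @ A.T
    dd = A.T @ A
    if weighting == "binary":
        mm = (mm > 0).astype(np.float64)
        dd = (dd > 0).astype(np.float64)
    return ViewGraph(mm, "semantic_mm"), ViewGraph(dd, "semantic_dd")
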