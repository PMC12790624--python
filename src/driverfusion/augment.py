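"""Feature augmentation: gene-set functional embeddings and structural encodings.

Two frozen structural descriptors are computed once from the PPI view:

* **Random-walk positional encoding** — the row-stochastic transition
  matrix T = D^{-1} A is reduced by PCA; each gene's coordinates are its
  scores on the leading principal components, scaled by the component
  singular values ("variance-scaled"). Isolated nodes get a self-transition
  of 1 so T stays row-stochastic. Component signs are fixed so the
  largest-magnitude loading of each component is positive, making the
  encoding reproducible.
* **PageRank centrality** — standard PageRank with uniform teleportation
  (damping 0.85 by default) and dangling mass redistributed uniformly,
  iterated to an L1 tolerance of 1e-10.

The gene-set functional embedding is trainable and lives in the model
graph: A = row-softmax(M W_attn) attends over gene sets and
E_gene = A E_set looks up a learned set-embedding table.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .io import AlignedView

__all__ = [
    "geneset_embed",
    "random_walk_positional",
    "pagerank",
    "structural_concat",
]


def geneset_embed(
    membership: np.ndarray, w_attn: nn.Tensor, e_set: nn.Tensor
) -> tuple[nn.Tensor, nn.Tensor]:
    """Gene-set attention embedding: returns ``(E_gene, A)``.

    ``membership`` is the binary N x S matrix; ``A = softmax(M W_attn)``
    row-wise (an all-zero membership row attends uniformly, 1/S each);
    ``E_gene = A E_set``.
    """
    if membership.shape[1] == 0:
        raise ValueError("gene-set matrix has no sets")
    m = nn.Tensor(np.asarray(membership, dtype=np.float64))
    attn = nn.softmax(nn.matmul(m, w_attn), axis=1)
    e_gene = nn.matmul(attn, e_set)
    return e_gene, attn


def transition_matrix(view: AlignedView, n: int) -> np.ndarray:
    """Row-stochastic random-walk matrix T = D^{-1} A (dense).

    Isolated nodes receive a self-transition of 1.
    """
    a = view.adjacency(n).toarray().astype(np.float64)
    deg = a.sum(axis=1)
    isolated = deg == 0
    t = np.divide(a, np.where(isolated, 1.0, deg)[:, None])
    t[isolated, :] = 0.0
    t[np.nonzero(isolated)[0], np.nonzero(isolated)[0]] = 1.0
    return t


def random_walk_positional(view: AlignedView, n: int, d_rw: int) -> np.ndarray:
    """PCA of the random-walk transition matrix, singular-value-scaled.

    Returns an N x d_rw block of principal-component scores (columns beyond
    the matrix rank are zero). Signs are deterministic: each component is
    flipped so its largest-magnitude loading is positive.
    """
    if d_rw > n:
        raise ValueError(f"d_rw={d_rw} exceeds the number of genes {n}")
    t = transition_matrix(view, n)
    tc = t - t.mean(axis=0, keepdims=True)  # center features (columns)
    u, s, vt = np.linalg.svd(tc, full_matrices=False)
    rank = int(np.sum(s > 1e-12 * (s[0] if s.size else 1.0)))
    k = min(d_rw, rank)
    out = np.zeros((n, d_rw))
    for comp in range(k):
        v = vt[comp]
        sign = 1.0 if v[np.argmax(np.abs(v))] >= 0 else -1.0
        out[:, comp] = sign * u[:, comp] * s[comp]
    return out


def pagerank(
    view: AlignedView,
    n: int,
    damping: float = 0.85,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> np.ndarray:
    """PageRank with uniform teleport and uniform dangling-mass redistribution.

    Power iteration on r <- (1-d)/N + d (T^T r + dangling_mass / N), run to
    an L1 residual below ``tol``. Raises on non-convergence.
    """
    if not 0.0 < damping < 1.0:
        raise ValueError("damping must lie in (0, 1)")
    a = view.adjacency(n)
    deg = np.asarray(a.sum(axis=1)).ravel()
    dangling = deg == 0
    inv_deg = np.where(dangling, 0.0, 1.0 / np.where(dangling, 1.0, deg))
    r = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        contrib = a.T @ (r * inv_deg)
        dangling_mass = r[dangling].sum()
        r_new = (1.0 - damping) / n + damping * (contrib + dangling_mass / n)
        residual = np.abs(r_new - r).sum()
        r = r_new
        if residual < tol:
            return r
    raise RuntimeError(
        f"PageRank did not converge in {max_iter} iterations (L1 residual {residual:.3e})"
    )


def structural_concat(e_rw: np.ndarray, e_pr: np.ndarray) -> np.ndarray:
    """Concatenate the positional block and the centrality column:
    e_struct = [e_rw | e_pr], width d_rw + 1."""
    e_pr = np.asarray(e_pr, dtype=np.float64).reshape(-1, 1)
    if e_rw.shape[0] != e_pr.shape[0]:
        raise ValueError(
            f"row mismatch: e_rw has {e_rw.shape[0]} rows, e_pr has {e_pr.shape[0]}"
        )
    return np.concatenate([e_rw, e_pr], axis=1)
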