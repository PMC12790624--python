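"""Per-view graph convolutions and attention fusion across views.

Each network view (PPI, GO semantic similarity, pathway co-occurrence) is
encoded by its own two-layer GCN over the shared z-scored feature matrix:

    h^(1) = ReLU(A_hat X W1^T),    z = A_hat h^(1) W2^T

with symmetric degree normalization and added self-loops,
A_hat = D~^{-1/2} (A + I) D~^{-1/2}. Self-loops guarantee that genes
isolated in a view (common for the GO/pathway views, which do not cover
all genes) still receive an embedding. Following the literal form of the
update, no activation is applied after the second layer. Message passing is
unweighted by default — edge scores gate existence and feed the
edge-attention bias — with score-weighted aggregation available behind a
flag.

The three view embeddings are fused by a learnable softmax attention over
view logits z_i^(m) . a, yielding per-gene modality weights alpha_i (the
interpretability handle) and the convex combination z_i^fusion.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from . import nn
from .io import AlignedView

__all__ = ["gcn_norm_adjacency", "gcn_two_layer", "fuse"]


def gcn_norm_adjacency(
    view: AlignedView,
    n: int,
    weighted: bool = False,
    mode: str = "sym",
) -> nn.Sparse:
    """Degree-normalized adjacency with self-loops for GCN propagation.

    ``sym``: D~^{-1/2} (A + I) D~^{-1/2} (c_ij = sqrt((deg_i+1)(deg_j+1))).
    ``row``: D~^{-1} (A + I).
    """
    a = view.adjacency(n, weighted=weighted) + sp.identity(n, format="csr")
    deg = np.asarray(a.sum(axis=1)).ravel()
    if mode == "sym":
        d = sp.diags(1.0 / np.sqrt(deg))
        a_hat = d @ a @ d
    elif mode == "row":
        a_hat = sp.diags(1.0 / deg) @ a
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return nn.Sparse(a_hat)


def gcn_two_layer(x, a_hat: nn.Sparse, w1: nn.Tensor, w2: nn.Tensor) -> nn.Tensor:
    """Two-layer GCN forward: A_hat ReLU(A_hat X W1^T) W2^T.

    ``w1`` maps the raw feature width F to the embedding width d (the
    layer-1 input dimension is F, which is what makes the update
    well-typed); ``w2`` is d x d.
    """
    x = x if isinstance(x, nn.Tensor) else nn.Tensor(x)
    if w1.shape[1] != x.shape[1]:
        raise ValueError(
            f"W1 expects input width {w1.shape[1]}, features have {x.shape[1]}"
        )
    h1 = nn.relu(nn.spmm(a_hat, nn.matmul(x, nn.transpose(w1))))
    return nn.spmm(a_hat, nn.matmul(h1, nn.transpose(w2)))


def fuse(view_embeddings: list[nn.Tensor], a: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
    """Softmax attention fusion over the (exactly three) view embeddings.

    Returns ``(z_fusion, alpha)`` where ``alpha`` is N x 3, each row
    non-negative and summing to 1, and
    ``z_fusion_i = sum_m alpha_im z_i^(m)``.
    """
    if len(view_embeddings) != 3:
        raise ValueError("fusion expects exactly three view embeddings")
    logits = nn.concat([nn.matmul(z, a) for z in view_embeddings], axis=1)  # (N, 3)
    if not np.all(np.isfinite(logits.data)):
        raise FloatingPointError("non-finite fusion logits")
    alpha = nn.softmax(logits, axis=1)
    parts = [
        nn.mul(nn.slice_cols(alpha, m, m + 1), z)
        for m, z in enumerate(view_embeddings)
    ]
    z_fusion = nn.add(nn.add(parts[0], parts[1]), parts[2])
    return z_fusion, alpha
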