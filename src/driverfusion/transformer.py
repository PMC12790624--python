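"""The fusion graph transformer: input assembly, edge-attention bias, and
the biased multi-head transformer encoder that scores genes.

Per gene the input is the concatenation

    h_input = [ x | z_fusion | E_gene | e_struct ]         (width F + 3d + 1
                                                            when d_rw = d)

projected to the model width d by one linear layer. A stack of L post-norm
transformer layers (multi-head self-attention over all genes, feed-forward
width 4d with GELU) refines the representations; a per-head edge-attention
bias B derived from the biological networks is added to the pre-softmax
attention logits of every layer, so attention between connected genes is
modulated by the existence and confidence of their edges:

    b_ij = sum_m sigmoid(W_edge s_ij^(m) + b_edge),
    s_ij^(m) = [score_ij^(m), 1]  for pairs with an edge in view m.

Pairs with no edge in any view contribute exactly zero bias ("no evidence,
no modulation"), which keeps B sparse in spirit and means the model with
B = 0 reduces exactly to a vanilla transformer encoder. One bias tensor is
shared across layers. The final score is sigmoid(w . h^(L) + b).

The scoring head (w, b) is zero-initialized so an untrained model outputs a
calibrated 0.5 for every gene; all other weights use fan-in-scaled uniform
initialization with zero biases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .augment import pagerank, random_walk_positional, structural_concat, geneset_embed
from .encoder import fuse, gcn_norm_adjacency, gcn_two_layer
from .io import MODALITIES, DriverDataset

__all__ = [
    "ModelConfig",
    "AblationSpec",
    "ABLATION_SWITCHES",
    "assemble_input",
    "project",
    "build_edge_bias",
    "transformer_forward",
    "predict_scores",
    "FusionGraphTransformer",
]

#: the six ablation switches: random-walk positional encoding, centrality
#: encoding, gene-set attention, edge-attention bias, network feature
#: encoder (multi-view fusion), initial multi-omics features.
ABLATION_SWITCHES = ("PE", "CE", "GSA", "EAA", "NFE", "IF")


@dataclass(frozen=True)
class AblationSpec:
    """Which architectural channels to disable (zeroed, parameters removed)."""

    disable: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "disable", frozenset(self.disable))
        unknown = self.disable - set(ABLATION_SWITCHES)
        if unknown:
            raise ValueError(f"unknown ablation switches: {sorted(unknown)}")

    def __contains__(self, switch: str) -> bool:
        return switch in self.disable

    @classmethod
    def parse(cls, text: str) -> "AblationSpec":
        parts = [p.strip().upper() for p in text.split(",") if p.strip()]
        return cls(frozenset(parts))


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``d`` is the shared embedding width (128 in the full-scale
    configuration; smaller values are appropriate for desk-scale synthetic
    benchmarks), ``n_layers``/``n_heads`` the transformer depth and head
    count, ``d_rw`` the random-walk positional width (defaults to ``d``,
    capped at N-1 on small graphs at build time), and ``n_max`` a memory
    guard on the full-graph attention.
    """

    d: int = 128
    n_layers: int = 3
    n_heads: int = 4
    dropout: float = 0.1
    d_rw: int | None = None
    n_max: int = 20_000
    gcn_weighted: bool = False
    gcn_norm: str = "sym"

    def __post_init__(self):
        if self.d % self.n_heads != 0:
            raise ValueError("embedding width d must be divisible by n_heads")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.n_layers < 1 or self.n_heads < 1:
            raise ValueError("n_layers and n_heads must be >= 1")

    @property
    def head_dim(self) -> int:
        return self.d // self.n_heads


# ---------------------------------------------------------------------------
# pipeline operations (also used standalone in tests)


def assemble_input(x, z_fusion, e_gene, e_struct):
    """Concatenate the four per-gene blocks; width F + d + d + (d_rw + 1)."""
    blocks = [x, z_fusion, e_gene, e_struct]
    rows = {b.shape[0] for b in blocks}
    if len(rows) != 1:
        raise ValueError(f"row mismatch across input blocks: {sorted(rows)}")
    if all(isinstance(b, np.ndarray) for b in blocks):
        return np.concatenate(blocks, axis=1)
    return nn.concat([b if isinstance(b, nn.Tensor) else nn.Tensor(b) for b in blocks], axis=1)


def project(h_input, w_proj: nn.Tensor, b_proj: nn.Tensor) -> nn.Tensor:
    """H0 = h_input W_proj^T + b_proj (row-wise linear map to width d)."""
    h = h_input if isinstance(h_input, nn.Tensor) else nn.Tensor(h_input)
    if w_proj.shape[1] != h.shape[1]:
        raise ValueError(
            f"projection expects input width {w_proj.shape[1]}, got {h.shape[1]}"
        )
    return nn.add(nn.matmul(h, nn.transpose(w_proj)), b_proj)


def _pair_table(graph) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Unique undirected pairs across all views plus per-view pair ids."""
    n = graph.n_genes
    keys = []
    for m in MODALITIES:
        ei = graph.views[m].edge_index
        keys.append(ei[0] * n + ei[1])
    all_keys = np.unique(np.concatenate(keys)) if keys else np.array([], dtype=np.intp)
    ids = {m: np.searchsorted(all_keys, k) for m, k in zip(MODALITIES, keys)}
    rows = (all_keys // n).astype(np.intp)
    cols = (all_keys % n).astype(np.intp)
    return rows, cols, ids


def build_edge_bias(
    graph, w_edge: nn.Tensor, b_edge: nn.Tensor, n_heads: int
) -> list[nn.Tensor]:
    """Per-head dense edge-attention bias matrices (symmetric, zero off-edge).

    For every pair with an edge in at least one view, each view with an
    edge contributes sigmoid(W_edge [score, 1] + b_edge) per head; the
    contributions are summed over views.
    """
    n = graph.n_genes
    rows, cols, ids = _pair_table(graph)
    n_pairs = len(rows)
    if n_pairs == 0:
        return [nn.Tensor(np.zeros((n, n))) for _ in range(n_heads)]
    per_view = []
    all_ids = []
    for m in MODALITIES:
        v = graph.views[m]
        if v.n_edges == 0:
            continue
        desc = np.stack([v.scores, np.ones_like(v.scores)], axis=1)  # (E, 2)
        logits = nn.add(nn.matmul(nn.Tensor(desc), nn.transpose(w_edge)), b_edge)
        per_view.append(nn.sigmoid(logits))  # (E, H)
        all_ids.append(ids[m])
    values = nn.concat(per_view, axis=0) if len(per_view) > 1 else per_view[0]
    pair_bias = nn.index_add_rows(values, np.concatenate(all_ids), n_pairs)  # (P, H)
    return [nn.scatter_pairs(_col(pair_bias, h), rows, cols, n) for h in range(n_heads)]


def _col(t: nn.Tensor, h: int) -> nn.Tensor:
    """Column h of a 2-D tensor as a 1-D tensor (differentiable)."""
    sliced = nn.slice_cols(t, h, h + 1)  # (P, 1)
    return nn.Tensor(
        sliced.data.ravel(),
        parents=(sliced,),
        backward=lambda g: (g.reshape(-1, 1),),
    )


def _linear(x: nn.Tensor, w: nn.Tensor, b: nn.Tensor) -> nn.Tensor:
    return nn.add(nn.matmul(x, nn.transpose(w)), b)


def transformer_layer(
    h: nn.Tensor,
    bias: list[nn.Tensor] | None,
    params: dict[str, nn.Tensor],
    config: ModelConfig,
    rng: np.random.Generator | None,
    training: bool,
    collect_attention: list | None = None,
) -> nn.Tensor:
    """One post-norm transformer layer with additive per-head attention bias."""
    dh = config.head_dim
    scale = 1.0 / np.sqrt(dh)
    q = _linear(h, params["Wq"], params["bq"])
    k = _linear(h, params["Wk"], params["bk"])
    v = _linear(h, params["Wv"], params["bv"])
    heads = []
    for hd in range(config.n_heads):
        qh = nn.slice_cols(q, hd * dh, (hd + 1) * dh)
        kh = nn.slice_cols(k, hd * dh, (hd + 1) * dh)
        vh = nn.slice_cols(v, hd * dh, (hd + 1) * dh)
        logits = nn.mul(nn.matmul(qh, nn.transpose(kh)), scale)
        if bias is not None:
            logits = nn.add(logits, bias[hd])
        att = nn.softmax(logits, axis=1)
        if collect_attention is not None:
            collect_attention.append(att.data)
        heads.append(nn.matmul(att, vh))
    attn_out = _linear(nn.concat(heads, axis=1), params["Wo"], params["bo"])
    attn_out = nn.dropout(attn_out, config.dropout, rng, training)
    h = nn.layer_norm(nn.add(h, attn_out), params["ln1_g"], params["ln1_b"])
    ff = _linear(nn.gelu(_linear(h, params["ff_W1"], params["ff_b1"])), params["ff_W2"], params["ff_b2"])
    ff = nn.dropout(ff, config.dropout, rng, training)
    h = nn.layer_norm(nn.add(h, ff), params["ln2_g"], params["ln2_b"])
    if not np.all(np.isfinite(h.data)):
        raise FloatingPointError("non-finite activations in transformer layer")
    return h


def transformer_forward(
    h0: nn.Tensor,
    bias: list[nn.Tensor] | None,
    config: ModelConfig,
    layer_params: list[dict[str, nn.Tensor]],
    rng: np.random.Generator | None = None,
    training: bool = False,
    collect_attention: list | None = None,
) -> nn.Tensor:
    """Run the stack of L biased transformer layers."""
    h = h0
    for params in layer_params:
        h = transformer_layer(h, bias, params, config, rng, training, collect_attention)
    return h


def predict_scores(hl: nn.Tensor, w: nn.Tensor, b: nn.Tensor) -> nn.Tensor:
    """Per-gene score: sigmoid(w . h_i^(L) + b), shape (N,)."""
    return nn.sigmoid(_col(nn.add(nn.matmul(hl, w), b), 0))


# ---------------------------------------------------------------------------
# the assembled model


class FusionGraphTransformer:
    """End-to-end model over one aligned dataset (transductive).

    Frozen inputs (features, normalized adjacencies, structural encodings,
    edge descriptors) are computed once at construction; trainable
    parameters live in ``self.params``. Ablation switches zero the
    corresponding input block and drop its parameters.
    """

    def __init__(
        self,
        dataset: DriverDataset,
        config: ModelConfig,
        rng: np.random.Generator,
        ablation: AblationSpec | None = None,
    ):
        self.config = config
        self.ablation = ablation or AblationSpec()
        n = dataset.n_genes
        if n > config.n_max:
            raise ValueError(
                f"{n} genes exceeds the full-graph attention cap n_max={config.n_max}; "
                "raise n_max explicitly if memory allows"
            )
        self.n = n
        self.graph = dataset.graph
        self.universe = dataset.graph.universe
        d = config.d
        f = dataset.features.n_features
        s = dataset.gene_sets.n_sets
        self.f, self.s = f, s
        d_rw = min(config.d_rw if config.d_rw is not None else d, n - 1)
        self.d_rw = d_rw

        # frozen inputs ------------------------------------------------------
        self.x = dataset.features.values if "IF" not in self.ablation else np.zeros((n, f))
        ppi = dataset.graph.views["PPI"]
        e_rw = (
            random_walk_positional(ppi, n, d_rw)
            if "PE" not in self.ablation
            else np.zeros((n, d_rw))
        )
        e_pr = pagerank(ppi, n) if "CE" not in self.ablation else np.zeros(n)
        self.e_struct = structural_concat(e_rw, e_pr)
        self.membership = dataset.gene_sets.membership
        if "NFE" not in self.ablation:
            self.a_hats = {
                m: gcn_norm_adjacency(
                    dataset.graph.views[m], n, config.gcn_weighted, config.gcn_norm
                )
                for m in MODALITIES
            }

        # parameters ----------------------------------------------------------
        self.params: dict[str, nn.Tensor] = {}
        self.no_decay: list[nn.Tensor] = []
        p, nd = self.params, self.no_decay

        def weight(name, shape, fan_in):
            p[name] = nn.uniform_fan_in(rng, shape, fan_in)

        def bias_(name, shape, ln: bool = False):
            t = nn.Tensor(np.ones(shape) if ln else np.zeros(shape), requires_grad=True)
            p[name] = t
            nd.append(t)

        if "NFE" not in self.ablation:
            for m in MODALITIES:
                weight(f"enc_{m}_W1", (d, f), f)
                weight(f"enc_{m}_W2", (d, d), d)
            weight("fusion_a", (d, 1), d)
        if "GSA" not in self.ablation:
            weight("gs_W_attn", (s, s), s)
            weight("gs_E_set", (s, d), s)
        in_width = f + d + d + (d_rw + 1)
        self.in_width = in_width
        weight("proj_W", (d, in_width), in_width)
        bias_("proj_b", (d,))
        if "EAA" not in self.ablation:
            weight("edge_W", (config.n_heads, 2), 2)
            bias_("edge_b", (config.n_heads,))
        self.layer_params: list[dict[str, nn.Tensor]] = []
        for layer in range(config.n_layers):
            lp: dict[str, nn.Tensor] = {}
            for nm in ("Wq", "Wk", "Wv", "Wo"):
                weight(f"l{layer}_{nm}", (d, d), d)
                bias_(f"l{layer}_b{nm[1:].lower()}", (d,))
            weight(f"l{layer}_ff_W1", (4 * d, d), d)
            bias_(f"l{layer}_ff_b1", (4 * d,))
            weight(f"l{layer}_ff_W2", (d, 4 * d), 4 * d)
            bias_(f"l{layer}_ff_b2", (d,))
            for nm in ("ln1_g", "ln2_g"):
                bias_(f"l{layer}_{nm}", (d,), ln=True)
            for nm in ("ln1_b", "ln2_b"):
                bias_(f"l{layer}_{nm}", (d,))
            self.layer_params.append(
                {
                    "Wq": p[f"l{layer}_Wq"], "bq": p[f"l{layer}_bq"],
                    "Wk": p[f"l{layer}_Wk"], "bk": p[f"l{layer}_bk"],
                    "Wv": p[f"l{layer}_Wv"], "bv": p[f"l{layer}_bv"],
                    "Wo": p[f"l{layer}_Wo"], "bo": p[f"l{layer}_bo"],
                    "ff_W1": p[f"l{layer}_ff_W1"], "ff_b1": p[f"l{layer}_ff_b1"],
                    "ff_W2": p[f"l{layer}_ff_W2"], "ff_b2": p[f"l{layer}_ff_b2"],
                    "ln1_g": p[f"l{layer}_ln1_g"], "ln1_b": p[f"l{layer}_ln1_b"],
                    "ln2_g": p[f"l{layer}_ln2_g"], "ln2_b": p[f"l{layer}_ln2_b"],
                }
            )
        # zero-initialized scoring head (calibrated 0.5 start)
        p["head_w"] = nn.zeros_param((d, 1))
        p["head_b"] = nn.zeros_param((1,))
        nd.append(p["head_b"])

    def parameters(self) -> list[nn.Tensor]:
        return list(self.params.values())

    def forward(
        self,
        training: bool = False,
        rng: np.random.Generator | None = None,
        collect_attention: list | None = None,
    ) -> dict:
        """Full forward pass; returns scores, fusion alphas and the bias."""
        n, d = self.n, self.config.d
        p = self.params
        x_t = nn.Tensor(self.x)
        if "NFE" not in self.ablation:
            z_views = [
                gcn_two_layer(x_t, self.a_hats[m], p[f"enc_{m}_W1"], p[f"enc_{m}_W2"])
                for m in MODALITIES
            ]
            z_fusion, alpha = fuse(z_views, p["fusion_a"])
        else:
            z_fusion, alpha = nn.Tensor(np.zeros((n, d))), None
        if "GSA" not in self.ablation:
            e_gene, _ = geneset_embed(self.membership, p["gs_W_attn"], p["gs_E_set"])
        else:
            e_gene = nn.Tensor(np.zeros((n, d)))
        h_input = assemble_input(x_t, z_fusion, e_gene, nn.Tensor(self.e_struct))
        h0 = project(h_input, p["proj_W"], p["proj_b"])
        if "EAA" not in self.ablation:
            bias = build_edge_bias(self.graph, p["edge_W"], p["edge_b"], self.config.n_heads)
        else:
            bias = None
        hl = transformer_forward(
            h0, bias, self.config, self.layer_params, rng, training, collect_attention
        )
        scores = predict_scores(hl, p["head_w"], p["head_b"])
        return {"scores": scores, "alpha": alpha, "bias": bias}

    # ---- persistence ------------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            if k not in state:
                raise KeyError(f"checkpoint missing parameter {k!r}")
            if state[k].shape != v.data.shape:
                raise ValueError(f"shape mismatch for parameter {k!r}")
            v.data = np.asarray(state[k], dtype=np.float64).copy()
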