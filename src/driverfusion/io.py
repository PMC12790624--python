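"""Reading, filtering and node-aligning the input data.

The pipeline consumes four kinds of files:

* three weighted undirected edge lists (TSV ``gene_a  gene_b  score``) — a
  protein–protein interaction (PPI) view, a GO semantic-similarity view and
  a KEGG pathway co-occurrence view, each thresholded at its own confidence
  cutoff;
* a per-gene multi-omics feature table (first column = gene symbol, the
  remaining columns numeric, e.g. 16 cancer types x {mutation rate,
  differential methylation, differential expression} = 48 columns);
* gene-set membership in GMT format (MSigDB style), with cancer-keyword
  sets excluded to avoid label leakage;
* positive / negative gene label lists (one symbol per line, ``#`` comments).

Everything is aligned onto a single lexicographically ordered gene universe
(by convention the node set of the PPI view) so that downstream matrices
share row indexing. Gene identifiers are opaque, case-sensitive strings
after whitespace stripping; no alias resolution is attempted.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: view name -> default minimum edge score (STRING-style PPI, GO semantic
#: similarity, KEGG pathway co-occurrence).
DEFAULT_THRESHOLDS = {"PPI": 0.85, "GO": 0.8, "Pathway": 0.6}

MODALITIES = ("PPI", "GO", "Pathway")


@dataclass(frozen=True)
class GeneUniverse:
    """An ordered, duplicate-free set of gene symbols with 0-based indexing."""

    symbols: tuple[str, ...]
    index: dict[str, int] = field(repr=False, default_factory=dict)

    @classmethod
    def from_symbols(cls, symbols) -> "GeneUniverse":
        ordered = tuple(sorted(set(symbols)))
        return cls(ordered, {s: i for i, s in enumerate(ordered)})

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.index


@dataclass
class NetworkView:
    """One loaded network view, keyed by gene symbols (pre-alignment)."""

    modality: str
    edges: dict[tuple[str, str], float]  # canonical (a, b) with a < b
    threshold: float

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return out

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class AlignedView:
    """A view re-indexed onto the shared universe (integer endpoints, i < j)."""

    modality: str
    edge_index: np.ndarray  # (2, E) intp, row0 < row1
    scores: np.ndarray  # (E,) float64
    threshold: float

    @property
    def n_edges(self) -> int:
        return self.edge_index.shape[1]

    def adjacency(self, n: int, weighted: bool = False) -> sp.csr_matrix:
        """Symmetric adjacency over the universe (binary unless ``weighted``)."""
        i, j = self.edge_index
        vals = self.scores if weighted else np.ones(len(self.scores))
        a = sp.coo_matrix((vals, (i, j)), shape=(n, n))
        return (a + a.T).tocsr()

    def neighbors(self, i: int) -> np.ndarray:
        mask_a = self.edge_index[0] == i
        mask_b = self.edge_index[1] == i
        return np.sort(
            np.concatenate([self.edge_index[1][mask_a], self.edge_index[0][mask_b]])
        )


@dataclass
class MultiViewGraph:
    """Three node-aligned views over one gene universe."""

    universe: GeneUniverse
    views: dict[str, AlignedView]

    @property
    def n_genes(self) -> int:
        return len(self.universe)


@dataclass
class OmicsFeatureMatrix:
    """Dense per-gene feature matrix (genes x features)."""

    values: np.ndarray
    feature_names: tuple[str, ...]
    normalized: bool = False

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class GeneSetMatrix:
    """Binary gene-set membership matrix (genes x sets)."""

    membership: np.ndarray  # (N, S) int8 in {0, 1}
    set_names: tuple[str, ...]

    @property
    def n_sets(self) -> int:
        return self.membership.shape[1]


@dataclass
class LabelSet:
    """Positive / negative universe indices; the remainder is unlabeled."""

    positives: np.ndarray
    negatives: np.ndarray
    n_genes: int

    def __post_init__(self):
        self.positives = np.asarray(sorted(set(map(int, self.positives))), dtype=np.intp)
        self.negatives = np.asarray(sorted(set(map(int, self.negatives))), dtype=np.intp)
        overlap = set(self.positives) & set(self.negatives)
        if overlap:
            raise ValueError(f"genes labeled both positive and negative: {sorted(overlap)}")

    @property
    def unlabeled(self) -> np.ndarray:
        mask = np.ones(self.n_genes, dtype=bool)
        mask[self.positives] = False
        mask[self.negatives] = False
        return np.nonzero(mask)[0]

    @property
    def labeled(self) -> np.ndarray:
        return np.sort(np.concatenate([self.positives, self.negatives]))

    def y(self) -> tuple[np.ndarray, np.ndarray]:
        """(labeled indices, binary labels) in sorted-index order."""
        idx = self.labeled
        y = np.isin(idx, self.positives).astype(np.float64)
        return idx, y


@dataclass
class DriverDataset:
    """The aligned bundle the model trains on."""

    graph: MultiViewGraph
    features: OmicsFeatureMatrix
    gene_sets: GeneSetMatrix
    labels: LabelSet

    @property
    def n_genes(self) -> int:
        return self.graph.n_genes

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update("|".join(self.graph.universe.symbols).encode())
        for m in MODALITIES:
            v = self.graph.views[m]
            h.update(v.edge_index.tobytes())
            h.update(np.round(v.scores, 12).tobytes())
        h.update(np.round(self.features.values, 12).tobytes())
        h.update(self.gene_sets.membership.tobytes())
        h.update(self.labels.positives.tobytes())
        h.update(self.labels.negatives.tobytes())
        return h.hexdigest()


# ---------------------------------------------------------------------------
# loading


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def load_edge_list(path, modality: str, threshold: float) -> NetworkView:
    """Load a TSV edge list, dropping self-loops, sub-threshold and duplicate edges.

    Duplicates (including reversed orientation) keep the maximum score. A
    header row is auto-detected by a non-numeric third field on line 1.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    edges: dict[tuple[str, str], float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            a, b, raw = fields[0].strip(), fields[1].strip(), fields[2].strip()
            if lineno == 1 and not _is_number(raw):
                continue  # header
            if not _is_number(raw):
                raise ValueError(f"{path}:{lineno}: non-numeric score {raw!r}")
            score = float(raw)
            if not 0.0 <= score <= 1.0:
                raise ValueError(f"{path}:{lineno}: score {score} outside [0, 1]")
            if a == b:
                continue
            if score < threshold:
                continue
            key = (a, b) if a < b else (b, a)
            if score > edges.get(key, -1.0):
                edges[key] = score
    return NetworkView(modality=modality, edges=edges, threshold=threshold)


def _align_view(view: NetworkView, universe: GeneUniverse) -> AlignedView:
    rows, cols, scores = [], [], []
    for (a, b), s in sorted(view.edges.items()):
        ia = universe.index.get(a)
        ib = universe.index.get(b)
        if ia is None or ib is None:
            continue
        i, j = (ia, ib) if ia < ib else (ib, ia)
        rows.append(i)
        cols.append(j)
        scores.append(s)
    edge_index = np.asarray([rows, cols], dtype=np.intp).reshape(2, -1)
    order = np.lexsort((edge_index[1], edge_index[0]))
    return AlignedView(
        modality=view.modality,
        edge_index=edge_index[:, order],
        scores=np.asarray(scores, dtype=np.float64)[order],
        threshold=view.threshold,
    )


def align_views(
    ppi: NetworkView,
    go: NetworkView,
    pathway: NetworkView,
    universe_policy: str = "ppi_nodes",
) -> MultiViewGraph:
    """Re-index the three views onto one universe.

    ``ppi_nodes`` (default): the universe is the PPI node set; GO/pathway
    edges with an endpoint outside it are dropped. ``union``: the universe
    is the union of all view node sets.
    """
    if universe_policy == "ppi_nodes":
        symbols = ppi.nodes
        if not symbols:
            raise ValueError("PPI view has no edges; cannot define a gene universe")
    elif universe_policy == "union":
        symbols = ppi.nodes | go.nodes | pathway.nodes
        if not symbols:
            raise ValueError("all views are empty; cannot define a gene universe")
    else:
        raise ValueError(f"unknown universe_policy {universe_policy!r}")
    universe = GeneUniverse.from_symbols(symbols)
    views = {
        "PPI": _align_view(ppi, universe),
        "GO": _align_view(go, universe),
        "Pathway": _align_view(pathway, universe),
    }
    return MultiViewGraph(universe=universe, views=views)


def load_gene_sets(
    path, universe: GeneUniverse, exclusion_keywords: tuple[str, ...] = ("cancer",)
) -> GeneSetMatrix:
    """Parse a GMT file into a binary membership matrix over the universe.

    Sets whose name contains any exclusion keyword (case-insensitive) are
    removed, as are sets with no universe genes.
    """
    keywords = tuple(k.lower() for k in exclusion_keywords)
    names: list[str] = []
    columns: list[np.ndarray] = []
    n = len(universe)
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                continue
            name, _desc, genes = fields[0], fields[1], fields[2:]
            if any(k in name.lower() for k in keywords):
                continue
            col = np.zeros(n, dtype=np.int8)
            for g in genes:
                idx = universe.index.get(g.strip())
                if idx is not None:
                    col[idx] = 1
            if col.any():
                names.append(name)
                columns.append(col)
    if not names:
        raise ValueError(
            "no gene sets survive keyword/universe filtering; "
            "check exclusion keywords and the gene universe"
        )
    return GeneSetMatrix(membership=np.stack(columns, axis=1), set_names=tuple(names))


def load_features(path, universe: GeneUniverse) -> OmicsFeatureMatrix:
    """Load the per-gene feature table (TSV/CSV) aligned to the universe.

    Universe genes missing from the table get NaN rows here; they become
    all-zero after z-score normalization (with a logged count).
    """
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    df.index = df.index.astype(str).str.strip()
    aligned = df.reindex(list(universe.symbols))
    missing = int(aligned.isna().all(axis=1).sum())
    if missing:
        logger.warning(
            "%d universe genes missing from the feature table; "
            "they receive all-zero features after normalization",
            missing,
        )
    return OmicsFeatureMatrix(
        values=aligned.to_numpy(dtype=np.float64),
        feature_names=tuple(str(c) for c in df.columns),
        normalized=False,
    )


def zscore_normalize(features: OmicsFeatureMatrix) -> OmicsFeatureMatrix:
    """Column-wise z-score using the population standard deviation.

    NaN entries (genes absent from the table) are ignored for the column
    statistics and mapped to 0; constant columns map to all-zeros. The
    standardization is computed once over the whole matrix, before any
    train/test split — the convention this pipeline follows; note this
    shares column statistics across folds.
    """
    x = features.values.astype(np.float64)
    if x.shape[0] < 2:
        raise ValueError("z-score normalization needs at least 2 genes")
    mean = np.nanmean(x, axis=0)
    sd = np.nanstd(x, axis=0)  # population sd
    sd_safe = np.where(sd < 1e-12, 1.0, sd)
    out = (x - mean) / sd_safe
    out[:, sd < 1e-12] = 0.0
    out = np.nan_to_num(out, nan=0.0)
    return OmicsFeatureMatrix(
        values=out, feature_names=features.feature_names, normalized=True
    )


def _read_symbol_list(path) -> list[str]:
    out = []
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            out.append(s)
    return out


def build_labels(positive_path, negative_path, universe: GeneUniverse) -> LabelSet:
    """Read positive/negative symbol lists and map them onto the universe."""
    pos_syms = _read_symbol_list(positive_path)
    neg_syms = _read_symbol_list(negative_path)
    conflict = sorted(set(pos_syms) & set(neg_syms))
    if conflict:
        raise ValueError(f"genes listed as both positive and negative: {conflict}")
    pos = [universe.index[s] for s in pos_syms if s in universe]
    neg = [universe.index[s] for s in neg_syms if s in universe]
    dropped = (len(pos_syms) - len(pos)) + (len(neg_syms) - len(neg))
    if dropped:
        logger.info("dropped %d labeled genes outside the universe", dropped)
    return LabelSet(positives=pos, negatives=neg, n_genes=len(universe))


def load_dataset(
    ppi_path,
    go_path,
    pathway_path,
    features_path,
    genesets_path,
    positives_path,
    negatives_path,
    thresholds: dict[str, float] | None = None,
    exclusion_keywords: tuple[str, ...] = ("cancer",),
    universe_policy: str = "ppi_nodes",
) -> DriverDataset:
    """Load and align every input file into one :class:`DriverDataset`."""
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    ppi = load_edge_list(ppi_path, "PPI", thr["PPI"])
    go = load_edge_list(go_path, "GO", thr["GO"])
    pathway = load_edge_list(pathway_path, "Pathway", thr["Pathway"])
    graph = align_views(ppi, go, pathway, universe_policy=universe_policy)
    features = zscore_normalize(load_features(features_path, graph.universe))
    gene_sets = load_gene_sets(genesets_path, graph.universe, exclusion_keywords)
    labels = build_labels(positives_path, negatives_path, graph.universe)
    return DriverDataset(graph=graph, features=features, gene_sets=gene_sets, labels=labels)
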