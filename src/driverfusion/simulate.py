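"""Seeded synthetic datasets with the statistical structure the model assumes.

The generator emulates the shape of the real training corpus: three
partially overlapping weighted gene networks with heterogeneous (hub-heavy)
degrees, a dense multi-omics-like feature matrix in which a planted driver
class has shifted means, a sparse binary gene-set matrix in which some sets
are enriched for drivers, and an imbalanced label set (defaults echo the
~1 : 2.7 positive-to-negative ratio of curated driver corpora).

Degree heterogeneity comes from a Chung–Lu expected-degree model: gene
``i`` carries a weight ``w_i`` (lognormal, multiplied by ``hub_bias`` for
drivers) and pair ``(i, j)`` is connected with probability proportional to
``w_i * w_j``, calibrated so the expected edge count matches
``edge_density``. A fraction ``view_overlap`` of PPI edges is copied into
the GO and pathway views; the remainder of each view is drawn
independently. Edge scores are uniform above each view's threshold, so
every generated file passes the loader's filters unchanged.

All randomness flows from one master seed through per-component
``numpy.random.SeedSequence`` spawns, making regeneration bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io import (
    DEFAULT_THRESHOLDS,
    MODALITIES,
    AlignedView,
    DriverDataset,
    GeneSetMatrix,
    GeneUniverse,
    LabelSet,
    MultiViewGraph,
    OmicsFeatureMatrix,
    zscore_normalize,
)

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate", "describe", "write_dataset"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters. Defaults are the package's standard benchmark
    conditions: 500 genes, 60 planted drivers vs 160 curated negatives
    (~1 : 2.7), a 1.5-sd mean shift on half of 48 features, 3x driver hub
    bias, and 4x gene-set enrichment over a 0.1 baseline."""

    n_genes: int = 500
    n_drivers: int = 60
    n_negatives: int = 160
    n_features: int = 48
    n_sets: int = 50
    feature_shift: float = 1.5
    hub_bias: float = 3.0
    set_enrichment: float = 0.4
    baseline_set_rate: float = 0.1
    view_overlap: float = 0.5
    edge_density: float = 0.016
    seed: int = 0

    def __post_init__(self):
        if self.n_drivers + self.n_negatives > self.n_genes:
            raise ValueError("n_drivers + n_negatives exceeds n_genes")
        if min(self.n_genes, self.n_drivers, self.n_negatives, self.n_features, self.n_sets) < 1:
            raise ValueError("all sizes must be positive")
        for name in ("set_enrichment", "baseline_set_rate"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")
        if not 0.0 <= self.view_overlap <= 1.0:
            raise ValueError("view_overlap must lie in [0, 1]")
        if not 0.0 < self.edge_density < 1.0:
            raise ValueError("edge_density must lie in (0, 1)")
        if self.hub_bias < 1.0:
            raise ValueError("hub_bias must be >= 1")
        # feasibility: at least one expected edge, and room for the planted classes
        if self.edge_density * self.n_genes * (self.n_genes - 1) / 2 < 1.0:
            raise ValueError("edge_density too low: expected edge count below 1")

    @classmethod
    def null(cls, seed: int = 0, **overrides) -> "SyntheticConfig":
        """A no-signal configuration: drivers are statistically
        indistinguishable from the background (flat features, no hub bias,
        baseline gene-set rates)."""
        cfg = cls(seed=seed, **overrides)
        return replace(
            cfg, feature_shift=0.0, hub_bias=1.0, set_enrichment=cfg.baseline_set_rate
        )


@dataclass
class SyntheticDataset:
    """A generated dataset plus the planted ground truth."""

    dataset: DriverDataset
    truth: np.ndarray  # bool, True where the gene is a planted driver
    config: SyntheticConfig

    # convenience passthroughs
    @property
    def graph(self) -> MultiViewGraph:
        return self.dataset.graph

    @property
    def features(self) -> OmicsFeatureMatrix:
        return self.dataset.features

    @property
    def gene_sets(self) -> GeneSetMatrix:
        return self.dataset.gene_sets

    @property
    def labels(self) -> LabelSet:
        return self.dataset.labels


def _chung_lu_edges(
    rng: np.random.Generator, weights: np.ndarray, target_edges: float
) -> set[tuple[int, int]]:
    """Sample undirected edges with P(i~j) proportional to w_i * w_j,
    scaled so the expected edge count equals ``target_edges`` (probabilities
    capped at 1)."""
    n = len(weights)
    iu, ju = np.triu_indices(n, k=1)
    p = weights[iu] * weights[ju]
    p *= target_edges / p.sum()
    np.clip(p, 0.0, 1.0, out=p)
    hit = rng.random(len(p)) < p
    return set(zip(iu[hit].tolist(), ju[hit].tolist()))


def _view_from_pairs(
    modality: str, pairs: set[tuple[int, int]], rng: np.random.Generator
) -> AlignedView:
    thr = DEFAULT_THRESHOLDS[modality]
    arr = np.asarray(sorted(pairs), dtype=np.intp).reshape(-1, 2).T
    scores = rng.uniform(thr, 1.0, size=arr.shape[1])
    return AlignedView(
        modality=modality, edge_index=arr, scores=scores, threshold=thr
    )


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate one dataset under ``config`` (bit-identical per config+seed)."""
    streams = np.random.SeedSequence(config.seed).spawn(7)
    rng_deg, rng_ppi, rng_go, rng_pw, rng_feat, rng_sets, rng_lab = (
        np.random.default_rng(s) for s in streams
    )
    n = config.n_genes
    width = len(str(n - 1))
    symbols = tuple(f"G{i:0{width}d}" for i in range(n))
    universe = GeneUniverse.from_symbols(symbols)

    # planted classes: the first n_drivers indices are drivers (the naming is
    # lexicographic, so indices are stable); negatives are sampled from the rest
    truth = np.zeros(n, dtype=bool)
    truth[: config.n_drivers] = True

    # --- networks -----------------------------------------------------------
    weights = rng_deg.lognormal(mean=0.0, sigma=0.5, size=n)
    weights[truth] *= config.hub_bias
    target = config.edge_density * n * (n - 1) / 2

    ppi_pairs = _chung_lu_edges(rng_ppi, weights, target)
    # the PPI view defines the universe downstream: attach isolated genes
    isolated = np.setdiff1d(np.arange(n), np.unique(np.asarray(sorted(ppi_pairs)).ravel()) if ppi_pairs else np.array([], dtype=int))
    for i in isolated:
        j = int(rng_ppi.integers(n - 1))
        j = j + 1 if j >= i else j
        ppi_pairs.add((min(i, j), max(i, j)))

    views: dict[str, AlignedView] = {"PPI": _view_from_pairs("PPI", ppi_pairs, rng_ppi)}
    for modality, rng_v in (("GO", rng_go), ("Pathway", rng_pw)):
        ppi_list = sorted(ppi_pairs)
        keep = rng_v.random(len(ppi_list)) < config.view_overlap
        shared = {p for p, k in zip(ppi_list, keep) if k}
        fresh = _chung_lu_edges(rng_v, weights, (1.0 - config.view_overlap) * target)
        views[modality] = _view_from_pairs(modality, shared | fresh, rng_v)
    graph = MultiViewGraph(universe=universe, views=views)

    # --- features ------------------------------------------------------------
    x = rng_feat.normal(size=(n, config.n_features))
    shifted_cols = rng_feat.choice(
        config.n_features, size=config.n_features // 2, replace=False
    )
    x[np.ix_(truth, shifted_cols)] += config.feature_shift
    features = zscore_normalize(
        OmicsFeatureMatrix(
            values=x,
            feature_names=tuple(f"feat_{k:02d}" for k in range(config.n_features)),
            normalized=False,
        )
    )

    # --- gene sets ------------------------------------------------------------
    p_member = np.where(truth[:, None], config.set_enrichment, config.baseline_set_rate)
    membership = (rng_sets.random((n, config.n_sets)) < p_member).astype(np.int8)
    keep_cols = membership.any(axis=0)
    membership = membership[:, keep_cols]
    set_names = tuple(
        f"SET_{k:04d}" for k in np.nonzero(keep_cols)[0]
    )
    gene_sets = GeneSetMatrix(membership=membership, set_names=set_names)

    # --- labels ---------------------------------------------------------------
    nondrivers = np.nonzero(~truth)[0]
    negatives = rng_lab.choice(nondrivers, size=config.n_negatives, replace=False)
    labels = LabelSet(
        positives=np.nonzero(truth)[0], negatives=negatives, n_genes=n
    )

    dataset = DriverDataset(
        graph=graph, features=features, gene_sets=gene_sets, labels=labels
    )
    return SyntheticDataset(dataset=dataset, truth=truth, config=config)


def describe(sd: SyntheticDataset) -> dict:
    """Summary counts (the synthetic analogue of a dataset overview table)."""
    n = sd.graph.n_genes
    out: dict = {"n_genes": n, "n_features": sd.features.n_features, "n_sets": sd.gene_sets.n_sets}
    for m in MODALITIES:
        v = sd.graph.views[m]
        touched = np.unique(v.edge_index.ravel()).size if v.n_edges else 0
        out[m] = {
            "nodes": int(touched),
            "edges": int(v.n_edges),
            "density": float(v.n_edges / (n * (n - 1) / 2)),
        }
    out["labels"] = {
        "positives": int(len(sd.labels.positives)),
        "negatives": int(len(sd.labels.negatives)),
        "unlabeled": int(len(sd.labels.unlabeled)),
    }
    return out


def write_dataset(sd: SyntheticDataset, outdir) -> dict[str, Path]:
    """Write the dataset in exactly the file formats the loaders read.

    Returns the path of every file written. Round-tripping through
    :func:`driverfusion.io.load_dataset` reproduces the in-memory dataset.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    symbols = sd.graph.universe.symbols
    paths: dict[str, Path] = {}

    for m, fname in (("PPI", "ppi.tsv"), ("GO", "go.tsv"), ("Pathway", "pathway.tsv")):
        v = sd.graph.views[m]
        p = outdir / fname
        with open(p, "w") as fh:
            fh.write("gene_a\tgene_b\tscore\n")
            for (i, j), s in zip(v.edge_index.T, v.scores):
                fh.write(f"{symbols[i]}\t{symbols[j]}\t{float(s)!r}\n")
        paths[m] = p

    p = outdir / "features.tsv"
    with open(p, "w") as fh:
        fh.write("gene\t" + "\t".join(sd.features.feature_names) + "\n")
        for i, sym in enumerate(symbols):
            row = "\t".join(repr(float(v)) for v in sd.features.values[i])
            fh.write(f"{sym}\t{row}\n")
    paths["features"] = p

    p = outdir / "genesets.gmt"
    with open(p, "w") as fh:
        for s, name in enumerate(sd.gene_sets.set_names):
            members = [symbols[i] for i in np.nonzero(sd.gene_sets.membership[:, s])[0]]
            fh.write("\t".join([name, "synthetic gene set"] + members) + "\n")
    paths["gene_sets"] = p

    for key, fname, idx in (
        ("positives", "positives.txt", sd.labels.positives),
        ("negatives", "negatives.txt", sd.labels.negatives),
    ):
        p = outdir / fname
        with open(p, "w") as fh:
            fh.write(f"# {key} (synthetic)\n")
            for i in idx:
                fh.write(symbols[i] + "\n")
        paths[key] = p

    p = outdir / "truth.tsv"
    with open(p, "w") as fh:
        fh.write("gene\tis_driver\n")
        for i, sym in enumerate(symbols):
            fh.write(f"{sym}\t{int(sd.truth[i])}\n")
    paths["truth"] = p
    return paths
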