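"""Coherent synthetic inputs with planted disease modules.

The generator emulates the statistical premise that the method exploits:
genes causing the same disease cluster in the interaction network, and
phenotypically similar diseases are caused by related genes.  A bundle
consists of

* a random interactome (preferential-attachment by default, so the degree
  distribution is heavy-tailed like real PPI networks; Erdos--Renyi is
  available);
* disease gene sets ("modules") grown inside small breadth-first
  neighborhoods; diseases are grouped into phenotype clusters whose members
  draw genes from one shared neighborhood pool, so similar phenotypes get
  overlapping or adjacent modules;
* extra within-module edges added with probability ``module_cohesion``,
  which is the main dial for how strongly modularity holds (1 makes each
  module a clique, 0 adds nothing);
* pairwise phenotype similarities drawn uniformly from a high range for
  same-cluster pairs and a low (sub-threshold) range for cross-cluster
  pairs;
* regularly spaced gene positions with jitter on a few synthetic
  chromosomes, enabling artificial-linkage-interval controls.

Setting ``localized_modules=False`` samples disease genes uniformly from
the whole network instead of from neighborhood pools; together with
``module_cohesion=0`` and overlapping similarity ranges this produces a
structureless null bundle on which no method should beat chance.

Everything is deterministic under ``SyntheticConfig.seed``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np

from .io import (
    GeneNetwork,
    GenePositions,
    write_associations,
    write_gene_positions,
    write_network,
)
from .phenotype import PhenotypeSimilarity, write_similarities

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticConfig",
    "Bundle",
    "generate_network",
    "plant_diseases",
    "generate_similarities",
    "generate_positions",
    "generate_bundle",
    "write_bundle",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic bundle.

    Defaults describe a desk-scale interactome: 300 genes with mean degree
    about 8 (the density regime of curated human PPI networks), 20 diseases
    of 2--4 genes each in 4 phenotype clusters, strong module cohesion, and
    informative within-cluster similarities (above the 0.3 threshold) versus
    uninformative cross-cluster ones (below it).
    """

    n_genes: int = 300
    graph_model: str = "ba"  # "ba" (preferential attachment) | "er"
    ba_m: int = 4
    er_p: float = 0.03
    n_diseases: int = 20
    genes_per_disease: tuple[int, int] = (2, 4)
    module_cohesion: float = 0.8
    n_phenotype_clusters: int = 4
    cluster_pool_size: int = 12
    within_cluster_sim: tuple[float, float] = (0.5, 0.9)
    cross_cluster_sim: tuple[float, float] = (0.0, 0.2)
    localized_modules: bool = True
    n_chromosomes: int = 4
    gene_spacing: int = 50_000
    gene_length: tuple[int, int] = (2_000, 5_000)
    position_jitter: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        if self.graph_model not in ("ba", "er"):
            raise ValueError(f"unknown graph model {self.graph_model!r}")
        if not 0.0 <= self.er_p <= 1.0:
            raise ValueError("er_p must be in [0, 1]")
        if not 0.0 <= self.module_cohesion <= 1.0:
            raise ValueError("module_cohesion must be in [0, 1]")
        lo, hi = self.genes_per_disease
        if lo < 2 or hi < lo:
            raise ValueError("genes_per_disease must satisfy 2 <= lo <= hi")
        for name in ("within_cluster_sim", "cross_cluster_sim"):
            lo, hi = getattr(self, name)
            if not 0.0 <= lo <= hi <= 1.0:
                raise ValueError(f"{name} must be an ordered range in [0, 1]")
        if self.n_phenotype_clusters < 1 or self.n_chromosomes < 1:
            raise ValueError("cluster and chromosome counts must be >= 1")


@dataclass
class Bundle:
    """In-memory synthetic dataset."""

    network: GeneNetwork
    associations: dict[str, frozenset[str]]
    similarities: PhenotypeSimilarity
    positions: GenePositions
    clusters: dict[str, int]
    config: SyntheticConfig


def _gene_name(i: int) -> str:
    return f"g{i:05d}"


def _disease_name(i: int) -> str:
    return f"D{i:03d}"


def generate_network(config: SyntheticConfig,
                     rng: np.random.Generator | None = None) -> GeneNetwork:
    """Random simple undirected interactome under the configured model."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    # networkx takes an integer seed; derive one below 2**31 from our stream
    nx_seed = int(rng.integers(0, 2**31 - 1))
    if config.graph_model == "ba":
        m = min(config.ba_m, config.n_genes - 1)
        graph = nx.barabasi_albert_graph(config.n_genes, m, seed=nx_seed)
    else:
        graph = nx.gnp_random_graph(config.n_genes, config.er_p, seed=nx_seed)
    edges = [(_gene_name(a), _gene_name(b)) for a, b in graph.edges]
    nodes = [_gene_name(i) for i in range(config.n_genes)]
    return GeneNetwork(edges=edges, nodes=nodes)


def _bfs_pool(network: GeneNetwork, anchor: str, size: int) -> list[str]:
    """First ``size`` nodes in breadth-first order from ``anchor`` (sorted
    within each depth level for determinism)."""
    pool = [anchor]
    seen = {anchor}
    frontier = [anchor]
    while frontier and len(pool) < size:
        nxt = []
        for node in frontier:
            for nb in network.neighbors(node):
                if nb not in seen:
                    seen.add(nb)
                    nxt.append(nb)
        nxt.sort()
        pool.extend(nxt)
        frontier = nxt
    return pool[:size]


def plant_diseases(network: GeneNetwork, config: SyntheticConfig,
                   rng: np.random.Generator | None = None,
                   ) -> tuple[GeneNetwork, dict[str, frozenset[str]], dict[str, int]]:
    """Plant disease modules; returns (augmented network, associations,
    disease -> phenotype-cluster assignment).

    Each phenotype cluster is anchored at a random node; its diseases draw
    their gene sets from the anchor's breadth-first neighborhood pool, so
    same-cluster diseases share network territory.  Each within-module gene
    pair then gains an edge with probability ``module_cohesion``.  With
    ``localized_modules=False`` gene sets are drawn uniformly from all
    genes and no territory is shared.
    """
    if network.n_nodes == 0:
        raise ValueError("cannot plant diseases on an empty network")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    nodes = list(network.nodes)
    clusters = {
        _disease_name(i): i % config.n_phenotype_clusters
        for i in range(config.n_diseases)
    }
    pools: dict[int, list[str]] = {}
    for c in range(config.n_phenotype_clusters):
        anchor = nodes[int(rng.integers(len(nodes)))]
        pools[c] = _bfs_pool(network, anchor,
                             max(config.cluster_pool_size,
                                 config.genes_per_disease[1]))
    associations: dict[str, frozenset[str]] = {}
    new_edges: set[tuple[str, str]] = set(network.edges)
    lo, hi = config.genes_per_disease
    for disease in sorted(clusters):
        pool = pools[clusters[disease]] if config.localized_modules else nodes
        k = min(int(rng.integers(lo, hi + 1)), len(pool))
        picked = rng.choice(len(pool), size=k, replace=False)
        genes = sorted(pool[i] for i in picked)
        associations[disease] = frozenset(genes)
        for i, a in enumerate(genes):
            for b in genes[i + 1:]:
                edge = (a, b) if a < b else (b, a)
                if edge not in new_edges and rng.random() < config.module_cohesion:
                    new_edges.add(edge)
    augmented = GeneNetwork(edges=new_edges, nodes=network.nodes)
    return augmented, associations, clusters


def generate_similarities(clusters: Mapping[str, int], config: SyntheticConfig,
                          rng: np.random.Generator | None = None,
                          ) -> PhenotypeSimilarity:
    """Pairwise similarities: same-cluster pairs from the high range,
    cross-cluster pairs from the low range."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sims = PhenotypeSimilarity()
    diseases = sorted(clusters)
    for i, a in enumerate(diseases):
        for b in diseases[i + 1:]:
            rng_range = (config.within_cluster_sim
                         if clusters[a] == clusters[b]
                         else config.cross_cluster_sim)
            sims.add(a, b, float(rng.uniform(*rng_range)))
    return sims


def generate_positions(network: GeneNetwork, config: SyntheticConfig,
                       rng: np.random.Generator | None = None) -> GenePositions:
    """Regularly spaced jittered gene intervals on synthetic chromosomes.

    Genes (in node order) are split evenly across chromosomes in consecutive
    blocks, so network-adjacent module members are usually genomic
    neighbors too -- the situation linkage-interval controls are meant to
    stress.
    """
    if network.n_nodes == 0:
        raise ValueError("cannot place genes of an empty network")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    genes = list(network.nodes)
    per_chrom = int(np.ceil(len(genes) / config.n_chromosomes))
    records: dict[str, tuple[str, int, int]] = {}
    for i, gene in enumerate(genes):
        chrom = f"chr{i // per_chrom + 1}"
        slot = i % per_chrom
        start = slot * config.gene_spacing + int(
            rng.integers(0, max(config.position_jitter, 1))
        )
        length = int(rng.integers(config.gene_length[0],
                                  config.gene_length[1] + 1))
        records[gene] = (chrom, start, start + length)
    return GenePositions(records=records)


def generate_bundle(config: SyntheticConfig) -> Bundle:
    """Generate all four artifacts from one seeded stream."""
    rng = np.random.default_rng(config.seed)
    base = generate_network(config, rng)
    network, associations, clusters = plant_diseases(base, config, rng)
    similarities = generate_similarities(clusters, config, rng)
    positions = generate_positions(network, config, rng)
    return Bundle(network=network, associations=associations,
                  similarities=similarities, positions=positions,
                  clusters=clusters, config=config)


def write_bundle(bundle: Bundle, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle as the four TSV inputs plus a manifest JSON.

    The manifest records the full configuration (including the seed), so
    the bundle can be regenerated identically.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "network": outdir / "network.tsv",
        "associations": outdir / "associations.tsv",
        "similarities": outdir / "similarities.tsv",
        "positions": outdir / "positions.bed",
        "manifest": outdir / "manifest.json",
    }
    write_network(bundle.network, paths["network"])
    write_associations(bundle.associations, paths["associations"])
    write_similarities(bundle.similarities, paths["similarities"])
    write_gene_positions(bundle.positions, paths["positions"])
    manifest = {
        "config": asdict(bundle.config),
        "clusters": bundle.clusters,
        "n_nodes": bundle.network.n_nodes,
        "n_edges": bundle.network.n_edges,
        "files": {k: v.name for k, v in paths.items() if k != "manifest"},
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("wrote bundle to %s (%d nodes, %d edges, %d diseases)",
                outdir, bundle.network.n_nodes, bundle.network.n_edges,
                len(bundle.associations))
    return paths
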