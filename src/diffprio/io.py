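"""Input/output for the four tabular data kinds and the transition matrix.

The package consumes four plain-text inputs:

* an undirected protein--protein interaction network as a two-column
  edge-list TSV of gene identifiers;
* disease--gene associations as a two-column TSV (disease_id, gene_id);
* sparse pairwise phenotype similarities as a three-column TSV
  (disease_id_a, disease_id_b, similarity in [0, 1]) -- parsed in
  :mod:`diffprio.phenotype`;
* optional gene positions as BED4 (chrom, chromStart, chromEnd, gene_id),
  0-based half-open, used to build artificial-linkage-interval controls.

Gene and disease identifiers are opaque strings; no symbol translation is
attempted.  Node order is fixed lexicographically at load time so that every
vector and matrix in the package shares one stable index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "DataFormatError",
    "GeneNetwork",
    "TransitionMatrix",
    "GenePositions",
    "load_network",
    "build_transition_matrix",
    "load_associations",
    "load_gene_positions",
    "write_network",
    "write_associations",
    "write_gene_positions",
]


class DataFormatError(ValueError):
    """An input file violates its documented format."""


def _data_lines(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    """Yield (1-based line number, whitespace-split fields), skipping blank
    lines and '#' comments."""
    with open(path, "r", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split()


class GeneNetwork:
    """Undirected simple graph over gene identifiers.

    Self-loops are dropped and parallel/reversed duplicate edges collapsed on
    construction.  Nodes are ordered lexicographically; ``node_index`` maps a
    gene id to its position in that order, which is the coordinate system of
    every distribution vector and transition matrix built from this network.
    """

    def __init__(self, edges: Iterable[tuple[str, str]] = (),
                 nodes: Iterable[str] = ()) -> None:
        graph = nx.Graph()
        graph.add_nodes_from(str(n) for n in nodes)
        graph.add_edges_from(
            (str(a), str(b)) for a, b in edges if str(a) != str(b)
        )
        self._graph = graph
        self.nodes: tuple[str, ...] = tuple(sorted(graph.nodes))
        self.node_index: dict[str, int] = {g: i for i, g in enumerate(self.nodes)}

    # -- basic queries ----------------------------------------------------

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        """Edge set as sorted (a, b) tuples with a < b."""
        return frozenset(tuple(sorted(e)) for e in self._graph.edges)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def __contains__(self, gene: str) -> bool:
        return gene in self.node_index

    def __len__(self) -> int:
        return len(self.nodes)

    def degree(self, gene: str) -> int:
        return int(self._graph.degree[gene])

    def neighbors(self, gene: str) -> list[str]:
        return sorted(self._graph.neighbors(gene))

    def to_networkx(self) -> nx.Graph:
        """A copy of the underlying :class:`networkx.Graph`."""
        return self._graph.copy()

    def largest_component(self) -> "GeneNetwork":
        """Restrict to the largest connected component (ties broken by the
        lexicographically smallest member node)."""
        if self.n_nodes == 0:
            return GeneNetwork()
        comps = sorted(nx.connected_components(self._graph),
                       key=lambda c: (-len(c), min(c)))
        keep = comps[0]
        return GeneNetwork(
            edges=(e for e in self.edges if e[0] in keep),
            nodes=keep,
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"GeneNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


@dataclass(frozen=True)
class TransitionMatrix:
    """Column-normalized adjacency matrix of a :class:`GeneNetwork`.

    ``matrix[i, j]`` is the probability that a walker at node ``j`` steps to
    node ``i``: ``1/degree(j)`` for each neighbor ``i`` of ``j``.  Columns of
    isolated (degree-0) nodes are all-zero; the diffusion engine compensates
    by renormalizing iterates (see :func:`diffprio.diffusion.rwr`).
    """

    matrix: sp.csr_matrix
    nodes: tuple[str, ...]
    node_index: Mapping[str, int]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


def load_network(path: str | Path, *, largest_component: bool = False) -> GeneNetwork:
    """Load an undirected network from a two-column edge-list TSV.

    Self-loops are dropped and duplicate edges (in either orientation)
    collapsed; the counts of dropped records are logged.  Lines starting with
    ``#`` are comments.  With ``largest_component=True`` the network is
    restricted to its largest connected component after loading.
    """
    edges: set[tuple[str, str]] = set()
    nodes: set[str] = set()
    n_self = 0
    n_dup = 0
    for lineno, fields in _data_lines(path):
        if len(fields) < 2:
            raise DataFormatError(
                f"{path}:{lineno}: expected at least 2 fields, got {len(fields)}"
            )
        a, b = fields[0], fields[1]
        nodes.update((a, b))
        if a == b:
            n_self += 1
            continue
        edge = (a, b) if a < b else (b, a)
        if edge in edges:
            n_dup += 1
        else:
            edges.add(edge)
    network = GeneNetwork(edges=edges, nodes=nodes)
    logger.info(
        "loaded network from %s: %d nodes, %d edges "
        "(%d self-loops and %d duplicate edges dropped)",
        path, network.n_nodes, network.n_edges, n_self, n_dup,
    )
    if largest_component:
        network = network.largest_component()
        logger.info("restricted to largest component: %d nodes, %d edges",
                    network.n_nodes, network.n_edges)
    return network


def build_transition_matrix(network: GeneNetwork) -> TransitionMatrix:
    """Column-normalize the adjacency matrix of ``network``.

    Every column over a node with degree >= 1 sums to exactly 1; columns of
    isolated nodes are left all-zero.
    """
    if network.n_nodes == 0:
        raise ValueError("cannot build a transition matrix for an empty network")
    n = network.n_nodes
    idx = network.node_index
    rows: list[int] = []
    cols: list[int] = []
    for a, b in network.edges:
        ia, ib = idx[a], idx[b]
        rows.extend((ia, ib))
        cols.extend((ib, ia))
    adj = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n), dtype=np.float64
    )
    degree = np.asarray(adj.sum(axis=0)).ravel()
    inv = np.zeros(n)
    nonzero = degree > 0
    inv[nonzero] = 1.0 / degree[nonzero]
    matrix = (adj @ sp.diags(inv)).tocsr()
    return TransitionMatrix(matrix=matrix, nodes=network.nodes,
                            node_index=dict(idx))


def load_associations(path: str | Path, network: GeneNetwork, *,
                      drop_single_gene: bool = False) -> dict[str, frozenset[str]]:
    """Load disease--gene associations as ``{disease_id: genes}``.

    Duplicate pairs collapse silently; pairs whose gene is not a network node
    are dropped with a logged count.  ``drop_single_gene=True`` additionally
    discards diseases left with a single associated gene, which makes the map
    usable for leave-one-out cross-validation.
    """
    raw: dict[str, set[str]] = {}
    n_missing = 0
    for lineno, fields in _data_lines(path):
        if len(fields) < 2:
            raise DataFormatError(
                f"{path}:{lineno}: expected 2 fields (disease_id, gene_id), "
                f"got {len(fields)}"
            )
        disease, gene = fields[0], fields[1]
        if gene not in network:
            n_missing += 1
            continue
        raw.setdefault(disease, set()).add(gene)
    if drop_single_gene:
        dropped = [d for d, genes in raw.items() if len(genes) < 2]
        for d in dropped:
            del raw[d]
        if dropped:
            logger.info("dropped %d single-gene diseases", len(dropped))
    if n_missing:
        logger.info("dropped %d associations with genes absent from the network",
                    n_missing)
    return {d: frozenset(genes) for d, genes in raw.items()}


@dataclass(frozen=True)
class GenePositions:
    """Genomic positions, BED convention (0-based, half-open)."""

    records: Mapping[str, tuple[str, int, int]]

    def __contains__(self, gene: str) -> bool:
        return gene in self.records

    def midpoint(self, gene: str) -> tuple[str, float]:
        """(chromosome, midpoint in bp) of a gene's interval."""
        chrom, start, end = self.records[gene]
        return chrom, (start + end) / 2.0


def load_gene_positions(path: str | Path) -> GenePositions:
    """Load a BED4 file (chrom, chromStart, chromEnd, gene_id)."""
    records: dict[str, tuple[str, int, int]] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 4:
            raise DataFormatError(
                f"{path}:{lineno}: expected 4 fields (chrom, start, end, name), "
                f"got {len(fields)}"
            )
        chrom, name = fields[0], fields[3]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise DataFormatError(
                f"{path}:{lineno}: non-integer coordinate"
            ) from exc
        if start > end:
            raise DataFormatError(f"{path}:{lineno}: start {start} > end {end}")
        if name in records:
            raise DataFormatError(f"{path}:{lineno}: duplicate record for {name!r}")
        records[name] = (chrom, start, end)
    return GenePositions(records=records)


# -- writers (round-trip counterparts used by the synthetic-data bundle) ---


def write_network(network: GeneNetwork, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("# gene_a\tgene_b\n")
        for a, b in sorted(network.edges):
            handle.write(f"{a}\t{b}\n")
        # isolated nodes are written as self-referential records: the loader
        # drops the self-loop but keeps both endpoints, so the node set
        # round-trips exactly
        for g in network.nodes:
            if network.degree(g) == 0:
                handle.write(f"{g}\t{g}\n")


def write_associations(associations: Mapping[str, Iterable[str]],
                       path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("# disease_id\tgene_id\n")
        for disease in sorted(associations):
            for gene in sorted(associations[disease]):
                handle.write(f"{disease}\t{gene}\n")


def write_gene_positions(positions: GenePositions, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for gene in sorted(positions.records):
            chrom, start, end = positions.records[gene]
            handle.write(f"{chrom}\t{start}\t{end}\t{gene}\n")
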