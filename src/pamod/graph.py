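"""Network data model, file I/O, construction filter, and connectivity.

The working representation is :class:`ScoredNetwork`: a simple undirected
graph whose nodes carry a differential-expression p-value and an additive
activity score. Candidate modules are binary membership vectors over a
fixed node ordering (lexicographic by gene id), which makes crossover on
bit vectors well defined and runs reproducible.

Connectivity of a candidate module is decided through the algebraic
connectivity (Fiedler value): the second-smallest eigenvalue of the
Laplacian L = D - A of the induced subgraph, which is positive iff the
subgraph is connected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.linalg import eigh

__all__ = [
    "ScoredNetwork",
    "read_network",
    "write_network",
    "build_network",
    "laplacian",
    "algebraic_connectivity",
    "is_connected",
    "CONNECTIVITY_EPS",
]

logger = logging.getLogger(__name__)

#: Tolerance below which a computed Fiedler value is treated as zero.
CONNECTIVITY_EPS = 1e-8


@dataclass
class ScoredNetwork:
    """Simple undirected graph with per-node p-values and activity scores.

    ``node_order`` is lexicographic by gene id and fixed at construction;
    membership vectors, adjacency matrices and all outputs are aligned to
    it. ``pvalues`` and ``scores`` are arrays in node order (NaN where
    unassigned).
    """

    graph: nx.Graph
    node_order: list[str] = field(init=False)
    pvalues: np.ndarray | None = None
    scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.node_order = sorted(self.graph.nodes)
        self._index = {g: i for i, g in enumerate(self.node_order)}
        self._adj = None
        self._nbrs = None

    # -- basic accessors ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.node_order)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def index_of(self, gene: str) -> int:
        return self._index[gene]

    def genes_of(self, sel: np.ndarray) -> list[str]:
        """Gene ids selected by a boolean membership vector."""
        sel = np.asarray(sel, dtype=bool)
        return [self.node_order[i] for i in np.flatnonzero(sel)]

    def selection_of(self, genes: Iterable[str]) -> np.ndarray:
        """Boolean membership vector for a collection of gene ids."""
        sel = np.zeros(self.n_nodes, dtype=bool)
        for g in genes:
            sel[self._index[g]] = True
        return sel

    # -- cached structure --------------------------------------------------
    @property
    def adjacency(self) -> np.ndarray:
        """Dense boolean adjacency matrix in node order (cached)."""
        if self._adj is None:
            self._adj = nx.to_numpy_array(
                self.graph, nodelist=self.node_order, dtype=float
            ).astype(bool)
        return self._adj

    @property
    def neighbor_indices(self) -> list[np.ndarray]:
        """Sorted neighbour index array per node (cached)."""
        if self._nbrs is None:
            self._nbrs = [
                np.array(
                    sorted(self._index[v] for v in self.graph.neighbors(g)),
                    dtype=np.int64,
                )
                for g in self.node_order
            ]
        return self._nbrs

    # -- scoring -----------------------------------------------------------
    def set_pvalues(self, pvals) -> None:
        """Attach p-values from a mapping/Series gene -> p."""
        arr = np.full(self.n_nodes, np.nan)
        for g, p in dict(pvals).items():
            if g in self._index:
                arr[self._index[g]] = p
        self.pvalues = arr

    def assign_scores(self, scheme) -> None:
        """Score every node from its p-value; nodes without a p-value get
        the score of p = 1 (i.e. the most non-significant score)."""
        from .bum import node_score

        if self.pvalues is None:
            raise ValueError("p-values must be set before scoring")
        p = np.where(np.isnan(self.pvalues), 1.0, self.pvalues)
        self.scores = np.asarray(node_score(p, scheme), dtype=float)


def _parse_edge_line(line: str, lineno: int, path) -> tuple[str, str] | None:
    parts = line.rstrip("\n").split("\t")
    if len(parts) == 1 and parts[0].strip() == "":
        return None
    if len(parts) == 2:
        return parts[0].strip(), parts[1].strip()
    if len(parts) == 3:  # SIF dialect: src <TAB> interaction-type <TAB> dst
        return parts[0].strip(), parts[2].strip()
    raise ValueError(
        f"{path}:{lineno}: expected 2 (edge list) or 3 (SIF) tab-separated "
        f"fields, got {len(parts)}"
    )


def read_network(path) -> ScoredNetwork:
    """Read an edge list (``src<TAB>dst``) or SIF (``src<TAB>type<TAB>dst``).

    Self-loops and duplicate edges are dropped with a logged count; the
    result is a simple undirected graph.
    """
    g = nx.Graph()
    n_self, n_dup = 0, 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parsed = _parse_edge_line(line, lineno, path)
            if parsed is None:
                continue
            u, v = parsed
            if not u or not v:
                raise ValueError(f"{path}:{lineno}: empty gene id")
            if u == v:
                n_self += 1
                continue
            if g.has_edge(u, v):
                n_dup += 1
                continue
            g.add_edge(u, v)
    if n_self or n_dup:
        logger.warning(
            "%s: dropped %d self-loop(s) and %d duplicate edge(s)",
            path, n_self, n_dup,
        )
    return ScoredNetwork(g)


def write_network(net: ScoredNetwork, path) -> None:
    """Write the edge list as ``src<TAB>dst``, edges in node order."""
    with open(path, "w") as fh:
        for u, v in sorted(
            (tuple(sorted(e)) for e in net.graph.edges), key=lambda e: e
        ):
            fh.write(f"{u}\t{v}\n")


def build_network(
    interactions: ScoredNetwork | Sequence[tuple[str, str]],
    de_table,
    p_cutoff: float = 0.05,
) -> ScoredNetwork:
    """Filter an interactome down to the differential-expression vicinity.

    Keeps exactly the interactions with at least one endpoint in the set of
    differentially expressed genes ``{g : p_adj(g) <= p_cutoff}`` (so that
    indirect interactions via a single non-DE partner are retained), and
    returns the graph on the nodes incident to kept edges.

    Parameters
    ----------
    interactions : ScoredNetwork or iterable of (src, dst) pairs
    de_table : mapping/Series gene -> adjusted p-value
    p_cutoff : float
        Adjusted-p-value cutoff defining differential expression.
    """
    if isinstance(interactions, ScoredNetwork):
        edges = list(interactions.graph.edges)
    else:
        edges = [tuple(e) for e in interactions]
    de_table = dict(de_table)
    de_genes = {g for g, p in de_table.items() if p <= p_cutoff}
    g = nx.Graph()
    for u, v in edges:
        if u == v:
            continue
        if u in de_genes or v in de_genes:
            g.add_edge(u, v)
    if g.number_of_edges() == 0:
        raise ValueError(
            f"no interaction has a differentially expressed endpoint at "
            f"adjusted p <= {p_cutoff}; consider relaxing the cutoff"
        )
    net = ScoredNetwork(g)
    net.set_pvalues({g_: p for g_, p in de_table.items() if g_ in net._index})
    return net


def laplacian(net: ScoredNetwork, sel: np.ndarray) -> np.ndarray:
    """Laplacian L = D - A of the subgraph induced by the selection."""
    idx = np.flatnonzero(np.asarray(sel, dtype=bool))
    if idx.size == 0:
        raise ValueError("empty selection has no Laplacian")
    sub = net.adjacency[np.ix_(idx, idx)].astype(float)
    return np.diag(sub.sum(axis=1)) - sub


def algebraic_connectivity(net: ScoredNetwork, sel: np.ndarray) -> float:
    """Fiedler value (second-smallest Laplacian eigenvalue) of the induced
    subgraph; positive iff the subgraph is connected."""
    idx = np.flatnonzero(np.asarray(sel, dtype=bool))
    if idx.size < 2:
        raise ValueError("algebraic connectivity needs a selection of size >= 2")
    lap = laplacian(net, sel)
    # only the two smallest eigenvalues are needed
    vals = eigh(lap, eigvals_only=True, subset_by_index=[0, 1])
    return float(vals[1])


def is_connected(net: ScoredNetwork, sel: np.ndarray) -> bool:
    """Connectivity of the induced subgraph via the Fiedler value.

    The empty selection is not connected; a single node is connected by
    convention; otherwise the test is ``algebraic_connectivity > eps``.
    """
    sel = np.asarray(sel, dtype=bool)
    k = int(sel.sum())
    if k == 0:
        return False
    if k == 1:
        return True
    return algebraic_connectivity(net, sel) > CONNECTIVITY_EPS


def write_gene_list(net: ScoredNetwork, sel: np.ndarray, path) -> None:
    """Export a module as a plain gene list (one id per line), the format
    accepted by GO enrichment web tools."""
    Path(path).write_text("".join(g + "\n" for g in net.genes_of(sel)))


def write_edge_sublist(net: ScoredNetwork, sel: np.ndarray, path) -> None:
    """Export the edges of the induced subgraph as a two-column TSV."""
    genes = set(net.genes_of(sel))
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in net.graph.edges):
            if u in genes and v in genes:
                fh.write(f"{u}\t{v}\n")
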