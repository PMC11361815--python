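"""Protein–protein interaction networks, seed sets, and network statistics.

A :class:`PPINetwork` is an undirected graph over opaque gene identifiers
with a sparse symmetric binary adjacency matrix.  Self-loops represent
self-interacting proteins (SIPs) and are stored as ``A_ii = 1``,
contributing 1 to their node's degree.  Disease seed genes are mapped onto
the network by exact, case-sensitive identifier match.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .exceptions import InputFormatError, SeedCoverageError

logger = logging.getLogger(__name__)

__all__ = [
    "PPINetwork",
    "SeedSet",
    "NetworkStats",
    "load_edge_list",
    "read_seed_file",
    "map_seeds",
    "network_stats",
    "laplacian",
]


@dataclass
class PPINetwork:
    """Undirected PPI network with binary symmetric adjacency.

    Parameters
    ----------
    node_ids
        Gene identifiers in index order (position defines node index).
    adjacency
        Sparse symmetric CSR matrix with entries in {0, 1}; ``A_ii = 1``
        marks a self-interacting protein.
    """

    node_ids: list[str]
    adjacency: sp.csr_matrix
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        A = sp.csr_matrix(self.adjacency, dtype=np.float64)
        if A.shape[0] != A.shape[1] or A.shape[0] != len(self.node_ids):
            raise InputFormatError("adjacency shape does not match node_ids")
        if len(set(self.node_ids)) != len(self.node_ids):
            raise InputFormatError("duplicate node identifiers")
        if (A != A.T).nnz != 0:
            raise InputFormatError("adjacency must be symmetric")
        data = A.data
        if data.size and not np.isin(data, (0.0, 1.0)).all():
            raise InputFormatError("adjacency entries must be 0 or 1")
        A.eliminate_zeros()
        self.adjacency = A
        self._index = {g: i for i, g in enumerate(self.node_ids)}

    @property
    def n(self) -> int:
        return len(self.node_ids)

    @property
    def m(self) -> int:
        """Undirected edge count, self-loops counted once."""
        n_loops = int(self.adjacency.diagonal().sum())
        return (self.adjacency.nnz - n_loops) // 2 + n_loops

    @property
    def sip_count(self) -> int:
        return int(self.adjacency.diagonal().sum())

    def index_of(self, gene: str) -> int:
        return self._index[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def degrees(self, include_self_loops: bool = True) -> np.ndarray:
        """Node degrees; a self-loop contributes 1 (or 0 if excluded)."""
        deg = np.asarray(self.adjacency.sum(axis=1)).ravel()
        if not include_self_loops:
            deg = deg - self.adjacency.diagonal()
        return deg

    def without_self_loops(self) -> "PPINetwork":
        """Copy of the network with all self-loops removed."""
        A = self.adjacency.tolil(copy=True)
        A.setdiag(0)
        return PPINetwork(list(self.node_ids), A.tocsr())

    def to_networkx(self, simple: bool = True) -> nx.Graph:
        """Export to a networkx graph; ``simple=True`` drops self-loops."""
        A = self.adjacency
        if simple:
            A = A.tolil(copy=True)
            A.setdiag(0)
            A = A.tocsr()
        g = nx.from_scipy_sparse_array(A)
        return nx.relabel_nodes(g, dict(enumerate(self.node_ids)))

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], node_order: Sequence[str] | None = None
    ) -> "PPINetwork":
        """Build a network from (gene, gene) pairs.

        Duplicate edges and orientation are collapsed; nodes are indexed in
        first-appearance order unless ``node_order`` is given.
        """
        order: list[str] = list(node_order) if node_order is not None else []
        index: dict[str, int] = {g: i for i, g in enumerate(order)}
        pairs: set[tuple[int, int]] = set()
        for a, b in edges:
            for g in (a, b):
                if g not in index:
                    index[g] = len(order)
                    order.append(g)
            i, j = index[a], index[b]
            pairs.add((min(i, j), max(i, j)))
        if not order:
            raise InputFormatError("no edges provided")
        rows, cols, vals = [], [], []
        for i, j in pairs:
            rows.append(i)
            cols.append(j)
            vals.append(1.0)
            if i != j:
                rows.append(j)
                cols.append(i)
                vals.append(1.0)
        n = len(order)
        A = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
        return cls(order, A)


@dataclass(frozen=True)
class SeedSet:
    """A disease's seed proteins resolved to node indices of one network."""

    disease_id: str
    seed_indices: frozenset[int]
    n: int  # size of the host network

    def __post_init__(self) -> None:
        if not self.seed_indices:
            raise InputFormatError(f"{self.disease_id}: empty seed set")
        if min(self.seed_indices) < 0 or max(self.seed_indices) >= self.n:
            raise InputFormatError(f"{self.disease_id}: seed index out of range")

    def __len__(self) -> int:
        return len(self.seed_indices)

    @property
    def indicator(self) -> np.ndarray:
        """Binary indicator vector v_S of length n."""
        v = np.zeros(self.n)
        v[sorted(self.seed_indices)] = 1.0
        return v


@dataclass(frozen=True)
class NetworkStats:
    """Summary topology statistics of a PPI network.

    ``density``, ``avg_clustering`` and ``assortativity`` are computed on the
    simple graph (self-loops removed); ``avg_degree`` counts a self-loop as 1.
    """

    n: int
    m: int
    avg_degree: float
    density: float
    avg_clustering: float
    assortativity: float
    sip_count: int

    def as_dict(self) -> dict[str, float | int]:
        return {
            "n": self.n,
            "m": self.m,
            "avg_degree": self.avg_degree,
            "density": self.density,
            "avg_clustering": self.avg_clustering,
            "assortativity": self.assortativity,
            "sip_count": self.sip_count,
        }


def load_edge_list(path: str | Path, delimiter: str | None = None) -> PPINetwork:
    """Read an undirected two-column edge list into a :class:`PPINetwork`.

    Lines starting with ``#`` and blank lines are skipped.  ``delimiter=None``
    splits on any whitespace (the default covers TSV).  A line ``x x`` yields
    a self-loop.  Duplicate edges and reversed orientations collapse to one
    undirected edge; node index order is first appearance in the file.
    """
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"edge list not found: {path}")
    edges: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split(delimiter)
            if len(fields) < 2:
                raise InputFormatError(
                    f"{path}:{lineno}: expected at least 2 fields, got {len(fields)}"
                )
            edges.append((fields[0], fields[1]))
    if not edges:
        raise InputFormatError(f"{path}: no valid edges")
    return PPINetwork.from_edges(edges)


def read_seed_file(path: str | Path, delimiter: str | None = None) -> dict[str, list[str]]:
    """Read disease seed genes from a plain-text file.

    Two formats are accepted: one gene per line (a single anonymous disease,
    keyed by the file stem), or two-column ``disease<TAB>gene`` lines
    (multiple diseases, keyed by the first column).  Returns diseases in
    first-appearance order.
    """
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"seed file not found: {path}")
    rows: list[list[str]] = []
    for raw in path.open():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split(delimiter))
    if not rows:
        raise InputFormatError(f"{path}: no seed genes")
    out: dict[str, list[str]] = {}
    if all(len(r) == 1 for r in rows):
        out[path.stem] = [r[0] for r in rows]
    else:
        for r in rows:
            if len(r) < 2:
                raise InputFormatError(f"{path}: mixed one- and two-column seed lines")
            out.setdefault(r[0], []).append(r[1])
    return out


def map_seeds(
    net: PPINetwork,
    genes: Sequence[str],
    min_coverage: int = 1,
    disease_id: str = "seeds",
) -> SeedSet:
    """Resolve seed gene identifiers to network node indices.

    Genes absent from the network are dropped (logged); duplicates collapse
    silently.  If fewer than ``min_coverage`` genes map, a
    :class:`SeedCoverageError` is raised — distinguishable from format errors
    so pipelines can skip under-covered diseases rather than abort.
    """
    if not genes:
        raise InputFormatError("empty gene list")
    if min_coverage < 1:
        raise InputFormatError("min_coverage must be >= 1")
    unique = list(dict.fromkeys(genes))
    if len(unique) < len(genes):
        logger.info("%s: collapsed %d duplicate seeds", disease_id, len(genes) - len(unique))
    mapped = [net.index_of(g) for g in unique if g in net]
    dropped = len(unique) - len(mapped)
    if dropped:
        logger.info("%s: dropped %d seeds absent from network", disease_id, dropped)
    if len(mapped) < min_coverage:
        raise SeedCoverageError(
            f"{disease_id}: only {len(mapped)} of {len(unique)} seeds map to the "
            f"network (min_coverage={min_coverage})"
        )
    _warn_if_outside_lcc(net, mapped, disease_id)
    return SeedSet(disease_id, frozenset(mapped), net.n)


def _warn_if_outside_lcc(net: PPINetwork, indices: Sequence[int], disease_id: str) -> None:
    """Log seeds lying outside the largest connected component.

    The analysis runs on the full graph; unreachable nodes simply score 0
    under every propagation method, but the user should know.
    """
    n_comp, labels = sp.csgraph.connected_components(net.adjacency, directed=False)
    if n_comp <= 1:
        return
    sizes = np.bincount(labels)
    outside = [i for i in indices if labels[i] != sizes.argmax()]
    if outside:
        logger.warning(
            "%s: %d seed(s) outside the largest connected component: %s",
            disease_id,
            len(outside),
            [net.node_ids[i] for i in outside],
        )


def network_stats(net: PPINetwork) -> NetworkStats:
    """Compute summary statistics (node/edge counts, degree, density,
    clustering, assortativity, SIP count).

    Clustering and assortativity follow the simple-graph conventions:
    self-loops are removed before computing them.  Assortativity is the
    Pearson correlation of degrees at edge endpoints; it is NaN on graphs
    where every node has the same degree.
    """
    if net.n < 2:
        raise InputFormatError("network statistics require at least 2 nodes")
    deg = net.degrees(include_self_loops=True)
    g = net.to_networkx(simple=True)
    n = net.n
    m_simple = g.number_of_edges()
    density = 2.0 * m_simple / (n * (n - 1))
    clustering = float(nx.average_clustering(g))
    if m_simple == 0:
        assortativity = float("nan")
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            assortativity = float(nx.degree_assortativity_coefficient(g))
    return NetworkStats(
        n=n,
        m=net.m,
        avg_degree=float(deg.mean()),
        density=density,
        avg_clustering=clustering,
        assortativity=assortativity,
        sip_count=net.sip_count,
    )


def laplacian(net: PPINetwork) -> sp.csr_matrix:
    """Graph Laplacian L = D − A with D the diagonal of row sums of A.

    Every row of L sums to zero; a self-loop contributes 1 to its node's
    degree and 1 to A_ii, cancelling in L.
    """
    A = net.adjacency
    deg = np.asarray(A.sum(axis=1)).ravel()
    return (sp.diags(deg) - A).tocsr()
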