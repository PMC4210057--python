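"""District adjacency and the intrinsic conditional-autoregressive structure.

The spatial term is an improper Gaussian Markov random field on districts:
conditionally, each district effect is normal with mean equal to the average
of its neighbours and variance ``sigma2 / N_d`` where ``N_d`` is the number
of neighbours.  The implied joint precision is proportional to the graph
Laplacian ``K = D - A``, which this module builds and validates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError


@dataclass
class DistrictGraph:
    """Ordered district ids with symmetric neighbour sets."""

    ids: list
    neighbors: dict

    def __post_init__(self) -> None:
        known = set(self.ids)
        if len(known) != len(self.ids):
            raise ValidationError("duplicate district ids")
        for d, nbrs in self.neighbors.items():
            if d in nbrs:
                raise ValidationError(f"self-loop at district {d!r}")
            for e in nbrs:
                if e not in known:
                    raise ValidationError(f"neighbor {e!r} of {d!r} is not a district")
                if d not in self.neighbors.get(e, set()):
                    raise ValidationError(f"asymmetric adjacency {d!r}->{e!r}")

    @property
    def n(self) -> int:
        return len(self.ids)

    def n_d(self, district: Hashable) -> int:
        return len(self.neighbors[district])

    @property
    def isolated(self) -> list:
        return [d for d in self.ids if not self.neighbors[d]]

    def index_of(self, district: Hashable) -> int:
        return self.ids.index(district)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.ids)
        for d, nbrs in self.neighbors.items():
            g.add_edges_from((d, e) for e in nbrs)
        return g

    def component_labels(self) -> np.ndarray:
        """Integer component label per district, in id order."""
        comps = list(nx.connected_components(self.to_networkx()))
        label = {}
        for k, comp in enumerate(sorted(comps, key=lambda c: min(self.ids.index(d) for d in c))):
            for d in comp:
                label[d] = k
        return np.array([label[d] for d in self.ids])

    def write_edge_list(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            seen = set()
            for d in self.ids:
                for e in sorted(self.neighbors[d], key=self.ids.index):
                    key = tuple(sorted((self.ids.index(d), self.ids.index(e))))
                    if key not in seen:
                        seen.add(key)
                        fh.write(f"{d} {e}\n")


@dataclass
class CARStructure:
    """Laplacian penalty matrix of the intrinsic CAR prior plus component labels."""

    matrix: np.ndarray
    components: np.ndarray = field(repr=False)

    @property
    def n_components(self) -> int:
        return int(self.components.max()) + 1

    @property
    def rank(self) -> int:
        return self.matrix.shape[0] - self.n_components


def from_edges(
    edges: Iterable[tuple[Hashable, Hashable]],
    ids: Sequence[Hashable] | None = None,
) -> DistrictGraph:
    """Build a graph from an edge iterable; duplicates and reversals collapse."""
    edges = list(edges)
    if ids is None:
        seen: list = []
        for a, b in edges:
            for v in (a, b):
                if v not in seen:
                    seen.append(v)
        ids = seen
    ids = list(ids)
    neighbors: dict = {d: set() for d in ids}
    for a, b in edges:
        if a == b:
            raise ValidationError(f"self-loop edge {a!r}-{b!r}")
        if a not in neighbors or b not in neighbors:
            raise ValidationError(f"edge {a!r}-{b!r} references unknown district")
        neighbors[a].add(b)
        neighbors[b].add(a)
    return DistrictGraph(ids=ids, neighbors=neighbors)


def read_adjacency(path: str | Path, ids: Sequence[Hashable] | None = None) -> DistrictGraph:
    """Read a whitespace-separated edge list (one ``id_a id_b`` pair per row).

    A CSV containing a symmetric 0/1 adjacency matrix (district ids as both
    header and first column) is also accepted.
    """
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise ParseError(f"empty adjacency file {path}")
    first = text.splitlines()[0]
    if "," in first:
        mat = pd.read_csv(path, index_col=0)
        if list(mat.index.astype(str)) != list(mat.columns.astype(str)):
            raise ParseError("adjacency matrix CSV must have matching row/column ids")
        a = mat.to_numpy()
        if not np.array_equal(a, a.T):
            raise ValidationError("adjacency matrix is not symmetric")
        if np.any(np.diag(a) != 0):
            raise ValidationError("adjacency matrix has self-loops on the diagonal")
        labels = list(mat.index)
        edges = [
            (labels[i], labels[j])
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
            if a[i, j]
        ]
        return from_edges(edges, ids=ids if ids is not None else labels)
    edges = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ParseError(f"{path}:{lineno}: expected 'id_a id_b', got {line!r}")
        edges.append((parts[0], parts[1]))
    return from_edges(edges, ids=ids)


def car_structure(graph: DistrictGraph) -> CARStructure:
    """Laplacian ``K = D - A`` over the graph's district order."""
    n = graph.n
    k = np.zeros((n, n))
    idx = {d: i for i, d in enumerate(graph.ids)}
    for d in graph.ids:
        i = idx[d]
        k[i, i] = graph.n_d(d)
        for e in graph.neighbors[d]:
            k[i, idx[e]] = -1.0
    return CARStructure(matrix=k, components=graph.component_labels())


def conditional_moments(
    graph: DistrictGraph,
    district: Hashable,
    values: Mapping[Hashable, float] | np.ndarray,
    sigma2: float,
) -> tuple[float, float]:
    """Full-conditional mean and variance of one district effect.

    The mean is the plain average of the neighbouring effects and the
    variance is ``sigma2 / N_d``.
    """
    if sigma2 <= 0:
        raise ValidationError("sigma2 must be positive")
    nd = graph.n_d(district)
    if nd == 0:
        raise ValidationError(
            f"district {district!r} has no neighbors; merge it into an adjacent "
            "district or drop it before building the spatial term"
        )
    if isinstance(values, Mapping):
        nbr_vals = [values[e] for e in graph.neighbors[district]]
    else:
        values = np.asarray(values, dtype=float)
        nbr_vals = [values[graph.index_of(e)] for e in graph.neighbors[district]]
    return float(np.mean(nbr_vals)), float(sigma2 / nd)


def lattice_graph(n: int, prefix: str = "D") -> DistrictGraph:
    """Connected 4-neighbour grid over ``n`` synthetic districts.

    Districts fill rows of a near-square grid; ids are ``D01, D02, ...``.
    Used as the documented stand-in when no real adjacency is supplied.
    """
    if n < 2:
        raise ValidationError("need at least 2 districts")
    ncol = int(np.ceil(np.sqrt(n)))
    width = len(str(n))
    ids = [f"{prefix}{i + 1:0{width}d}" for i in range(n)]
    edges = []
    for i in range(n):
        r, c = divmod(i, ncol)
        if c + 1 < ncol and i + 1 < n:
            edges.append((ids[i], ids[i + 1]))
        if i + ncol < n:
            edges.append((ids[i], ids[i + ncol]))
    return from_edges(edges, ids=ids)


def ring_graph(n: int, prefix: str = "D") -> DistrictGraph:
    """Cycle graph over ``n`` synthetic districts."""
    if n < 3:
        raise ValidationError("ring needs at least 3 districts")
    width = len(str(n))
    ids = [f"{prefix}{i + 1:0{width}d}" for i in range(n)]
    edges = [(ids[i], ids[(i + 1) % n]) for i in range(n)]
    return from_edges(edges, ids=ids)
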