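"""Neighborhood adjacency structures for the intrinsic CAR prior.

The spatial random effect in a BYM-type model is defined relative to a
symmetric, binary contiguity graph over the areal units (census block
groups).  This module builds regular-lattice graphs (the synthetic stand-in
for real contiguity), reads/writes GAL neighbor files (GeoDa dialect), and
exposes the intrinsic-CAR structure matrix Q = D - W whose quadratic form
drives the spatial prior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "AdjacencyGraph",
    "lattice_graph",
    "read_gal",
    "write_gal",
    "icar_structure",
]


@dataclass
class AdjacencyGraph:
    """Symmetric binary neighbor structure over ``n_areas`` areal units.

    ``neighbors[i]`` is a sorted integer array of the areas adjacent to
    area ``i``; ``degrees[i]`` is its length (the ``n_i`` entering the CAR
    conditional variance).  Self-loops are forbidden and symmetry is
    enforced at construction.
    """

    neighbors: list[np.ndarray]
    n_areas: int = field(init=False)
    degrees: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.neighbors = [np.asarray(sorted(set(int(j) for j in nb)), dtype=np.int64)
                          for nb in self.neighbors]
        self.n_areas = len(self.neighbors)
        for i, nb in enumerate(self.neighbors):
            if len(nb) and (nb.min() < 0 or nb.max() >= self.n_areas):
                raise ValueError(f"area {i} lists a neighbor outside 0..{self.n_areas - 1}")
            if i in nb:
                raise ValueError(f"area {i} lists itself as a neighbor (self-loop)")
            for j in nb:
                if i not in self.neighbors[j]:
                    raise ValueError(f"asymmetric adjacency: {i}->{j} but not {j}->{i}")
        self.degrees = np.array([len(nb) for nb in self.neighbors], dtype=np.int64)

    # -- derived structures -------------------------------------------------

    def csr_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Flat (indptr, indices) CSR arrays, the form the MCMC kernel consumes."""
        indptr = np.zeros(self.n_areas + 1, dtype=np.int64)
        indptr[1:] = np.cumsum(self.degrees)
        indices = (np.concatenate(self.neighbors) if self.n_areas and indptr[-1]
                   else np.zeros(0, dtype=np.int64))
        return indptr, indices.astype(np.int64)

    def adjacency_matrix(self) -> csr_matrix:
        indptr, indices = self.csr_indices()
        return csr_matrix((np.ones(len(indices)), indices, indptr),
                          shape=(self.n_areas, self.n_areas))

    def components(self) -> tuple[int, np.ndarray]:
        """Number of connected components and per-area component labels."""
        n_comp, labels = connected_components(self.adjacency_matrix(), directed=False)
        return int(n_comp), labels.astype(np.int64)

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (m, 2) array with i < j."""
        out = [(i, int(j)) for i in range(self.n_areas)
               for j in self.neighbors[i] if i < j]
        return np.array(out, dtype=np.int64).reshape(-1, 2)

    @property
    def islands(self) -> np.ndarray:
        return np.flatnonzero(self.degrees == 0)


def lattice_graph(rows: int, cols: int, contiguity: str = "rook") -> AdjacencyGraph:
    """Regular grid contiguity graph, clipped at the borders.

    ``rook`` joins horizontally/vertically adjacent cells (4-neighborhood);
    ``queen`` adds the diagonals (8-neighborhood).  Areas are numbered in
    row-major order.
    """
    if rows < 1 or cols < 1 or rows * cols < 2:
        raise ValueError("lattice needs rows*cols >= 2")
    if contiguity not in ("rook", "queen"):
        raise ValueError(f"unknown contiguity {contiguity!r}; use 'rook' or 'queen'")
    if contiguity == "rook":
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                   if (dr, dc) != (0, 0)]
    neighbors = []
    for r in range(rows):
        for c in range(cols):
            nb = [(r + dr) * cols + (c + dc) for dr, dc in offsets
                  if 0 <= r + dr < rows and 0 <= c + dc < cols]
            neighbors.append(np.array(nb, dtype=np.int64))
    return AdjacencyGraph(neighbors)


def read_gal(path, area_ids: list[str] | None = None) -> AdjacencyGraph:
    """Read a GAL neighbor file (GeoDa dialect).

    The header line carries the area count (either ``n`` alone or the GeoDa
    form ``0 n <layer> <key>``); each area then contributes an ``id count``
    line followed by a line of neighbor ids.  Ids are opaque strings; if
    ``area_ids`` is given they are mapped onto that ordering, otherwise
    onto order of appearance.  Asymmetric input is symmetrized with a
    warning; an id referenced but never declared raises.
    """
    with open(path, "rt", encoding="utf-8") as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("!")]
    if not lines:
        raise ValueError(f"{path}: empty GAL file")
    head = lines[0].split()
    n = int(head[1]) if len(head) >= 2 else int(head[0])
    blocks: dict[str, list[str]] = {}
    order: list[str] = []
    pos = 1
    for _ in range(n):
        if pos + 1 > len(lines):
            raise ValueError(f"{path}: truncated GAL file (expected {n} blocks)")
        aid, cnt = lines[pos].split()[0], int(lines[pos].split()[1])
        nbr = lines[pos + 1].split() if cnt > 0 else []
        if cnt > 0:
            pos += 2
        else:
            # zero-neighbor blocks may or may not carry an (empty) neighbor line
            pos += 1
            if pos < len(lines) and len(lines[pos].split()) != 2:
                pos += 1
        if len(nbr) != cnt:
            raise ValueError(f"{path}: area {aid} declares {cnt} neighbors, lists {len(nbr)}")
        blocks[aid] = nbr
        order.append(aid)
    ids = list(area_ids) if area_ids is not None else order
    if area_ids is not None and set(order) != set(ids):
        raise ValueError("GAL area ids do not match the supplied area_ids")
    index = {a: i for i, a in enumerate(ids)}
    neighbors = [set() for _ in ids]
    asymmetric = False
    for aid, nbr in blocks.items():
        for b in nbr:
            if b not in index:
                raise ValueError(f"{path}: neighbor id {b!r} is not a declared area")
            neighbors[index[aid]].add(index[b])
    for i, nb in enumerate(neighbors):
        for j in list(nb):
            if i not in neighbors[j]:
                asymmetric = True
                neighbors[j].add(i)
    if asymmetric:
        warnings.warn(f"{path}: asymmetric GAL adjacency symmetrized", stacklevel=2)
    return AdjacencyGraph([np.array(sorted(nb), dtype=np.int64) for nb in neighbors])


def write_gal(graph: AdjacencyGraph, path, area_ids: list[str] | None = None) -> None:
    """Write the graph as a GAL neighbor file readable by :func:`read_gal`."""
    ids = area_ids if area_ids is not None else [str(i) for i in range(graph.n_areas)]
    if len(ids) != graph.n_areas:
        raise ValueError("area_ids length does not match graph size")
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"{graph.n_areas}\n")
        for i, aid in enumerate(ids):
            nb = graph.neighbors[i]
            fh.write(f"{aid} {len(nb)}\n")
            if len(nb):
                fh.write(" ".join(ids[j] for j in nb) + "\n")


def icar_structure(graph: AdjacencyGraph) -> np.ndarray:
    """Dense intrinsic-CAR structure matrix Q = D - W.

    Q is symmetric positive semidefinite with row sums exactly zero; its
    rank is ``n - c`` where ``c`` is the number of connected components.
    The improper ICAR prior density is exp(-S'QS / (2 sigma_S^2)) restricted
    to the per-component sum-to-zero subspace.
    """
    n = graph.n_areas
    Q = np.zeros((n, n))
    for i, nb in enumerate(graph.neighbors):
        Q[i, i] = len(nb)
        Q[i, nb] = -1.0
    return Q
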