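"""All-pairs exact Jaccard similarity and thresholded plasmid networks.

The similarity between two plasmids is the exact Jaccard index (JI) of their
k-mer sets, |A ∩ B| / |A ∪ B| — computed on full sets, never on sketches.
Pairs sharing fewer than ``min_shared`` k-mers (100 by default) are treated
as having JI = 0 and never stored: with 21-mers, fewer than 100 shared
windows means less than one typical gene's worth of common sequence, i.e.
noise rather than homology.

Networks are undirected and weighted by JI. A sparsification threshold t
keeps edges with JI >= t; the "original" network is the one at t = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .sequences import KmerSet

__all__ = [
    "SimilarityMatrix",
    "pairwise_jaccard",
    "build_network",
    "density",
    "isolation_classes",
    "write_edge_list",
    "read_edge_list",
]

DEFAULT_MIN_SHARED = 100


@dataclass
class SimilarityMatrix:
    """Sparse symmetric pairwise JI values after the shared-k-mer cutoff.

    Entries are keyed by index pairs ``(i, j)`` with ``i < j`` into ``ids``
    and hold ``(ji, shared)`` where ``shared`` is the shared-k-mer count.
    Absent pairs have JI treated as zero.
    """

    ids: list[str]
    entries: dict[tuple[int, int], tuple[float, int]] = field(default_factory=dict)
    min_shared: int = DEFAULT_MIN_SHARED

    def __post_init__(self) -> None:
        self._index = {pid: i for i, pid in enumerate(self.ids)}
        if len(self._index) != len(self.ids):
            raise ValueError("duplicate plasmid ids in similarity matrix")

    def ji(self, a: str, b: str) -> float:
        """JI between two plasmids by id; 0.0 for unstored (cutoff) pairs."""
        i, j = self._index[a], self._index[b]
        if i == j:
            return 1.0
        if i > j:
            i, j = j, i
        entry = self.entries.get((i, j))
        return entry[0] if entry is not None else 0.0

    def __len__(self) -> int:
        return len(self.entries)

    def iter_pairs(self) -> Iterable[tuple[str, str, float, int]]:
        """Yield (id_i, id_j, ji, shared) for every stored pair."""
        for (i, j), (ji, shared) in self.entries.items():
            yield self.ids[i], self.ids[j], ji, shared


def pairwise_jaccard(
    kmersets: Sequence[KmerSet],
    min_shared: int = DEFAULT_MIN_SHARED,
) -> SimilarityMatrix:
    """Exact all-pairs Jaccard index with the shared-k-mer cutoff.

    Pairs whose intersection holds fewer than ``min_shared`` k-mers are
    omitted (JI treated as zero downstream). Set arithmetic is exact; no
    MinHash or other sketch approximation is involved.

    Raises
    ------
    ValueError
        If the k-mer sets were built with different k, or ids collide.
    """
    ks = {s.k for s in kmersets}
    if len(ks) > 1:
        raise ValueError(f"mixed k values in k-mer sets: {sorted(ks)}")
    ids = [s.plasmid_id for s in kmersets]
    matrix = SimilarityMatrix(ids=list(ids), min_shared=min_shared)
    sets = [s.kmers for s in kmersets]
    n = len(sets)
    for i in range(n):
        a = sets[i]
        if not a:
            continue
        for j in range(i + 1, n):
            b = sets[j]
            # iterate over the smaller set: intersection cost is O(min(|A|,|B|))
            shared = len(a & b) if len(a) <= len(b) else len(b & a)
            if shared < min_shared or shared == 0:
                continue
            union = len(a) + len(b) - shared
            matrix.entries[(i, j)] = (shared / union, shared)
    return matrix


def build_network(matrix: SimilarityMatrix, threshold: float = 0.0) -> nx.Graph:
    """Materialize the weighted plasmid network at a JI threshold.

    All plasmids appear as vertices, including those left isolated. Edges are
    matrix entries with ``ji >= threshold`` (inclusive: edges *below* the
    threshold are removed, ties are kept); ``threshold=0`` reproduces the
    original network. Edge attributes: ``weight`` (the JI) and ``shared``.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    g = nx.Graph(threshold=threshold)
    g.add_nodes_from(matrix.ids)
    for a, b, ji, shared in matrix.iter_pairs():
        if ji >= threshold:
            g.add_edge(a, b, weight=ji, shared=shared)
    return g


def density(network: nx.Graph) -> float:
    """Network density 2E / (N(N-1)); undefined for fewer than 2 vertices."""
    n = network.number_of_nodes()
    if n < 2:
        raise ValueError("density undefined for networks with < 2 vertices")
    return 2.0 * network.number_of_edges() / (n * (n - 1))


def isolation_classes(network: nx.Graph) -> dict[str, set]:
    """Partition vertices into singletons, members of lone pairs, and others.

    Singletons have degree zero; ``pair_members`` sit in connected components
    of exactly two vertices (the classification is by component size, not
    degree — the middle of a path of three is *not* a pair member). The three
    classes are disjoint and exhaustive.
    """
    singletons: set = set()
    pair_members: set = set()
    others: set = set()
    for comp in nx.connected_components(network):
        if len(comp) == 1:
            singletons |= comp
        elif len(comp) == 2:
            pair_members |= comp
        else:
            others |= comp
    return {"singletons": singletons, "pair_members": pair_members, "others": others}


# --- interchange format -------------------------------------------------------


def write_edge_list(matrix: SimilarityMatrix, path: str | Path) -> None:
    """Write the similarity matrix as the edge-list TSV interchange format.

    Columns: id1, id2, jaccard, shared_kmers. Isolated plasmids are recorded
    as a header comment so the full vertex set round-trips.
    """
    with open(path, "w") as fh:
        fh.write("#ids\t" + "\t".join(matrix.ids) + "\n")
        fh.write(f"#min_shared\t{matrix.min_shared}\n")
        fh.write("id1\tid2\tjaccard\tshared_kmers\n")
        for a, b, ji, shared in sorted(matrix.iter_pairs()):
            fh.write(f"{a}\t{b}\t{ji:.10g}\t{shared}\n")


def read_edge_list(path: str | Path) -> SimilarityMatrix:
    """Read the edge-list TSV written by :func:`write_edge_list`."""
    ids: list[str] = []
    index: dict[str, int] = {}
    min_shared = DEFAULT_MIN_SHARED
    entries: dict[tuple[int, int], tuple[float, int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#ids\t"):
                ids = line.split("\t")[1:]
                index = {pid: i for i, pid in enumerate(ids)}
                continue
            if line.startswith("#min_shared\t"):
                min_shared = int(line.split("\t")[1])
                continue
            if not line or line.startswith(("id1\t", "#")):
                continue
            a, b, ji, shared = line.split("\t")
            if not ids:
                raise ValueError(f"edge list {path}: missing #ids header")
            i, j = index[a], index[b]
            if i > j:
                i, j = j, i
            entries[(i, j)] = (float(ji), int(shared))
    matrix = SimilarityMatrix(ids=ids, min_shared=min_shared)
    matrix.entries = entries
    return matrix
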