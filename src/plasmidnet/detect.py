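"""Stochastic detection of statistically significant plasmid communities.

The detector follows the logic of ordered-statistics local optimization
(OSLOM-style): starting from randomly chosen seed vertices, clusters are
grown by repeatedly admitting the external neighbour whose connection to the
cluster is least likely under a configuration-model null (a random network
preserving every vertex's degree), and cleaned by expelling internal
vertices that fail the same test. Because candidates are examined as the
best of ``m`` neighbours, raw null tail probabilities are corrected with the
order statistic of the minimum (``Beta(r, m - r + 1)``). Clusters that
recur across many independent runs are reported as communities.

Communities of size three or more are then checked for *completeness*
against the original (unthresholded) network: only complete subgraphs —
cliques — are retained for downstream analysis. Exact maximal-clique
enumeration (Bron–Kerbosch with pivoting) is provided as the comparison
method.

The null model: for a candidate vertex of degree ``k_v`` and a cluster whose
members hold ``K_C`` of the network's ``M`` edge endpoints, the number of
edges from the candidate into the cluster is Binomial(k_v, K_C / M) under
degree-preserving rewiring; the score is the upper tail at the observed
internal degree. Topology drives significance; JI edge weights are used
only to order candidates with tied scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .network import SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DetectionConfig",
    "Community",
    "CliqueSet",
    "vertex_significance",
    "detect_communities",
    "validate_cliques",
    "max_cliques",
    "internal_similarity",
]


@dataclass
class DetectionConfig:
    """Tunable parameters of the community detector.

    ``p_threshold`` is the cluster significance level; ``n_runs`` the number
    of independent full-network coverages (50 is adequate for threshold
    sweeps, 250 for a final analysis); ``consensus_fraction`` the fraction of
    runs in which a cluster must recur to be reported. ``overlap_merge``
    merges strongly overlapping significant clusters instead of keeping the
    single most significant one; ``allow_unassigned`` permits vertices to end
    up in no community. Only one hierarchy level is analysed.
    ``bootstrap_size`` is the cluster size below which growth admits the
    best-scoring neighbour unconditionally: binomial tails cannot clear any
    sensible significance level for clusters of one or two vertices, so tiny
    seeds are grown greedily and left to the cleanup phase to dismantle.
    """

    p_threshold: float = 0.05
    n_runs: int = 50
    seed: int = 1
    consensus_fraction: float = 0.5
    overlap_merge: bool = False
    allow_unassigned: bool = True
    hierarchy_levels: int = 1
    bootstrap_size: int = 6

    def __post_init__(self) -> None:
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must be in (0, 1)")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if not 0.0 < self.consensus_fraction <= 1.0:
            raise ValueError("consensus_fraction must be in (0, 1]")
        if self.hierarchy_levels != 1:
            raise ValueError("only a single hierarchy level is supported")


@dataclass(frozen=True)
class Community:
    """A recurrent significant cluster: members, p-value and run support."""

    members: frozenset[str]
    p_value: float
    support: float

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("community members must be nonempty")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must be in [0, 1]")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class CliqueSet:
    """Validated cliques (size >= 3) with possibly overlapping membership.

    ``assignment`` is the exact inverse of ``cliques``; plasmids absent from
    it belong to no clique. ``rejected`` records communities that failed the
    completeness check, as (members, number of missing pairs).
    """

    cliques: dict[str, frozenset[str]] = field(default_factory=dict)
    assignment: dict[str, set[str]] = field(default_factory=dict)
    rejected: list[tuple[frozenset[str], int]] = field(default_factory=list)

    @property
    def n_cliques(self) -> int:
        return len(self.cliques)

    @property
    def assigned_plasmids(self) -> set[str]:
        return set(self.assignment)

    def multi_assigned(self) -> set[str]:
        """Plasmids assigned to more than one clique (chimera candidates)."""
        return {p for p, cs in self.assignment.items() if len(cs) > 1}

    def labels(self) -> dict[str, str]:
        """Flat clique label per assigned plasmid (composite when multiple)."""
        return {
            p: "+".join(sorted(cs)) for p, cs in self.assignment.items() if cs
        }


# --- configuration-model scoring ---------------------------------------------


class _Scorer:
    """Precomputed adjacency/degree view of a network for fast null scores."""

    def __init__(self, network: nx.Graph):
        self.adj: dict = {v: set(network.neighbors(v)) for v in network}
        self.deg: dict = {v: len(s) for v, s in self.adj.items()}
        self.weight: dict = {}
        for u, v, w in network.edges(data="weight", default=1.0):
            self.weight[(u, v)] = w
            self.weight[(v, u)] = w
        self.M = 2 * network.number_of_edges()
        self.nodes = sorted(network.nodes())

    def cluster_degree(self, cluster: Iterable) -> int:
        return sum(self.deg[v] for v in cluster)

    def internal_edges(self, cluster: set) -> int:
        return sum(len(self.adj[v] & cluster) for v in cluster) // 2

    def raw_scores(self, candidates: Sequence, cluster: set,
                   free_stubs: bool = False) -> np.ndarray:
        """Binomial upper-tail scores for candidates against a cluster.

        With ``free_stubs=False`` the success probability is K_C / M (every
        endpoint of a cluster member counts). With ``free_stubs=True`` it is
        (K_C - 2 E_in) / M: endpoints already consumed by the cluster's
        internal edges cannot catch a candidate's stubs, which keeps the null
        informative even when a cluster holds most of a small network.
        """
        if self.M == 0:
            return np.ones(len(candidates))
        k_cluster = self.cluster_degree(cluster)
        if free_stubs:
            k_cluster -= 2 * self.internal_edges(cluster)
        p = min(1.0, max(0, k_cluster) / self.M)
        obs = np.fromiter(
            (len(self.adj[c] & cluster) for c in candidates), dtype=np.int64,
            count=len(candidates),
        )
        kv = np.fromiter(
            (self.deg[c] for c in candidates), dtype=np.int64,
            count=len(candidates),
        )
        return stats.binom.sf(obs - 1, kv, p)

    def wsum(self, v, cluster: set) -> float:
        return sum(self.weight[(v, u)] for u in self.adj[v] & cluster)


def vertex_significance(candidate, cluster: Iterable, network: nx.Graph) -> float:
    """Configuration-model tail probability of a vertex's ties to a cluster.

    With ``k_v`` the candidate's degree, ``K_C`` the summed degree of cluster
    members and ``M`` the total number of edge endpoints, the internal degree
    of the candidate under degree-preserving rewiring is Binomial(k_v,
    K_C / M); the score is P[X >= observed internal degree]. An isolated
    candidate scores 1.0 (uninformative).
    """
    cluster = set(cluster)
    if candidate in cluster:
        raise ValueError("candidate must not be a member of the cluster")
    scorer = _Scorer(network)
    if scorer.deg.get(candidate, 0) == 0:
        return 1.0
    return float(scorer.raw_scores([candidate], cluster)[0])


def _order_corrected(raw: float, rank: int, m: int) -> float:
    """Order-statistics correction: Beta(r, m - r + 1) CDF at the raw score.

    A candidate ranked r-th best among m is only surprising if its score beats
    the r-th order statistic of m uniforms; for r = 1 this is 1 - (1-x)^m.
    """
    if m <= 0:
        return raw
    if rank == 1:
        return float(-np.expm1(m * np.log1p(-min(raw, 1.0 - 1e-300))))
    return float(stats.beta.cdf(raw, rank, m - rank + 1))


# --- single-run grow / clean cycle -------------------------------------------


def _external_neighbours(scorer: _Scorer, cluster: set) -> list:
    out: set = set()
    for v in cluster:
        out |= scorer.adj[v]
    out -= cluster
    return sorted(out)


def _grow(scorer: _Scorer, cluster: set, config: DetectionConfig) -> bool:
    """Admit external neighbours one at a time; returns True if any joined."""
    changed = False
    while True:
        candidates = _external_neighbours(scorer, cluster)
        if not candidates:
            return changed
        raws = scorer.raw_scores(candidates, cluster, free_stubs=True)
        # best candidate: lowest score, then strongest JI ties, then id
        order = sorted(
            range(len(candidates)),
            key=lambda i: (raws[i], -scorer.wsum(candidates[i], cluster),
                           candidates[i]),
        )
        best = order[0]
        if len(cluster) < config.bootstrap_size:
            cluster.add(candidates[best])
            changed = True
            continue
        corrected = _order_corrected(float(raws[best]), 1, len(candidates))
        if corrected < config.p_threshold:
            cluster.add(candidates[best])
            changed = True
        else:
            return changed


def _member_scores(scorer: _Scorer, cluster: set) -> dict:
    """Leave-one-out corrected score for every member of a cluster."""
    m_ext = len(_external_neighbours(scorer, cluster)) + 1
    members = sorted(cluster)
    scores = {}
    for v in members:
        rest = cluster - {v}
        raw = float(scorer.raw_scores([v], rest, free_stubs=True)[0])
        scores[v] = _order_corrected(raw, 1, m_ext)
    return scores


def _clean(scorer: _Scorer, cluster: set, config: DetectionConfig) -> bool:
    """Expel worst-scoring members until all pass the test; True if changed."""
    changed = False
    while len(cluster) > 1:
        scores = _member_scores(scorer, cluster)
        worst = max(sorted(scores), key=lambda v: scores[v])
        if scores[worst] < config.p_threshold:
            return changed
        cluster.discard(worst)
        changed = True
    return changed


def _cluster_p_value(scorer: _Scorer, cluster: set) -> float:
    """Significance of a stable cluster: its worst member's corrected score."""
    if len(cluster) < 2:
        return 1.0
    return max(_member_scores(scorer, cluster).values())


def _grow_clean(scorer: _Scorer, seed_vertex, config: DetectionConfig) -> set:
    cluster = {seed_vertex}
    seen: set[frozenset] = set()
    for _ in range(30):
        state = frozenset(cluster)
        if state in seen:
            break
        seen.add(state)
        grew = _grow(scorer, cluster, config)
        cleaned = _clean(scorer, cluster, config)
        if not grew and not cleaned:
            break
        if not cluster:
            break
    return cluster


def _single_run(scorer: _Scorer, order: Sequence, config: DetectionConfig
                ) -> list[tuple[frozenset, float]]:
    """One full-network coverage: grow clusters from uncovered seeds."""
    covered: set = set()
    found: list[tuple[frozenset, float]] = []
    for seed_vertex in order:
        if seed_vertex in covered:
            continue
        if scorer.deg[seed_vertex] == 0:
            covered.add(seed_vertex)
            continue
        cluster = _grow_clean(scorer, seed_vertex, config)
        p = _cluster_p_value(scorer, cluster)
        if len(cluster) >= 2 and p < config.p_threshold:
            found.append((frozenset(cluster), p))
            covered |= cluster
        else:
            covered.add(seed_vertex)
    return found


# --- consensus across runs ----------------------------------------------------


def _overlap_jaccard(a: frozenset, b: frozenset) -> float:
    inter = len(a & b)
    if inter == 0:
        return 0.0
    return inter / (len(a) + len(b) - inter)


def detect_communities(network: nx.Graph,
                       config: Optional[DetectionConfig] = None
                       ) -> list[Community]:
    """Detect recurrent, configuration-model-significant communities.

    Runs ``config.n_runs`` independent coverages of the network (seeded, so
    identical inputs give identical output), matches clusters across runs by
    member-overlap Jaccard >= 0.5, and returns clusters recurring in at least
    ``consensus_fraction`` of the runs. With ``overlap_merge`` off, of any
    two strongly overlapping surviving clusters only the more significant is
    kept (ties broken toward larger size, then smallest member id). Vertices
    may remain in no community; an empty result is legal.
    """
    if config is None:
        config = DetectionConfig()
    if network.number_of_nodes() == 0:
        raise ValueError("network must be nonempty")
    scorer = _Scorer(network)
    rng = np.random.default_rng(config.seed)
    nodes = np.array(scorer.nodes, dtype=object)

    all_clusters: list[tuple[frozenset, float, int]] = []
    for run in range(config.n_runs):
        order = nodes[rng.permutation(len(nodes))]
        for members, p in _single_run(scorer, order, config):
            all_clusters.append((members, p, run))

    # group clusters across runs by membership overlap
    groups: list[dict] = []
    for members, p, run in sorted(
        all_clusters, key=lambda t: (t[1], -len(t[0]), tuple(sorted(t[0])))
    ):
        target = None
        best = 0.5
        for g in groups:
            ov = _overlap_jaccard(g["rep"], members)
            if ov >= best:
                target, best = g, ov
        if target is None:
            target = {"rep": members, "occurrences": [], "runs": set()}
            groups.append(target)
        target["occurrences"].append((members, p))
        target["runs"].add(run)

    communities: list[Community] = []
    for g in groups:
        support = len(g["runs"]) / config.n_runs
        if support < config.consensus_fraction:
            continue
        # modal member set; ties resolved toward the more significant cluster
        counts: dict[frozenset, int] = {}
        best_p: dict[frozenset, float] = {}
        for members, p in g["occurrences"]:
            counts[members] = counts.get(members, 0) + 1
            best_p[members] = min(p, best_p.get(members, 1.0))
        chosen = min(
            counts,
            key=lambda ms: (-counts[ms], best_p[ms], -len(ms), tuple(sorted(ms))),
        )
        communities.append(
            Community(members=chosen, p_value=best_p[chosen], support=support)
        )

    communities.sort(key=lambda c: (c.p_value, -len(c.members),
                                    tuple(sorted(c.members))))

    if config.overlap_merge:
        merged: list[Community] = []
        for c in communities:
            for i, kept in enumerate(merged):
                if _overlap_jaccard(kept.members, c.members) >= 0.5:
                    merged[i] = Community(
                        members=kept.members | c.members,
                        p_value=min(kept.p_value, c.p_value),
                        support=max(kept.support, c.support),
                    )
                    break
            else:
                merged.append(c)
        communities = merged
    else:
        # keep only the most significant of mutually overlapping clusters
        kept: list[Community] = []
        for c in communities:  # already sorted best-first
            if all(_overlap_jaccard(k.members, c.members) < 0.5 for k in kept):
                kept.append(c)
        communities = kept

    if not config.allow_unassigned and communities:
        assigned = set().union(*(c.members for c in communities))
        extra: dict[int, set] = {}
        for v in scorer.nodes:
            if v in assigned or scorer.deg[v] == 0:
                continue
            links = [
                (-len(scorer.adj[v] & set(c.members)), i)
                for i, c in enumerate(communities)
                if scorer.adj[v] & set(c.members)
            ]
            if links:
                extra.setdefault(min(links)[1], set()).add(v)
        for i, vs in extra.items():
            c = communities[i]
            communities[i] = Community(
                members=c.members | vs, p_value=c.p_value, support=c.support
            )

    communities.sort(key=lambda c: (-len(c.members), tuple(sorted(c.members))))
    return communities


# --- clique validation and enumeration ---------------------------------------


def validate_cliques(communities: Iterable[Community],
                     original: nx.Graph) -> CliqueSet:
    """Keep communities of size >= 3 that are complete in the original network.

    Completeness is judged against the *unthresholded* network: a community
    detected on a sparsified network may rely on edges that fell below the
    working threshold yet still reflect genuine similarity. Failures are
    recorded with their missing-pair counts.
    """
    declared = original.graph.get("threshold", 0.0)
    if declared not in (0, 0.0):
        raise ValueError(
            f"completeness must be judged on the original network "
            f"(threshold 0), got threshold={declared}"
        )
    result = CliqueSet()
    passing: list[frozenset] = []
    for community in communities:
        unknown = [v for v in community.members if v not in original]
        if unknown:
            raise ValueError(
                f"community references unknown vertices: {sorted(unknown)[:5]}"
            )
        members = sorted(community.members)
        if len(members) < 3:
            continue
        missing = 0
        for i, u in enumerate(members):
            for v in members[i + 1 :]:
                if not original.has_edge(u, v):
                    missing += 1
        if missing == 0:
            passing.append(frozenset(members))
        else:
            result.rejected.append((frozenset(members), missing))
            logger.info(
                "community of size %d rejected: %d missing pair(s)",
                len(members), missing,
            )
    passing.sort(key=lambda ms: (-len(ms), tuple(sorted(ms))))
    width = max(3, len(str(len(passing))))
    for idx, members in enumerate(passing, start=1):
        cid = f"C{idx:0{width}d}"
        result.cliques[cid] = members
        for p in members:
            result.assignment.setdefault(p, set()).add(cid)
    return result


def max_cliques(network: nx.Graph, min_size: int = 3) -> list[frozenset[str]]:
    """All maximal cliques of size >= min_size (Bron–Kerbosch with pivoting).

    Each maximal clique is reported exactly once; output is sorted by size
    (descending) then lexicographically by members.
    """
    cliques = [
        frozenset(c) for c in nx.find_cliques(network) if len(c) >= min_size
    ]
    cliques.sort(key=lambda c: (-len(c), tuple(sorted(c))))
    return cliques


def internal_similarity(clique: Iterable[str], matrix: SimilarityMatrix) -> float:
    """Mean pairwise JI over all member pairs of a clique.

    Pairs absent from the matrix (below the shared-k-mer cutoff) contribute
    zero — for validated cliques this is an error path, not a normal one.
    """
    members = sorted(set(clique))
    if len(members) < 2:
        raise ValueError("internal similarity undefined for < 2 members")
    total = 0.0
    n_pairs = 0
    for i, a in enumerate(members):
        for b in members[i + 1 :]:
            total += matrix.ji(a, b)
            n_pairs += 1
    return total / n_pairs
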