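"""Biological characterization of validated plasmid cliques.

Covers three analyses. First, per-clique summaries of numeric plasmid
properties (GC content, sequence length) with an ANOVA + Tukey HSD test of
how often two cliques differ significantly. Second, gene-content
classification: a gene is *core* when every plasmid of some clique it
occurs in carries it (within-clique frequency of one), and *private* when
it is confined to a single clique, is core there, and occurs nowhere
outside cliques. Third, the clique-level aggregated network: cliques become
vertices, plasmids assigned to multiple cliques remain as solitary anchor
vertices, unassigned plasmids are dropped, and cliques are linked when the
average JI between their members is high enough.

Gene presence/absence is an input contract (rows: plasmids, columns: genes,
0/1) — typically the output of an annotation + pan-genome pipeline, or of
the synthetic generator's truth table.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .detect import CliqueSet, internal_similarity
from .network import SimilarityMatrix
from .sequences import PlasmidRecord

__all__ = [
    "GenePresenceTable",
    "clique_numeric_stats",
    "PairwiseTestResult",
    "pairwise_difference_test",
    "GeneClassification",
    "classify_genes",
    "aggregate_cliques",
    "group_gene_overlap",
]


@dataclass
class GenePresenceTable:
    """Boolean plasmid × gene presence matrix."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.table = self.table.astype(bool)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenePresenceTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df > 0)

    def to_tsv(self, path: str | Path) -> None:
        self.table.astype(int).to_csv(path, sep="\t")

    @property
    def plasmids(self) -> list[str]:
        return list(self.table.index)

    @property
    def genes(self) -> list[str]:
        return list(self.table.columns)

    def occurrence(self) -> pd.Series:
        """Number of plasmids carrying each gene, across the whole dataset."""
        return self.table.sum(axis=0)

    def carriers(self, gene: str) -> set[str]:
        col = self.table[gene]
        return set(col.index[col])


def clique_numeric_stats(
    cliques: CliqueSet, values: Mapping[str, float]
) -> pd.DataFrame:
    """Per-clique mean, sample SD (n-1 denominator) and n of a numeric value.

    Raises if any clique member lacks a value, naming the plasmid.
    """
    rows = {}
    for cid, members in cliques.cliques.items():
        missing = [p for p in sorted(members) if p not in values]
        if missing:
            raise ValueError(f"clique {cid}: no value for plasmid {missing[0]!r}")
        data = np.array([values[p] for p in sorted(members)], dtype=float)
        rows[cid] = {
            "mean": data.mean(),
            "sd": data.std(ddof=1) if len(data) > 1 else 0.0,
            "n": len(data),
        }
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


@dataclass
class PairwiseTestResult:
    """Outcome of the ANOVA + Tukey HSD comparison across cliques."""

    fraction_significant: float
    anova_p: float
    pairs: pd.DataFrame  # clique_a, clique_b, meandiff, p_adj, significant
    alpha: float


def pairwise_difference_test(
    cliques: CliqueSet,
    values: Mapping[str, float],
    alpha: float = 0.001,
) -> PairwiseTestResult:
    """How often does a numeric property differ significantly between cliques?

    One-way fixed-effects ANOVA across cliques followed by Tukey's HSD over
    all clique pairs (Tukey–Kramer studentized-range adjustment for unequal
    group sizes). Returns the fraction of clique pairs with adjusted
    p < ``alpha`` together with the full pair table. Plasmids assigned to
    several cliques contribute an observation to each.

    Raises when fewer than two cliques have two valued members, or when the
    within-group variance is zero everywhere (the test is undefined).
    """
    groups: list[str] = []
    obs: list[float] = []
    for cid, members in sorted(cliques.cliques.items()):
        usable = [p for p in sorted(members) if p in values]
        if len(usable) < 2:
            continue
        groups.extend([cid] * len(usable))
        obs.extend(values[p] for p in usable)
    labels = sorted(set(groups))
    if len(labels) < 2:
        raise ValueError("need >= 2 cliques with >= 2 valued members")
    arrays = [
        np.array([o for g, o in zip(groups, obs) if g == cid]) for cid in labels
    ]
    if all(a.std(ddof=1) == 0.0 for a in arrays):
        raise ValueError(
            "zero within-group variance in every clique: ANOVA/Tukey undefined"
        )
    anova = stats.f_oneway(*arrays)
    hsd = pairwise_tukeyhsd(np.asarray(obs, dtype=float), np.asarray(groups),
                            alpha=0.05)
    pair_names = list(combinations([str(name) for name in hsd.groupsunique], 2))
    pairs = pd.DataFrame(
        {
            "clique_a": [a for a, _ in pair_names],
            "clique_b": [b for _, b in pair_names],
            "meandiff": hsd.meandiffs,
            "p_adj": hsd.pvalues,
        }
    )
    pairs["significant"] = pairs["p_adj"] < alpha
    return PairwiseTestResult(
        fraction_significant=float(pairs["significant"].mean()),
        anova_p=float(anova.pvalue),
        pairs=pairs,
        alpha=alpha,
    )


@dataclass
class GeneClassification:
    """Core/private classification of genes against a clique structure."""

    genes: pd.DataFrame  # occurrence, assessed, core, private, core_in
    n_assessed: int
    core_share: float
    private_share: float
    core_counts: dict[str, int]  # per clique, including zero-core cliques


def classify_genes(
    table: GenePresenceTable,
    cliques: CliqueSet,
    min_occurrence: int = 5,
) -> GeneClassification:
    """Classify genes as core and/or private with respect to cliques.

    Only genes occurring at least ``min_occurrence`` times in the dataset are
    assessed. A gene's within-clique frequency in clique c is (carriers in
    c) / |c|, inspected only for cliques where the gene occurs at least
    once; *core* means frequency one in at least one such clique. *Private*
    means the gene occurs in exactly one clique, with frequency one there,
    and on no plasmid outside cliques.
    """
    missing = [
        p for ms in cliques.cliques.values() for p in ms
        if p not in table.table.index
    ]
    if missing:
        raise ValueError(
            f"gene table does not cover clique member {sorted(set(missing))[0]!r}"
        )
    occurrence = table.occurrence()
    in_cliques = set().union(*cliques.cliques.values()) if cliques.cliques else set()
    rows = []
    core_counts = {cid: 0 for cid in cliques.cliques}
    for gene in table.genes:
        occ = int(occurrence[gene])
        assessed = occ >= min_occurrence
        carriers = table.carriers(gene)
        core_in: set[str] = set()
        present_in: set[str] = set()
        for cid, members in cliques.cliques.items():
            hit = len(carriers & members)
            if hit == 0:
                continue
            present_in.add(cid)
            if hit == len(members):
                core_in.add(cid)
        core = assessed and bool(core_in)
        private = (
            assessed
            and len(present_in) == 1
            and present_in == core_in
            and not (carriers - in_cliques)
        )
        if core:
            for cid in core_in:
                core_counts[cid] += 1
        rows.append(
            {
                "gene": gene,
                "occurrence": occ,
                "assessed": assessed,
                "core": core,
                "private": private,
                "core_in": ";".join(sorted(core_in)) if core else "",
            }
        )
    genes = pd.DataFrame(rows).set_index("gene")
    n_assessed = int(genes["assessed"].sum())
    assessed_mask = genes["assessed"]
    return GeneClassification(
        genes=genes,
        n_assessed=n_assessed,
        core_share=(
            float(genes.loc[assessed_mask, "core"].mean()) if n_assessed else 0.0
        ),
        private_share=(
            float(genes.loc[assessed_mask, "private"].mean()) if n_assessed else 0.0
        ),
        core_counts=core_counts,
    )


def aggregate_cliques(
    matrix: SimilarityMatrix,
    cliques: CliqueSet,
    records: Sequence[PlasmidRecord],
    display_threshold: float = 0.01,
) -> nx.Graph:
    """Aggregate the plasmid network to the clique level.

    Plasmids of one clique collapse into a single vertex (attributes: size,
    internal JI, dominant host genus); plasmids assigned to multiple cliques
    stay as solitary anchor vertices attached to each of their cliques;
    unassigned plasmids are dropped. Two cliques are linked when the mean JI
    over *all* cross-pairs of their members exceeds ``display_threshold``
    (zero keeps the unfiltered network); ``n_connections`` counts cross-pairs
    with any stored similarity. Anchor plasmids are excluded from cross-pair
    averaging between the cliques they anchor, and their membership edges
    are always retained.
    """
    genus = {r.id: r.host_lineage.get("genus") for r in records}
    anchors = cliques.multi_assigned()
    g = nx.Graph(display_threshold=display_threshold)

    for cid, members in cliques.cliques.items():
        hosts = [h for h in (genus.get(p) for p in members) if h is not None]
        # modal genus; ties resolved toward the lexicographically smallest
        dominant = None
        if hosts:
            counts: dict[str, int] = {}
            for h in hosts:
                counts[h] = counts.get(h, 0) + 1
            top = max(counts.values())
            dominant = min(h for h, c in counts.items() if c == top)
        g.add_node(
            cid,
            kind="clique",
            size=len(members),
            internal_ji=internal_similarity(members, matrix),
            dominant_host=dominant,
            exclusive_members=tuple(sorted(members - anchors)),
        )
    for p in sorted(anchors):
        g.add_node(p, kind="anchor")

    clique_ids = sorted(cliques.cliques)
    for i, a in enumerate(clique_ids):
        ma = cliques.cliques[a]
        for b in clique_ids[i + 1 :]:
            mb = cliques.cliques[b]
            both = ma & mb
            pairs = [
                (p, q)
                for p in sorted(ma - both)
                for q in sorted(mb - both)
                if p != q
            ]
            if not pairs:
                continue
            jis = [matrix.ji(p, q) for p, q in pairs]
            mean_ji = float(np.mean(jis))
            n_connections = sum(1 for x in jis if x > 0)
            if display_threshold > 0 and mean_ji <= display_threshold:
                continue
            if n_connections == 0:
                continue
            g.add_edge(a, b, mean_ji=mean_ji, n_connections=n_connections)

    for p in sorted(anchors):
        for cid in sorted(cliques.assignment[p]):
            others = sorted(cliques.cliques[cid] - {p})
            jis = [matrix.ji(p, q) for q in others]
            g.add_edge(
                p, cid,
                mean_ji=float(np.mean(jis)) if jis else 0.0,
                n_connections=sum(1 for x in jis if x > 0),
            )
    return g


def group_gene_overlap(
    table: GenePresenceTable,
    groups: Mapping[str, Iterable[str]],
    cliques: CliqueSet,
) -> dict[str, dict[str, int]]:
    """Venn-style shared/core gene counts between groups of cliques.

    ``groups`` maps a group name (e.g. a host-genus cluster of cliques) to a
    set of clique ids; groups must be disjoint over cliques. For every
    nonempty combination of groups, counts genes present in exactly that
    combination ("present" table) and likewise for genes core in at least
    one clique of each group ("core" table). Keys are "A", "A&B", ... with
    group names sorted.
    """
    names = sorted(groups)
    claimed: set[str] = set()
    for name in names:
        cs = set(groups[name])
        unknown = cs - set(cliques.cliques)
        if unknown:
            raise ValueError(f"group {name!r}: unknown cliques {sorted(unknown)}")
        if cs & claimed:
            raise ValueError("groups must be disjoint over cliques")
        claimed |= cs

    present: dict[str, set[str]] = {}
    core: dict[str, set[str]] = {}
    for name in names:
        members: set[str] = set()
        for cid in groups[name]:
            members |= cliques.cliques[cid]
        sub = table.table.loc[sorted(members & set(table.table.index))]
        present[name] = set(sub.columns[sub.any(axis=0)])
        core_genes: set[str] = set()
        for cid in groups[name]:
            clique_members = sorted(cliques.cliques[cid])
            block = table.table.loc[clique_members]
            core_genes |= set(block.columns[block.all(axis=0) & block.any(axis=0)])
        core[name] = core_genes

    def venn(sets: Mapping[str, set[str]]) -> dict[str, int]:
        out: dict[str, int] = {}
        n = len(names)
        for mask in range(1, 2 ** n):
            inside = [names[i] for i in range(n) if mask >> i & 1]
            outside = [names[i] for i in range(n) if not mask >> i & 1]
            region = set.intersection(*(sets[g] for g in inside))
            for g in outside:
                region = region - sets[g]
            out["&".join(inside)] = len(region)
        return out

    return {"present": venn(present), "core": venn(core)}
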