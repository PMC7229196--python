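"""Concordance between clique assignments and external plasmid typings.

Two clustering-comparison scores are implemented. Normalized mutual
information (NMI) between two flat labelings C1 and C2,

    NMI(C1, C2) = I(C1, C2) / ((H(C1) + H(C2)) / 2),

with mutual information I and Shannon entropies H computed from the
contingency table in natural log (the base cancels). NMI is 1 for identical
partitions and 0 for independent ones, and penalizes differences in the
number of classes. Purity of a set of cliques C against a typing scheme T,

    purity(C, T) = (1 / N) * sum_{c_i in C} max_{t_j in T} |c_i ∩ t_j|,

where N is the total number of typed plasmid-to-clique assignments retained.
Following the exclusion rules used for replicon/MOB typing: only cliques
containing at least one typed plasmid are assessed, and untyped plasmids
inside assessed cliques are disregarded.

Plasmids can carry several labels (e.g. multiple replicon types) and can be
assigned to several cliques; both are flattened to single composite labels
("IncF+IncY", order-free) or restricted to singly-labeled items.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Literal, Mapping

import numpy as np

from .sequences import TAXONOMY_RANKS, PlasmidRecord

if TYPE_CHECKING:  # pragma: no cover
    from .detect import CliqueSet

__all__ = [
    "Labeling",
    "flatten_labels",
    "contingency_table",
    "nmi",
    "purity",
    "host_purity",
]


@dataclass
class Labeling:
    """Item -> label-set mapping; an empty set marks an unlabeled item."""

    assignment: dict[str, set[str]]
    label_universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        seen = set().union(*self.assignment.values()) if self.assignment else set()
        if not self.label_universe:
            self.label_universe = seen
        elif not seen <= self.label_universe:
            raise ValueError(
                f"labels outside universe: {sorted(seen - self.label_universe)[:5]}"
            )

    @classmethod
    def from_records(
        cls, records: Iterable[PlasmidRecord],
        kind: Literal["replicon", "mob"] = "replicon",
    ) -> "Labeling":
        attr = "replicon_types" if kind == "replicon" else "mob_types"
        return cls({r.id: set(getattr(r, attr)) for r in records})


def flatten_labels(
    labeling: Labeling | Mapping[str, set[str]],
    mode: Literal["composite", "single_only"] = "composite",
) -> dict[str, str]:
    """Reduce label sets to one flat label per item.

    ``composite`` joins multi-label sets into a single sorted "a+b" label;
    ``single_only`` drops items carrying more than one label. Unlabeled
    items are always dropped.
    """
    if mode not in ("composite", "single_only"):
        raise ValueError(f"unknown mode {mode!r}")
    assignment = (
        labeling.assignment if isinstance(labeling, Labeling) else labeling
    )
    flat: dict[str, str] = {}
    for item, labels in assignment.items():
        if not labels:
            continue
        if len(labels) == 1:
            flat[item] = next(iter(labels))
        elif mode == "composite":
            flat[item] = "+".join(sorted(labels))
    return flat


def contingency_table(
    a: Mapping[str, str], b: Mapping[str, str]
) -> tuple[np.ndarray, list[str], list[str]]:
    """Cross-tabulate two flat labelings over their common items."""
    common = sorted(set(a) & set(b))
    if not common:
        raise ValueError("labelings share no items")
    rows = sorted({a[i] for i in common})
    cols = sorted({b[i] for i in common})
    ri = {lab: k for k, lab in enumerate(rows)}
    ci = {lab: k for k, lab in enumerate(cols)}
    table = np.zeros((len(rows), len(cols)), dtype=np.int64)
    for item in common:
        table[ri[a[item]], ci[b[item]]] += 1
    return table, rows, cols


def _entropy(counts: np.ndarray) -> float:
    """Shannon entropy in nats of a count vector."""
    n = counts.sum()
    probs = counts[counts > 0] / n
    return float(-(probs * np.log(probs)).sum())


def nmi(a: Mapping[str, str], b: Mapping[str, str]) -> float:
    """Normalized mutual information between two flat labelings.

    Items missing from either labeling are excluded first (plasmids left
    unclassified by a typing scheme are disregarded). Normalization is by
    the arithmetic mean of the two Shannon entropies; if both partitions
    are single-class (both entropies zero) the labelings are identical by
    construction and the score is 1.
    """
    table, _, _ = contingency_table(a, b)
    n = table.sum()
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    h_a = _entropy(row)
    h_b = _entropy(col)
    if h_a == 0.0 and h_b == 0.0:
        return 1.0
    # mutual information in nats from the contingency table
    nz = table > 0
    p = table[nz] / n
    outer = np.outer(row, col)[nz] / (n * n)
    info = float((p * np.log(p / outer)).sum())
    value = info / ((h_a + h_b) / 2.0)
    # clip tiny negative rounding noise
    return min(1.0, max(0.0, value))


def purity(
    cliques: "CliqueSet | Mapping[str, Iterable[str]]",
    labeling: Labeling | Mapping[str, set[str]],
) -> float:
    """Clique homogeneity against a typing scheme.

    For each assessed clique the best-represented type's member count is
    summed and divided by N, the total number of retained (plasmid, clique)
    assignments — a plasmid sitting in two cliques is counted in both.
    Cliques with no typed member are skipped; untyped members of assessed
    cliques are disregarded. Multi-label plasmids count toward each of
    their labels when the per-clique maximum is taken.
    """
    clique_map = getattr(cliques, "cliques", cliques)
    assignment = (
        labeling.assignment if isinstance(labeling, Labeling) else labeling
    )
    n_retained = 0
    total = 0
    for members in clique_map.values():
        typed = [p for p in members if assignment.get(p)]
        if not typed:
            continue
        counts: dict[str, int] = {}
        for p in typed:
            for label in assignment[p]:
                counts[label] = counts.get(label, 0) + 1
        total += max(counts.values())
        n_retained += len(typed)
    if n_retained == 0:
        raise ValueError("no clique contains a typed plasmid")
    return total / n_retained


def host_purity(
    cliques: "CliqueSet | Mapping[str, Iterable[str]]",
    records: Iterable[PlasmidRecord],
    rank: str,
) -> float:
    """Purity of cliques with respect to host taxonomy at a given rank.

    Plasmids lacking the rank in their host lineage are treated as untyped.
    """
    if rank not in TAXONOMY_RANKS:
        raise ValueError(f"unknown taxonomy rank {rank!r}")
    labeling = {
        r.id: ({r.host_lineage[rank]} if rank in r.host_lineage else set())
        for r in records
    }
    return purity(cliques, labeling)
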