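"""Sparsification-threshold optimization for the plasmid network.

The original JI network is usually too dense for stable community detection,
so edges below a JI threshold are removed before detection. A grid of
thresholds is evaluated against four criteria: (i) the clique-to-community
ratio, (ii) the percentage of plasmids covered by cliques, (iii) the
congruence with replicon typing (NMI, in an "all types" and a "single type"
variant) and (iv) the consistency of the stochastic detector across seeds
(the standard-deviation terms). The working threshold is then chosen by a
replaceable selection policy.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import networkx as nx

from .detect import DetectionConfig, detect_communities, validate_cliques
from .metrics import flatten_labels, nmi
from .network import SimilarityMatrix, build_network
from .sequences import PlasmidRecord

__all__ = ["SweepPoint", "sweep_thresholds", "select_threshold", "DEFAULT_SEEDS"]

#: Seeds used to replicate the stochastic detector at every threshold.
DEFAULT_SEEDS = (1, 5, 42, 93, 212)

_METRICS = (
    "n_communities",
    "n_cliques",
    "clique_community_ratio",
    "pct_plasmids_in_cliques",
    "nmi_all_types",
    "nmi_single_types",
)


@dataclass
class SweepPoint:
    """Per-seed metrics and their summary at one JI threshold.

    Metrics that cannot be computed (no communities, or no typed plasmids)
    are ``None`` — reported as missing, never coerced to zero. ``mean`` and
    ``sd`` (sample SD across seeds) skip missing values; error bars of
    roughly ±2 SD describe detector consistency.
    """

    threshold: float
    per_seed: dict[int, dict[str, Optional[float]]] = field(default_factory=dict)
    mean: dict[str, Optional[float]] = field(default_factory=dict)
    sd: dict[str, Optional[float]] = field(default_factory=dict)

    def summarize(self) -> None:
        for metric in _METRICS:
            values = [
                rec[metric] for rec in self.per_seed.values()
                if rec.get(metric) is not None
            ]
            if not values:
                self.mean[metric] = None
                self.sd[metric] = None
                continue
            m = sum(values) / len(values)
            self.mean[metric] = m
            if len(values) > 1:
                self.sd[metric] = math.sqrt(
                    sum((v - m) ** 2 for v in values) / (len(values) - 1)
                )
            else:
                self.sd[metric] = 0.0


def evaluate_point(
    matrix: SimilarityMatrix,
    original: nx.Graph,
    threshold: float,
    seed: int,
    records: Sequence[PlasmidRecord],
    config: DetectionConfig,
) -> dict[str, Optional[float]]:
    """Run detection at one (threshold, seed) and compute the four criteria."""
    network = build_network(matrix, threshold)
    run_config = dataclasses.replace(config, seed=seed)
    communities = detect_communities(network, run_config)
    big = [c for c in communities if len(c.members) >= 3]
    cliques = validate_cliques(communities, original)

    record: dict[str, Optional[float]] = {
        "n_communities": float(len(big)),
        "n_cliques": float(cliques.n_cliques),
        "clique_community_ratio": (
            cliques.n_cliques / len(big) if big else None
        ),
        "pct_plasmids_in_cliques": (
            100.0 * len(cliques.assigned_plasmids) / len(records)
        ),
    }

    clique_labels = cliques.labels()
    replicon = {r.id: set(r.replicon_types) for r in records}
    if not any(replicon.values()):
        record["nmi_all_types"] = None
        record["nmi_single_types"] = None
        return record
    for metric, mode in (
        ("nmi_all_types", "composite"),
        ("nmi_single_types", "single_only"),
    ):
        typed = flatten_labels(replicon, mode=mode)
        common = set(typed) & set(clique_labels)
        if common:
            record[metric] = nmi(
                {p: clique_labels[p] for p in common},
                {p: typed[p] for p in common},
            )
        else:
            record[metric] = None
    return record


def sweep_thresholds(
    matrix: SimilarityMatrix,
    original: nx.Graph,
    thresholds: Sequence[float],
    records: Sequence[PlasmidRecord],
    seeds: Sequence[int] = DEFAULT_SEEDS,
    config: Optional[DetectionConfig] = None,
) -> list[SweepPoint]:
    """Evaluate every threshold with every detector seed.

    The percentage of plasmids in cliques is computed against the full
    dataset size (singletons included in the denominator). Each
    (threshold, seed) cell is a pure function of its inputs, so re-running
    a sweep point reproduces it exactly.
    """
    if not thresholds:
        raise ValueError("thresholds must be nonempty")
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    if not seeds:
        raise ValueError("at least one seed is required")
    if config is None:
        config = DetectionConfig()
    points = []
    for threshold in thresholds:
        point = SweepPoint(threshold=threshold)
        for seed in seeds:
            point.per_seed[seed] = evaluate_point(
                matrix, original, threshold, seed, records, config
            )
        point.summarize()
        points.append(point)
    return points


def _default_policy(sweep: Sequence[SweepPoint]) -> float:
    """Joint-criteria selection.

    Among thresholds whose clique-to-community ratio lies within one SD of
    the best ratio, and whose clique coverage lies within one SD of the
    coverage at the ratio-maximizing threshold, pick the one maximizing the
    single-type NMI; ties go to the smaller threshold.
    """
    with_ratio = [p for p in sweep if p.mean.get("clique_community_ratio") is not None]
    if not with_ratio:
        raise ValueError("no sweep point produced any community; choose manually")
    eps = 1e-12
    best_ratio = max(p.mean["clique_community_ratio"] for p in with_ratio)
    argmax = min(
        (p for p in with_ratio
         if p.mean["clique_community_ratio"] >= best_ratio - eps),
        key=lambda p: p.threshold,
    )
    pct_ref = argmax.mean["pct_plasmids_in_cliques"]

    candidates = []
    for p in with_ratio:
        ratio_sd = p.sd.get("clique_community_ratio") or 0.0
        pct_sd = p.sd.get("pct_plasmids_in_cliques") or 0.0
        if p.mean["clique_community_ratio"] + ratio_sd < best_ratio - eps:
            continue
        if abs(p.mean["pct_plasmids_in_cliques"] - pct_ref) > pct_sd + eps:
            continue
        candidates.append(p)
    if not candidates:
        candidates = [argmax]
    scored = [p for p in candidates if p.mean.get("nmi_single_types") is not None]
    if not scored:
        if all(p.mean.get("nmi_single_types") is None for p in sweep):
            raise ValueError(
                "no sweep point has an NMI score (no typed plasmids); "
                "select the threshold manually"
            )
        scored = candidates
        return min(scored, key=lambda p: p.threshold).threshold
    best_nmi = max(p.mean["nmi_single_types"] for p in scored)
    return min(
        (p for p in scored if p.mean["nmi_single_types"] >= best_nmi - eps),
        key=lambda p: p.threshold,
    ).threshold


def select_threshold(
    sweep: Sequence[SweepPoint],
    policy: Optional[Callable[[Sequence[SweepPoint]], float]] = None,
) -> float:
    """Choose the working JI threshold from a sweep.

    The default policy trades off the four criteria as documented in
    :func:`_default_policy`; pass any callable taking the sweep and
    returning a threshold to override it.
    """
    if not sweep:
        raise ValueError("sweep must be nonempty")
    if len(sweep) == 1:
        return sweep[0].threshold
    return (policy or _default_policy)(sweep)
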