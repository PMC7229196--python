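"""Synthetic plasmid datasets with planted clique structure.

The generator emulates the features of real plasmid populations that drive
the network analysis: groups of plasmids sharing a mutated common backbone
(high within-group JI), chains of related groups whose backbones diverged
from a common ancestor (weak between-group similarity that a sparsification
threshold should remove), a pool of mobile-element segments inserted across
groups (low cross-group JI, the HGT signal), per-group GC content, host
taxonomy and replicon/MOB labels correlated with groups, chimeric plasmids
spanning two backbones, and unrelated singleton sequences. Every emitted
plasmid carries a truth row, so clique recovery, chimera multi-assignment
and robustness to mobile-element pruning can all be scored exactly.

Sequence model: a group backbone is an i.i.d. random sequence with the
group's target GC; each member substitutes every site independently with
probability ``mutation_rate``, drawing the replacement from the target base
composition (which is therefore exactly stationary; a draw equal to the
current base is silent). Two members then share a fraction
s = (1 - mu_eff)^(2k) of their k-mer windows in expectation, with mu_eff
the effective base-change rate, giving a within-group Jaccard index of
about s / (2 - s).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .characterize import GenePresenceTable
from .sequences import PlasmidRecord

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "simulate",
    "prune_mobile_elements",
    "expected_within_ji",
]

_MOB_TYPES = ("MOBF", "MOBP", "MOBQ", "MOBC", "MOBH", "MOBV")


def effective_rate(mutation_rate: float, gc: float = 0.5) -> float:
    """Per-site base-change probability under the composition-drawn kernel.

    Replacements are drawn from the target composition (so the composition is
    exactly stationary); a draw equal to the current base is silent. With
    composition probabilities c_b, the base-change probability is
    mu * (1 - sum_b c_b^2).
    """
    comp = _composition(gc)
    return mutation_rate * (1.0 - float((comp**2).sum()))


def expected_within_ji(mutation_rate: float, k: int = 21,
                       gc: float = 0.5) -> float:
    """Expected JI between two members mutated independently from one backbone.

    A k-window survives in both copies with probability
    s = (1 - mu_eff)^(2k), with mu_eff the effective base-change rate; with
    set sizes unchanged in expectation, JI ≈ s / (2 - s).
    """
    s = (1.0 - effective_rate(mutation_rate, gc)) ** (2 * k)
    return s / (2.0 - s)


@dataclass
class SimulationConfig:
    """Parameters of the planted-structure generator.

    Defaults describe the standard study conditions: 10 cliques of 5-15
    members on 20-50 kb backbones, a per-member substitution rate of 0.01
    (within-clique JI ≈ 0.55-0.6 at k = 21), two chains of three related
    cliques whose adjacent backbones diverged by 0.18 per site
    (between-clique JI ≈ 0.02, chain ends falling below the shared-k-mer
    cutoff), a modest shared mobile-element pool, 10 singletons and 2
    chimeras.
    """

    n_cliques: int = 10
    clique_size_range: tuple[int, int] = (5, 15)
    backbone_length_range: tuple[int, int] = (20_000, 50_000)
    gc_range: tuple[float, float] = (0.35, 0.65)
    mutation_rate: float = 0.01
    # shared mobile-element pool
    n_elements: int = 6
    element_length_range: tuple[int, int] = (500, 1_000)
    element_insertion_prob: float = 0.1
    accessory_prob: float = 0.3
    accessory_length_range: tuple[int, int] = (300, 800)
    # related-backbone chains (weak between-clique similarity)
    n_chains: int = 2
    chain_length: int = 3
    backbone_divergence: float = 0.18
    # extras
    n_singletons: int = 10
    singleton_length_range: tuple[int, int] = (5_000, 20_000)
    n_chimeras: int = 2
    # labels
    replicon_labels: Optional[dict[int, str]] = None
    seed: int = 7
    k: int = 21

    def __post_init__(self) -> None:
        if self.n_cliques < 1:
            raise ValueError("n_cliques must be >= 1")
        if self.clique_size_range[0] < 3:
            raise ValueError("clique sizes must be >= 3")
        for lo, hi in (
            self.clique_size_range,
            self.backbone_length_range,
            self.element_length_range,
            self.accessory_length_range,
            self.singleton_length_range,
        ):
            if lo > hi or lo < 1:
                raise ValueError(f"invalid range ({lo}, {hi})")
        if self.backbone_length_range[0] < self.k:
            raise ValueError("backbone length must be >= k")
        if not (0.25 <= self.gc_range[0] <= self.gc_range[1] <= 0.75):
            raise ValueError("GC targets must lie within [0.25, 0.75]")
        for p in (
            self.mutation_rate,
            self.element_insertion_prob,
            self.accessory_prob,
            self.backbone_divergence,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities/rates must be in [0, 1]")
        if self.n_chains * self.chain_length > self.n_cliques:
            raise ValueError("chains cannot cover more cliques than exist")

    @property
    def recommended_min_shared(self) -> int:
        """Shared-k-mer cutoff appropriate for the simulated backbone scale.

        The default cutoff of 100 assumes gene-scale sequences; keep it for
        backbones of at least 5 kb, scale it down proportionally below that
        so toy datasets are not rendered edgeless.
        """
        shortest = self.backbone_length_range[0]
        if shortest >= 5_000:
            return 100
        return max(1, int(100 * shortest / 5_000))


@dataclass
class SyntheticTruth:
    """Planted labels and mobile-element coordinates for every plasmid.

    ``clique_of`` maps each plasmid id to its planted clique label, to
    ``SINGLETON``, or to ``CHIMERA:<a>+<b>`` naming its two parents.
    ``elements`` holds 0-based half-open (start, end, element_id) intervals
    of inserted mobile elements; ``accessory`` likewise for private
    accessory segments. ``params`` echoes the generator configuration.
    """

    clique_of: dict[str, str] = field(default_factory=dict)
    elements: dict[str, list[tuple[int, int, str]]] = field(default_factory=dict)
    accessory: dict[str, list[tuple[int, int, str]]] = field(default_factory=dict)
    gc_targets: dict[str, float] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def planted_labels(self) -> dict[str, str]:
        """Clique label per regular member (singletons and chimeras excluded)."""
        return {
            pid: lab for pid, lab in self.clique_of.items()
            if lab != "SINGLETON" and not lab.startswith("CHIMERA:")
        }

    def chimeras(self) -> dict[str, tuple[str, str]]:
        out = {}
        for pid, lab in self.clique_of.items():
            if lab.startswith("CHIMERA:"):
                a, b = lab.removeprefix("CHIMERA:").split("+")
                out[pid] = (a, b)
        return out

    def singletons(self) -> set[str]:
        return {p for p, lab in self.clique_of.items() if lab == "SINGLETON"}


@dataclass
class SyntheticDataset:
    """Generator output: records with metadata, gene table and truth."""

    records: list[PlasmidRecord]
    gene_table: GenePresenceTable
    truth: SyntheticTruth
    manifest: dict

    def write(self, out_dir: str | Path) -> None:
        """Write FASTA, metadata TSV, gene TSV, truth TSV and manifest JSON.

        All files follow the pipeline's input contracts, so a written
        dataset round-trips through :func:`plasmidnet.read_plasmids`.
        """
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "plasmids.fasta", "w") as fh:
            for r in self.records:
                fh.write(f">{r.id}\n")
                for i in range(0, len(r.sequence), 80):
                    fh.write(r.sequence[i : i + 80] + "\n")
        with open(out / "metadata.tsv", "w") as fh:
            ranks = ("phylum", "class", "order", "family", "genus", "species")
            fh.write("id\t" + "\t".join(ranks) + "\treplicon_types\tmob_types\n")
            for r in self.records:
                row = [r.id]
                row += [r.host_lineage.get(rank, "") for rank in ranks]
                row.append(";".join(sorted(r.replicon_types)))
                row.append(";".join(sorted(r.mob_types)))
                fh.write("\t".join(row) + "\n")
        self.gene_table.to_tsv(out / "genes.tsv")
        with open(out / "truth.tsv", "w") as fh:
            fh.write("id\tplanted\telements\taccessory\tgc_target\n")
            for r in self.records:
                pid = r.id
                fmt = lambda ivs: ";".join(f"{s}-{e}:{g}" for s, e, g in ivs)
                fh.write(
                    f"{pid}\t{self.truth.clique_of[pid]}\t"
                    f"{fmt(self.truth.elements.get(pid, []))}\t"
                    f"{fmt(self.truth.accessory.get(pid, []))}\t"
                    f"{self.truth.gc_targets.get(pid, '')}\n"
                )
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)


# --- sequence primitives (2-bit codes; A=0 C=1 G=2 T=3) ----------------------

_LETTERS = np.frombuffer(b"ACGT", dtype=np.uint8)


def _composition(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _random_codes(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    return rng.choice(4, size=length, p=_composition(gc)).astype(np.uint8)


def _mutate(rng: np.random.Generator, codes: np.ndarray, rate: float,
            gc: float) -> np.ndarray:
    """Substitute each site w.p. ``rate``, drawing the replacement from the
    target base composition.

    Because replacements are drawn from the stationary composition, the
    expected base composition is preserved exactly at any divergence; draws
    equal to the current base are silent (see :func:`effective_rate`).
    """
    if rate == 0.0:
        return codes.copy()
    out = codes.copy()
    hit = np.flatnonzero(rng.random(len(codes)) < rate)
    if hit.size:
        out[hit] = rng.choice(4, size=hit.size,
                              p=_composition(gc)).astype(np.uint8)
    return out


def _to_str(codes: np.ndarray) -> str:
    return _LETTERS[codes].tobytes().decode("ascii")


def _insert_segment(
    rng: np.random.Generator,
    seq: np.ndarray,
    intervals: list[tuple[int, int, str, str]],
    segment: np.ndarray,
    gene_id: str,
    kind: str,
) -> np.ndarray:
    """Insert ``segment`` at a position not strictly inside another insert."""
    length = len(segment)
    for _ in range(200):
        pos = int(rng.integers(0, len(seq) + 1))
        if all(not (s < pos < e) for s, e, _, _ in intervals):
            break
    else:  # pragma: no cover - essentially unreachable at sane densities
        raise RuntimeError("could not place segment outside existing elements")
    for i, (s, e, g, knd) in enumerate(intervals):
        if s >= pos:
            intervals[i] = (s + length, e + length, g, knd)
    intervals.append((pos, pos + length, gene_id, kind))
    return np.concatenate([seq[:pos], segment, seq[pos:]])


# --- the generator ------------------------------------------------------------


def simulate(config: Optional[SimulationConfig] = None) -> SyntheticDataset:
    """Generate a plasmid dataset with known clique structure.

    Fully deterministic given ``config.seed``: identical configurations
    produce byte-identical outputs.
    """
    if config is None:
        config = SimulationConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_cliques

    # per-clique scaffolding: chains first, independent cliques after
    chain_of = {}
    heads = {}
    idx = 0
    for c in range(config.n_chains):
        for pos in range(config.chain_length):
            chain_of[idx] = (c, pos)
            if pos == 0:
                heads[c] = idx
            idx += 1

    gc_targets = np.linspace(config.gc_range[0], config.gc_range[1], n)
    sizes = rng.integers(
        config.clique_size_range[0], config.clique_size_range[1] + 1, size=n
    )

    backbones: list[np.ndarray] = [None] * n  # type: ignore[list-item]
    eff_gc = np.array(gc_targets)
    for i in range(n):
        if i in chain_of and chain_of[i][1] > 0:
            parent = i - 1
            eff_gc[i] = eff_gc[parent]
            backbones[i] = _mutate(
                rng, backbones[parent], config.backbone_divergence, eff_gc[i]
            )
        else:
            length = int(rng.integers(*config.backbone_length_range))
            backbones[i] = _random_codes(rng, length, eff_gc[i])

    # shared mobile-element pool (neutral composition)
    elements = [
        _random_codes(rng, int(rng.integers(*config.element_length_range)), 0.5)
        for _ in range(config.n_elements)
    ]
    element_ids = [f"mge{e:02d}" for e in range(config.n_elements)]

    clique_label = [f"clique{i:02d}" for i in range(n)]
    if config.replicon_labels is not None:
        replicon_of = dict(config.replicon_labels)
    else:
        # one replicon label per clique, except the first chain, whose cliques
        # share a label: a single incompatibility group split across several
        # related cliques, as seen for broad-host-range plasmids
        replicon_of = {i: f"Inc{i:02d}" for i in range(n)}
        if config.n_chains >= 1:
            for pos in range(config.chain_length):
                replicon_of[heads[0] + pos] = "IncSplit"
    mob_of = {i: _MOB_TYPES[i % len(_MOB_TYPES)] for i in range(n)}

    def lineage(i: int, member: int) -> dict[str, str]:
        return {
            "phylum": f"Phylum{i // 5}",
            "class": f"Class{i // 4}",
            "order": f"Order{i // 3}",
            "family": f"Family{i // 2}",
            "genus": f"Genus{i:02d}",
            "species": f"Genus{i:02d} sp{member % 3}",
        }

    records: list[PlasmidRecord] = []
    truth = SyntheticTruth(params={"config": config.__dict__.copy()})
    gene_rows: dict[str, set[str]] = {}

    for i in range(n):
        for m in range(int(sizes[i])):
            pid = f"c{i:02d}_p{m:02d}"
            seq = _mutate(rng, backbones[i], config.mutation_rate, eff_gc[i])
            intervals: list[tuple[int, int, str, str]] = []
            genes = {f"bb_{clique_label[i]}"}
            for e, element in enumerate(elements):
                if rng.random() < config.element_insertion_prob:
                    seq = _insert_segment(
                        rng, seq, intervals, element, element_ids[e], "mge"
                    )
                    genes.add(element_ids[e])
            if rng.random() < config.accessory_prob:
                acc = _random_codes(
                    rng,
                    int(rng.integers(*config.accessory_length_range)),
                    eff_gc[i],
                )
                gid = f"acc_{pid}"
                seq = _insert_segment(rng, seq, intervals, acc, gid, "acc")
                genes.add(gid)
            records.append(
                PlasmidRecord(
                    id=pid,
                    sequence=_to_str(seq),
                    host_lineage=lineage(i, m),
                    replicon_types={replicon_of[i]},
                    mob_types={mob_of[i]},
                )
            )
            truth.clique_of[pid] = clique_label[i]
            truth.elements[pid] = [
                (s, e, g) for s, e, g, knd in sorted(intervals) if knd == "mge"
            ]
            truth.accessory[pid] = [
                (s, e, g) for s, e, g, knd in sorted(intervals) if knd == "acc"
            ]
            truth.gc_targets[pid] = float(eff_gc[i])
            gene_rows[pid] = genes

    # chimeras: halves of two backbones from unrelated lineages
    for c in range(config.n_chimeras):
        for _ in range(100):
            a, b = (int(x) for x in rng.choice(n, size=2, replace=False))
            a, b = min(a, b), max(a, b)
            same_chain = (
                a in chain_of and b in chain_of
                and chain_of[a][0] == chain_of[b][0]
            )
            if not same_chain:
                break
        pid = f"chimera{c:02d}"
        half_a = backbones[a][: len(backbones[a]) // 2]
        half_b = backbones[b][len(backbones[b]) // 2 :]
        gc_mix = float((eff_gc[a] + eff_gc[b]) / 2)
        seq = _mutate(rng, np.concatenate([half_a, half_b]),
                      config.mutation_rate, gc_mix)
        records.append(
            PlasmidRecord(
                id=pid,
                sequence=_to_str(seq),
                host_lineage=lineage(a, 0),
                replicon_types={replicon_of[a], replicon_of[b]},
                mob_types={mob_of[a], mob_of[b]},
            )
        )
        truth.clique_of[pid] = f"CHIMERA:{clique_label[a]}+{clique_label[b]}"
        truth.elements[pid] = []
        truth.accessory[pid] = []
        truth.gc_targets[pid] = gc_mix
        gene_rows[pid] = {f"bb_{clique_label[a]}", f"bb_{clique_label[b]}"}

    for s in range(config.n_singletons):
        pid = f"singleton{s:02d}"
        gc = float(rng.uniform(*config.gc_range))
        seq = _random_codes(
            rng, int(rng.integers(*config.singleton_length_range)), gc
        )
        records.append(
            PlasmidRecord(
                id=pid,
                sequence=_to_str(seq),
                host_lineage={"phylum": "PhylumX", "genus": f"Lone{s:02d}"},
            )
        )
        truth.clique_of[pid] = "SINGLETON"
        truth.elements[pid] = []
        truth.accessory[pid] = []
        truth.gc_targets[pid] = gc
        gene_rows[pid] = set()

    all_genes = sorted(set().union(*gene_rows.values()))
    table = pd.DataFrame(
        [[g in gene_rows[r.id] for g in all_genes] for r in records],
        index=[r.id for r in records],
        columns=all_genes,
        dtype=bool,
    )

    manifest = {
        "n_plasmids": len(records),
        "n_cliques": n,
        "clique_sizes": [int(s) for s in sizes],
        "k": config.k,
        "min_shared": config.recommended_min_shared,
        "mutation_rate": config.mutation_rate,
        "expected_within_ji": expected_within_ji(config.mutation_rate, config.k),
        "gc_targets": [float(g) for g in eff_gc],
        "seed": config.seed,
    }
    return SyntheticDataset(
        records=records,
        gene_table=GenePresenceTable(table),
        truth=truth,
        manifest=manifest,
    )


def _merge_intervals(
    intervals: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def prune_mobile_elements(
    records: Sequence[PlasmidRecord], truth: SyntheticTruth
) -> list[PlasmidRecord]:
    """Excise every planted mobile-element segment from the sequences.

    Mirrors the robustness check of removing transposition-associated
    accessory genes before re-running clique assignment. Overlapping
    excision intervals are merged first; metadata is carried over unchanged.
    """
    out: list[PlasmidRecord] = []
    for r in records:
        coords = [(s, e) for s, e, _ in truth.elements.get(r.id, [])]
        if not coords:
            out.append(
                PlasmidRecord(
                    id=r.id,
                    sequence=r.sequence,
                    host_lineage=dict(r.host_lineage),
                    replicon_types=set(r.replicon_types),
                    mob_types=set(r.mob_types),
                )
            )
            continue
        for s, e in coords:
            if not (0 <= s <= e <= len(r.sequence)):
                raise ValueError(
                    f"invalid excision interval ({s}, {e}) for {r.id!r}"
                )
        keep = []
        cursor = 0
        for s, e in _merge_intervals(coords):
            keep.append(r.sequence[cursor:s])
            cursor = e
        keep.append(r.sequence[cursor:])
        out.append(
            PlasmidRecord(
                id=r.id,
                sequence="".join(keep),
                host_lineage=dict(r.host_lineage),
                replicon_types=set(r.replicon_types),
                mob_types=set(r.mob_types),
            )
        )
    return out
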