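"""Per-clique statistics, gene-content classes and the clique-level network."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import plasmidnet as pn
from plasmidnet.detect import CliqueSet


def _clique_set(*member_sets) -> CliqueSet:
    cs = CliqueSet()
    for i, members in enumerate(member_sets):
        cid = f"C{i:03d}"
        cs.cliques[cid] = frozenset(members)
        for p in members:
            cs.assignment.setdefault(p, set()).add(cid)
    return cs


def _table(data: dict[str, dict[str, int]]) -> pn.GenePresenceTable:
    return pn.GenePresenceTable(pd.DataFrame(data).fillna(0).T)


class TestCliqueNumericStats:
    def test_constant_values_have_zero_sd(self):
        cs = _clique_set({"a", "b", "c"})
        stats_df = pn.clique_numeric_stats(cs, {"a": 2.0, "b": 2.0, "c": 2.0})
        assert stats_df.loc["C000", "sd"] == 0.0
        assert stats_df.loc["C000", "n"] == 3

    def test_hand_computed_mean_and_sample_sd(self):
        cs = _clique_set({"a", "b", "c"})
        stats_df = pn.clique_numeric_stats(
            cs, {"a": 0.4, "b": 0.5, "c": 0.6}
        )
        assert stats_df.loc["C000", "mean"] == pytest.approx(0.5)
        assert stats_df.loc["C000", "sd"] == pytest.approx(0.1)

    def test_missing_value_names_the_plasmid(self):
        cs = _clique_set({"a", "b", "c"})
        with pytest.raises(ValueError, match="'b'"):
            pn.clique_numeric_stats(cs, {"a": 1.0, "c": 1.0})

    def test_generator_backbone_gc_means_match_targets(self, small_dataset,
                                                       small_cliques):
        # GC control applies to the backbone; strip planted inserts first
        # (mobile elements have neutral composition and dilute short backbones)
        truth = small_dataset.truth
        backbone_gc = {}
        for r in small_dataset.records:
            cuts = sorted(
                [(s, e) for s, e, _ in truth.elements.get(r.id, [])]
                + [(s, e) for s, e, _ in truth.accessory.get(r.id, [])]
            )
            kept, cursor = [], 0
            for s, e in cuts:
                kept.append(r.sequence[cursor:s])
                cursor = e
            kept.append(r.sequence[cursor:])
            backbone_gc[r.id] = pn.gc_content("".join(kept))
        stats_df = pn.clique_numeric_stats(small_cliques, backbone_gc)
        for cid, members in small_cliques.cliques.items():
            member_targets = {truth.gc_targets[p] for p in members
                              if not p.startswith("chimera")}
            if len(member_targets) != 1:
                continue
            # kilobase backbones carry binomial composition noise of their
            # own (sd ~ 0.009 at 3 kb), shared by every member of the clique
            assert stats_df.loc[cid, "mean"] == pytest.approx(
                member_targets.pop(), abs=0.03
            )


class TestPairwiseDifferenceTest:
    def test_forced_separation_flags_every_pair(self):
        rng = np.random.default_rng(0)
        cs = _clique_set({f"a{i}" for i in range(8)},
                         {f"b{i}" for i in range(8)})
        values = {f"a{i}": float(x) for i, x in
                  enumerate(rng.normal(0.0, 1.0, 8))}
        values |= {f"b{i}": float(x) for i, x in
                   enumerate(rng.normal(20.0, 1.0, 8))}
        result = pn.pairwise_difference_test(cs, values, alpha=0.001)
        assert result.fraction_significant == 1.0
        assert result.anova_p < 1e-6

    def test_one_shifted_clique_yields_exactly_its_two_pairs(self):
        rng = np.random.default_rng(1)
        groups = {
            "x": rng.normal(0.0, 1.0, 10),
            "y": rng.normal(0.0, 1.0, 10),
            "z": rng.normal(30.0, 1.0, 10),
        }
        cs = _clique_set(*({f"{g}{i}" for i in range(10)} for g in groups))
        values = {
            f"{g}{i}": float(v)
            for g, arr in groups.items() for i, v in enumerate(arr)
        }
        result = pn.pairwise_difference_test(cs, values, alpha=0.001)
        sig = result.pairs[result.pairs["significant"]]
        assert len(sig) == 2
        # the two significant pairs are those involving the shifted clique
        involved = set(sig["clique_a"]) | set(sig["clique_b"])
        assert len(involved) == 3

    def test_reference_tukey_oracle_agreement(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(m, 1.0, 6) for m in (0.0, 0.5, 3.0)]
        cs = _clique_set(*({f"g{k}_{i}" for i in range(6)}
                           for k in range(3)))
        values = {
            f"g{k}_{i}": float(v)
            for k, arr in enumerate(groups) for i, v in enumerate(arr)
        }
        ours = pn.pairwise_difference_test(cs, values, alpha=0.05)
        ref = stats.tukey_hsd(*groups)
        expected = [ref.pvalue[0, 1], ref.pvalue[0, 2], ref.pvalue[1, 2]]
        assert np.allclose(sorted(ours.pairs["p_adj"]), sorted(expected),
                           atol=1e-6)

    def test_zero_variance_everywhere_is_an_error(self):
        cs = _clique_set({"a", "b"}, {"c", "d"})
        with pytest.raises(ValueError, match="variance"):
            pn.pairwise_difference_test(
                cs, {"a": 1.0, "b": 1.0, "c": 2.0, "d": 2.0}
            )


class TestClassifyGenes:
    def test_gene_filling_one_clique_is_core_and_private(self):
        cs = _clique_set({"a", "b", "c"}, {"d", "e", "f"})
        table = _table({p: {"g1": int(p in "abc")} for p in "abcdef"})
        result = pn.classify_genes(table, cs, min_occurrence=3)
        assert result.genes.loc["g1", "core"]
        assert result.genes.loc["g1", "private"]
        assert result.core_counts == {"C000": 1, "C001": 0}

    def test_core_via_one_clique_but_present_elsewhere_is_not_private(self):
        cs = _clique_set({"a", "b", "c"}, {"d", "e", "f", "g", "h"})
        presence = {p: {"g1": 1} for p in "abc"} | {"d": {"g1": 1}}
        presence |= {p: {} for p in "efgh"}
        result = pn.classify_genes(_table(presence), cs, min_occurrence=4)
        assert result.genes.loc["g1", "core"]
        assert not result.genes.loc["g1", "private"]

    def test_low_occurrence_genes_are_not_assessed(self):
        cs = _clique_set({"a", "b", "c", "d"})
        presence = {p: {"g1": int(p in "abcd"), "g2": int(p in "ab")}
                    for p in "abcd"}
        result = pn.classify_genes(_table(presence), cs, min_occurrence=5)
        assert not result.genes.loc["g1", "assessed"]  # occurs 4 < 5
        assert result.n_assessed == 0

    def test_brute_force_reimplementation_on_random_tables(self):
        rng = np.random.default_rng(11)
        plasmids = [f"p{i}" for i in range(12)]
        cs = _clique_set(set(plasmids[0:4]), set(plasmids[3:8]))
        in_cliques = set(plasmids[0:8])
        for _ in range(20):
            presence = pd.DataFrame(
                rng.random((12, 6)) < 0.4,
                index=plasmids,
                columns=[f"g{j}" for j in range(6)],
            )
            result = pn.classify_genes(
                pn.GenePresenceTable(presence), cs, min_occurrence=2
            )
            for gene in presence.columns:
                carriers = set(presence.index[presence[gene]])
                assessed = len(carriers) >= 2
                freq_one = {
                    cid for cid, ms in cs.cliques.items()
                    if carriers >= ms
                }
                occupied = {
                    cid for cid, ms in cs.cliques.items() if carriers & ms
                }
                expect_core = assessed and bool(freq_one)
                expect_private = (
                    assessed and len(occupied) == 1
                    and occupied == freq_one
                    and not carriers - in_cliques
                )
                assert result.genes.loc[gene, "core"] == expect_core
                assert result.genes.loc[gene, "private"] == expect_private


class TestAggregateCliques:
    def _matrix(self, ids, entries):
        mat = pn.SimilarityMatrix(ids=list(ids), min_shared=1)
        index = {p: i for i, p in enumerate(ids)}
        for (a, b), ji in entries.items():
            i, j = sorted((index[a], index[b]))
            mat.entries[(i, j)] = (ji, 10)
        return mat

    def _records(self, ids, genus="Escherichia"):
        return [
            pn.PlasmidRecord(id=p, sequence="ACGT",
                             host_lineage={"genus": genus})
            for p in ids
        ]

    def test_unconnected_cliques_get_no_edge(self):
        ids = ["a", "b", "c", "d", "e", "f"]
        cs = _clique_set({"a", "b", "c"}, {"d", "e", "f"})
        mat = self._matrix(ids, {("a", "b"): 0.5, ("a", "c"): 0.5,
                                 ("b", "c"): 0.5, ("d", "e"): 0.5,
                                 ("d", "f"): 0.5, ("e", "f"): 0.5})
        g = pn.aggregate_cliques(mat, cs, self._records(ids))
        assert not g.has_edge("C000", "C001")

    def test_cross_pair_mean_uses_all_pairs(self):
        # cliques {a,b}, {c,d}; JI(a,c) = 0.4, others 0 -> mean 0.1, one link
        ids = ["a", "b", "c", "d"]
        cs = _clique_set({"a", "b"}, {"c", "d"})
        mat = self._matrix(ids, {("a", "b"): 0.9, ("c", "d"): 0.9,
                                 ("a", "c"): 0.4})
        g = pn.aggregate_cliques(mat, cs, self._records(ids),
                                 display_threshold=0.01)
        assert g.edges[("C000", "C001")]["mean_ji"] == pytest.approx(0.1)
        assert g.edges[("C000", "C001")]["n_connections"] == 1

    def test_display_threshold_filters_weak_edges(self):
        ids = ["a", "b", "c", "d"]
        cs = _clique_set({"a", "b"}, {"c", "d"})
        mat = self._matrix(ids, {("a", "b"): 0.9, ("c", "d"): 0.9,
                                 ("a", "c"): 0.4})
        unfiltered = pn.aggregate_cliques(mat, cs, self._records(ids),
                                          display_threshold=0.0)
        assert unfiltered.has_edge("C000", "C001")
        strict = pn.aggregate_cliques(mat, cs, self._records(ids),
                                      display_threshold=0.15)
        assert not strict.has_edge("C000", "C001")

    def test_anchor_vertices_conserve_assignments(self):
        ids = ["a", "b", "c", "x", "d", "e", "f"]
        cs = _clique_set({"a", "b", "c", "x"}, {"x", "d", "e", "f"})
        entries = {("a", "b"): 0.5, ("a", "c"): 0.5, ("b", "c"): 0.5,
                   ("x", "a"): 0.5, ("x", "b"): 0.5, ("x", "c"): 0.5,
                   ("d", "e"): 0.5, ("d", "f"): 0.5, ("e", "f"): 0.5,
                   ("x", "d"): 0.5, ("x", "e"): 0.5, ("x", "f"): 0.5}
        mat = self._matrix(ids, entries)
        g = pn.aggregate_cliques(mat, cs, self._records(ids))
        assert g.nodes["x"]["kind"] == "anchor"
        assert g.has_edge("x", "C000") and g.has_edge("x", "C001")
        exclusive = (set(g.nodes["C000"]["exclusive_members"])
                     | set(g.nodes["C001"]["exclusive_members"]))
        assert exclusive | {"x"} == set(ids)
        assert "x" not in exclusive

    def test_dominant_host_is_modal_genus(self):
        ids = ["a", "b", "c"]
        cs = _clique_set({"a", "b", "c"})
        mat = self._matrix(ids, {("a", "b"): 0.5, ("a", "c"): 0.5,
                                 ("b", "c"): 0.5})
        records = self._records(["a", "b"], genus="Escherichia") + \
            self._records(["c"], genus="Klebsiella")
        g = pn.aggregate_cliques(mat, cs, records)
        assert g.nodes["C000"]["dominant_host"] == "Escherichia"


class TestGroupGeneOverlap:
    def test_disjoint_pools_have_empty_intersections(self):
        cs = _clique_set({"a", "b", "c"}, {"d", "e", "f"})
        presence = {p: {"g1": int(p in "abc"), "g2": int(p in "def")}
                    for p in "abcdef"}
        out = pn.group_gene_overlap(
            _table(presence), {"G1": {"C000"}, "G2": {"C001"}}, cs
        )
        assert out["present"]["G1&G2"] == 0
        assert out["present"]["G1"] == 1 and out["present"]["G2"] == 1

    def test_gene_planted_in_all_groups_reaches_full_intersection(self):
        cs = _clique_set({"a", "b"}, {"c", "d"}, {"e", "f"})
        presence = {p: {"shared": 1} for p in "abcdef"}
        out = pn.group_gene_overlap(
            _table(presence),
            {"G1": {"C000"}, "G2": {"C001"}, "G3": {"C002"}},
            cs,
        )
        assert out["present"]["G1&G2&G3"] >= 1
        assert out["core"]["G1&G2&G3"] >= 1  # frequency one in each clique

    def test_region_counts_match_set_oracle(self, small_dataset,
                                            small_cliques):
        cliques = sorted(small_cliques.cliques)
        if len(cliques) < 2:
            pytest.skip("needs two cliques")
        groups = {"A": {cliques[0]}, "B": {cliques[1]}}
        out = pn.group_gene_overlap(small_dataset.gene_table, groups,
                                    small_cliques)
        table = small_dataset.gene_table.table
        union = {}
        for name, cids in groups.items():
            members = set().union(*(small_cliques.cliques[c] for c in cids))
            sub = table.loc[sorted(members)]
            union[name] = set(sub.columns[sub.any(axis=0)])
        assert out["present"]["A"] == len(union["A"] - union["B"])
        assert out["present"]["B"] == len(union["B"] - union["A"])
        assert out["present"]["A&B"] == len(union["A"] & union["B"])

    def test_overlapping_groups_are_rejected(self):
        cs = _clique_set({"a", "b"}, {"c", "d"})
        with pytest.raises(ValueError, match="disjoint"):
            pn.group_gene_overlap(
                _table({p: {"g": 1} for p in "abcd"}),
                {"G1": {"C000"}, "G2": {"C000", "C001"}},
                cs,
            )
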