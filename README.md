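# plasmidnet

Alignment-free population structure for bacterial plasmids: k-mer Jaccard
similarity networks, statistically validated cliques, and clique-level
biology.

## The problem

Plasmids exchange genes horizontally, recombine, and merge; their history is
poorly captured by phylogenetic trees built from alignments. A practical
alternative is to treat each plasmid genome as a *set of k-mers* and build a
network in which vertices are plasmids and edge weights are exact Jaccard
indices between their k-mer sets:

```
JI(A, B) = |A ∩ B| / |A ∪ B|
```

computed on canonical 21-mers, with pairs sharing fewer than 100 k-mers
treated as JI = 0 (less than a typical gene's worth of common sequence).
Groups of plasmids sharing a common backbone then appear as **cliques** —
complete subgraphs of mutually similar plasmids. Cliques correlate with
replicon (Inc) and MOB typing, host taxonomy, GC content and gene content,
and plasmids assigned to two cliques flag chimeras and large-scale
transfer events.

`plasmidnet` is aimed at microbial genomics researchers who want to go from
a FASTA of plasmid sequences (plus optional typing metadata and a gene
presence table) to validated plasmid cliques and their characterization,
entirely from Python.

## What the package does

1. **k-mer sets** (`extract_kmers`) — canonical (strand-collapsed) 21-mers.
2. **Similarity network** (`pairwise_jaccard`, `build_network`) — exact
   all-pairs JI with the shared-k-mer cutoff; sparsification at a JI
   threshold (edges with JI ≥ t are kept).
3. **Community detection** (`detect_communities`) — an ordered-statistics
   local-optimization detector: clusters are grown and cleaned using
   binomial tail probabilities under a configuration-model null (degree-
   preserving random rewiring), with an order-statistic correction
   Beta(r, m−r+1) for picking the best of m neighbours; clusters recurring
   across many seeded runs are reported. `vertex_significance` exposes the
   null: for a candidate of degree k_v and a cluster holding K_C of the
   network's M edge endpoints, the internal degree is Binomial(k_v, K_C/M).
4. **Clique validation** (`validate_cliques`) — communities of size ≥ 3 are
   kept only if complete in the *original* (unthresholded) network.
   `max_cliques` provides exact Bron–Kerbosch enumeration for comparison.
5. **Threshold sweep** (`sweep_thresholds`, `select_threshold`) — evaluates
   a threshold grid against the clique/community ratio, clique coverage,
   replicon-typing NMI and cross-seed consistency.
6. **Concordance metrics** (`nmi`, `purity`, `host_purity`) —

   ```
   NMI(C1, C2) = I(C1, C2) / ((H(C1) + H(C2)) / 2)
   purity(C, T) = (1/N) Σ_{c_i ∈ C} max_{t_j ∈ T} |c_i ∩ t_j|
   ```

   with the standard exclusions: untyped plasmids are disregarded, and only
   cliques containing a typed plasmid enter the purity.
7. **Characterization** (`clique_numeric_stats`, `pairwise_difference_test`,
   `classify_genes`, `aggregate_cliques`, `group_gene_overlap`) — per-clique
   GC/length statistics with ANOVA + Tukey HSD, core/private gene classes,
   and the clique-level network (cliques collapsed to vertices, multi-clique
   plasmids kept as anchors, unassigned plasmids dropped).
8. **Synthetic data** (`simulate`, `prune_mobile_elements`) — planted-clique
   plasmid populations (mutated backbones, related-backbone chains, a shared
   mobile-element pool, chimeras, singletons) with exact truth tables, so
   the whole pipeline is testable without external data.

## Worked example

`examples/02_detect_and_validate_cliques.py` simulates a small population
(6 backbone cliques, 4 unrelated singletons, 1 chimera), builds the network
and recovers the cliques:

```
communities detected: 6; validated cliques (complete in the original network): 6; rejected: 0
  C001: 8 plasmids, internal JI 0.44
  C002: 7 plasmids, internal JI 0.41
  C003: 6 plasmids, internal JI 0.54
  C004: 5 plasmids, internal JI 0.40
  C005: 5 plasmids, internal JI 0.49
  C006: 4 plasmids, internal JI 0.49
agreement with planted cliques (NMI over 32 plasmids): 0.981
multi-assigned plasmids (chimera candidates): ['c01_p03', 'chimera00']
```

Every detected community is a genuine clique of the original network; the
NMI of 0.981 against the planted labels means the recovered cliques almost
exactly reproduce the simulated backbone groups, and the planted chimera is
assigned to both of its parent cliques. The other examples cover the
similarity network itself (`01`), threshold optimization (`03`) and clique
characterization — typing concordance, GC statistics, gene classes and the
clique-level network (`04`).

## Layout

```
src/plasmidnet/
  sequences.py     records, FASTA/metadata I/O, canonical k-mers, GC
  network.py       exact pairwise JI, thresholded networks, edge-list TSV
  detect.py        community detection, clique validation, Bron–Kerbosch
  sweep.py         threshold sweep and selection policy
  metrics.py       NMI, purity, host purity
  characterize.py  GC/length statistics, Tukey HSD, gene classes, clique network
  simulate.py      planted-structure generator and mobile-element pruning
examples/          narrative scripts, one per capability
docs/methods.md    model, assumptions, parameter choices, limitations
```
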