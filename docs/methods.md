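# Methods

This note documents the models and procedures implemented in `plasmidnet`,
the parameter choices that matter, what the synthetic generator does and
does not emulate, and the numerical decisions taken where the design was
genuinely open.

## Sequence similarity

Each plasmid is decomposed into the set of its canonical 21-mers: every
window over {A, C, G, T} is replaced by the lexicographic minimum of itself
and its reverse complement, so both strands of a molecule yield the same
set. Windows containing ambiguity codes are skipped, and sequences are
treated as linear — no windows span the circular origin (the omission costs
at most k−1 k-mers per plasmid). Canonicalization is the default because
plasmids are double-stranded and deposited sequences have arbitrary strand
orientation; a flag disables it.

Similarity is the exact Jaccard index |A∩B|/|A∪B| over full k-mer sets —
never a MinHash or other sketch, so downstream thresholds act on exact
values. Pairs sharing fewer than `min_shared = 100` k-mers are treated as
JI = 0 and are not stored: 100 consecutive 21-mers correspond to ~120 bp of
identical sequence, below a typical gene, so such pairs carry no usable
homology signal. The cutoff is configurable because kilobase-scale test
data would otherwise be edgeless; the generator's manifest records the
value appropriate to its backbone scale (100 for backbones ≥ 5 kb,
proportionally smaller below).

The similarity matrix is stored as a sparse upper-triangle map keyed by
index pairs. Networks are materialized at a JI threshold t by keeping edges
with JI ≥ t (inclusive, so ties at the threshold survive); t = 0 gives the
"original" network used for clique validation.

## Community detection

The detector is an ordered-statistics local-optimization scheme. The null
model is the configuration model: networks rewired at random while
preserving every vertex's degree. For a candidate vertex of degree `k_v`
and a cluster C, the number of the candidate's edges landing in C is
modelled as Binomial(k_v, p), and the score is the upper tail at the
observed internal degree.

Two variants of `p` are used:

* The **public null** (`vertex_significance`) takes `p = K_C / M`, with
  `K_C` the summed degree of the cluster's members and `M` the number of
  edge endpoints (2×edges). This is the plain stub-counting argument and is
  the surface used for calibration checks (on degree-preserving rewirings
  its scores are stochastically no smaller than uniform).
* The **detector's internal kernel** takes `p = (K_C − 2·E_in(C)) / M`,
  counting only the cluster's *free* stubs — endpoints not already consumed
  by its internal edges. The plain form degenerates on small or dense
  graphs: a cluster holding most of a component's endpoints drives `p`
  toward 1, making even a perfect clique "insignificant" (a lone K6 scores
  1 for every member). Conditioning on the internally consumed stubs keeps
  the null informative at every scale while remaining a binomial stub-model
  tail. This choice is what lets an isolated clique, or two cliques joined
  by a single bridge edge, be recovered exactly.

Scores are corrected for selection: a candidate ranked r-th best among m
neighbours is admitted only if Beta(r, m−r+1) evaluated at its raw score —
for the best candidate, 1−(1−s)^m — clears the significance level
(`p_threshold = 0.05`).

One run proceeds by seeding a cluster at each uncovered vertex (in a
seeded-random order), then alternating growth (admit the lowest-scoring
external neighbour while it passes the corrected test) and cleanup (expel
the worst-scoring member while it fails the same test) until a fixed point
or revisited state. Binomial tails cannot clear any sensible level for
clusters of one or two vertices, so growth is greedy below
`bootstrap_size = 6` members and relies on cleanup to dismantle false
starts; on noise graphs this leaves essentially no surviving clusters. A
cluster's p-value is its worst member's corrected leave-one-out score at
the fixed point.

Runs are repeated `n_runs` times (50 is adequate for threshold sweeps, 250
for a final analysis; tests and examples use ~10 because the planted
structure is far cleaner than real data). Clusters are matched across runs
by member-overlap Jaccard ≥ 0.5; clusters recurring in at least
`consensus_fraction = 0.5` of runs are reported, taking the modal member
set of each recurrence group. Of two strongly overlapping survivors only
the more significant is kept (ties break toward larger size, then smallest
member id); mildly overlapping communities — e.g. two cliques sharing one
chimeric plasmid — are both kept, which is what produces multi-clique
assignments. Everything is deterministic given the seed; ties anywhere
resolve lexicographically.

Detection runs on the thresholded network, but **completeness is judged on
the original network**: a community of size ≥ 3 becomes a clique only if
every member pair shares at least the k-mer cutoff. Validation failures are
recorded with their missing-pair counts. Exact maximal-clique enumeration
(Bron–Kerbosch with pivoting, via networkx) is available as the comparison
method; it treats similarity as binary and typically produces many more,
heavily overlapping cliques.

## Threshold sweep and selection

A grid of thresholds (default 0.05–0.6 in steps of 0.05) is evaluated with
several detector seeds (default 1, 5, 42, 93, 212). Per threshold and seed:
the number of communities (size ≥ 3), validated cliques, their ratio, the
percentage of all plasmids covered by cliques (denominator includes
singletons), and NMI against replicon typing in two variants — "all types"
(multi-typed plasmids get composite labels) and "single types" (multi-typed
plasmids dropped). Metrics that cannot be computed are reported missing,
never as zero. Cross-seed sample standard deviations quantify detector
consistency.

The default selection policy operationalizes a joint reading of the four
criteria: among thresholds whose clique/community ratio is within one SD of
the maximum and whose coverage is within one SD of the coverage at the
ratio-maximizing threshold, pick the one maximizing single-type NMI, tie
toward the smaller threshold. The policy is a replaceable callable, and the
sweep table is returned in full so a human can override the choice.

## Concordance metrics

NMI is computed from the contingency table of two flat labelings in natural
log, normalized by the arithmetic mean of the two Shannon entropies; items
missing from either labeling are excluded first, and two single-class
labelings (both entropies zero) score 1 by construction. Multi-label items
(multiple replicon types, multiple clique assignments) are flattened to
sorted composite labels, or dropped in single-label mode.

Purity sums, over cliques containing at least one typed plasmid, the size
of the best-represented type, divided by the number of retained
(plasmid, clique) assignments — a plasmid in two cliques is counted in
both, so each clique's contribution is self-contained. Untyped members of
assessed cliques are disregarded. Host purity is the same formula with
taxon labels at a chosen rank; plasmids lacking that rank count as untyped.

## Clique characterization

Numeric properties (GC, length) get per-clique means and sample SDs
(n−1 denominator). Differences across cliques are tested with one-way
fixed-effects ANOVA followed by Tukey's HSD over all clique pairs, using
the studentized-range distribution with the Tukey–Kramer unequal-n
adjustment (statsmodels implementation); the headline statistic is the
fraction of clique pairs with adjusted p below 0.001. Zero within-group
variance everywhere is reported as an error, not patched.

Gene content is an input contract (plasmid × gene 0/1 table); annotation is
out of scope. Genes occurring at least `min_occurrence = 5` times are
assessed: a gene is *core* if its within-clique frequency is one in at
least one clique where it occurs, and *private* if it occurs in exactly one
clique, is core there, and occurs nowhere outside cliques.

The clique-level network collapses each clique to a vertex (size, internal
JI, modal host genus), keeps multi-clique plasmids as solitary anchor
vertices, and drops unassigned plasmids. Clique–clique edges carry the mean
JI over *all* cross-pairs of members — zero pairs included, which damps
spurious single-edge links — and the count of cross-pairs with any stored
similarity; edges at or below the display threshold (default 0.01) are
dropped, zero keeps the unfiltered network. Anchor plasmids are excluded
from cross-pair averages between the cliques they anchor (their self-
similarity would inflate the link) and their membership edges are always
retained.

## Synthetic data

The generator plants the structures the pipeline is meant to find. Each
clique has a backbone: an i.i.d. random sequence at the clique's GC target
(targets spread evenly over 0.35–0.65). Members substitute each site
independently with probability μ = 0.01, drawing the replacement from the
target composition — the composition is therefore exactly stationary, and
with c_b the composition probabilities the effective base-change rate is
μ_eff = μ(1 − Σ c_b²). Two members then share a fraction
s = (1 − μ_eff)^(2k) of windows in expectation, giving within-clique
JI ≈ s/(2 − s) ≈ 0.55–0.6 at the defaults.

Weak between-clique structure comes from two chains of three cliques whose
backbones derive from a common lineage at divergence 0.18 per site per
step: adjacent cliques in a chain share JI ≈ 0.02 (well below any sensible
working threshold but above the shared-k-mer cutoff), while chain ends
share fewer k-mers than the cutoff and are unconnected. This is what makes
the unthresholded network merge related cliques into communities that fail
the completeness check, so that sparsification demonstrably improves the
clique/community ratio.

A pool of 6 mobile elements (500–1000 bp, neutral GC) is inserted into each
member with probability 0.1 per element, at uniform positions never inside
another insert; private accessory segments (at the clique's GC) are added
with probability 0.3. Each insert is recorded as a gene and with its exact
coordinates, so `prune_mobile_elements` can excise every element and the
pruning-robustness experiment can compare assignments before and after.
Chimeras concatenate half-backbones of two cliques from different lineages
(JI ≈ 0.2 to both parent cliques); singletons are unrelated random
sequences. Host taxonomy is a nested synthetic hierarchy (genus unique per
clique), replicon labels are per-clique with one chain sharing a label (one
incompatibility group split over related cliques), and MOB labels cycle
through six types.

What the generator does **not** emulate: recombination within backbones,
insertion-site preference, sequencing error, circular rotations, and the
heavy host-sampling biases of public databases. Passing tests therefore
show that the pipeline recovers clean planted structure at realistic scale
and noise — not that real RefSeq-scale collections would yield any
particular clique count or concordance value.

## Problem sizes and numerical choices

Tests and the acceptance checks run the full pipeline on the generator
defaults (≈ 112 plasmids of 20–50 kb, ≈ 3·10⁶ k-mers) with 10 detector runs
per sweep point and a 12-point threshold grid — sizes chosen so the entire
suite completes in a couple of minutes on one CPU while keeping every
planted feature (chains, chimeras, singletons, elements) at realistic
sequence scale. Unit tests use a kilobase-scale variant with the
shared-k-mer cutoff scaled accordingly.

Degenerate inputs are errors, not silent defaults: GC of a sequence with no
ACGT symbols, density of a one-vertex network, internal similarity of a
singleton, purity with no typed plasmid, ANOVA with zero variance
everywhere, NMI over an empty common item set. k is limited to 31 by the
packed 2-bit integer representation used for window extraction.

## Known limitations

* The detector is faithful to the *idea* of ordered-statistics local
  optimization, not to any reference binary; only one hierarchy level is
  implemented, and cluster merging is deliberately absent (the most
  significant of strongly overlapping clusters wins).
* The free-stub null is an approximation: it conditions on the cluster's
  internal edge count but still treats stubs as independent.
* NMI on overlapping assignments uses composite labels, which penalizes
  overlaps more than an overlap-aware NMI would.
* The mean cross-clique JI in the aggregated network averages over all
  pairs; sparse strong links between large cliques are therefore damped by
  design.
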