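"""Optimize the sparsification threshold against the four sweep criteria.

Evaluates a grid of JI thresholds with several detector seeds, printing the
clique-to-community ratio, clique coverage and replicon-typing concordance
(NMI) per threshold, then applies the default selection policy.
"""

import plasmidnet as pn

config = pn.SimulationConfig(
    n_cliques=6, clique_size_range=(4, 7),
    backbone_length_range=(3_000, 5_000),
    n_elements=4, element_length_range=(200, 400),
    n_singletons=4, singleton_length_range=(1_000, 2_000),
    n_chimeras=1, seed=11,
)
dataset = pn.simulate(config)
kmersets = [pn.extract_kmers(r) for r in dataset.records]
matrix = pn.pairwise_jaccard(kmersets, min_shared=dataset.manifest["min_shared"])
original = pn.build_network(matrix, 0.0)

sweep = pn.sweep_thresholds(
    matrix, original,
    thresholds=[0.05, 0.1, 0.2, 0.3, 0.4, 0.5],
    records=dataset.records,
    seeds=(1, 5, 42),
    config=pn.DetectionConfig(n_runs=8),
)

print("thr   ratio   %in-cliques   NMI(single)")
for point in sweep:
    ratio = point.mean["clique_community_ratio"]
    pct = point.mean["pct_plasmids_in_cliques"]
    nmi = point.mean["nmi_single_types"]
    fmt = lambda v: "  n/a" if v is None else f"{v:5.2f}"
    print(f"{point.threshold:4.2f}  {fmt(ratio)}   {fmt(pct)}        {fmt(nmi)}")

selected = pn.select_threshold(sweep)
print(f"selected working threshold: {selected}")
# The ratio and NMI stay maximal across the band between the planted
# between-group (~0.02) and within-group (~0.55) similarity; the policy
# breaks ties toward the smallest threshold in that band.
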