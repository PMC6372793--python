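"""Pairwise differential expression and response-group clustering.

Compares sulfate-stimulated substrate treatments at day 36 with a
negative-binomial moment/Wald test on size-factor-normalized counts,
then clusters the significant genes into response groups by
1 - Pearson correlation distance of variance-stabilized counts.
"""

from itertools import combinations

import pandas as pd

import zerogrowth as zg

# simulate the day-36 sulfate-stimulated stratum
catalog = zg.generate_gene_catalog(n_genes=1000, seed=200)
design = zg.default_design(sulfates=("plusS",), days=(36,))
params = zg.SimulationParams(n_genes=1000, dispersion=0.1, seed=201)
cm = zg.simulate_counts(catalog, design, params)

size_factors = zg.median_ratio_size_factors(cm.counts)
print("size factors:")
print(size_factors.round(3).to_string())

# pairwise DE between all substrate groups
groups = {s: list(g["sample_id"]) for s, g in cm.design.groupby("substrate")}
significant = set()
for a, b in combinations(sorted(groups), 2):
    res = zg.nb_moment_de(cm.counts, size_factors, groups[a], groups[b])
    n_sig = int((res["p_adj"] < 0.05).sum())
    significant |= set(res.loc[res["p_adj"] < 0.05, "gene_id"])
    print(f"{a:>10} vs {b:<10} {n_sig:4d} genes at FDR < 0.05")

print(f"\nunion of significant genes: {len(significant)}")

# response-group clustering of the significant genes
vst = zg.variance_stabilize(cm.counts, size_factors)
profiles = vst.loc[sorted(significant)]
profiles = profiles[profiles.apply(lambda r: r.max() > r.min(), axis=1)]
dist = zg.pearson_distance(profiles)
dendro = zg.hierarchical_cluster(dist, linkage="average")
clusters = zg.cut_clusters(dendro, k=4)
print("\nresponse groups (k = 4):")
print(clusters.groupby("cluster_id").size().rename("n_genes").to_string())

# category makeup of each response group
merged = clusters.merge(catalog[["gene_id", "category"]], on="gene_id")
print("\ndominant category per response group:")
print(merged.groupby("cluster_id")["category"]
      .agg(lambda s: s.value_counts().idxmax()).to_string())
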