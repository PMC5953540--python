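"""Discover a phenotype-linked gene cluster in a simulated strain collection.

Simulates 24 strains (8 digoxin metabolizers carrying a planted 8-gene
cluster), clusters proteins into ortholog groups, builds the
presence/absence matrix, collapses co-occurring columns and ranks features
by random-forest Gini importance.
"""

from cgrmap.pangenome import build_matrix, cluster_orthologs
from cgrmap.simulate import PangenomeSimConfig, simulate_pangenome
from cgrmap.trait_mapping import collapse_features, rf_gini_importance

ds = simulate_pangenome(PangenomeSimConfig(seed=7))
clusters = cluster_orthologs(ds.genes)
matrix = build_matrix(clusters, sorted(ds.genomes))
collapsed, groups = collapse_features(matrix)
table = rf_gini_importance(collapsed, ds.truth.phenotype_labels, seed=7,
                           group_map=groups)

top = table.iloc[0]
print(f"clusters: {len(clusters)}  ({matrix.class_counts()})")
print(f"top feature: {top['feature']}  rank={top['rank']}  "
      f"gini={top['mean_decrease_gini']:.4f}  "
      f"perfect={bool(top['perfect_discriminator'])}  "
      f"fisher_p={top['fisher_p']:.2e}")
print(f"genes in that feature: {len(top['member_clusters'].split(','))}")
# The top-ranked feature is a perfect discriminator holding the whole
# planted cluster: presence of these co-occurring genes exactly separates
# metabolizers from non-metabolizers, with the smallest Fisher p the
# 8/16 design allows.
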