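"""Classic marker statistics vs the tree-based dispersity index.

Computes per-marker PIC and exclusion probability from the parental
allele frequencies, the cumulative PE of a marker set, and the
Spearman correlation between those single-marker summaries and the
pair-aware PDI.
"""

from pmskit import (
    SimConfig,
    cpe,
    enumerate_parent_pairs,
    indicator_correlations,
    marker_stats,
    offspring_sets,
    simulate_pool,
)

sim = simulate_pool(SimConfig(n_markers=50, seed=21))
pairs = enumerate_parent_pairs(sim.pool, sex_mode="known")
sets = offspring_sets(sim.matrix, pairs, sim.panel)

stats = marker_stats(sim.matrix, sim.panel)
print("first five markers:")
print(stats.head().round(4))

subset = list(stats.index[:5])
print(f"\nCPE of {subset}: {cpe(stats.loc[subset, 'pe']):.4f}")

corr = indicator_correlations(sim.panel, sim.matrix, pairs, sets=sets)
print("\nSpearman correlations across the panel:")
print(corr.round(4))

# PIC and PE rank markers almost identically (both are frequency
# summaries); PDI ranks in the opposite direction (lower = better) and
# only partially agrees, because it scores a marker by how it splits
# the actual candidate pairs rather than a hypothetical population.
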