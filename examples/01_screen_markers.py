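"""Screen a small candidate pool for its minimal parentage marker set.

Builds a 3-sire x 2-dam pool genotyped at 30 multiallelic markers,
runs the recommended workflow (greedy screen, then exhaustive
de-redundancy, then backup-marker collection) and prints the result.
"""

from pmskit import (
    SimConfig,
    enumerate_parent_pairs,
    offspring_sets,
    recommended_screen,
    simulate_pool,
)

sim = simulate_pool(SimConfig(n_markers=30, seed=11))
pairs = enumerate_parent_pairs(sim.pool, sex_mode="known")
sets = offspring_sets(sim.matrix, pairs, sim.panel)

rec = recommended_screen(sim.panel, pairs, sets)

print(f"candidate parents : {', '.join(sim.pool.parent_ids)}")
print(f"candidate pairs   : {len(pairs)} (every sire x dam family)")
print(f"panel size        : {len(sim.panel)} markers")
print(f"base PMS          : {list(rec.base_pms.marker_ids)}")
print(f"redundancy set    : {rec.redundancy_set}")

# The base PMS is the smallest marker subset whose simulated offspring
# genotypes identify every family uniquely; the redundancy set holds
# up to 2x|base| backup markers from alternative PMSs, to be added when
# genotyping errors or dropouts are expected.
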