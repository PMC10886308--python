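# pmskit

Minimal and low-redundancy **parentage marker set** screening for
closed diploid populations with fully genotyped candidate parents.

## The problem

In aquaculture and livestock breeding, dozens of full-sib families are
raised together and pedigree must be recovered from marker genotypes.
When every candidate parent is genotyped (a *closed population*, e.g.
an NCII factorial cross), all offspring genotypes a family can produce
are enumerable under Mendel's law of segregation: a pair with
genotypes {G_i1,G_i2} × {G_j1,G_j2} yields the set
{{G_i1,G_j1},{G_i1,G_j2},{G_i2,G_j1},{G_i2,G_j2}} (1–4 distinct
genotypes) at each marker.  A **parentage marker set (PMS)** is a
marker subset on which no two candidate pairs can produce a common
offspring genotype vector — every offspring then traces back to a
unique family.  Genotyping cost scales with panel size, so the goal is
the *smallest* such subset, plus a few backup markers for robustness.

pmskit implements:

* an **exhaustive screen** that traverses marker combinations in
  ascending size and emits all non-redundant PMSs (first = global
  minimum), or an unsolvability report naming the indistinguishable
  parent pairs;
* a **greedy multiway-tree screen** for large panels, selecting at
  each layer the marker with the lowest **Parental Dispersity Index**
  (PDI = mean + population SD of parent-pair counts over the non-leaf,
  deduplicated child nodes; 0 when the marker resolves everything);
* the **recommended workflow**: greedy screen → exhaustive
  de-redundancy → backup-marker collection (≤ 2× the base PMS size),
  and PMS **merging** into low-redundancy panels that tolerate
  genotyping errors and dropouts;
* classical statistics (PIC, exclusion probabilities PE/CPE) as
  comparison indicators and report columns;
* a seed-deterministic **synthetic-population generator** and
  experiment harness (random-group sampling, solution classification,
  error injection);
* a genotype-table reader/writer (TSV/CSV, `allele1/allele2` cells), a
  biallelic VCF importer, and a thin `pmskit` command-line interface.

## Worked example

```python
from pmskit import (SimConfig, simulate_pool, enumerate_parent_pairs,
                    offspring_sets, recommended_screen)

sim = simulate_pool(SimConfig(n_markers=30, seed=11))   # 3 sires x 2 dams
pairs = enumerate_parent_pairs(sim.pool, sex_mode="known")
sets = offspring_sets(sim.matrix, pairs, sim.panel)
rec = recommended_screen(sim.panel, pairs, sets)
print(rec.base_pms.marker_ids, rec.redundancy_set)
```

prints

```
('M003', 'M001') ['M018', 'M014', 'M002', 'M023']
```

two markers suffice to separate all six sire×dam families of this
simulated pool, and four independent backups are recommended for a
low-redundancy panel.  The narrated scripts in `examples/` go further;
`examples/02_exhaustive_vs_greedy.py` prints, for 200 random 10-marker
groups of a simulated 225-marker panel:

```
groups sampled           : 200
resoluble (solvable)     : 123 (61.5%)
greedy optimal rate      : 93.50%
optimal or redundant     : 97.56%
mean minimum PMS size    : 2.56
mean greedy PMS size     : 2.63
```

i.e. the greedy screen finds a true minimum PMS in >90% of solvable
groups, and almost all remaining cases are merely redundant (fixable
by the exhaustive de-redundancy step).  `examples/04_error_robustness.py`
shows why panels are merged: with one allelic error per offspring,
recovery climbs from 63% (base PMS alone) to 91% (merged panel).

## Command line

```sh
pmskit simulate --n-markers 50 --seed 7 --out parents.tsv
pmskit screen parents.tsv --algorithm recommended --out report.json
pmskit metrics parents.tsv --correlations
pmskit assign parents.tsv offspring.tsv --markers M003,M001 --max-mismatch 1
```

`screen` exits 0 when a PMS is found, 3 on a correctly detected
unsolvable instance (the report then lists the indistinguishable
pairs), 2 on input errors.

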