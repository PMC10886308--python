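# Methods

## Problem setting

pmskit addresses parentage assignment in *closed* diploid populations:
every candidate parent is genotyped, and the true parents of any
offspring are guaranteed to be among the candidates.  This is the
situation of factorial (NCII) mating designs in aquaculture and
livestock breeding, where dozens of full-sib families are reared in a
common environment and pedigree must be recovered from genotypes.
Because the parental genotypes are complete, *all* offspring genotypes
a family can produce are enumerable in advance, and marker selection
can be posed combinatorially rather than probabilistically.

For a marker m, a parent pair with genotypes {G_i1, G_i2} and
{G_j1, G_j2} produces the offspring genotype set

    G_ij,m = { {G_i1,G_j1}, {G_i1,G_j2}, {G_i2,G_j1}, {G_i2,G_j2} }

(deduplicated; 1 ≤ |G_ij,m| ≤ 4).  Two candidate pairs are
**confusable** on a marker set M when some offspring genotype vector is
producible by both.  Since markers segregate independently here, the
product of per-marker sets intersects iff every per-marker factor
intersects, so confusability is checked per marker in O(|M|); the
equivalence is asserted against a brute-force vector-enumeration oracle
in the test suite.  A **parentage marker set (PMS)** is a marker subset
on which no two candidate pairs are confusable; a PMS is
**non-redundant** when no proper subset is a PMS, and **minimum** when
its size is globally smallest.

Candidate pairs are every sire × dam combination when sexes are known,
or every unordered pair of distinct parents when they are not (selfing
pairs are off by default and available behind a flag for
hermaphroditic species).  Missing parental genotypes are a hard error
for screening: offspring sets of an ungenotyped parent are undefined,
and silently dropping markers would change the optimization problem.

## Exhaustive screen

Marker combinations are traversed in ascending size, within a size in
lexicographic panel order.  A combination is emitted iff it is a PMS
and contains no previously emitted PMS; the superset filter makes
every emission non-redundant, and the first emission is a minimum PMS.
By default the traversal stops after finishing the first size that
produced a solution (all minimum PMSs are then already enumerated); a
flag continues to larger sizes, in which case the output is exactly
the set of all non-redundant PMSs (verified against a subset-lattice
oracle on small instances).  If the traversal up to the full panel
size finds nothing, the instance is unsolvable and the report lists
every pair of candidate pairs confusable on the entire panel — the
maximal-information case, which directly indicates which families need
new markers.  A search budget below the full panel size that finds
nothing raises a partial-result error instead of claiming
unsolvability.

The work is Σ C(n,i) combinations in the worst case, so the exhaustive
screen is intended for panels up to roughly 20 markers, or for
de-redundancy of an already small greedy solution (`minimal_subset`,
which restricts the traversal to subsets of a given working set).

## Greedy multiway-tree screen and the PDI

The greedy screen builds a tree whose root node holds all candidate
pairs.  Genotyping the population at a marker splits each node: every
observable offspring genotype g induces the child node of pairs whose
offspring set contains g.  Single-pair nodes are leaves (resolved
families); duplicated child nodes — identical pair sets — are merged
across the whole layer, since they present identical residual
subproblems.  Screening terminates when only leaves remain; the
selected markers then form a PMS (termination ⇔ no confusable pair
remains, asserted on random instances).

The **Parental Dispersity Index** of marker m on the current layer is

    PDI_m = mean_m + SD_m

where mean and SD are taken over the pair counts of the child branch
nodes after removing leaves and duplicates, and SD is the *population*
standard deviation (denominator T, not T−1).  An empty remainder — the
marker resolves everything still open — scores 0, the minimum.  Lower
PDI rewards markers that resolve many pairs outright and split the
remainder evenly.

Each round evaluates every unused, progress-making marker and selects
the minimum-PDI one.  Two numerical choices matter and were genuinely
open:

* **Progress** means the residual *branch* layer changes.  Leaf
  children of a node that itself survives intact are not progress: the
  pair is still confusable inside the surviving node, and counting
  such markers as candidates lets them tie on PDI and be selected
  without resolving anything, inflating the PMS badly.
* **Ties** on PDI are broken toward the marker leaving the fewest
  residual confusable pair-of-pairs (Σ C(n_i, 2) over child branch
  nodes), then by panel order.  The secondary key exists because
  mean+SD is invariant to the *number* of equal-sized branch nodes: a
  marker that resolves two of three size-2 nodes (remainder {2}) ties
  with one that resolves a single node (remainder {2,2}), yet leaves
  half the work.  On simulated benchmark ensembles this tie rule is
  what keeps the greedy optimal-solution rate above 90%; with plain
  panel-order ties it drops to ~84%.  A seeded random tie break is
  available behind a flag for ensemble studies.

Since each round consumes one marker, at most |PMS| rounds of at most
n evaluations occur (O(M·N·p) overall); the evaluation counter is
exposed on the result and asserted in tests.  If branch nodes survive
and no unused marker makes progress, the instance is unsolvable and
the report lists the pairs confusable on the full panel — identical to
the exhaustive report, because full-panel-confusable pairs necessarily
co-occupy a surviving branch node.

For comparison studies the selection score can be swapped for PIC or
PE (maximized, still restricted to progress-making markers so
termination is preserved).  These single-marker scores ignore marker
interaction and produce substantially larger PMSs, which is the point
of the comparison.

## Recommended workflow and low-redundancy PMSs

The default recipe is: greedy screen → exhaustive de-redundancy of the
greedy PMS (`minimal_subset`) → collection of backup markers.  Backups
come from alternative PMSs obtained by excluding the base PMS (and
then each earlier alternative) from the panel and re-screening; by
default the alternatives are therefore mutually disjoint and maximally
independent, and the backup list is truncated at twice the base PMS
size.  A `subset` exclusion mode that drops one base marker at a time
produces overlapping alternatives instead.

Merging two PMSs (set union, order-preserving) yields a
**low-redundancy PMS**: a few extra markers in exchange for tolerance
of genotyping error and missingness.  Monotonicity guarantees the
union still works.

The built-in assigner is deliberately exact Mendelian compatibility
with a mismatch budget, not a likelihood model: a candidate pair is
compatible at a marker when the offspring genotype lies in its
offspring set; pairs with at most `max_mismatch` incompatible typed
markers are ranked by mismatch count.  Its role is internal validation
of screened panels (error-free offspring on a working PMS match
exactly their true pair, by construction), not a replacement for
full-featured assignment software.

## Marker statistics

PIC uses the Botstein form, PIC = 1 − Σp_i² − Σ_{i<j} 2p_i²p_j².  PE
is computed in two modes from first principles by conditioning on the
offspring genotype under Hardy–Weinberg proportions: `single` excludes
a random individual that shares no allele with the offspring; `pair`
excludes a random pair that cannot produce the offspring genotype
(using carrier probabilities c_a = 1 − (1−p_a)²).  These closed forms
are algebraically the standard one-parent and parent-pair exclusion
probabilities and are verified in tests against an exact enumeration
oracle (1e-9) and a 10⁶-replicate Monte-Carlo simulation (0.01).
CPE = 1 − Π(1 − PE_i) treats markers as independent — exactly the
approximation the tree-based screen avoids, which is why a small PMS
can assign perfectly while its CPE looks unimpressive.  Allele
frequencies are estimated from the candidate-parent pool itself, the
only genotyped generation in a closed population.  The formula
variants are recorded in every report; published tables computed with
other variants are not expected to match bit-for-bit.

## Synthetic data

`simulate_pool` emulates the benchmark study conditions by default:
3 sires × 2 dams (NCII, six families), 225 markers, 4–8 alleles per
marker drawn uniformly, Dirichlet(1) allele-frequency spectra, and
Hardy–Weinberg genotype sampling.  SNP-style panels use
`alleles_per_marker=2`.  The generator is seed-deterministic and
returns its true frequency spectra for convergence checks.

What it does *not* emulate: linkage between markers, null alleles,
mutation, population structure and genotyping-platform artifacts.
Passing ensemble tests therefore demonstrate algorithmic correctness
and the relative behavior of indicators under idealized Mendelian
sampling, not performance guarantees on any particular real panel —
real marker sets have lower effective diversity and correlated
information content, which chiefly lowers the fraction of resoluble
marker groups.

The error model is single-allele substitution (one allele of a typed
genotype replaced by a different allele drawn uniformly from the
marker's alphabet), with independent per-cell missingness that deletes
the genotype; `n_errors` forces an exact error count for controlled
trials.  All perturbations are logged.

`random_sampling_experiment` draws many random marker groups, screens
each exhaustively (gold standard) and greedily, and classifies the
greedy solution: **optimal** (a minimum PMS), **redundant** (strictly
contains a non-redundant PMS, detected via `minimal_subset`),
**intersection** (shares a marker with some minimum PMS), **other** —
with precedence in that order, since the categories are not inherently
disjoint.  `planted_panel` rejection-samples a pool whose first k
markers are guaranteed to form a PMS, for recovery experiments with
known ground truth.

## Problem sizes used in the shipped experiments

The test-suite and acceptance-script ensembles use 500 random
oracle-checked instances (3–8 markers, 6 candidate pairs), 1000 random
10-marker groups for rate estimates, 250 groups for the
indicator-comparison means and 1000 offspring trials for the
error-robustness comparison.  These sizes give stable two-digit rates
under the fixed seeds while the whole suite runs in well under a
minute; all of them are plain parameters of the experiment functions.

## Known limitations

* Diploid, biparental, closed populations only; no likelihoods, no
  mutation or null-allele model, no polyploidy.
* The exhaustive screen is exponential by design (reference
  semantics); no branch-and-bound acceleration is attempted.
* The greedy screen is a local optimizer: on adversarial instances it
  can exceed the minimum size even with de-redundancy (it is then
  still non-redundant, just not minimum).
* `pairs_confusable`'s per-marker factorization assumes unlinked
  markers; tightly linked loci should be collapsed into a single
  multiallelic locus (e.g. a microhaplotype) before screening.
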