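"""Shared fixtures and independent first-principles oracles.

The oracles never call package code: Mendelian sets are enumerated from
ordered transmissions, confusability by enumerating full offspring
genotype vectors (Cartesian product over markers), and minimum PMSs by
walking the whole subset lattice.  They are deliberately exponential —
usable only on the tiny instances the tests construct.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np
import pytest

from pmskit import (
    GenotypeMatrix,
    ParentPool,
    enumerate_parent_pairs,
    offspring_sets,
    parse_genotype,
)

# ---------------------------------------------------------------- oracles


def oracle_mendel(g1, g2):
    """Offspring genotypes by direct enumeration of the 4 ordered
    transmissions (one allele from each parent)."""
    out = set()
    for a in g1:
        for b in g2:
            out.add(tuple(sorted((a, b))))
    return out


def oracle_confusable(genos_a, genos_b, markers):
    """Vector-level confusability: exists a full offspring genotype
    vector producible by both pairs.

    ``genos_a`` / ``genos_b``: marker -> (parent genotype, parent genotype).
    """
    sets_a = {m: oracle_mendel(*genos_a[m]) for m in markers}
    sets_b = {m: oracle_mendel(*genos_b[m]) for m in markers}
    if not markers:
        return True
    for vector in product(*(sorted(sets_a[m]) for m in markers)):
        if all(v in sets_b[m] for m, v in zip(markers, vector)):
            return True
    return False


def oracle_marker_sets(matrix, pairs, markers):
    """marker -> pair -> offspring set, from raw genotypes."""
    table = {}
    for m in markers:
        table[m] = {
            pair: oracle_mendel(matrix.get(pair[0], m), matrix.get(pair[1], m))
            for pair in pairs
        }
    return table


def oracle_is_pms(subset, pairs, marker_sets):
    """Per-marker disjointness oracle (validated against the vector
    oracle separately): a subset works iff every pair-of-pairs has some
    marker in the subset with disjoint offspring sets."""
    for a, b in combinations(pairs, 2):
        if all(not marker_sets[m][a].isdisjoint(marker_sets[m][b]) for m in subset):
            return False
    return True


def oracle_lattice(matrix, pairs, markers):
    """Walk the whole subset lattice.

    Returns (min_size or None, list of all minimum working subsets,
    list of all non-redundant working subsets, confusable pair list on
    the full panel).
    """
    marker_sets = oracle_marker_sets(matrix, pairs, markers)
    working = []
    for size in range(1, len(markers) + 1):
        for combo in combinations(markers, size):
            if oracle_is_pms(combo, pairs, marker_sets):
                working.append(frozenset(combo))
    if not working:
        confusable = [
            (a, b)
            for a, b in combinations(sorted(pairs), 2)
            if all(
                not marker_sets[m][a].isdisjoint(marker_sets[m][b]) for m in markers
            )
        ]
        return None, [], [], confusable
    min_size = min(len(w) for w in working)
    minima = [w for w in working if len(w) == min_size]
    non_redundant = [
        w for w in working if not any(o < w for o in working)
    ]
    return min_size, minima, non_redundant, []


# ------------------------------------------------------------- builders


def make_matrix(rows):
    """Build pool/panel/matrix from {parent: {marker: 'A/B'}}."""
    parents = list(rows)
    markers = list(next(iter(rows.values())))
    entries = {
        (p, m): parse_genotype(rows[p][m]) for p in parents for m in markers
    }
    return GenotypeMatrix(parents, markers, entries)


def random_instance(rng, n_parents=4, n_markers=5, max_alleles=4):
    """Random small instance: matrix, panel, all-unordered pairs, sets."""
    parents = [f"p{i}" for i in range(1, n_parents + 1)]
    markers = [f"m{i}" for i in range(1, n_markers + 1)]
    entries = {}
    for m in markers:
        k = int(rng.integers(2, max_alleles + 1))
        alphabet = [chr(ord("A") + i) for i in range(k)]
        for p in parents:
            a, b = rng.choice(alphabet, size=2)
            entries[(p, m)] = tuple(sorted((str(a), str(b))))
    matrix = GenotypeMatrix(parents, markers, entries)
    pool = ParentPool(tuple(parents), {p: "U" for p in parents})
    pairs = enumerate_parent_pairs(pool, sex_mode="unknown")
    sets = offspring_sets(matrix, pairs, markers)
    return matrix, markers, pairs, sets


@pytest.fixture
def rng():
    return np.random.default_rng(20240213)


@pytest.fixture
def toy_solvable():
    """5 parents (3M/2F), 3 markers; m2 alone separates all 6 families."""
    rows = {
        "s1": {"m1": "A/A", "m2": "A/A", "m3": "A/B"},
        "s2": {"m1": "A/A", "m2": "C/C", "m3": "A/B"},
        "s3": {"m1": "A/B", "m2": "E/E", "m3": "A/A"},
        "d1": {"m1": "A/A", "m2": "G/G", "m3": "B/B"},
        "d2": {"m1": "A/B", "m2": "J/J", "m3": "A/B"},
    }
    matrix = make_matrix(rows)
    pool = ParentPool(
        ("s1", "s2", "s3", "d1", "d2"),
        {"s1": "M", "s2": "M", "s3": "M", "d1": "F", "d2": "F"},
    )
    pairs = enumerate_parent_pairs(pool, sex_mode="known")
    sets = offspring_sets(matrix, pairs, matrix.marker_ids)
    return pool, matrix, list(matrix.marker_ids), pairs, sets
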