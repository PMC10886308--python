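"""Synthetic parent pools, offspring simulation and sampling experiments.

The generator emulates the closed NCII (factorial) mating designs of
aquaculture breeding: a small candidate pool (default 3 sires x 2 dams,
six full-sib families when sexes are known) genotyped at a large panel
of multiallelic markers (default 225 markers with 4-8 alleles each,
Dirichlet(1) frequency spectra, Hardy-Weinberg genotype sampling).
Those defaults model microhaplotype-style panels; SNP-style panels are
obtained with ``alleles_per_marker=2``.

Experiments mirror the random-sampling design used to benchmark the
greedy screen: many small marker groups are drawn from the panel, each
is screened exhaustively (gold standard) and greedily, and the greedy
solution is classified as optimal / redundant / intersection / other.

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    GenotypeMatrix,
    Genotype,
    InvalidInputError,
    OffspringSets,
    ParentPair,
    ParentPool,
    enumerate_parent_pairs,
    genotype,
    offspring_sets,
)
from .exhaustive import PMS, ScreenResult, SearchBudget, exhaustive_screen, minimal_subset
from .greedy import greedy_screen
from . import scheme

__all__ = [
    "SimConfig",
    "SimulatedPool",
    "simulate_pool",
    "simulate_offspring",
    "inject_problems",
    "random_sampling_experiment",
    "summarize_experiment",
    "classify_solution",
    "planted_panel",
    "SOLUTION_CLASSES",
]

SOLUTION_CLASSES = ("optimal", "redundant", "intersection", "other")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic pool.

    Defaults are the benchmark conditions: an NCII 3-sire x 2-dam pool
    and a 225-marker multiallelic panel with 4-8 alleles per marker and
    flat-Dirichlet frequency spectra.
    """

    n_sires: int = 3
    n_dams: int = 2
    n_markers: int = 225
    alleles_per_marker: tuple = (4, 8)  # inclusive range, or (k, k) for fixed k
    frequency_model: str = "dirichlet"  # "dirichlet" | "uniform"
    dirichlet_alpha: float = 1.0
    seed: int = 0

    def __post_init__(self):
        rng = self.alleles_per_marker
        if isinstance(rng, int):
            object.__setattr__(self, "alleles_per_marker", (rng, rng))
            rng = (rng, rng)
        lo, hi = rng
        if min(self.n_sires, self.n_dams, self.n_markers, lo) < 1 or hi < lo:
            raise InvalidInputError("all SimConfig counts must be positive, range ordered")
        if self.frequency_model not in ("dirichlet", "uniform"):
            raise InvalidInputError("frequency_model must be 'dirichlet' or 'uniform'")


@dataclass
class SimulatedPool:
    """Generator output: pool, panel, matrix and the true frequencies."""

    pool: ParentPool
    panel: list
    matrix: GenotypeMatrix
    frequencies: dict  # marker -> {allele: true generator frequency}
    config: SimConfig = field(repr=False, default=None)

    def __iter__(self):  # allow tuple-unpacking (pool, panel, matrix)
        return iter((self.pool, self.panel, self.matrix))


def _marker_alphabet(k: int) -> list:
    # A01, A02, ... keeps lexicographic and numeric order aligned.
    return [f"A{i:02d}" for i in range(1, k + 1)]


def simulate_pool(config: SimConfig = SimConfig()) -> SimulatedPool:
    """Draw a candidate-parent pool under Hardy-Weinberg sampling.

    Per marker, an allele count is drawn uniformly from the configured
    range and a frequency vector from the configured model; each parent
    then receives two independent allele draws (HWE pairing).
    """
    rng = np.random.default_rng(config.seed)
    sires = [f"S{i}" for i in range(1, config.n_sires + 1)]
    dams = [f"D{i}" for i in range(1, config.n_dams + 1)]
    pool = ParentPool(
        tuple(sires + dams),
        {**{s: "M" for s in sires}, **{d: "F" for d in dams}},
    )
    panel = [f"M{i:03d}" for i in range(1, config.n_markers + 1)]
    lo, hi = config.alleles_per_marker
    entries = {}
    freqs = {}
    for m in panel:
        k = int(rng.integers(lo, hi + 1))
        alphabet = _marker_alphabet(k)
        if config.frequency_model == "dirichlet":
            p = rng.dirichlet(np.full(k, config.dirichlet_alpha))
        else:
            p = np.full(k, 1.0 / k)
        freqs[m] = dict(zip(alphabet, p.tolist()))
        for parent in pool.parent_ids:
            a1, a2 = rng.choice(alphabet, size=2, p=p)
            entries[(parent, m)] = genotype(str(a1), str(a2))
    matrix = GenotypeMatrix(pool.parent_ids, panel, entries)
    return SimulatedPool(pool, panel, matrix, freqs, config)


def simulate_offspring(
    pair: ParentPair,
    matrix: GenotypeMatrix,
    panel: Sequence[str],
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> dict:
    """One Mendelian offspring: each parent transmits one random allele
    per marker."""
    if rng is None:
        rng = np.random.default_rng(seed)
    matrix.require_complete(panel)
    i, j = pair
    out = {}
    for m in panel:
        gi, gj = matrix.get(i, m), matrix.get(j, m)
        out[m] = genotype(gi[int(rng.integers(2))], gj[int(rng.integers(2))])
    return out


def inject_problems(
    genotypes: Mapping[str, Optional[Genotype]],
    alphabet: Mapping[str, Sequence[str]],
    error_rate: float = 0.0,
    missing_rate: float = 0.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    n_errors: Optional[int] = None,
):
    """Perturb an offspring genotype map with allelic errors and dropouts.

    Per typed cell, independently: with ``missing_rate`` the genotype
    is deleted (set to None); otherwise with ``error_rate`` one allele
    is replaced by a different allele drawn uniformly from the marker's
    alphabet (the single-allelic-error model).  ``n_errors`` instead
    forces exactly that many error cells (uniformly chosen), for
    controlled robustness trials.  Returns ``(perturbed, change_log)``;
    the log records every change as ``(marker, kind, before, after)``.
    """
    if not (0.0 <= error_rate <= 1.0 and 0.0 <= missing_rate <= 1.0):
        raise InvalidInputError("rates must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    out = dict(genotypes)
    log = []
    typed = [m for m, g in genotypes.items() if g is not None]

    def _flip(m):
        # replace one of the two alleles with a different allele
        g = out[m]
        slot = int(rng.integers(2))
        candidates = [a for a in alphabet[m] if a != g[slot]]
        if not candidates:  # monomorphic alphabet: no possible error
            return
        new_allele = str(candidates[int(rng.integers(len(candidates)))])
        new_g = genotype(new_allele, g[1 - slot])
        log.append((m, "error", g, new_g))
        out[m] = new_g

    if n_errors is not None:
        if n_errors > len(typed):
            raise InvalidInputError("n_errors exceeds typed marker count")
        for m in rng.choice(typed, size=n_errors, replace=False):
            _flip(str(m))
    else:
        for m in typed:
            if rng.random() < missing_rate:
                log.append((m, "missing", out[m], None))
                out[m] = None
            elif error_rate and rng.random() < error_rate:
                _flip(m)
    return out, log


def classify_solution(
    greedy_pms: PMS,
    exhaustive_result: ScreenResult,
    pairs: Sequence[ParentPair],
    sets: OffspringSets,
) -> str:
    """Label a greedy solution against the exhaustive gold standard.

    ``optimal``      — the greedy PMS is itself a minimum PMS;
    ``redundant``    — it strictly contains some non-redundant PMS;
    ``intersection`` — it shares at least one marker with some minimum
                       PMS (without being optimal or redundant);
    ``other``        — none of the above.  Precedence in that order.
    """
    if exhaustive_result.unsolvable:
        raise InvalidInputError("cannot classify a solution of an unsolvable instance")
    min_size = len(exhaustive_result.best)
    gset = greedy_pms.marker_set
    if len(greedy_pms) == min_size:
        return "optimal"
    core = minimal_subset(greedy_pms.marker_ids, pairs, sets)
    if core.marker_set < gset:
        return "redundant"
    optimal_sets = [p.marker_set for p in exhaustive_result.pms_list
                    if len(p) == min_size]
    if any(gset & s for s in optimal_sets):
        return "intersection"
    return "other"


def random_sampling_experiment(
    panel: Sequence[str],
    matrix: GenotypeMatrix,
    pairs: Sequence[ParentPair],
    n_groups: int = 1000,
    group_size: int = 10,
    seed: int = 0,
    sets: Optional[OffspringSets] = None,
    indicator: str = "pdi",
) -> pd.DataFrame:
    """Screen many random marker groups exhaustively and greedily.

    Each group of ``group_size`` markers drawn (without replacement)
    from the panel is screened by the exhaustive algorithm (all minimum
    PMSs enumerated) and by the greedy algorithm; solvable groups get a
    solution class.  Returns one row per group with sizes and class.
    """
    panel = list(panel)
    if group_size > len(panel):
        raise InvalidInputError("group_size exceeds panel size")
    if sets is None:
        sets = offspring_sets(matrix, pairs, panel)
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_groups):
        group = [str(m) for m in rng.choice(panel, size=group_size, replace=False)]
        group.sort(key=panel.index)
        ex = exhaustive_screen(group, pairs, sets, SearchBudget(max_pms=10_000))
        row = {
            "group": g,
            "markers": ",".join(group),
            "solvable": not ex.unsolvable,
            "min_size": len(ex.best) if not ex.unsolvable else None,
            "greedy_size": None,
            "solution_class": None,
        }
        if not ex.unsolvable:
            gr = greedy_screen(group, pairs, sets, indicator=indicator, matrix=matrix)
            row["greedy_size"] = len(gr.best)
            row["solution_class"] = classify_solution(gr.best, ex, pairs, sets)
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_experiment(table: pd.DataFrame) -> dict:
    """Aggregate rates over a sampling experiment table.

    Rates are over solvable (resoluble) groups, except the resoluble
    rate itself which is over all groups.
    """
    n = len(table)
    solvable = table[table["solvable"]]
    ns = len(solvable)
    counts = solvable["solution_class"].value_counts().to_dict() if ns else {}
    opt = counts.get("optimal", 0)
    red = counts.get("redundant", 0)
    return {
        "n_groups": n,
        "resoluble_count": ns,
        "resoluble_rate": ns / n if n else float("nan"),
        "optimal_rate": opt / ns if ns else float("nan"),
        "redundant_rate": red / ns if ns else float("nan"),
        "optimal_or_redundant_rate": (opt + red) / ns if ns else float("nan"),
        "intersection_count": counts.get("intersection", 0),
        "other_count": counts.get("other", 0),
        "mean_min_size": float(solvable["min_size"].mean()) if ns else float("nan"),
        "mean_greedy_size": float(solvable["greedy_size"].mean()) if ns else float("nan"),
    }


def planted_panel(
    config: SimConfig,
    planted_size: int,
    n_background: int,
    sex_mode: str = "known",
    max_tries: int = 1000,
) -> SimulatedPool:
    """Generate a pool whose first ``planted_size`` markers jointly form
    a PMS, followed by random background markers.

    Gives recovery experiments a known ground truth: marker columns are
    redrawn (rejection sampling) until the planted prefix separates all
    candidate pairs.
    """
    base_cfg = replace(config, n_markers=planted_size + n_background)
    for attempt in range(max_tries):
        sim = simulate_pool(replace(base_cfg, seed=(config.seed + attempt * 7919) % (2**31)))
        pairs = enumerate_parent_pairs(sim.pool, sex_mode=sex_mode)
        planted = sim.panel[:planted_size]
        sets = offspring_sets(sim.matrix, pairs, planted)
        from .core import is_pms

        if is_pms(planted, pairs, sets):
            return sim
    raise InvalidInputError(
        f"could not plant a size-{planted_size} solution in {max_tries} tries; "
        "increase planted_size or allele diversity"
    )
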