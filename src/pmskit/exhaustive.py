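"""Exhaustive marker-combination search for minimum parentage marker sets.

Traverses all marker combinations in ascending size (within a size, in
lexicographic order of panel position) and emits every combination that
distinguishes all candidate parent pairs and contains no previously
emitted solution.  The first emission is therefore a minimum PMS, and
every emission is non-redundant.  The total number of combinations of a
panel of n markers is ``sum(C(n, i) for i in 1..n)``, which bounds the
work counter the search reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

from .core import (
    InvalidInputError,
    OffspringSets,
    ParentPair,
    PmskitError,
    confusable_pair_list,
    is_pms,
)

__all__ = [
    "SearchBudget",
    "PMS",
    "ScreenResult",
    "BudgetExhaustedError",
    "exhaustive_screen",
    "minimal_subset",
]


@dataclass
class SearchBudget:
    """Caps on the combinatorial traversal.

    ``max_size`` limits combination sizes (default: the panel size);
    ``max_pms`` caps the number of emitted solutions; ``max_combinations``
    caps the number of subsets examined.
    """

    max_size: Optional[int] = None
    max_pms: int = 100
    max_combinations: Optional[int] = None

    def __post_init__(self):
        if self.max_size is not None and self.max_size < 1:
            raise InvalidInputError("max_size must be positive")
        if self.max_pms < 1:
            raise InvalidInputError("max_pms must be positive")
        if self.max_combinations is not None and self.max_combinations < 1:
            raise InvalidInputError("max_combinations must be positive")


@dataclass(frozen=True)
class PMS:
    """A parentage marker set with provenance flags.

    ``non_redundant`` — no proper subset is itself a PMS;
    ``minimal``       — size equals the global minimum over all subsets
                        of the panel it was screened from.
    """

    marker_ids: tuple
    source: str = "exhaustive"  # exhaustive | greedy | merged
    non_redundant: bool = False
    minimal: bool = False

    def __len__(self):
        return len(self.marker_ids)

    def __contains__(self, marker_id):
        return marker_id in self.marker_ids

    def __iter__(self):
        return iter(self.marker_ids)

    @property
    def marker_set(self) -> frozenset:
        return frozenset(self.marker_ids)


@dataclass
class ScreenResult:
    """Outcome of a screening run: solutions or an unsolvability report."""

    pms_list: list = field(default_factory=list)
    unsolvable: bool = False
    indistinguishable_pairs: list = field(default_factory=list)
    stats: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.unsolvable != (len(self.pms_list) == 0):
            raise InvalidInputError("unsolvable iff no PMS emitted")
        if self.unsolvable and not self.indistinguishable_pairs:
            raise InvalidInputError("unsolvability report must name confusable pairs")

    @property
    def best(self) -> Optional[PMS]:
        return self.pms_list[0] if self.pms_list else None


class BudgetExhaustedError(PmskitError):
    """Search budget ran out before the current size finished.

    Carries the partial progress: solutions emitted so far and the
    number of combinations examined.
    """

    def __init__(self, message: str, pms_list, combinations_examined: int):
        super().__init__(message)
        self.pms_list = list(pms_list)
        self.combinations_examined = combinations_examined


def exhaustive_screen(
    panel: Sequence[str],
    pairs: Sequence[ParentPair],
    sets: OffspringSets,
    budget: Optional[SearchBudget] = None,
    stop_after_first_size: bool = True,
) -> ScreenResult:
    """Enumerate non-redundant PMSs in ascending size order.

    By default the traversal stops after finishing the smallest size
    that produced at least one solution (the first emission is already
    the global minimum); ``stop_after_first_size=False`` continues up
    to ``budget.max_size`` (still skipping supersets of emitted
    solutions, so the output stays non-redundant).  If the full
    traversal up to size n finds nothing, the instance is unsolvable
    and the report lists every pair of parent pairs confusable on the
    entire panel.
    """
    panel = list(panel)
    if not pairs:
        raise InvalidInputError("need at least one candidate pair")
    budget = budget or SearchBudget()
    n = len(panel)
    max_size = n if budget.max_size is None else min(budget.max_size, n)

    if len(pairs) == 1:
        # A single candidate pair needs no marker at all.
        pms = PMS((), source="exhaustive", non_redundant=True, minimal=True)
        return ScreenResult([pms], stats={"combinations_examined": 0})

    emitted: list = []
    emitted_sets: list = []
    examined = 0
    for size in range(1, max_size + 1):
        found_at_size = False
        for combo in combinations(panel, size):
            examined += 1
            if budget.max_combinations is not None and examined > budget.max_combinations:
                raise BudgetExhaustedError(
                    f"combination budget ({budget.max_combinations}) exhausted at size {size}",
                    emitted,
                    examined - 1,
                )
            cset = frozenset(combo)
            # A superset of an emitted PMS works but is redundant: skip.
            if any(es <= cset for es in emitted_sets):
                continue
            if is_pms(combo, pairs, sets):
                emitted.append(
                    PMS(tuple(combo), source="exhaustive", non_redundant=True,
                        minimal=not emitted or len(emitted[0]) == size)
                )
                emitted_sets.append(cset)
                found_at_size = True
                if len(emitted) >= budget.max_pms:
                    return ScreenResult(emitted, stats={"combinations_examined": examined})
        if found_at_size and stop_after_first_size:
            break

    if emitted:
        return ScreenResult(emitted, stats={"combinations_examined": examined})
    if max_size < n:
        raise BudgetExhaustedError(
            f"no PMS found up to size cap {max_size} < panel size {n}; "
            "unsolvability not established",
            [],
            examined,
        )
    report = confusable_pair_list(panel, pairs, sets)
    return ScreenResult(
        [], unsolvable=True, indistinguishable_pairs=report,
        stats={"combinations_examined": examined},
    )


def minimal_subset(
    markers: Sequence[str],
    pairs: Sequence[ParentPair],
    sets: OffspringSets,
    source: str = "exhaustive",
) -> PMS:
    """Smallest working subset of an already-working marker list.

    Used to strip redundant markers from a greedy solution: the
    exhaustive traversal is rerun restricted to subsets of the given
    list.  Ties break to the lexicographically first combination in the
    list's own order.  The result is non-redundant by construction
    (any smaller working subset would have been found first).
    """
    markers = list(markers)
    if len(pairs) > 1 and not is_pms(markers, pairs, sets):
        raise InvalidInputError("input marker list is not itself a working PMS")
    if len(pairs) == 1:
        return PMS((), source=source, non_redundant=True)
    for size in range(1, len(markers) + 1):
        for combo in combinations(markers, size):
            if is_pms(combo, pairs, sets):
                return PMS(tuple(combo), source=source, non_redundant=True)
    raise AssertionError("unreachable: input verified as a working PMS")
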