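"""End-to-end screening recipes and the Mendelian-compatibility assigner.

The recommended workflow runs the greedy screen first (fast, near
optimal), then strips redundant markers with the exhaustive search
restricted to the greedy solution.  Alternative PMSs generated on the
shrunken panel (with earlier solutions excluded) supply a *redundancy
set* of backup markers — capped at twice the base PMS size — from which
users can compose a low-redundancy PMS that tolerates genotyping error
and missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .core import (
    ConfigurationError,
    Genotype,
    InvalidInputError,
    OffspringSets,
    ParentPair,
    UnsolvableError,
)
from .exhaustive import PMS, ScreenResult, minimal_subset
from .greedy import greedy_screen

__all__ = [
    "RecommendedResult",
    "recommended_screen",
    "alternative_pms",
    "merge_pms",
    "assign_parents",
]


@dataclass
class RecommendedResult:
    """A non-redundant base PMS plus recommended backup markers."""

    base_pms: PMS
    redundancy_set: list = field(default_factory=list)

    def __post_init__(self):
        if set(self.redundancy_set) & self.base_pms.marker_set:
            raise InvalidInputError("redundancy set overlaps the base PMS")
        if len(self.redundancy_set) > 2 * len(self.base_pms):
            raise InvalidInputError("redundancy set exceeds twice the base PMS size")


def alternative_pms(
    panel: Sequence[str],
    pairs: Sequence[ParentPair],
    sets: OffspringSets,
    exclude: frozenset | set = frozenset(),
    indicator: str = "pdi",
    **greedy_kwargs,
) -> PMS:
    """Rerun the greedy screen with some markers excluded.

    Removing the markers of an already-found PMS from the panel and
    re-screening yields an alternative solution (disjoint from the
    excluded set).  Raises :class:`UnsolvableError` when the shrunken
    panel can no longer separate all pairs, and a configuration error
    when nothing is left to screen.
    """
    shrunken = [m for m in panel if m not in exclude]
    if not shrunken:
        raise ConfigurationError("all markers excluded; nothing left to screen")
    result = greedy_screen(shrunken, pairs, sets, indicator=indicator, **greedy_kwargs)
    if result.unsolvable:
        raise UnsolvableError(
            "shrunken panel cannot separate all candidate pairs", result
        )
    return result.best


def recommended_screen(
    panel: Sequence[str],
    pairs: Sequence[ParentPair],
    sets: OffspringSets,
    exclusion_mode: str = "disjoint",
) -> RecommendedResult:
    """Greedy screen, exhaustive de-redundancy, then backup collection.

    ``exclusion_mode='disjoint'`` (default) excludes every marker of
    the base and of earlier alternatives before each re-screen, so the
    backups are mutually disjoint and maximally independent;
    ``'subset'`` excludes one base marker at a time, producing
    overlapping alternatives.  Backup markers are collected in
    discovery order and truncated at twice the base PMS size.

    Raises :class:`UnsolvableError` (carrying the report) when even the
    full panel cannot separate all pairs.
    """
    if exclusion_mode not in ("disjoint", "subset"):
        raise InvalidInputError("exclusion_mode must be 'disjoint' or 'subset'")
    greedy_result = greedy_screen(panel, pairs, sets)
    if greedy_result.unsolvable:
        raise UnsolvableError("instance is unsolvable on the full panel", greedy_result)
    base = minimal_subset(greedy_result.best.marker_ids, pairs, sets, source="greedy")

    quota = 2 * len(base)
    backups: list = []
    if quota:
        if exclusion_mode == "disjoint":
            excluded = set(base.marker_ids)
            while len(backups) < quota:
                try:
                    alt = alternative_pms(panel, pairs, sets, exclude=excluded)
                except (UnsolvableError, ConfigurationError):
                    break
                alt = minimal_subset(alt.marker_ids, pairs, sets, source="greedy")
                new = [m for m in alt.marker_ids if m not in excluded and m not in backups]
                backups.extend(new)
                excluded.update(alt.marker_ids)
                if not new:
                    break
        else:
            for drop in base.marker_ids:
                if len(backups) >= quota:
                    break
                try:
                    alt = alternative_pms(panel, pairs, sets, exclude={drop})
                except UnsolvableError:
                    continue
                for m in alt.marker_ids:
                    if m not in base.marker_set and m not in backups:
                        backups.append(m)
    return RecommendedResult(base_pms=base, redundancy_set=backups[:quota])


def merge_pms(a: PMS, b: PMS) -> PMS:
    """Union of two PMSs: a low-redundancy PMS.

    Order preserves ``a`` then the unseen markers of ``b``; merging a
    working PMS with anything keeps it working (adding markers never
    creates confusability).
    """
    merged = list(a.marker_ids) + [m for m in b.marker_ids if m not in a.marker_set]
    return PMS(tuple(merged), source="merged")


def assign_parents(
    offspring_genotypes: Mapping[str, Optional[Genotype]],
    pairs: Sequence[ParentPair],
    sets: OffspringSets,
    max_mismatch: int = 0,
    return_scores: bool = False,
):
    """Mendelian-compatibility parentage assignment.

    A candidate pair is compatible at a marker when the offspring
    genotype lies in the pair's Mendelian offspring set; untyped
    (``None``) offspring markers are skipped.  Pairs with at most
    ``max_mismatch`` incompatible typed markers are returned sorted by
    mismatch count, then pair id.  On a working PMS with
    ``max_mismatch=0`` an error-free offspring matches exactly its true
    pair.  This assigner is deliberately exact-compatibility (no
    likelihoods): its role is internal validation of screened PMSs.
    """
    typed = [(m, g) for m, g in offspring_genotypes.items() if g is not None]
    if not typed:
        raise InvalidInputError("offspring has no typed marker")
    if max_mismatch < 0:
        raise InvalidInputError("max_mismatch must be >= 0")
    scored = []
    for pair in pairs:
        mismatches = sum(1 for m, g in typed if g not in sets.get(pair, m))
        if mismatches <= max_mismatch:
            scored.append((mismatches, pair))
    scored.sort()
    if return_scores:
        return [(pair, mm) for mm, pair in scored]
    return [pair for _, pair in scored]
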