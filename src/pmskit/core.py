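"""Core genotype model for parentage-marker-set screening.

A *closed population* is one where every candidate parent has been
genotyped and the true parents of any offspring are guaranteed to be in
the candidate pool.  Under Mendel's law of segregation, a parent pair
can produce at most four distinct offspring genotypes per marker; two
candidate pairs are *confusable* on a marker set when some offspring
genotype vector is producible by both.  A marker set on which no two
candidate pairs are confusable is a parentage marker set (PMS): every
simulated offspring traces back to a unique pair.

Genotypes are unordered diploid allele pairs; phase is never modeled.
Alleles are arbitrary alphanumeric tokens (SSR fragment sizes, SNP
bases, microhaplotype strings) compared case-sensitively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "PmskitError",
    "ConfigurationError",
    "IncompleteGenotypeError",
    "InvalidInputError",
    "UnknownMarkerError",
    "UnsolvableError",
    "Genotype",
    "ParentPair",
    "genotype",
    "parse_genotype",
    "format_genotype",
    "parent_pair",
    "ParentPool",
    "GenotypeMatrix",
    "OffspringSets",
    "mendelian_offspring_genotypes",
    "enumerate_parent_pairs",
    "offspring_sets",
    "pairs_confusable",
    "is_pms",
    "confusable_pair_list",
]


class PmskitError(Exception):
    """Base class for all pmskit errors."""


class ConfigurationError(PmskitError):
    """Invalid configuration (bad sex mode, empty panel, ...)."""


class IncompleteGenotypeError(PmskitError):
    """A screening entry point was given a matrix with missing cells.

    Screening on partially genotyped parents is unsafe: the offspring
    genotype sets of an ungenotyped parent are undefined, so the whole
    cell is a hard error rather than a silently dropped marker.
    """


class InvalidInputError(PmskitError):
    """Structurally valid call with semantically invalid arguments."""


class UnknownMarkerError(PmskitError):
    """A marker id absent from the precomputed offspring sets."""


class UnsolvableError(PmskitError):
    """Raised by operations whose contract requires a solvable instance.

    Carries the unsolvability report (a ScreenResult with
    ``unsolvable=True``) in :attr:`result`.
    """

    def __init__(self, message: str, result=None):
        super().__init__(message)
        self.result = result


# A genotype is a lexicographically sorted 2-tuple of allele tokens, so
# A/B == B/A and homozygotes are (a, a).  A parent pair is a sorted
# 2-tuple of parent ids.  Plain tuples keep hashing and equality free.
Genotype = tuple
ParentPair = tuple


def _check_allele(token: str) -> str:
    if not isinstance(token, str) or not token:
        raise InvalidInputError(f"allele token must be a non-empty string, got {token!r}")
    if "/" in token:
        raise InvalidInputError(f"allele token may not contain '/': {token!r}")
    return token


def genotype(a1: str, a2: str) -> Genotype:
    """Canonical unordered diploid genotype (alleles sorted)."""
    _check_allele(a1)
    _check_allele(a2)
    return (a1, a2) if a1 <= a2 else (a2, a1)


def parse_genotype(text: str) -> Genotype:
    """Parse ``"allele1/allele2"`` into a canonical genotype."""
    parts = text.split("/")
    if len(parts) != 2:
        raise InvalidInputError(
            f"genotype {text!r} must contain exactly two '/'-separated alleles"
        )
    return genotype(parts[0], parts[1])


def format_genotype(g: Genotype) -> str:
    return f"{g[0]}/{g[1]}"


def parent_pair(i: str, j: str) -> ParentPair:
    """Canonical unordered pair of distinct parent ids."""
    if i == j:
        raise InvalidInputError(f"parent pair members must be distinct, got {i!r} twice")
    return (i, j) if i <= j else (j, i)


MALE, FEMALE, UNKNOWN = "M", "F", "U"
_SEX_TOKENS = {MALE, FEMALE, UNKNOWN}


@dataclass(frozen=True)
class ParentPool:
    """Ordered candidate parents with their sexes (M/F/U)."""

    parent_ids: tuple
    sex: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        ids = tuple(self.parent_ids)
        if len(set(ids)) != len(ids):
            raise InvalidInputError("duplicate parent ids in pool")
        sex = dict(self.sex)
        for pid in ids:
            sex.setdefault(pid, UNKNOWN)
            if sex[pid] not in _SEX_TOKENS:
                raise InvalidInputError(
                    f"sex of parent {pid!r} must be one of M/F/U, got {sex[pid]!r}"
                )
        object.__setattr__(self, "parent_ids", ids)
        object.__setattr__(self, "sex", sex)

    def males(self):
        return [p for p in self.parent_ids if self.sex[p] == MALE]

    def females(self):
        return [p for p in self.parent_ids if self.sex[p] == FEMALE]

    def __len__(self):
        return len(self.parent_ids)


class GenotypeMatrix:
    """Parent x marker table of unordered diploid genotypes.

    Cells may be ``None`` (missing) after file import, but every
    screening entry point requires a complete matrix over the markers
    it uses; ``require_complete`` enforces that.
    """

    def __init__(
        self,
        parent_ids: Sequence[str],
        marker_ids: Sequence[str],
        entries: Mapping[tuple, Optional[Genotype]],
    ):
        self.parent_ids = tuple(parent_ids)
        self.marker_ids = tuple(marker_ids)
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise InvalidInputError("duplicate marker ids")
        self._entries = dict(entries)

    def get(self, parent_id: str, marker_id: str) -> Optional[Genotype]:
        return self._entries.get((parent_id, marker_id))

    def missing_cells(self, marker_ids: Optional[Sequence[str]] = None):
        markers = self.marker_ids if marker_ids is None else marker_ids
        return [
            (p, m)
            for p in self.parent_ids
            for m in markers
            if self._entries.get((p, m)) is None
        ]

    def require_complete(self, marker_ids: Optional[Sequence[str]] = None) -> None:
        missing = self.missing_cells(marker_ids)
        if missing:
            cells = ", ".join(f"{p}@{m}" for p, m in missing[:5])
            raise IncompleteGenotypeError(
                f"{len(missing)} missing genotype cell(s) (e.g. {cells}); "
                "screening requires a fully genotyped parental pool"
            )

    def marker_alleles(self, marker_id: str):
        """Sorted distinct alleles observed at a marker."""
        alleles = set()
        for p in self.parent_ids:
            g = self._entries.get((p, marker_id))
            if g is not None:
                alleles.update(g)
        return sorted(alleles)


def mendelian_offspring_genotypes(g1: Genotype, g2: Genotype) -> frozenset:
    """All distinct offspring genotypes a parental cross can produce.

    The four ordered transmissions collapse to between 1 (both parents
    homozygous for the same allele) and 4 (fully heterozygous cross
    sharing at most one allele) distinct unordered genotypes.
    """
    return frozenset(
        genotype(a, b) for a in g1 for b in g2
    )


def enumerate_parent_pairs(
    pool: ParentPool,
    sex_mode: str = "known",
    include_self_pairs: bool = False,
) -> list:
    """Candidate parent pairs under the chosen sex mode.

    ``known``   — every male x female pair (requires all sexes typed);
    ``unknown`` — every unordered pair of distinct parents (the mating
    design is ignored, which inflates the candidate family count).

    ``include_self_pairs`` adds P_i x P_i selfing pairs for
    hermaphroditic species (unknown mode only); default off.
    """
    if sex_mode not in ("known", "unknown"):
        raise ConfigurationError(f"sex_mode must be 'known' or 'unknown', got {sex_mode!r}")
    if len(pool) < 2 and not include_self_pairs:
        raise ConfigurationError("need at least two candidate parents")
    if sex_mode == "known":
        untyped = [p for p in pool.parent_ids if pool.sex[p] == UNKNOWN]
        if untyped:
            raise ConfigurationError(
                f"sex_mode='known' requires typed sexes; unknown for: {', '.join(untyped)}"
            )
        pairs = [
            parent_pair(m, f) for m in pool.males() for f in pool.females()
        ]
    else:
        pairs = [parent_pair(i, j) for i, j in combinations(pool.parent_ids, 2)]
        if include_self_pairs:
            pairs += [(p, p) for p in pool.parent_ids]
    if not pairs:
        raise ConfigurationError("no valid parent pair (e.g. single-sex pool in known mode)")
    return sorted(set(pairs))


class OffspringSets:
    """Precomputed Mendelian offspring genotype sets G_{pair,marker}."""

    def __init__(self, table: Mapping[tuple, frozenset], marker_ids: Sequence[str]):
        self._table = dict(table)
        self.marker_ids = tuple(marker_ids)

    def get(self, pair: ParentPair, marker_id: str) -> frozenset:
        try:
            return self._table[(pair, marker_id)]
        except KeyError:
            raise UnknownMarkerError(
                f"no offspring set for pair {pair} at marker {marker_id!r}"
            ) from None

    def __contains__(self, key):
        return key in self._table


def offspring_sets(
    matrix: GenotypeMatrix,
    pairs: Iterable[ParentPair],
    panel: Sequence[str],
) -> OffspringSets:
    """Mendelian offspring sets for every (pair, marker) combination."""
    pairs = list(pairs)
    matrix.require_complete(panel)
    table = {}
    for pair in pairs:
        i, j = pair
        for m in panel:
            gi, gj = matrix.get(i, m), matrix.get(j, m)
            table[(pair, m)] = mendelian_offspring_genotypes(gi, gj)
    return OffspringSets(table, panel)


def pairs_confusable(
    pair_a: ParentPair,
    pair_b: ParentPair,
    markers: Sequence[str],
    sets: OffspringSets,
) -> bool:
    """Can both pairs produce a common offspring genotype vector?

    Because markers segregate independently in this model, the product
    of per-marker offspring sets intersects iff every per-marker factor
    intersects, so the check is linear in the number of markers.  An
    empty marker list distinguishes nothing and returns True.
    """
    for m in markers:
        if sets.get(pair_a, m).isdisjoint(sets.get(pair_b, m)):
            return False
    return True


def is_pms(
    markers: Sequence[str],
    pairs: Sequence[ParentPair],
    sets: OffspringSets,
) -> bool:
    """True iff no two distinct candidate pairs are confusable on ``markers``."""
    if not pairs:
        raise InvalidInputError("need at least one candidate pair")
    for a, b in combinations(pairs, 2):
        if pairs_confusable(a, b, markers, sets):
            return False
    return True


def confusable_pair_list(
    markers: Sequence[str],
    pairs: Sequence[ParentPair],
    sets: OffspringSets,
) -> list:
    """All unordered (pairA, pairB) still confusable on ``markers``.

    This is the unsolvability report: parent pairs listed here cannot
    be told apart even by the given markers, guiding the addition of
    new markers.
    """
    return [
        (a, b)
        for a, b in combinations(sorted(pairs), 2)
        if pairs_confusable(a, b, markers, sets)
    ]
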