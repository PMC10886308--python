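"""Classical single-marker statistics used as comparison indicators.

PIC (polymorphic information content) and PE (probability of exclusion)
summarize a marker's discriminating power from allele frequencies
alone, ignoring how markers interact; CPE multiplies per-marker PE into
a set-level summary.  They serve here as alternative greedy selection
scores and as per-PMS report columns, to be contrasted with the
tree-based PDI which evaluates markers jointly on the actual candidate
pairs.

Frequencies are estimated from the candidate-parent pool itself — in a
closed population it is the only genotyped generation.

PE closed forms are derived by conditioning on the offspring genotype
under Hardy-Weinberg proportions:

* ``single`` mode excludes a random unrelated individual as a putative
  parent (excluded iff it carries neither offspring allele);
* ``pair`` mode excludes a random unrelated pair (excluded iff the pair
  cannot produce the offspring genotype under Mendelian segregation).

These are algebraically the standard one-parent and parent-pair
exclusion probabilities.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .core import (
    GenotypeMatrix,
    InvalidInputError,
    OffspringSets,
    ParentPair,
)

__all__ = [
    "allele_frequencies",
    "pic",
    "pe",
    "cpe",
    "root_pdi",
    "indicator_correlations",
    "marker_stats",
]

_SUM_TOL = 1e-9


def allele_frequencies(
    matrix: GenotypeMatrix, panel: Optional[Sequence[str]] = None
) -> dict:
    """Per-marker allele frequencies from the candidate-parent pool.

    Every parent contributes two allele observations per marker;
    missing cells are a hard error (frequency estimates on partially
    genotyped pools would silently change denominators).
    """
    panel = list(matrix.marker_ids if panel is None else panel)
    if not matrix.parent_ids:
        raise InvalidInputError("empty parent pool")
    matrix.require_complete(panel)
    out = {}
    denom = 2 * len(matrix.parent_ids)
    for m in panel:
        counts: dict = {}
        for p in matrix.parent_ids:
            for allele in matrix.get(p, m):
                counts[allele] = counts.get(allele, 0) + 1
        out[m] = {a: c / denom for a, c in sorted(counts.items())}
    return out


def _check_freqs(freqs: Mapping[str, float]) -> np.ndarray:
    p = np.asarray(list(freqs.values()), dtype=float)
    if p.size == 0 or np.any(p <= 0) or abs(p.sum() - 1.0) > _SUM_TOL:
        raise InvalidInputError(
            f"allele frequencies must be positive and sum to 1, got {dict(freqs)}"
        )
    return p


def pic(freqs: Mapping[str, float]) -> float:
    """Polymorphic information content (Botstein form).

    PIC = 1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2.  0 for a
    monomorphic marker; 0.375 for a balanced biallelic one; always
    below the expected heterozygosity 1 - sum(p_i^2).
    """
    p = _check_freqs(freqs)
    p2 = p**2
    cross = (p2.sum() ** 2 - (p2**2).sum()) / 2.0  # sum_{i<j} p_i^2 p_j^2
    return float(1.0 - p2.sum() - 2.0 * cross)


def pe(freqs: Mapping[str, float], mode: str = "pair") -> float:
    """Probability of exclusion of one marker.

    ``pair``   — probability that a random offspring genotype is not
                 producible by an independent random (non-parental)
                 pair;
    ``single`` — probability that a random unrelated individual shares
                 no allele with a random offspring genotype.
    """
    if mode not in ("pair", "single"):
        raise InvalidInputError(f"pe mode must be 'pair' or 'single', got {mode!r}")
    p = _check_freqs(freqs)
    carrier = 1.0 - (1.0 - p) ** 2  # P(random individual carries allele i)
    total = 0.0
    k = len(p)
    for i in range(k):
        # homozygous offspring i/i (HWE prob p_i^2)
        if mode == "pair":
            excl = 1.0 - carrier[i] ** 2
        else:
            excl = (1.0 - p[i]) ** 2
        total += p[i] ** 2 * excl
        for j in range(i + 1, k):
            # heterozygous offspring i/j (HWE prob 2 p_i p_j)
            if mode == "pair":
                # pair produces i/j iff one member carries i and the other j
                both = (2.0 * p[i] * p[j]) ** 2  # both members are i/j hets
                producible = 2.0 * carrier[i] * carrier[j] - both
                excl = 1.0 - producible
            else:
                excl = (1.0 - p[i] - p[j]) ** 2
            total += 2.0 * p[i] * p[j] * excl
    return float(total)


def cpe(pe_values: Sequence[float]) -> float:
    """Cumulative probability of exclusion, 1 - prod(1 - PE_i).

    Monotone non-decreasing as markers are appended; 0 for an empty
    set.  Treats markers as independent, which is exactly the
    approximation the tree-based screening avoids.
    """
    vals = list(pe_values)
    for v in vals:
        if not (0.0 <= v < 1.0):
            raise InvalidInputError(f"PE values must lie in [0, 1), got {v}")
    return float(1.0 - np.prod([1.0 - v for v in vals])) if vals else 0.0


def root_pdi(
    panel: Sequence[str], pairs: Sequence[ParentPair], sets: OffspringSets
) -> dict:
    """PDI of each marker evaluated at the root layer (all pairs in one node)."""
    from .greedy import TreeLayer, TreeNode, pdi as _pdi

    root = TreeLayer([TreeNode(frozenset(pairs))], layer_index=1)
    return {m: _pdi(root, m, sets).pdi for m in panel}


def marker_stats(
    matrix: GenotypeMatrix,
    panel: Optional[Sequence[str]] = None,
    pe_mode: str = "pair",
) -> pd.DataFrame:
    """Per-marker PIC and PE table (index = marker id)."""
    panel = list(matrix.marker_ids if panel is None else panel)
    freqs = allele_frequencies(matrix, panel)
    rows = {m: {"pic": pic(freqs[m]), "pe": pe(freqs[m], mode=pe_mode)} for m in panel}
    return pd.DataFrame.from_dict(rows, orient="index").loc[panel]


def indicator_correlations(
    panel: Sequence[str],
    matrix: GenotypeMatrix,
    pairs: Sequence[ParentPair],
    sets: Optional[OffspringSets] = None,
    pe_mode: str = "pair",
) -> pd.DataFrame:
    """Spearman correlations between PDI, PIC and PE across markers.

    PDI is evaluated at the root layer (all candidate pairs in one
    node).  With constant columns the coefficient is undefined and
    reported as NaN.
    """
    from .core import offspring_sets as _osets

    panel = list(panel)
    if len(panel) < 3:
        raise InvalidInputError("need at least 3 markers for a rank correlation")
    if sets is None:
        sets = _osets(matrix, pairs, panel)
    table = marker_stats(matrix, panel, pe_mode=pe_mode)
    pdis = root_pdi(panel, pairs, sets)
    table["pdi"] = [pdis[m] for m in panel]

    def _r(x, y):
        if np.allclose(x, x[0]) or np.allclose(y, y[0]):
            return float("nan")
        return float(_sps.spearmanr(x, y).statistic)

    x = {c: table[c].to_numpy() for c in ("pic", "pe", "pdi")}
    rows = {
        "pic_vs_pe": _r(x["pic"], x["pe"]),
        "pdi_vs_pic": _r(x["pdi"], x["pic"]),
        "pdi_vs_pe": _r(x["pdi"], x["pe"]),
    }
    return pd.DataFrame({"spearman_r": rows})
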