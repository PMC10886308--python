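"""Multiway-tree greedy screening driven by the Parental Dispersity Index.

The tree starts from a root node holding every candidate parent pair.
Genotyping the population at one marker splits each node: offspring
showing genotype g can only descend from the pairs whose Mendelian set
at that marker contains g, so each observable genotype induces a child
node.  A node with a single pair is a leaf (that family is resolved);
a node with several pairs is a branch node that a further marker must
split.  Screening ends when only leaves remain — the selected markers
then form a PMS.

The Parental Dispersity Index (PDI) of a marker, evaluated on the
current layer, is

    PDI = mean + SD

of the pair counts over the child branch nodes that remain after
removing leaves and duplicated nodes (identical pair sets), with SD the
population standard deviation (divide by the node count).  Lower PDI
means the marker both resolves more pairs outright and splits the rest
evenly, so the greedy step picks the unused marker with the smallest
PDI.  A marker that turns every remaining pair into a leaf scores the
minimum, 0.

For comparison studies the selection score can be swapped for classic
single-marker statistics (PIC or exclusion probability, maximized
instead of minimized); the tree mechanics are unchanged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import (
    ConfigurationError,
    GenotypeMatrix,
    OffspringSets,
    ParentPair,
    confusable_pair_list,
)
from .exhaustive import PMS, ScreenResult

__all__ = [
    "TreeNode",
    "TreeLayer",
    "PdiValue",
    "expand_layer",
    "pdi",
    "greedy_screen",
    "INDICATORS",
]

logger = logging.getLogger(__name__)

INDICATORS = ("pdi", "pic", "pe")


@dataclass(frozen=True)
class TreeNode:
    """A tree node: the set of parent pairs still jointly compatible."""

    pair_set: frozenset

    @property
    def count(self) -> int:
        return len(self.pair_set)

    @property
    def is_leaf(self) -> bool:
        return len(self.pair_set) == 1


@dataclass
class TreeLayer:
    """One level of the multiway tree."""

    nodes: list
    layer_index: int = 1

    @property
    def node_count(self) -> int:
        return len(self.nodes)

    def branch_nodes(self) -> list:
        return [n for n in self.nodes if not n.is_leaf]


@dataclass(frozen=True)
class PdiValue:
    mean: float
    sd: float

    @property
    def pdi(self) -> float:
        return self.mean + self.sd


def _root_layer(pairs: Sequence[ParentPair]) -> TreeLayer:
    return TreeLayer([TreeNode(frozenset(pairs))], layer_index=1)


def _children_of(node: TreeNode, marker: str, sets: OffspringSets) -> list:
    """Child pair-sets induced by each observable genotype at ``marker``.

    Deterministic order: genotypes sorted lexicographically.
    """
    union = set()
    for pair in node.pair_set:
        union.update(sets.get(pair, marker))
    children = []
    seen = set()
    for g in sorted(union):
        child = frozenset(p for p in node.pair_set if g in sets.get(p, marker))
        if child not in seen:
            seen.add(child)
            children.append(child)
    return children


def _child_pair_sets(layer: TreeLayer, marker: str, sets: OffspringSets) -> list:
    """Deduplicated child pair-sets of all branch nodes (layer-wide dedup).

    Two child nodes with identical pair sets present identical residual
    subproblems, so duplicates are merged across the whole layer.
    """
    out = []
    seen = set()
    for node in layer.branch_nodes():
        for child in _children_of(node, marker, sets):
            if child not in seen:
                seen.add(child)
                out.append(child)
    return out


def expand_layer(layer: TreeLayer, marker: str, sets: OffspringSets) -> TreeLayer:
    """Genotype the layer at ``marker`` and return the next layer.

    Branch nodes are split into their genotype-induced children
    (deduplicated layer-wide); existing leaves are carried through for
    termination bookkeeping.
    """
    children = _child_pair_sets(layer, marker, sets)
    seen = set(children)
    carried = []
    for node in layer.nodes:
        if node.is_leaf and node.pair_set not in seen:
            seen.add(node.pair_set)
            carried.append(node.pair_set)
    nodes = [TreeNode(s) for s in children + carried]
    return TreeLayer(nodes, layer_index=layer.layer_index + 1)


def pdi(layer: TreeLayer, marker: str, sets: OffspringSets) -> PdiValue:
    """Parental Dispersity Index of ``marker`` evaluated on ``layer``.

    Computes the child layer, removes leaves and duplicated branch
    nodes, and returns mean + population SD of the remaining pair
    counts.  An empty remainder (the marker resolves everything still
    open) scores mean = sd = 0, the minimum.
    """
    counts = [len(s) for s in _child_pair_sets(layer, marker, sets) if len(s) > 1]
    if not counts:
        return PdiValue(0.0, 0.0)
    mean = sum(counts) / len(counts)
    var = sum((c - mean) ** 2 for c in counts) / len(counts)
    return PdiValue(mean, math.sqrt(var))


def _marker_makes_progress(layer: TreeLayer, marker: str, sets: OffspringSets) -> bool:
    """A marker makes progress iff the residual branch layer changes.

    Comparison is between deduplicated child *branch* nodes and the
    current branch nodes: leaf children of a node that itself survives
    intact do not resolve anything (the pair is still confusable inside
    the surviving node), so they must not count as progress — otherwise
    a useless marker could tie on the indicator and be selected.
    """
    current = {n.pair_set for n in layer.branch_nodes()}
    children = {s for s in _child_pair_sets(layer, marker, sets) if len(s) > 1}
    return children != current


def _static_scores(
    indicator: str,
    panel: Sequence[str],
    matrix: Optional[GenotypeMatrix],
    pe_mode: str,
) -> dict:
    from . import metrics  # local import to avoid a cycle

    if matrix is None:
        raise ConfigurationError(
            f"indicator={indicator!r} needs a GenotypeMatrix to estimate allele frequencies"
        )
    freqs = metrics.allele_frequencies(matrix, panel)
    if indicator == "pic":
        return {m: metrics.pic(freqs[m]) for m in panel}
    return {m: metrics.pe(freqs[m], mode=pe_mode) for m in panel}


def greedy_screen(
    panel: Sequence[str],
    pairs: Sequence[ParentPair],
    sets: OffspringSets,
    indicator: str = "pdi",
    matrix: Optional[GenotypeMatrix] = None,
    pe_mode: str = "pair",
    tie_break: str = "panel",
    rng: Optional[np.random.Generator] = None,
) -> ScreenResult:
    """Layer-by-layer greedy marker selection.

    Each round evaluates every unused, progress-making marker on the
    current layer of branch nodes; with ``indicator='pdi'`` the
    minimum-PDI marker is selected, with ``'pic'``/``'pe'`` the
    maximum-score marker among progress-making candidates.  Indicator
    ties are broken toward the marker leaving the fewest residual
    confusable pair-of-pairs (mean+SD cannot distinguish layers that
    differ only in branch-node count), then by panel order — or seeded
    random with ``tie_break='random'``.  The chosen
    marker expands the layer, resolved leaves are dropped, and the loop
    repeats until no branch node remains.  If branch nodes survive and
    no unused marker makes progress, the instance is unsolvable and the
    report lists the parent pairs confusable on the full panel.
    """
    panel = list(panel)
    if not panel:
        raise ConfigurationError("empty marker panel")
    if indicator not in INDICATORS:
        raise ConfigurationError(f"indicator must be one of {INDICATORS}, got {indicator!r}")
    if tie_break not in ("panel", "random"):
        raise ConfigurationError("tie_break must be 'panel' or 'random'")
    if tie_break == "random" and rng is None:
        raise ConfigurationError("tie_break='random' requires an rng")
    if not pairs:
        raise ConfigurationError("need at least one candidate pair")

    static = None
    if indicator in ("pic", "pe"):
        static = _static_scores(indicator, panel, matrix, pe_mode)

    layer = _root_layer(pairs)
    # Drop any initial leaf (single-pair instance): nothing to split.
    layer = TreeLayer(layer.branch_nodes(), layer.layer_index)
    selected: list = []
    unused = list(panel)
    evaluations = 0
    selection_log: list = []

    while layer.nodes:
        current = {n.pair_set for n in layer.nodes}
        candidates = []
        for m in unused:
            evaluations += 1
            branch_kids = [s for s in _child_pair_sets(layer, m, sets) if len(s) > 1]
            if set(branch_kids) == current:
                continue  # no progress: residual branch layer unchanged
            if indicator == "pdi":
                counts = [len(s) for s in branch_kids]
                if counts:
                    mean = sum(counts) / len(counts)
                    var = sum((c - mean) ** 2 for c in counts) / len(counts)
                    score = mean + math.sqrt(var)
                else:
                    score = 0.0
            else:
                score = -static[m]  # maximize PIC/PE = minimize negation
            # Secondary key: residual confusable pair-of-pairs count.
            # mean+SD is invariant to the NUMBER of equal-sized branch
            # nodes (resolving one of three size-2 nodes ties with
            # resolving two), so ties are broken toward the marker that
            # leaves the least unresolved work, then by panel order.
            residual = sum(len(s) * (len(s) - 1) // 2 for s in branch_kids)
            candidates.append((m, (score, residual)))
        if not candidates:
            remaining = sorted(set().union(*[n.pair_set for n in layer.nodes]))
            report = confusable_pair_list(panel, remaining, sets)
            if not report:  # defensive: should not happen
                report = [(p, q) for n in layer.nodes
                          for p in sorted(n.pair_set) for q in sorted(n.pair_set) if p < q]
            return ScreenResult(
                [], unsolvable=True, indistinguishable_pairs=report,
                stats={"indicator_evaluations": evaluations, "indicator": indicator},
            )
        best_key = min(k for _, k in candidates)
        tied = [m for m, k in candidates if k == best_key]
        if tie_break == "random" and len(tied) > 1:
            choice = tied[int(rng.integers(len(tied)))]
        else:
            choice = tied[0]  # candidates iterate in panel order
        nxt = expand_layer(layer, choice, sets)
        layer = TreeLayer(nxt.branch_nodes(), nxt.layer_index)
        selected.append(choice)
        unused.remove(choice)
        selection_log.append(
            {"marker": choice,
             "score": best_key[0] if indicator == "pdi" else static[choice],
             "branch_nodes": layer.node_count}
        )
        logger.info(
            "greedy layer %d: selected %s (%s=%.4f), %d branch node(s) remain",
            len(selected), choice,
            indicator, selection_log[-1]["score"], layer.node_count,
        )

    pms = PMS(tuple(selected), source="greedy")
    return ScreenResult(
        [pms],
        stats={
            "indicator_evaluations": evaluations,
            "indicator": indicator,
            "selection_log": selection_log,
        },
    )
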