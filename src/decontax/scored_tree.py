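"""Per-sample scored taxonomic trees and the recursive folding procedure.

Each node holds the reads assigned *exactly* to its taxid (``self_count``)
with their mean classification score (``self_score``).  Folding prepares a
tree for comparison at a rank of interest: working from the leaves upward, a
node is accumulated into its parent whenever its accumulated subtree count is
under ``mintaxa`` or its rank is below the rank floor.  Accumulation is not
pruning — counts are preserved and the parent score becomes the weighted
average

    sigma_p' = (sigma_p * n_p + sum_i sigma_i * n_i) / (n_p + sum_i n_i)

so total read count and total score mass are invariant under folding.

Worked example (mintaxa=10, floor=genus): a genus G1 with no reads of its own
and leaf children (4 reads @ 60), (2 @ 35), (2 @ 45) first accumulates them,
becoming 8 reads at score (60*4 + 35*2 + 45*2)/8 = 50; still under mintaxa,
it is then absorbed by its family F1 (2 reads @ 100), which ends at
(50*8 + 100*2)/10 = 60.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

from .errors import DegenerateSampleError, UsageError
from .taxonomy import NO_RANK, Rank, Taxonomy


@dataclass
class ScoredNode:
    """A taxon in a sample's scored tree."""

    taxid: int
    rank: Rank
    self_count: int = 0
    self_score: float = 0.0
    children: list["ScoredNode"] = field(default_factory=list)

    def subtree_count(self) -> int:
        """Reads assigned to this taxon or any descendant."""
        return self.self_count + sum(c.subtree_count() for c in self.children)

    def score_mass(self) -> float:
        """Sum over the subtree of self_count * self_score."""
        return self.self_count * self.self_score + sum(c.score_mass() for c in self.children)

    def subtree_score(self) -> float:
        """Count-weighted mean score over the subtree (0.0 if empty)."""
        n = self.subtree_count()
        return self.score_mass() / n if n else 0.0

    def iter_nodes(self) -> Iterator["ScoredNode"]:
        """Pre-order traversal."""
        yield self
        for child in self.children:
            yield from child.iter_nodes()

    def find(self, taxid: int) -> "ScoredNode | None":
        for node in self.iter_nodes():
            if node.taxid == taxid:
                return node
        return None

    def copy(self) -> "ScoredNode":
        return ScoredNode(self.taxid, self.rank, self.self_count, self.self_score,
                          [c.copy() for c in self.children])


@dataclass(frozen=True)
class FoldParams:
    """Parameters of the folding procedure."""

    rank_floor: Rank
    mintaxa: int = 1
    include: frozenset[int] = frozenset()
    exclude: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.mintaxa < 1:
            raise UsageError("mintaxa must be >= 1")
        if self.include & self.exclude:
            raise UsageError("include and exclude sets overlap")


def default_mintaxa(n_passing: int) -> int:
    """Nearest integer of log10 of the reads passing minscore, at least 1.

    Grows with the order of magnitude of the effective sample size.
    """
    if n_passing <= 0:
        raise DegenerateSampleError("cannot derive mintaxa for an empty sample")
    return max(1, math.floor(math.log10(n_passing) + 0.5))


def build_tree(profile, taxonomy: Taxonomy) -> ScoredNode:
    """Build a sample's scored tree from its taxid -> (count, score) profile.

    ``profile`` is a SampleProfile (see classifier_io) or any object with
    ``counts`` and ``mean_score`` mappings.  The tree contains exactly the
    union of lineages of observed taxids; unobserved lineage nodes get a
    self count of 0.  Children are ordered by taxid, so the tree does not
    depend on input ordering.
    """
    nodes: dict[int, ScoredNode] = {}

    def get_node(taxid: int) -> ScoredNode:
        node = nodes.get(taxid)
        if node is None:
            node = nodes[taxid] = ScoredNode(taxid, taxonomy.rank[taxid])
        return node

    root = get_node(taxonomy.root)
    edges: set[tuple[int, int]] = set()
    for taxid, count in profile.counts.items():
        lineage = taxonomy.lineage(taxid)
        for up, down in zip(lineage, lineage[1:]):
            if (up, down) not in edges:
                edges.add((up, down))
                get_node(up).children.append(get_node(down))
        leaf = get_node(lineage[-1])
        leaf.self_count += count
        leaf.self_score = profile.mean_score[taxid]
    for node in nodes.values():
        node.children.sort(key=lambda c: c.taxid)
    return root


def tree_from_taxon_counts(taxa: Mapping[int, tuple[int, float]],
                           taxonomy: Taxonomy) -> ScoredNode:
    """Build a tree from a flat taxid -> (count, score) mapping."""

    class _Profile:
        counts = {t: c for t, (c, _) in taxa.items()}
        mean_score = {t: s for t, (_, s) in taxa.items()}

    return build_tree(_Profile, taxonomy)


def _prune(node: ScoredNode, params: FoldParams) -> ScoredNode | None:
    """Apply exclude/include subtree filters before folding."""
    if node.taxid in params.exclude:
        return None
    if params.include and node.taxid in params.include:
        # Whole subtree retained; excluded descendants still removed.
        node.children = [c for c in (_prune_exclude_only(c, params) for c in node.children)
                         if c is not None]
        return node
    node.children = [c for c in (_prune(c, params) for c in node.children) if c is not None]
    if params.include:
        # Not itself included: keep only as a connective ancestor of an
        # included subtree, contributing no reads of its own.
        if not node.children:
            return None
        node.self_count = 0
        node.self_score = 0.0
    return node


def _prune_exclude_only(node: ScoredNode, params: FoldParams) -> ScoredNode | None:
    if node.taxid in params.exclude:
        return None
    node.children = [c for c in (_prune_exclude_only(c, params) for c in node.children)
                     if c is not None]
    return node


def _rank_retains(node: ScoredNode, nearest_ranked_ancestor: Rank | None,
                  floor: Rank) -> bool:
    """Rank half of the retention test.

    A ranked node is retained iff its rank is at or above the floor.  A
    NO_RANK node survives only if it lies on the ancestor side of the floor,
    i.e. its nearest ranked ancestor is strictly above the floor.
    """
    if not node.rank.is_no_rank:
        return node.rank >= floor
    return nearest_ranked_ancestor is not None and nearest_ranked_ancestor > floor


def _fold_node(node: ScoredNode, params: FoldParams,
               inherited_rank: Rank | None) -> None:
    effective = node.rank if not node.rank.is_no_rank else inherited_rank
    kept: list[ScoredNode] = []
    add_count = 0
    add_mass = 0.0
    for child in node.children:
        _fold_node(child, params, effective)
        if (_rank_retains(child, effective, params.rank_floor)
                and child.subtree_count() >= params.mintaxa):
            kept.append(child)
        else:
            add_count += child.subtree_count()
            add_mass += child.score_mass()
    if add_count:
        total = node.self_count + add_count
        node.self_score = (node.self_score * node.self_count + add_mass) / total
        node.self_count = total
    node.children = kept


def fold(root: ScoredNode, params: FoldParams) -> ScoredNode:
    """Fold a tree to the rank floor under the mintaxa rule (pure function).

    Exclude subtrees are removed first; if the include set is nonempty, only
    included subtrees (plus connective ancestors) survive.  Then nodes are
    accumulated post-order into their parents per the weighted-average rule.
    On return every leaf has rank >= rank_floor and subtree count >= mintaxa
    (or is the root); the root is never accumulated away.
    """
    tree = _prune(root.copy(), params)
    if tree is None:
        tree = ScoredNode(root.taxid, root.rank)
    _fold_node(tree, params, None)
    return tree


def taxa_at_rank(root: ScoredNode, rank: Rank) -> dict[int, tuple[int, float]]:
    """Taxa of a folded tree sitting exactly at ``rank``.

    After folding to ``rank`` these are leaves; returns taxid ->
    (subtree count, subtree mean score), ordered by taxid.
    """
    out = {
        node.taxid: (node.subtree_count(), node.subtree_score())
        for node in root.iter_nodes()
        if not node.rank.is_no_rank and node.rank.order_index == rank.order_index
    }
    return dict(sorted(out.items()))
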