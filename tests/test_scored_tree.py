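"""Tree building and the folding recursion, checked against a read-level oracle."""

import numpy as np
import pytest

import decontax as dx
from decontax.errors import DegenerateSampleError
from decontax.scored_tree import (FoldParams, ScoredNode, build_tree,
                                  default_mintaxa, fold, taxa_at_rank)

# Ranks by tree depth for the random generator (root stays unranked).
DEPTH_RANKS = ("domain", "phylum", "class", "order", "family", "genus",
               "species", "subspecies")


def random_tree(rng: np.random.Generator, n_nodes: int = 50) -> ScoredNode:
    """Random ranked tree; rank strictly increases toward the root."""
    ranks = dx.DEFAULT_RANKS
    root = ScoredNode(1, dx.NO_RANK)
    nodes = [(root, 0)]
    for taxid in range(2, n_nodes + 2):
        parent, depth = nodes[rng.integers(len(nodes))]
        if depth >= len(DEPTH_RANKS):
            continue
        count = int(rng.choice([0, 0, 1, 2, 5, 12, 40]))
        score = float(rng.integers(0, 101)) if count else 0.0
        node = ScoredNode(taxid, ranks[DEPTH_RANKS[depth]], count, score)
        parent.children.append(node)
        nodes.append((node, depth + 1))
    return root


def oracle_fold(root: ScoredNode, params: FoldParams):
    """Independent read-level reassignment oracle.

    Every read moves to its deepest retained ancestor-or-self, where a node
    is retained iff its rank is at/above the floor and its ORIGINAL subtree
    count reaches mintaxa (plus the root).  Returns taxid -> (count, mean
    score) of nodes holding reads.
    """
    retained: set[int] = {root.taxid}

    def mark(node: ScoredNode) -> None:
        if (not node.rank.is_no_rank and node.rank >= params.rank_floor
                and node.subtree_count() >= params.mintaxa):
            retained.add(node.taxid)
        for child in node.children:
            mark(child)

    mark(root)

    reads: dict[int, list[float]] = {}

    def assign(node: ScoredNode, path: list[int]) -> None:
        here = path + [node.taxid]
        if node.self_count:
            target = next(t for t in reversed(here) if t in retained)
            reads.setdefault(target, []).extend([node.self_score] * node.self_count)
        for child in node.children:
            assign(child, here)

    assign(root, [])
    return {t: (len(v), sum(v) / len(v)) for t, v in reads.items()}


def folded_read_map(root: ScoredNode):
    return {n.taxid: (n.self_count, n.self_score)
            for n in root.iter_nodes() if n.self_count}


def test_fig1_worked_example(fig1, ranks):
    params = FoldParams(rank_floor=ranks["genus"], mintaxa=10)
    g1_folded = fold(fig1.children[0], params)
    assert g1_folded.self_count == 8
    assert g1_folded.self_score == pytest.approx(50.0)
    assert not g1_folded.children
    f1_folded = fold(fig1, params)
    assert f1_folded.self_count == 10
    assert f1_folded.self_score == pytest.approx(60.0)


def test_node_above_thresholds_is_untouched(fig1, ranks):
    params = FoldParams(rank_floor=ranks["genus"], mintaxa=5)
    folded = fold(fig1, params)
    # G1 accumulates its species (below floor) but at 8 >= mintaxa it stands.
    g1 = folded.find(10)
    assert g1 is not None and g1.self_count == 8
    assert folded.self_count == 2 and folded.self_score == 100.0


@pytest.mark.parametrize("n_passing, expected", [
    (1000, 3), (50000, 5), (9, 1), (1, 1), (31623, 5), (31622, 4)])
def test_default_mintaxa_rounds_half_up_with_floor_one(n_passing, expected):
    assert default_mintaxa(n_passing) == expected


def test_default_mintaxa_rejects_empty_sample():
    with pytest.raises(DegenerateSampleError):
        default_mintaxa(0)


def test_build_tree_structure(mini_tax):
    profile = dx.SampleProfile("s", counts={562: 10, 623: 5, 83333: 2},
                               mean_score={562: 50.0, 623: 60.0, 83333: 70.0})
    tree = build_tree(profile, mini_tax)
    assert tree.taxid == 1
    assert tree.subtree_count() == 17
    family = tree.find(543)
    assert family is not None and len(family.children) == 2  # 191675 + 620
    assert tree.find(562).self_count == 10
    assert tree.find(561).self_count == 0  # unobserved lineage node


def test_build_tree_empty_profile(mini_tax):
    profile = dx.SampleProfile("s")
    tree = build_tree(profile, mini_tax)
    assert tree.subtree_count() == 0 and not tree.children


def test_no_rank_strain_accumulates_into_species(mini_tax):
    profile = dx.SampleProfile("s", counts={83333: 20, 562: 10},
                               mean_score={83333: 80.0, 562: 50.0})
    tree = build_tree(profile, mini_tax)
    folded = fold(tree, FoldParams(rank_floor=mini_tax.rank_order["species"],
                                   mintaxa=1))
    species = folded.find(562)
    assert species.self_count == 30
    assert species.self_score == pytest.approx((80 * 20 + 50 * 10) / 30)
    assert folded.find(83333) is None


def test_no_rank_node_above_floor_survives(mini_tax):
    # 191675 sits between family and genus: above a genus floor it may stand.
    profile = dx.SampleProfile("s", counts={191675: 50, 562: 50},
                               mean_score={191675: 10.0, 562: 20.0})
    tree = build_tree(profile, mini_tax)
    folded = fold(tree, FoldParams(rank_floor=mini_tax.rank_order["genus"],
                                   mintaxa=5))
    assert folded.find(191675) is not None
    # but below a family floor it accumulates
    folded2 = fold(tree, FoldParams(rank_floor=mini_tax.rank_order["family"],
                                    mintaxa=5))
    assert folded2.find(191675) is None
    assert folded2.find(543).self_count == 100


@pytest.mark.parametrize("seed", range(12))
def test_fold_matches_read_level_oracle(seed):
    rng = np.random.default_rng(seed)
    root = random_tree(rng)
    floor = dx.DEFAULT_RANKS[["species", "genus", "family"][seed % 3]]
    params = FoldParams(rank_floor=floor, mintaxa=int(rng.integers(1, 16)))
    expected = oracle_fold(root, params)
    observed = folded_read_map(fold(root, params))
    assert set(observed) == set(expected)
    for taxid, (count, score) in expected.items():
        assert observed[taxid][0] == count
        assert observed[taxid][1] == pytest.approx(score)


@pytest.mark.parametrize("seed", range(8))
def test_fold_conserves_reads_and_score_mass(seed):
    rng = np.random.default_rng(100 + seed)
    root = random_tree(rng)
    params = FoldParams(rank_floor=dx.DEFAULT_RANKS["genus"],
                        mintaxa=int(rng.integers(1, 20)))
    folded = fold(root, params)
    assert folded.subtree_count() == root.subtree_count()
    if root.score_mass():
        assert folded.score_mass() == pytest.approx(root.score_mass(), rel=1e-9)


@pytest.mark.parametrize("seed", range(8))
def test_fold_is_idempotent(seed):
    rng = np.random.default_rng(200 + seed)
    root = random_tree(rng)
    params = FoldParams(rank_floor=dx.DEFAULT_RANKS["genus"],
                        mintaxa=int(rng.integers(1, 20)))
    once = fold(root, params)
    twice = fold(once, params)
    assert twice == once


@pytest.mark.parametrize("seed", range(6))
def test_increasing_mintaxa_never_adds_taxa(seed):
    rng = np.random.default_rng(300 + seed)
    root = random_tree(rng)
    floor = dx.DEFAULT_RANKS["genus"]
    previous = None
    for mintaxa in (1, 2, 5, 10, 25, 60):
        n_taxa = sum(1 for _ in fold(root, FoldParams(rank_floor=floor,
                                                      mintaxa=mintaxa)).iter_nodes())
        if previous is not None:
            assert n_taxa <= previous
        previous = n_taxa


@pytest.mark.parametrize("seed", range(6))
def test_folded_scores_bounded_by_contributors(seed):
    rng = np.random.default_rng(400 + seed)
    root = random_tree(rng)
    scores = [n.self_score for n in root.iter_nodes() if n.self_count]
    if not scores:
        return
    folded = fold(root, FoldParams(rank_floor=dx.DEFAULT_RANKS["genus"],
                                   mintaxa=8))
    for node in folded.iter_nodes():
        if node.self_count:
            assert min(scores) - 1e-9 <= node.self_score <= max(scores) + 1e-9


def test_exclude_removes_subtree_before_folding(mini_tax):
    profile = dx.SampleProfile("s", counts={562: 10, 623: 5},
                               mean_score={562: 50.0, 623: 60.0})
    tree = build_tree(profile, mini_tax)
    params = FoldParams(rank_floor=mini_tax.rank_order["species"], mintaxa=1,
                        exclude=frozenset({620}))
    folded = fold(tree, params)
    assert folded.find(623) is None
    assert folded.subtree_count() == 10


def test_include_keeps_only_selected_clade(mini_tax):
    profile = dx.SampleProfile("s", counts={562: 10, 623: 5, 28901: 3},
                               mean_score={562: 50.0, 623: 60.0, 28901: 70.0})
    tree = build_tree(profile, mini_tax)
    params = FoldParams(rank_floor=mini_tax.rank_order["species"], mintaxa=1,
                        include=frozenset({561}))  # Escherichia genus
    folded = fold(tree, params)
    assert folded.subtree_count() == 10
    assert folded.find(562) is not None
    assert folded.find(623) is None


def test_taxa_at_rank_reports_folded_leaves(mini_tax):
    profile = dx.SampleProfile("s", counts={562: 60, 623: 40},
                               mean_score={562: 50.0, 623: 75.0})
    folded = fold(build_tree(profile, mini_tax),
                  FoldParams(rank_floor=mini_tax.rank_order["species"], mintaxa=1))
    assert taxa_at_rank(folded, mini_tax.rank_order["species"]) == {
        562: (60, 50.0), 623: (40, 75.0)}
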