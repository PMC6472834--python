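"""Level classification, crossover tests and robust control subtraction."""

import json

import numpy as np
import pandas as pd
import pytest

import decontax as dx
from decontax.decontam import (DecontamParams, classify_levels,
                               crossover_sources, relative_frequencies,
                               subtract_controls)
from decontax.errors import DegenerateSampleError, UsageError
from decontax.outputs import node_to_dict
from decontax.scored_tree import tree_from_taxon_counts
from decontax import mockgen as mg


def trees_from_counts(samples, taxonomy):
    """sample -> {taxid: count} to sample -> species-level tree."""
    return {
        name: tree_from_taxon_counts(
            {t: (c, 50.0) for t, c in counts.items()}, taxonomy)
        for name, counts in samples.items()
    }


def test_relative_frequencies_direct_ratio(mini_tax):
    trees = trees_from_counts({"s": {562: 60, 623: 40}}, mini_tax)
    freqs = relative_frequencies(trees, mini_tax.rank_order["species"])
    assert freqs.loc[562, "s"] == pytest.approx(0.6)
    assert freqs.loc[623, "s"] == pytest.approx(0.4)


def test_relative_frequencies_absent_taxon_is_zero_columns_sum_to_one(mini_tax):
    rng = np.random.default_rng(3)
    rank = mini_tax.rank_order["species"]
    for _ in range(20):
        samples = {
            f"s{i}": {t: int(rng.integers(1, 500))
                      for t in rng.choice([562, 623, 28901], size=rng.integers(1, 4),
                                          replace=False)}
            for i in range(3)
        }
        freqs = relative_frequencies(trees_from_counts(samples, mini_tax), rank)
        assert freqs.sum(axis=0).to_numpy() == pytest.approx(np.ones(3))
        for taxid in freqs.index:
            for name, counts in samples.items():
                if taxid not in counts:
                    assert freqs.loc[taxid, name] == 0.0


def test_relative_frequencies_degenerate_sample(mini_tax):
    trees = trees_from_counts({"s": {}}, mini_tax)
    with pytest.raises(DegenerateSampleError):
        relative_frequencies(trees, mini_tax.rank_order["species"])


def test_classify_levels_thresholds():
    params = DecontamParams()
    controls = pd.DataFrame({"c1": [0.25, 0.05, 0.002, 5e-4, 0.3]},
                            index=[10, 20, 30, 40, 50])
    present = {10: True, 20: True, 30: True, 40: True, 50: False}
    levels = classify_levels(controls, present, params)
    assert levels == {10: "critical", 20: "severe", 30: "mild",
                      40: "other",       # below the mild cutoff
                      50: "other"}       # control-only: nothing to remove from


def test_classify_levels_requires_controls():
    with pytest.raises(UsageError):
        classify_levels(pd.DataFrame(index=[1]), {}, DecontamParams())


def test_crossover_worked_example():
    # controls {1e-5, 2e-5}, reals {5e-2, 1e-5, 8e-6}; delta=3, xi=2:
    # median 1e-5, Qn = 3.4760 * 2e-6, outlier cut ~3.086e-5, magnitude cut 2e-3
    values = np.array([1e-5, 2e-5, 5e-2, 1e-5, 8e-6])
    names = ["c1", "c2", "r1", "r2", "r3"]
    sources = crossover_sources(values, names, 2, DecontamParams(delta=3, xi=2))
    assert sources == {"r1"}


def test_crossover_boundary_is_strict():
    controls = [1e-5, 2e-5]
    exact = 10.0 ** 2 * max(controls)  # exactly the magnitude threshold
    values = np.array(controls + [exact, 1e-5, 8e-6])
    names = ["c1", "c2", "r1", "r2", "r3"]
    sources = crossover_sources(values, names, 2, DecontamParams(delta=3, xi=2))
    assert "r1" not in sources


def test_crossover_equal_frequencies_no_source():
    values = np.full(6, 0.125)
    names = [f"s{i}" for i in range(6)]
    assert crossover_sources(values, names, 2, DecontamParams()) == frozenset()


@pytest.mark.parametrize("param", ["delta", "xi"])
def test_raising_delta_or_xi_is_monotone(param):
    rng = np.random.default_rng(11)
    names = [f"s{i}" for i in range(8)]
    for _ in range(25):
        values = rng.exponential(1e-3, size=8)
        previous = None
        for value in (1.0, 2.0, 3.0, 5.0, 8.0):
            params = DecontamParams(**{param: value})
            sources = crossover_sources(values, names, 2, params)
            if previous is not None:
                assert sources <= previous
            previous = sources


def fig2_like_trees(mini_tax):
    """2 controls + 3 reals: two general contaminants and one crossover
    taxon whose source is sample r1 (mirrors the removal illustration)."""
    contaminant_a, contaminant_b, crossover, native = 562, 623, 28901, 573
    counts = {
        "c1": {contaminant_a: 3000, contaminant_b: 800, crossover: 2},
        "c2": {contaminant_a: 2800, contaminant_b: 900, crossover: 3},
        "r1": {contaminant_a: 2000, contaminant_b: 500, crossover: 6000, native: 1500},
        "r2": {contaminant_a: 2500, contaminant_b: 600, crossover: 8, native: 1200},
        "r3": {contaminant_a: 2200, contaminant_b: 700, crossover: 9, native: 1100},
    }
    return trees_from_counts(counts, mini_tax), (contaminant_a, contaminant_b,
                                                 crossover, native)


def test_subtract_controls_fig2_pattern(mini_tax):
    trees, (cont_a, cont_b, crossover, native) = fig2_like_trees(mini_tax)
    rank = mini_tax.rank_order["species"]
    ctrl, report = subtract_controls(trees, 2, rank, DecontamParams(delta=3, xi=2))
    # general contaminants removed from every real sample
    for sample in ("r1", "r2", "r3"):
        assert cont_a not in ctrl[sample]
        assert cont_b not in ctrl[sample]
    # crossover kept only in its source sample
    assert crossover in ctrl["r1"]
    assert crossover not in ctrl["r2"] and crossover not in ctrl["r3"]
    decision = report.decisions[crossover]
    assert decision.crossover and decision.source_samples == {"r1"}
    assert decision.removed_from == {"r2", "r3"}
    # native species untouched (never a candidate)
    assert native in ctrl["r1"] and native not in report.decisions


def test_subtract_controls_never_adds_taxa_and_keeps_counts(mini_tax):
    trees, _ = fig2_like_trees(mini_tax)
    rank = mini_tax.rank_order["species"]
    ctrl, _ = subtract_controls(trees, 2, rank)
    for sample, profile in ctrl.items():
        before = dx.taxa_at_rank(trees[sample], rank)
        assert set(profile) <= set(before)
        for taxid, value in profile.items():
            assert value == before[taxid]  # surviving counts/scores unchanged


def test_controls_not_modified(mini_tax):
    trees, _ = fig2_like_trees(mini_tax)
    rank = mini_tax.rank_order["species"]
    snapshot = {name: json.dumps(node_to_dict(tree, mini_tax), sort_keys=True)
                for name, tree in trees.items()}
    subtract_controls(trees, 2, rank)
    after = {name: json.dumps(node_to_dict(tree, mini_tax), sort_keys=True)
             for name, tree in trees.items()}
    assert after == snapshot


def test_no_shared_taxa_means_no_removal(mini_tax):
    trees = trees_from_counts({
        "c1": {562: 100}, "r1": {623: 100, 28901: 50}}, mini_tax)
    rank = mini_tax.rank_order["species"]
    ctrl, report = subtract_controls(trees, 1, rank)
    assert set(ctrl["r1"]) == {623, 28901}
    assert all(not d.removed_from for d in report.decisions.values())


def test_other_taxon_with_no_source_removed_unless_keep_other(mini_tax):
    counts = {
        "c1": {562: 10000, 623: 4},  # 623 at 4e-4: "other" level
        "r1": {562: 9000, 623: 5, 28901: 1000},
        "r2": {562: 8000, 623: 6, 28901: 900},
    }
    rank = mini_tax.rank_order["species"]
    ctrl, report = subtract_controls(trees_from_counts(counts, mini_tax), 1, rank)
    assert report.decisions[623].level == "other"
    assert not report.decisions[623].crossover
    assert 623 not in ctrl["r1"] and 623 not in ctrl["r2"]

    ctrl2, _ = subtract_controls(trees_from_counts(counts, mini_tax), 1, rank,
                                 DecontamParams(keep_other=True))
    assert 623 in ctrl2["r1"] and 623 in ctrl2["r2"]


def test_known_contaminants_injected_at_mild_level(mini_tax):
    counts = {
        "c1": {562: 100},
        "r1": {562: 90, 623: 500, 28901: 400},
    }
    rank = mini_tax.rank_order["species"]
    ctrl, report = subtract_controls(trees_from_counts(counts, mini_tax), 1, rank,
                                     known_contaminants={623})
    assert report.decisions[623].level == "mild"
    assert 623 not in ctrl["r1"] and 28901 in ctrl["r1"]


def test_report_audit_trail_on_mock(mock_decontam, mock_folded, species_rank):
    ctrl, report = mock_decontam
    reals = [s for s in mock_folded if not s.startswith("ctrl")]
    for sample in reals:
        before = set(dx.taxa_at_rank(mock_folded[sample], species_rank))
        removed = before - set(ctrl[sample])
        for taxid in removed:
            decision = report.decisions[taxid]
            assert sample in decision.removed_from
            assert decision.level in ("critical", "severe", "mild", "other")
        # report never names a survivor as removed from this sample
        assert removed == report.removed(sample) & before


def test_source_samples_disjoint_from_removed_and_never_controls(mock_decontam):
    _, report = mock_decontam
    for decision in report.decisions.values():
        assert not (decision.source_samples & decision.removed_from)
        assert bool(decision.source_samples) == decision.crossover
        assert all(not s.startswith("ctrl") for s in decision.source_samples)
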