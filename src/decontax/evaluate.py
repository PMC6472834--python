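"""Score decontamination results against a mock truth table (ROC harness).

For each real sample, the evaluation universe is the set of taxa present in
its *raw* folded profile at the rank of interest (absent taxa are not counted
as true negatives).  A retained native taxon is a TP, a removed native an FN,
a retained contaminant an FP and a removed contaminant a TN; sensitivity is
TP/(TP+FN) and specificity TN/(TN+FP).  The raw baseline treats every
observed taxon as retained.  ``mintaxa_sweep`` re-folds and re-decontaminates
the dataset for a series of mintaxa values to chart the parameter's effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .classifier_io import SampleProfile
from .decontam import DecontamParams, subtract_controls
from .errors import EvaluationError
from .scored_tree import FoldParams, ScoredNode, build_tree, fold, taxa_at_rank
from .taxonomy import Rank, Taxonomy


@dataclass
class ConfusionResult:
    """Per-sample confusion counts over the evaluated candidate taxa."""

    sample: str
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else math.nan

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else math.nan


def fold_truth(truth: pd.DataFrame, taxonomy: Taxonomy, rank: Rank) -> pd.DataFrame:
    """Collapse a taxid-level truth table to ``rank``.

    Each taxid maps to its ancestor at or above the rank; a collapsed taxon
    is NATIVE in a sample if any constituent is, else CONTAMINANT if any is
    present, else ABSENT.
    """
    order = {"ABSENT": 0, "CONTAMINANT": 1, "NATIVE": 2}
    grouped: dict[int, dict[str, str]] = {}
    for taxid, row in truth.iterrows():
        anc = taxonomy.ancestor_at_or_above(int(taxid), rank)
        target = grouped.setdefault(anc, {})
        for sample, label in row.items():
            if order[label] > order.get(target.get(sample, "ABSENT"), 0):
                target[sample] = label
    frame = pd.DataFrame.from_dict(grouped, orient="index").fillna("ABSENT")
    frame.index.name = "taxid"
    return frame.sort_index()


def score_against_truth(
    retained: Mapping[str, Iterable[int]],
    universe: Mapping[str, Iterable[int]],
    truth: pd.DataFrame,
    taxonomy: Taxonomy,
    rank: Rank,
) -> dict[str, ConfusionResult]:
    """Confusion counts per sample at ``rank``.

    ``retained`` maps sample -> taxa surviving removal; ``universe`` maps
    sample -> taxa of the raw folded sample (the candidates evaluated).
    A universe taxon the folded truth does not cover is a design mismatch.
    """
    truth_k = fold_truth(truth, taxonomy, rank)
    results: dict[str, ConfusionResult] = {}
    for sample, taxa in universe.items():
        result = ConfusionResult(sample=sample)
        kept = set(retained.get(sample, ()))
        for taxid in taxa:
            if taxid not in truth_k.index:
                raise EvaluationError(
                    f"taxon {taxid} in sample {sample!r} is not covered by the truth table")
            label = truth_k.loc[taxid, sample]
            if label == "ABSENT":
                raise EvaluationError(
                    f"taxon {taxid} observed in {sample!r} but ABSENT in truth")
            native = label == "NATIVE"
            if taxid in kept:
                if native:
                    result.tp += 1
                else:
                    result.fp += 1
            else:
                if native:
                    result.fn += 1
                else:
                    result.tn += 1
        results[sample] = result
    return results


def confusion_frame(results: Mapping[str, ConfusionResult]) -> pd.DataFrame:
    rows = [
        {"sample": r.sample, "tp": r.tp, "fp": r.fp, "tn": r.tn, "fn": r.fn,
         "sensitivity": r.sensitivity, "specificity": r.specificity}
        for r in results.values()
    ]
    return pd.DataFrame(rows)


def mintaxa_sweep(
    profiles: Mapping[str, SampleProfile],
    n_controls: int,
    taxonomy: Taxonomy,
    truth: pd.DataFrame,
    mintaxa_values: Sequence[int],
    rank: Rank,
    params: DecontamParams | None = None,
) -> pd.DataFrame:
    """Re-run fold + removal per mintaxa value and tabulate the per-sample ROC.

    Returns a frame with columns mintaxa, sample, tp, fp, tn, fn,
    sensitivity, specificity (TSV-ready for plotting).
    """
    params = params or DecontamParams()
    trees = {name: build_tree(profile, taxonomy)
             for name, profile in profiles.items()}
    rows = []
    for mintaxa in mintaxa_values:
        fold_params = FoldParams(rank_floor=rank, mintaxa=mintaxa)
        folded = {name: fold(tree, fold_params) for name, tree in trees.items()}
        ctrl_profiles, _ = subtract_controls(folded, n_controls, rank, params)
        universe = {name: set(taxa_at_rank(folded[name], rank))
                    for name in list(folded)[n_controls:]}
        retained = {name: set(profile) for name, profile in ctrl_profiles.items()}
        results = score_against_truth(retained, universe, truth, taxonomy, rank)
        frame = confusion_frame(results)
        frame.insert(0, "mintaxa", mintaxa)
        rows.append(frame)
    return pd.concat(rows, ignore_index=True)
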