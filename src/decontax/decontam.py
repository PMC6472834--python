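"""Robust negative-control contamination removal with crossover detection.

At a taxonomic rank k, the candidate contaminants are the taxa observed in
any folded control sample.  Candidates are classified by their maximum
relative frequency across the controls into level groups — critical, severe,
mild, other — and critical/severe/mild taxa are removed from every
non-control sample.  "Other" (low-frequency) candidates are then screened for
crossover contamination: a taxon truly native to one sample that bled into
the rest of the batch.  A non-control sample s is accepted as a source of
taxon t iff BOTH strict tests pass on the relative-frequency vector f:

    outlier test:    f(t, s) > median{f(t, 1..S)} + delta * Qn{f(t, 1..S)}
    magnitude test:  f(t, s) > 10^xi * max{f(t, controls)}

Crossover taxa are kept (with their original counts and scores) only in
their source samples; controls are never modified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DegenerateSampleError, UsageError
from .robust_stats import median, qn
from .scored_tree import ScoredNode, taxa_at_rank
from .taxonomy import Rank

LEVELS = ("critical", "severe", "mild", "other")


@dataclass(frozen=True)
class DecontamParams:
    """Tunables of the removal algorithm.

    delta is the outlier cutoff factor (typically 3-5); xi the order-of-
    magnitude gap against the controls (typically 2-3); level_thresholds are
    strictly decreasing cutoffs on the maximum control relative frequency
    bounding the critical, severe and mild groups (anything lower is
    "other").
    """

    delta: float = 3.0
    xi: float = 2.0
    level_thresholds: tuple[float, float, float] = (0.1, 0.01, 0.001)
    keep_other: bool = False

    def __post_init__(self) -> None:
        if self.delta <= 0 or self.xi <= 0:
            raise UsageError("delta and xi must be positive")
        if not all(a > b for a, b in zip(self.level_thresholds,
                                         self.level_thresholds[1:])):
            raise UsageError("level thresholds must be strictly decreasing")


@dataclass
class TaxonDecision:
    """Audit record of the fate of one candidate contaminant."""

    taxid: int
    level: str
    crossover: bool
    source_samples: frozenset[str]
    removed_from: frozenset[str]
    max_control_freq: float


@dataclass
class ContaminationReport:
    """Per-taxon decisions plus the frequency table they were based on."""

    rank: Rank
    decisions: dict[int, TaxonDecision]
    frequencies: pd.DataFrame  # taxid x sample relative frequencies
    n_controls: int

    def removed(self, sample: str) -> set[int]:
        return {t for t, d in self.decisions.items() if sample in d.removed_from}


def relative_frequencies(folded_trees: Mapping[str, ScoredNode],
                         rank: Rank) -> pd.DataFrame:
    """Taxon x sample relative-frequency table at ``rank``.

    f(t, s) = count of t in s / total retained reads of s at that rank, so
    each sample's frequencies over its present taxa sum to 1; absent taxa
    are 0.  A sample retaining no reads at the rank is degenerate.
    """
    columns: dict[str, dict[int, float]] = {}
    for name, tree in folded_trees.items():
        taxa = taxa_at_rank(tree, rank)
        total = sum(count for count, _ in taxa.values())
        if total == 0:
            raise DegenerateSampleError(
                f"sample {name!r} retains no reads at rank {rank.label!r}")
        columns[name] = {t: count / total for t, (count, _) in taxa.items()}
    frame = pd.DataFrame(columns, dtype=float).fillna(0.0)
    frame = frame.reindex(sorted(frame.index))
    return frame[list(folded_trees)]


def classify_levels(control_freqs: pd.DataFrame,
                    present_elsewhere: Mapping[int, bool],
                    params: DecontamParams) -> dict[int, str]:
    """Assign a contamination level to every candidate taxon.

    The level follows the maximum relative frequency across the controls;
    taxa below the mild cutoff — or absent from every non-control sample,
    leaving nothing to remove them from — fall into "other".
    """
    if control_freqs.shape[1] == 0:
        raise UsageError("no control samples")
    crit, sev, mild = params.level_thresholds
    levels: dict[int, str] = {}
    for taxid, row in control_freqs.iterrows():
        top = float(row.max())
        if not present_elsewhere.get(taxid, False):
            levels[taxid] = "other"
        elif top >= crit:
            levels[taxid] = "critical"
        elif top >= sev:
            levels[taxid] = "severe"
        elif top >= mild:
            levels[taxid] = "mild"
        else:
            levels[taxid] = "other"
    return levels


def crossover_sources(values: np.ndarray, sample_names: list[str],
                      n_controls: int, params: DecontamParams) -> frozenset[str]:
    """Non-control samples passing both strict crossover tests for a taxon.

    ``values`` holds the taxon's relative frequencies over all S samples,
    controls first.
    """
    values = np.asarray(values, dtype=float)
    if values.size < n_controls + 1:
        raise UsageError("need at least one non-control sample")
    outlier_cut = median(values) + params.delta * qn(values)
    magnitude_cut = 10.0 ** params.xi * float(values[:n_controls].max())
    return frozenset(
        sample_names[i]
        for i in range(n_controls, values.size)
        if values[i] > outlier_cut and values[i] > magnitude_cut
    )


def subtract_controls(
    folded_trees: Mapping[str, ScoredNode],
    n_controls: int,
    rank: Rank,
    params: DecontamParams | None = None,
    known_contaminants: set[int] | None = None,
) -> tuple[dict[str, dict[int, tuple[int, float]]], ContaminationReport]:
    """Produce CTRL (control-subtracted) profiles for the non-control samples.

    ``folded_trees`` maps sample name -> tree folded at ``rank``, controls
    first (the first ``n_controls`` entries).  Critical/severe/mild
    contaminants are removed from every non-control sample; "other"
    candidates are removed from each non-control sample unless that sample
    passes both crossover tests (with ``keep_other``, an "other" taxon with
    no passing sample is instead kept everywhere).  Controls are never
    modified.  ``known_contaminants`` are injected as pseudo-candidates at
    the mild level.  Remaining taxa keep their folded counts and scores.
    """
    params = params or DecontamParams()
    names = list(folded_trees)
    if not 0 < n_controls < len(names):
        raise UsageError("need at least one control and one non-control sample")
    controls, reals = names[:n_controls], names[n_controls:]

    freqs = relative_frequencies(folded_trees, rank)
    taxa_by_sample = {name: taxa_at_rank(tree, rank)
                      for name, tree in folded_trees.items()}

    candidates = sorted(set().union(*(taxa_by_sample[c].keys() for c in controls)))
    present_elsewhere = {
        t: any(t in taxa_by_sample[r] for r in reals) for t in candidates
    }
    levels = classify_levels(freqs.loc[candidates, controls], present_elsewhere,
                             params)
    for taxid in sorted(known_contaminants or ()):
        if taxid not in levels and taxid in freqs.index:
            levels[taxid] = "mild"

    decisions: dict[int, TaxonDecision] = {}
    for taxid, level in levels.items():
        present_reals = [r for r in reals if taxid in taxa_by_sample[r]]
        max_ctrl = float(freqs.loc[taxid, controls].max()) if taxid in freqs.index else 0.0
        sources: frozenset[str] = frozenset()
        if level == "other":
            sources = crossover_sources(freqs.loc[taxid, names].to_numpy(),
                                        names, n_controls, params)
            if sources:
                removed = frozenset(r for r in present_reals if r not in sources)
            elif params.keep_other:
                removed = frozenset()
            else:
                removed = frozenset(present_reals)
        else:
            removed = frozenset(present_reals)
        decisions[taxid] = TaxonDecision(
            taxid=taxid,
            level=level,
            crossover=bool(sources),
            source_samples=sources,
            removed_from=removed,
            max_control_freq=max_ctrl,
        )

    report = ContaminationReport(rank=rank, decisions=decisions,
                                 frequencies=freqs, n_controls=n_controls)
    ctrl_profiles = {
        r: {t: cs for t, cs in taxa_by_sample[r].items() if r not in _removed_in(decisions, t)}
        for r in reals
    }
    return ctrl_profiles, report


def _removed_in(decisions: dict[int, TaxonDecision], taxid: int) -> frozenset[str]:
    decision = decisions.get(taxid)
    return decision.removed_from if decision else frozenset()
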