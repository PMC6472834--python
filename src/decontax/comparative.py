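"""Derived samples: CTRL, EXCLUSIVE, SHARED, SHARED_CONTROL and SUMMARY.

With S samples of which the first N are negative controls, and T(s) the taxa
of sample s folded to rank k, the derived taxon sets are

    CTRL(s)        = T(s) \\ union over controls n of T(n)
    EXCLUSIVE(s)   = T(s) \\ union over m != s of T(m)
    SHARED         = intersection over all m of T(m)
    SHARED_CONTROL = intersection over non-controls of T(m)
                     \\ union over controls n of T(n)

CTRL and EXCLUSIVE keep the owning sample's folded counts and scores; SHARED
profiles take, per taxon, the minimum count across the contributing samples
(a conservative lower bound on co-occurrence) and the unweighted mean of
their scores.  SUMMARY condenses the per-rank results of one sample into a
single profile where each taxon appears once, at its most specific surviving
rank.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import UsageError
from .scored_tree import ScoredNode, taxa_at_rank
from .taxonomy import Rank

Profile = dict[int, tuple[int, float]]


@dataclass
class DerivedSampleSet:
    """All derived profiles at one rank."""

    rank: Rank
    ctrl: dict[str, Profile]
    exclusive: dict[str, Profile]
    shared: Profile
    shared_control: Profile | None


def _combined(taxa: set[int], samples: Sequence[Profile]) -> Profile:
    """min-count / mean-score profile of ``taxa`` over contributing samples."""
    out: Profile = {}
    for taxid in sorted(taxa):
        counts = [p[taxid][0] for p in samples if taxid in p]
        scores = [p[taxid][1] for p in samples if taxid in p]
        out[taxid] = (min(counts), sum(scores) / len(scores))
    return out


def derive_sets(folded_trees: Mapping[str, ScoredNode], n_controls: int,
                rank: Rank) -> DerivedSampleSet:
    """Compute the four derived sample sets at ``rank``.

    ``folded_trees`` maps sample name -> tree folded at ``rank`` with the
    controls first.  With ``n_controls`` = 0 the CTRL and SHARED_CONTROL
    analyses are skipped (SHARED and EXCLUSIVE remain defined).
    """
    names = list(folded_trees)
    if len(names) < 2:
        raise UsageError("need at least two samples to derive sets")
    if not 0 <= n_controls < len(names):
        raise UsageError("n_controls must be in [0, S)")
    controls, reals = names[:n_controls], names[n_controls:]

    taxa = {name: taxa_at_rank(tree, rank) for name, tree in folded_trees.items()}
    sets = {name: set(p) for name, p in taxa.items()}
    control_union: set[int] = set().union(*(sets[c] for c in controls)) if controls else set()

    ctrl: dict[str, Profile] = {}
    if controls:
        for name in reals:
            keep = sets[name] - control_union
            ctrl[name] = {t: taxa[name][t] for t in sorted(keep)}

    exclusive: dict[str, Profile] = {}
    for name in names:
        others: set[int] = set().union(*(sets[m] for m in names if m != name))
        keep = sets[name] - others
        exclusive[name] = {t: taxa[name][t] for t in sorted(keep)}

    shared_taxa = set.intersection(*sets.values())
    shared = _combined(shared_taxa, [taxa[name] for name in names])

    shared_control: Profile | None = None
    if controls:
        shared_real = set.intersection(*(sets[r] for r in reals)) - control_union
        shared_control = _combined(shared_real, [taxa[r] for r in reals])

    return DerivedSampleSet(rank=rank, ctrl=ctrl, exclusive=exclusive,
                            shared=shared, shared_control=shared_control)


def summarize(per_rank_ctrl: Mapping[Rank, Mapping[str, Profile]],
              ranks_of_interest: Sequence[Rank]) -> dict[str, dict[int, tuple[int, float, Rank]]]:
    """Condense per-rank CTRL profiles into one SUMMARY profile per sample.

    Each taxon is reported once, at the most specific rank of interest where
    it survived.
    """
    if not per_rank_ctrl:
        raise UsageError("no ranks computed")
    ordered = sorted(ranks_of_interest, key=lambda r: r.order_index)
    samples: list[str] = []
    for profiles in per_rank_ctrl.values():
        for name in profiles:
            if name not in samples:
                samples.append(name)
    summary: dict[str, dict[int, tuple[int, float, Rank]]] = {s: {} for s in samples}
    for rank in ordered:
        profiles = per_rank_ctrl.get(rank, {})
        for name, profile in profiles.items():
            for taxid, (count, score) in profile.items():
                summary[name].setdefault(taxid, (count, score, rank))
    return summary
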