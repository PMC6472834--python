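# Methods

## Scored taxonomic trees and folding

Each parsed sample is a map taxid → (read count *n*, mean classification
score *σ*), embedded in the NCBI taxid tree so that every observed taxon's
full lineage is present (unobserved lineage nodes carry zero reads). Folding
prepares a sample for comparison at a rank of interest: working strictly
post-order (leaves first), a node is accumulated into its parent when its
accumulated subtree count is below `mintaxa` or its rank is below the rank
floor. Accumulation adds the child subtree's reads to the parent and updates
the parent score to the count-weighted mean

σ′p = (σp·np + Σi σi·ni) / (np + Σi ni).

The order in which siblings are absorbed is immaterial because the batch
weighted mean is associative, and a parent with no reads of its own enters
the mean with weight zero (its pre-fold score is undefined and never used).
Two invariants follow and are asserted in the tests to 1e-9 relative
tolerance: the root's subtree count and the total score mass
Σ n·σ are unchanged by folding, folding is idempotent, and raising
`mintaxa` can only shrink the set of retained taxa. The `mintaxa` retention
test uses the *accumulated* subtree count, so a node that absorbs its
children is re-tested at its new size before its own fate is decided.

Nodes without a defined rank ("no rank", "clade", …) survive folding only
when they lie on the ancestor side of the rank floor — concretely, when
their nearest ranked ancestor is strictly above the floor. Strains beneath a
species therefore always accumulate into the species at a species-level
analysis, while unranked clades between family and genus survive a
genus-level one. This keeps every folded leaf at a well-defined rank at or
above the floor.

`mintaxa` defaults per sample to round-half-up(log₁₀ n_passing), clamped to
at least 1, where n_passing counts the reads passing `minscore`; controls
may override it independently (`--ctrlmintaxa`), as may `--mintaxa` for real
samples. Include/exclude taxid lists prune subtrees *before* folding so that
removed reads never pollute parent scores.

## Rank order

The rank vocabulary is a strictly ordered list from most specific to most
general (isolate … forma … subspecies < species < … < superkingdom <
domain), with a NO_RANK sentinel excluded from comparisons. Because taxonomy
releases change the rank set, the list is configurable
(`RankOrder.from_file`, one label per line); the built-in default covers the
current NCBI vocabulary. Labels outside the vocabulary map to NO_RANK rather
than erroring, which is how "clade" nodes are handled.

## Classifier input

Centrifuge, Kraken and CLARK outputs are parsed natively; anything else goes
through the generic delimited parser with a 1-based column spec. Score
schemes: RAW (classifier-native, default), LENGTH, LOGLENGTH (log₂ read
length, for variable-length long-read data) and SCORE_PER_BASE. Kraken
prints no per-read score, so the package derives one as the fraction of a
read's non-ambiguous k-mer LCA hits lying within the assigned clade, scaled
to [0, 100] — a package convention, documented as such. Centrifuge
multi-match rows keep only the first (best) row per read id so the
accounting identity n_total = unclassified + lost + failed-minscore +
n_passing holds exactly; it is asserted for every parsed file. Taxids
missing from the taxonomy resolve through merged.dmp when available and are
otherwise counted as "lost" with a warning instead of aborting the run.

## Robust contamination removal

At rank *k* the candidates are the union of taxa in the folded control
samples. Levels are assigned from the maximum control relative frequency
with default thresholds critical ≥ 0.1, severe ≥ 0.01, mild ≥ 0.001 —
values not fixed by the procedure itself, chosen here as round
order-of-magnitude cuts and overridable in `DecontamParams`. Taxa below the
mild cutoff, or absent from every real sample (nothing to remove them
from), fall into "other". Critical/severe/mild candidates are removed from
every real sample unconditionally.

"Other" candidates are screened per real sample with two strict tests on
the relative-frequency vector over all S samples: f > median + δ·Qn and
f > 10^ξ·max(controls). Qn is the pairwise-order-statistic scale estimator
with d = 3.4760 (the constant suited to asymmetric, near-exponential data)
and m = C(⌊S/2⌋+1, 2), which reduces to (S/4)(S/2+1) for even S; no further
finite-sample corrections are applied. Defaults δ = 3 and ξ = 2 sit at the
permissive end of their customary ranges (3–5 and 2–3). A sample passing
both tests is a source; crossover taxa are kept with their original folded
counts and scores in their sources and removed elsewhere. An "other" taxon
with no source is removed everywhere by default; `--keep-other` inverts
that one rule for users preferring the reading in which the "other" group
is only touched when a crossover is established. Both tests use the same
rank-k folded trees as the removal itself, so tests and removal see one
consistent view. A user-supplied list of previously known contaminants is
injected at the mild level. Controls are never modified.

Raising δ or ξ is monotone (never yields more sources), and removal never
adds taxa to a sample; both properties are under test.

## Derived samples

CTRL, EXCLUSIVE, SHARED and SHARED_CONTROL follow the set equations in the
README. Counts and scores for the intersection-type profiles are not fixed
by the set algebra; the package takes the minimum count across contributing
samples (a conservative lower bound of co-occurrence) and the unweighted
mean of their scores. SUMMARY condenses the per-rank CTRL profiles so each
taxon appears once at its most specific surviving rank — the rule preserves
maximal resolution without duplicating lineage counts. With zero controls
the CTRL and SHARED_CONTROL analyses are skipped with a logged notice.

## Synthetic data generator

The generator emulates classifier output, not sequencing: exact designed
read counts per (sample, taxon), read ids `<sample>_<taxid>_<serial>`,
constant 100 bp read length, and per-read scores from a normal distribution
floored at zero (mean/sd per taxon) so that `minscore` filtering can be
exercised. It does not simulate sequences, error models or classifier
confusion between related taxa.

The packaged design mirrors a deliberately adversarial validation scenario:
three negative controls and five real samples, one of which (smplH) carries
a 241-species high-complexity roster (synthetic stand-ins; only the
cardinality and role of the original benchmark roster are emulated).
Contaminant analogs span all levels — human at ~0.97 control frequency
(critical), *C. acnes* ~0.025 (severe), *M. globosa* and a contaminant
*M. formicicum* strain ~0.003 (mild) — and two crossover species:
*M. mazei*, ubiquitous but native only to smpl1, and *M. barkeri*, native to
smpl3 and absent from one control. A native *M. formicicum* strain in smpl2
collides with the contaminant strain at species rank, making exactly one
designed false negative. Controls are spiked with designated native taxa at
fractions around 2×10⁻⁴ of their source abundance to emulate control noise
(misclassification/bleed); spikes are restricted to sample-exclusive
natives, whose single-source frequency profile is exactly the signature the
crossover check is designed to rescue, and sized at or above the controls'
default `mintaxa` (4 at the ~10⁴-read control depth) so they genuinely
enter the candidate set instead of folding away. Spike counts are the
deterministic ceiling of fraction × source abundance. Abundances are the
package's own choices within that qualitative structure.

What passing on this mock shows: the algorithm's level routing, crossover
rescue and conservation behavior under realistic frequency contrasts. What
it does not show: robustness to classifier misassignment between sister
taxa, compositional drift between controls, or batch effects — none of
which the generator models.

## Evaluation harness

Per real sample the evaluation universe is the raw folded taxon set at the
rank of interest (taxa absent from a sample are not counted as true
negatives). The strain-level truth table collapses to the evaluation rank
with NATIVE dominating CONTAMINANT dominating ABSENT, so a species with any
native constituent counts as native. The raw baseline treats every observed
taxon as retained. `mintaxa_sweep` re-folds and re-runs the removal per
mintaxa value on the already-parsed profiles — folding is the only
mintaxa-dependent stage, so this equals a full re-run while parsing once.

## Determinism and parallelism

Stage 1 (parsing) runs in a process pool with an order-preserving map;
later stages are sequential at desk scale. All writers use fixed ordering
(children sorted by taxid, rows by sample/count/taxid) and fixed float
formats (scores %.6g, frequencies %.6e), and the generator derives
per-sample RNG streams from the run seed, so outputs are byte-identical
across worker counts and generation order. Degenerate samples (no passing
reads, or nothing retained at a rank) are skipped with a warning and the
run continues.

## Problem sizes

The packaged mock totals roughly 6×10⁵ reads across eight samples; the
full pipeline (generate, parse, fold six ranks, decontaminate, write) runs
in a few seconds, and the property suites use 50-node random trees, 200
random set fixtures and 1000 random Qn vectors. These sizes were chosen as
comfortable desk-scale defaults that still exercise every code path.

## Known limitations

- LMAT output is not parsed natively (its per-read format has no documented
  score mapping); the generic parser is the escape hatch.
- No abundance re-normalization after removal, no diversity statistics, no
  differential-abundance testing — downstream concerns.
- The interactive chart of the original ecosystem is out of scope; the
  Krona-text and JSON writers are renderer-agnostic replacements, and since
  the two-column Krona text dialect cannot carry scores, scores live in the
  JSON output only.
- The Qn "equal zero iff constant data" intuition fails under heavy ties
  (more than m equal pairwise distances); the tests assert only the sound
  direction.
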