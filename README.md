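# decontax

Score-aware comparative analysis of taxonomic classification results for
shotgun metagenomics, with robust removal of negative-control contamination
and detection of crossover (sample-to-sample) contamination.

Low-biomass metagenomic studies are dominated by noise: reagent "kitome" DNA,
host reads, index hopping and crossover bleed between samples of a batch.
When the signal approaches the order of magnitude of that noise, taxa found
in template-free negative controls cannot simply be deleted from every
sample — a taxon truly native to one specimen leaks into the controls too,
and naive subtraction destroys it everywhere. `decontax` parses read-level
classifier output (Centrifuge, Kraken, CLARK, or any delimited format),
organizes each sample into a scored taxonomic tree over the NCBI Taxonomy,
and applies a robust statistical procedure to separate contaminants from
genuine signal.

## The model

**Scored tree folding.** Each taxon *i* in a sample holds *n<sub>i</sub>*
reads with mean classification score *σ<sub>i</sub>*. To compare samples at a
rank of interest *k*, the tree is recursively folded from the leaves: a taxon
is accumulated into its parent *p* when its subtree count is below `mintaxa`
or its rank is below *k*, updating the parent score as the weighted average

σ′<sub>p</sub> = (σ<sub>p</sub>·n<sub>p</sub> + Σ<sub>i</sub> σ<sub>i</sub>·n<sub>i</sub>) / (n<sub>p</sub> + Σ<sub>i</sub> n<sub>i</sub>)

so read counts and total score mass are conserved. `mintaxa` defaults to the
nearest integer of log₁₀ of the reads passing the `minscore` filter.

**Derived samples.** With *S* samples of which the first *N* are negative
controls and T<sub>s→k</sub> the folded taxa of sample *s*:

- CTRL(s) = T<sub>s→k</sub> \ ∪<sub>n≤N</sub> T<sub>n→k</sub>
- EXCLUSIVE(s) = T<sub>s→k</sub> \ ∪<sub>m≠s</sub> T<sub>m→k</sub>
- SHARED = ∩<sub>m</sub> T<sub>m→k</sub>
- SHARED_CONTROL = ∩<sub>m>N</sub> T<sub>m→k</sub> \ ∪<sub>n≤N</sub> T<sub>n→k</sub>

plus a SUMMARY per sample condensing all ranks of interest.

**Robust contamination removal.** Candidate contaminants are the taxa
observed in any control. By their maximum relative frequency
(f<sub>i</sub> = n<sub>i</sub>/Σn<sub>i</sub>) across controls they are
classified as critical, severe, mild or other; the first three classes are
removed from every real sample. Low-frequency ("other") candidates are
screened for crossover contamination: sample *s* is a source of taxon *t*
iff both strict tests pass,

- outliers test: f<sub>ts</sub> > median{f<sub>t1</sub>, …, f<sub>tS</sub>} + δ·Q<sub>n</sub>
- order-of-magnitude test: f<sub>ts</sub> > 10<sup>ξ</sup>·max{f<sub>t1</sub>, …, f<sub>tN</sub>}

where Q<sub>n</sub> = d·{|f<sub>i</sub> − f<sub>j</sub>|; i<j}<sub>(m)</sub>
with d = 3.4760 and m = (S/4)(S/2+1) for even S is the Rousseeuw–Croux scale
estimator (50% breakdown point, suitable for the asymmetric distributions of
relative frequencies). Crossover taxa are kept only in their source samples;
controls are never modified.

## Worked example

```sh
decontax mock --out mock --seed 1        # packaged synthetic dataset
decontax run \
  --file CENTRIFUGE:mock/ctrl1.tsv --file CENTRIFUGE:mock/ctrl2.tsv \
  --file CENTRIFUGE:mock/ctrl3.tsv --file CENTRIFUGE:mock/smpl1.tsv \
  --file CENTRIFUGE:mock/smpl2.tsv --file CENTRIFUGE:mock/smpl3.tsv \
  --file CENTRIFUGE:mock/smpl4.tsv --file CENTRIFUGE:mock/smplH.tsv \
  --nodes mock/taxdump --controls 3 --ranks species --out mock/res
```

The mock dataset holds five real samples (smpl1–smpl4 plus a 241-species
high-complexity sample smplH) and three spiked negative controls, with a
dominant human contaminant, *Cutibacterium acnes* and *Malassezia globosa*
analogs, two *Methanosarcina* crossover species and a two-strain
*Methanobacterium formicicum* collision. `mock/res.species.contamination.tsv`
then contains, among others:

```
taxid    name                        rank     level     crossover  sources  removed_from                     max_control_freq
2208     Methanosarcina barkeri      species  other     true       smpl3    smpl1,smpl2,smpl4,smplH          5.897965e-04
2209     Methanosarcina mazei        species  other     true       smpl1    smpl2,smpl3,smpl4,smplH          5.088023e-04
9606     Homo sapiens                species  critical  false               smpl1,smpl2,smpl3,smpl4,smplH    9.667243e-01
```

reading: human reads are a critical-level contaminant removed everywhere,
while the two *Methanosarcina* species are recognized as crossover
contamination and kept only in their true source samples (smpl1 and smpl3).
`mock/res.species.stats.tsv` holds the per-taxon tables of the raw samples
and of the CTRL/EXCLUSIVE/SHARED/SHARED_CONTROL derived samples, and
`decontax roc --mock-dir mock --out roc.tsv` scores the removal against the
designed truth (specificity rises from 0 to 1 in every real sample at the
default settings, at the cost of a single false negative from the designed
two-strain collision).

The same machinery is available as a library (`decontax.fold`,
`decontax.subtract_controls`, `decontax.derive_sets`, …) on any parsed
samples.

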