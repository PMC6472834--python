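"""Synthetic classifier-output generator driven by a mock design table.

A :class:`MockDesign` assigns each taxon a role — native, one of four
contaminant classes, or crossover (native to named source samples and a
contaminant elsewhere) — and a per-sample read abundance.  :func:`generate`
writes one Centrifuge-format file per sample with exactly the designed read
counts, drawing per-read scores from a truncated-normal model, and spikes
the negative controls with low-frequency reads of designated native taxa to
emulate the misclassification/sequencing noise that makes real controls
imperfect.  A machine-readable truth table is written alongside.

The packaged :func:`default_design` mirrors a challenging validation
scenario: four real samples plus a 241-species high-complexity sample and
three controls, with a dominant human contaminant, *Cutibacterium acnes*
and *Malassezia globosa* analogs, two *Methanosarcina* crossover species
with distinct source samples (one missing from a control), and a
*Methanobacterium formicicum* species carrying one native and one
contaminant strain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier_io import Format
from .errors import DesignError
from .taxonomy import NO_RANK, RankOrder, Taxonomy, DEFAULT_RANKS


class Role(str, Enum):
    NATIVE = "NATIVE"
    CRITICAL_CONT = "CRITICAL_CONT"
    SEVERE_CONT = "SEVERE_CONT"
    MILD_CONT = "MILD_CONT"
    OTHER_CONT = "OTHER_CONT"
    CROSSOVER = "CROSSOVER"


@dataclass(frozen=True)
class TaxonSpec:
    """Role and score model of one designed taxon."""

    taxid: int
    role: Role
    sources: tuple[str, ...] = ()
    score_mean: float = 120.0
    score_sd: float = 15.0
    control_noise: float = 0.0  # spike fraction of the max designed abundance

    def __post_init__(self) -> None:
        if self.role is Role.CROSSOVER and not self.sources:
            raise DesignError(f"crossover taxon {self.taxid} names no source sample")
        if not 0.0 <= self.control_noise < 1.0:
            raise DesignError("control_noise must be in [0, 1)")


@dataclass
class MockDesign:
    """Samples (controls first), taxa roles and the abundance matrix."""

    samples: list[str]
    n_controls: int
    taxa: list[TaxonSpec]
    abundances: dict[int, dict[str, int]]  # taxid -> sample -> reads
    seed: int = 0
    read_length: int = 100

    @property
    def control_samples(self) -> list[str]:
        return self.samples[: self.n_controls]

    @property
    def real_samples(self) -> list[str]:
        return self.samples[self.n_controls:]

    def abundance(self, taxid: int, sample: str) -> int:
        return self.abundances.get(taxid, {}).get(sample, 0)

    def validate(self, taxonomy: Taxonomy) -> None:
        for spec in self.taxa:
            if spec.taxid not in taxonomy:
                raise DesignError(f"design taxid {spec.taxid} absent from taxonomy")
            for source in spec.sources:
                if source not in self.real_samples:
                    raise DesignError(
                        f"crossover source {source!r} is not a real sample")
            for sample, n in self.abundances.get(spec.taxid, {}).items():
                if n < 0:
                    raise DesignError(f"negative abundance for {spec.taxid}/{sample}")

    def spike_count(self, spec: TaxonSpec) -> int:
        """Control spike reads for a native taxon: ceil(fraction * the taxon's
        largest designed abundance)."""
        if spec.role is not Role.NATIVE or spec.control_noise == 0.0:
            return 0
        top = max((self.abundance(spec.taxid, s) for s in self.real_samples),
                  default=0)
        return math.ceil(spec.control_noise * top)

    def reads_in(self, spec: TaxonSpec, sample: str) -> int:
        n = self.abundance(spec.taxid, sample)
        if sample in self.control_samples:
            n += self.spike_count(spec)
        return n

    def truth_table(self) -> pd.DataFrame:
        """taxid x real-sample table of NATIVE / CONTAMINANT / ABSENT."""
        rows = {}
        for spec in self.taxa:
            row = {}
            for sample in self.real_samples:
                if self.abundance(spec.taxid, sample) == 0:
                    row[sample] = "ABSENT"
                elif spec.role is Role.NATIVE:
                    row[sample] = "NATIVE"
                elif spec.role is Role.CROSSOVER:
                    row[sample] = "NATIVE" if sample in spec.sources else "CONTAMINANT"
                else:
                    row[sample] = "CONTAMINANT"
            rows[spec.taxid] = row
        frame = pd.DataFrame.from_dict(rows, orient="index")
        frame.index.name = "taxid"
        return frame.sort_index()

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as out:
            header = ["taxid", "role", "source", "score_mean", "score_sd",
                      "control_noise"] + self.samples
            out.write("\t".join(header) + "\n")
            out.write(f"#controls\t{self.n_controls}\n")
            for spec in self.taxa:
                row = [str(spec.taxid), spec.role.value, ",".join(spec.sources),
                       f"{spec.score_mean:g}", f"{spec.score_sd:g}",
                       f"{spec.control_noise:g}"]
                row += [str(self.abundance(spec.taxid, s)) for s in self.samples]
                out.write("\t".join(row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path, seed: int = 0) -> "MockDesign":
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        header = lines[0].split("\t")
        samples = header[6:]
        n_controls = 0
        taxa: list[TaxonSpec] = []
        abundances: dict[int, dict[str, int]] = {}
        for line in lines[1:]:
            if line.startswith("#controls"):
                n_controls = int(line.split("\t")[1])
                continue
            fields = line.split("\t")
            taxid = int(fields[0])
            sources = tuple(s for s in fields[2].split(",") if s)
            taxa.append(TaxonSpec(taxid, Role(fields[1]), sources,
                                  float(fields[3]), float(fields[4]),
                                  float(fields[5])))
            abundances[taxid] = {
                s: int(v) for s, v in zip(samples, fields[6:]) if int(v) > 0
            }
        return cls(samples=samples, n_controls=n_controls, taxa=taxa,
                   abundances=abundances, seed=seed)


_CENTRIFUGE_HEADER = ("readID\tseqID\ttaxID\tscore\t2ndBestScore\t"
                      "hitLength\tqueryLength\tnumMatches\n")


def generate(design: MockDesign, out_dir: str | Path, taxonomy: Taxonomy,
             format: Format = Format.CENTRIFUGE,
             seed: int | None = None) -> dict[str, Path]:
    """Write one classifier file per sample plus the truth table.

    Deterministic for a given seed (per-sample generators are derived from
    it, so output does not depend on generation order).  Returns a mapping
    of sample name (plus ``"truth"`` and ``"design"``) to written path.
    """
    if Format(format) is not Format.CENTRIFUGE:
        raise DesignError("only Centrifuge-format mock output is supported")
    design.validate(taxonomy)
    base_seed = design.seed if seed is None else seed
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    hit = max(1, int(design.read_length * 0.8))
    for idx, sample in enumerate(design.samples):
        rng = np.random.default_rng([base_seed, idx])
        path = out_dir / f"{sample}.tsv"
        with open(path, "w", encoding="utf-8") as out:
            out.write(_CENTRIFUGE_HEADER)
            for spec in design.taxa:
                n = design.reads_in(spec, sample)
                if n == 0:
                    continue
                scores = np.maximum(
                    0.0, rng.normal(spec.score_mean, spec.score_sd, size=n))
                for serial, score in enumerate(scores):
                    out.write(
                        f"{sample}_{spec.taxid}_{serial:06d}\tmock_{spec.taxid}\t"
                        f"{spec.taxid}\t{score:.1f}\t0\t{hit}\t"
                        f"{design.read_length}\t1\n")
        paths[sample] = path
    truth_path = out_dir / "truth.tsv"
    design.truth_table().to_csv(truth_path, sep="\t")
    paths["truth"] = truth_path
    design_path = out_dir / "design.tsv"
    design.to_tsv(design_path)
    paths["design"] = design_path
    return paths


def mock_taxonomy(rank_order: RankOrder = DEFAULT_RANKS) -> Taxonomy:
    """Fixture taxonomy covering the packaged default design.

    Well-known taxa keep their real NCBI taxids; the synthetic native and
    high-complexity rosters use taxids above 5,000,000 (synthetic stand-ins:
    only the cardinality and roles of the original high-complexity benchmark
    roster are emulated, not its membership).
    """
    parent: dict[int, int] = {}
    rank: dict[int, str] = {}
    name: dict[int, str] = {}

    def add(taxid: int, up: int, rank_label: str, label: str) -> None:
        parent[taxid] = up
        rank[taxid] = rank_label
        name[taxid] = label

    add(1, 1, "no rank", "root")
    add(2, 1, "superkingdom", "Bacteria")
    add(2157, 1, "superkingdom", "Archaea")
    add(2759, 1, "superkingdom", "Eukaryota")
    # Human lineage
    for args in ((7711, 2759, "phylum", "Chordata"),
                 (40674, 7711, "class", "Mammalia"),
                 (9443, 40674, "order", "Primates"),
                 (9604, 9443, "family", "Hominidae"),
                 (9605, 9604, "genus", "Homo"),
                 (9606, 9605, "species", "Homo sapiens")):
        add(*args)
    # Malassezia lineage
    for args in ((5204, 2759, "phylum", "Basidiomycota"),
                 (162484, 5204, "class", "Malasseziomycetes"),
                 (162474, 162484, "order", "Malasseziales"),
                 (742845, 162474, "family", "Malasseziaceae"),
                 (55193, 742845, "genus", "Malassezia"),
                 (76773, 55193, "species", "Malassezia globosa")):
        add(*args)
    # Cutibacterium lineage
    for args in ((201174, 2, "phylum", "Actinobacteria"),
                 (1760, 201174, "class", "Actinomycetia"),
                 (85009, 1760, "order", "Propionibacteriales"),
                 (31957, 85009, "family", "Propionibacteriaceae"),
                 (1912216, 31957, "genus", "Cutibacterium"),
                 (1747, 1912216, "species", "Cutibacterium acnes")):
        add(*args)
    # Methanosarcina lineage (crossover species)
    for args in ((28890, 2157, "phylum", "Euryarchaeota"),
                 (224756, 28890, "class", "Methanomicrobia"),
                 (94695, 224756, "order", "Methanosarcinales"),
                 (2206, 94695, "family", "Methanosarcinaceae"),
                 (2207, 2206, "genus", "Methanosarcina"),
                 (2209, 2207, "species", "Methanosarcina mazei"),
                 (2208, 2207, "species", "Methanosarcina barkeri")):
        add(*args)
    # Methanobacterium formicicum with two strains (no-rank nodes)
    for args in ((183925, 2157, "class", "Methanobacteria"),
                 (2158, 183925, "order", "Methanobacteriales"),
                 (2159, 2158, "family", "Methanobacteriaceae"),
                 (2160, 2159, "genus", "Methanobacterium"),
                 (2162, 2160, "species", "Methanobacterium formicicum"),
                 (2162001, 2162, "no rank", "Methanobacterium formicicum strain DSM-A"),
                 (2162002, 2162, "no rank", "Methanobacterium formicicum strain JCM-B")):
        add(*args)
    # Synthetic bacterial clade hosting the native and high-complexity rosters
    add(5000000, 2, "phylum", "Mockibacterota")
    add(5000001, 5000000, "class", "Mockibacteria")
    add(5000002, 5000001, "order", "Mockibacteriales")
    n_families = 8
    for f in range(n_families):
        add(5100000 + f, 5000002, "family", f"Mockaceae{f + 1}")
    for g in range(50):
        add(5200000 + g, 5100000 + g % n_families, "genus", f"Mockium{g + 1}")
    # 11 designed native species + 241 high-complexity species
    for k in range(11):
        add(5300000 + k, 5200000 + k % 10, "species", f"Mockium nativus{k + 1}")
    for k in range(241):
        add(5310000 + k, 5200000 + 10 + k % 40, "species", f"Mockium diversus{k + 1}")

    taxonomy = Taxonomy(parent=parent,
                        rank={t: rank_order[r] for t, r in rank.items()},
                        name=name, merged={}, root=1, rank_order=rank_order)
    return taxonomy


# Named taxids of the packaged design (module-level for tests and docs).
HUMAN = 9606
C_ACNES = 1747
M_GLOBOSA = 76773
M_MAZEI = 2209
M_BARKERI = 2208
M_FORMICICUM = 2162
MF_STRAIN_NATIVE = 2162001
MF_STRAIN_CONT = 2162002
#: Designed native species of the packaged scenario: sample-exclusive natives
#: (spiked ones marked by a nonzero control_noise in the design) and natives
#: shared between real samples.
NATIVE_SPECIES = {label: 5300000 + k for k, label in enumerate(
    ("excl1a", "excl1b", "excl2a", "excl2b", "excl3a", "excl3b",
     "excl4a", "excl4b", "shared_all", "shared12", "shared34"))}
#: First taxid of the 241-species high-complexity roster (smplH).
HIGH_COMPLEXITY_BASE = 5310000


def default_design(seed: int = 0) -> MockDesign:
    """The packaged validation scenario (see module docstring)."""
    samples = ["ctrl1", "ctrl2", "ctrl3", "smpl1", "smpl2", "smpl3", "smpl4",
               "smplH"]
    n_controls = 3
    taxa: list[TaxonSpec] = []
    abundances: dict[int, dict[str, int]] = {}

    def design(taxid: int, role: Role, abund: dict[str, int],
               sources: tuple[str, ...] = (), noise: float = 0.0,
               score_mean: float = 120.0, score_sd: float = 15.0) -> None:
        taxa.append(TaxonSpec(taxid, role, sources, score_mean, score_sd, noise))
        abundances[taxid] = abund

    design(HUMAN, Role.CRITICAL_CONT,
           {"ctrl1": 10000, "ctrl2": 9500, "ctrl3": 9800, "smpl1": 15000,
            "smpl2": 12000, "smpl3": 9000, "smpl4": 11000, "smplH": 8000},
           score_mean=140.0)
    design(C_ACNES, Role.SEVERE_CONT,
           {"ctrl1": 250, "ctrl2": 230, "ctrl3": 260, "smpl1": 2000,
            "smpl2": 1800, "smpl3": 1500, "smpl4": 1700, "smplH": 1200})
    design(M_GLOBOSA, Role.MILD_CONT,
           {"ctrl1": 25, "ctrl2": 22, "ctrl3": 28, "smpl1": 150, "smpl2": 120,
            "smpl3": 100, "smpl4": 110, "smplH": 90}, score_mean=100.0)
    design(M_MAZEI, Role.CROSSOVER,
           {"ctrl1": 5, "ctrl2": 5, "ctrl3": 5, "smpl1": 12000, "smpl2": 150,
            "smpl3": 130, "smpl4": 140, "smplH": 120}, sources=("smpl1",))
    design(M_BARKERI, Role.CROSSOVER,
           {"ctrl1": 5, "ctrl3": 6, "smpl1": 100, "smpl2": 120, "smpl3": 14000,
            "smpl4": 110, "smplH": 100}, sources=("smpl3",))
    design(MF_STRAIN_NATIVE, Role.NATIVE, {"smpl2": 5000}, score_mean=125.0)
    design(MF_STRAIN_CONT, Role.MILD_CONT,
           {"ctrl1": 30, "ctrl2": 28, "ctrl3": 32, "smpl1": 300, "smpl2": 250,
            "smpl3": 280, "smpl4": 260, "smplH": 240}, score_mean=110.0)

    natives = {
        "excl1a": ({"smpl1": 30000}, 2e-4),
        "excl1b": ({"smpl1": 15000}, 3e-4),
        "excl2a": ({"smpl2": 25000}, 2e-4),
        "excl2b": ({"smpl2": 12000}, 0.0),
        "excl3a": ({"smpl3": 28000}, 2e-4),
        "excl3b": ({"smpl3": 10000}, 0.0),
        "excl4a": ({"smpl4": 26000}, 2e-4),
        "excl4b": ({"smpl4": 9000}, 0.0),
        "shared_all": ({"smpl1": 20000, "smpl2": 18000, "smpl3": 15000,
                        "smpl4": 16000}, 0.0),
        "shared12": ({"smpl1": 10000, "smpl2": 9000}, 0.0),
        "shared34": ({"smpl3": 8000, "smpl4": 7000}, 0.0),
    }
    for label, (abund, noise) in natives.items():
        design(NATIVE_SPECIES[label], Role.NATIVE, abund, noise=noise)

    # High-complexity roster: 241 species, three of them abundant enough to be
    # spiked into the controls as designed crossover-like native noise.
    for k in range(241):
        taxid = 5310000 + k
        if k == 0:
            design(taxid, Role.NATIVE, {"smplH": 25000}, noise=2e-4)
        elif k == 1:
            design(taxid, Role.NATIVE, {"smplH": 22000}, noise=2e-4)
        elif k == 2:
            design(taxid, Role.NATIVE, {"smplH": 20000}, noise=2e-4)
        else:
            design(taxid, Role.NATIVE, {"smplH": 100 + ((k * 37) % 50) * 20})

    return MockDesign(samples=samples, n_controls=n_controls, taxa=taxa,
                      abundances=abundances, seed=seed)
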