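"""Parse read-level taxonomic classifier outputs into per-sample profiles.

Supported formats: Centrifuge TSV, Kraken TSV, CLARK CSV, and a generic
delimited format driven by a column spec.  Parsing applies a score scheme and
the ``minscore`` filter, and keeps a full read-accounting so that

    n_total = unclassified + n_lost + failed-minscore + n_passing

holds for every parsed file.  ``extract_reads`` pulls reads of interest out of
single or paired FASTQ files by their taxonomic assignment.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import PairingError, ParseError, UnknownTaxonError, UsageError
from .taxonomy import Taxonomy

logger = logging.getLogger(__name__)


class Format(str, Enum):
    CENTRIFUGE = "CENTRIFUGE"
    KRAKEN = "KRAKEN"
    CLARK = "CLARK"
    GENERIC = "GENERIC"


class Scheme(str, Enum):
    """Score visualization/filter schemes.

    RAW uses the classifier score as printed.  LENGTH and LOGLENGTH (log2 of
    the read length) serve variable-length nanopore reads; SCORE_PER_BASE
    normalizes the score by read length.
    """

    RAW = "RAW"
    LENGTH = "LENGTH"
    LOGLENGTH = "LOGLENGTH"
    SCORE_PER_BASE = "SCORE_PER_BASE"


@dataclass(frozen=True)
class ClassifiedRead:
    """One read's classification; taxid 0 means unclassified."""

    read_id: str
    taxid: int
    score: float
    read_length: int = 0


@dataclass
class SampleProfile:
    """Per-sample taxid -> (count, mean score) plus read accounting."""

    sample_name: str
    is_control: bool = False
    counts: dict[int, int] = field(default_factory=dict)
    mean_score: dict[int, float] = field(default_factory=dict)
    n_total: int = 0
    n_classified: int = 0
    n_passing: int = 0
    n_lost: int = 0


@dataclass(frozen=True)
class GenericColspec:
    """1-based column indices for the generic delimited format.

    Only ``taxid_col`` is required; score and length default to 0 when their
    columns are absent.  The delimiter is inferred from the file extension
    (.csv -> ',', .tsv -> tab, .ssv -> space) unless set explicitly.
    """

    taxid_col: int
    score_col: int | None = None
    length_col: int | None = None
    read_id_col: int | None = None
    delimiter: str | None = None


def _infer_delimiter(path: str | Path, colspec: GenericColspec | None) -> str:
    if colspec is not None and colspec.delimiter is not None:
        return colspec.delimiter
    suffix = Path(path).suffix.lower()
    return {".csv": ",", ".ssv": " "}.get(suffix, "\t")


def scheme_score(read: ClassifiedRead, scheme: Scheme) -> float:
    if scheme is Scheme.RAW:
        return read.score
    if scheme is Scheme.LENGTH:
        return float(read.read_length)
    if scheme is Scheme.LOGLENGTH:
        return math.log2(read.read_length) if read.read_length > 1 else 0.0
    if scheme is Scheme.SCORE_PER_BASE:
        return read.score / read.read_length if read.read_length else 0.0
    raise UsageError(f"unknown score scheme: {scheme}")


def _num(value: str, path, lineno: int, kind=float):
    try:
        return kind(value)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: non-numeric field {value!r}") from None


def _iter_centrifuge(path: str | Path) -> Iterator[ClassifiedRead]:
    # Multi-match rows (numMatches > 1) repeat a read id consecutively with
    # the best hit first; only the first row per read id is kept so the
    # accounting identity is not broken by double counting.
    last_id = None
    with open(path, encoding="utf-8") as handle:
        for lineno, row in enumerate(csv.reader(handle, delimiter="\t"), start=1):
            if not row:
                continue
            if lineno == 1 and row[0] == "readID":
                continue
            if len(row) < 7:
                raise ParseError(f"{path}:{lineno}: expected >=7 fields, got {len(row)}")
            read_id = row[0]
            if read_id == last_id:
                continue
            last_id = read_id
            if row[1] == "unclassified":
                yield ClassifiedRead(read_id, 0, 0.0, _num(row[6], path, lineno, int))
                continue
            yield ClassifiedRead(
                read_id,
                _num(row[2], path, lineno, int),
                _num(row[3], path, lineno),
                _num(row[6], path, lineno, int),
            )


def _kraken_read_score(pairs: str, taxid: int, taxonomy: Taxonomy | None,
                       cache: dict[int, bool]) -> float:
    """Fraction of k-mer LCA hits within the assigned clade, scaled to [0,100].

    A package convention (Kraken prints no per-read score): hits at the
    assigned taxid or any of its descendants count as in-clade; ambiguous
    ('A') k-mers are ignored; unmatched ('0') k-mers stay in the denominator.
    """
    total = 0
    in_clade = 0
    for pair in pairs.split():
        key, _, count = pair.partition(":")
        if key == "A":
            continue
        n = int(count)
        total += n
        if key == "0":
            continue
        hit = int(key)
        ok = cache.get(hit)
        if ok is None:
            if taxonomy is None or hit not in taxonomy:
                ok = hit == taxid
            else:
                ok = taxonomy.is_ancestor(taxid, hit)
            cache[hit] = ok
        if ok:
            in_clade += n
    return 100.0 * in_clade / total if total else 0.0


def _iter_kraken(path: str | Path, taxonomy: Taxonomy | None) -> Iterator[ClassifiedRead]:
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            row = line.rstrip("\n").split("\t")
            if row == [""]:
                continue
            if len(row) < 4:
                raise ParseError(f"{path}:{lineno}: expected >=4 fields, got {len(row)}")
            flag, read_id, taxid_s, length_s = row[0], row[1], row[2], row[3]
            length = _num(length_s.split("|")[0], path, lineno, int)
            if flag == "U":
                yield ClassifiedRead(read_id, 0, 0.0, length)
                continue
            taxid = _num(taxid_s, path, lineno, int)
            cache: dict[int, bool] = {}
            score = _kraken_read_score(row[4] if len(row) > 4 else "", taxid,
                                       taxonomy, cache)
            yield ClassifiedRead(read_id, taxid, score, length)


def _iter_clark(path: str | Path) -> Iterator[ClassifiedRead]:
    with open(path, encoding="utf-8") as handle:
        for lineno, row in enumerate(csv.reader(handle), start=1):
            if not row:
                continue
            if len(row) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 fields, got {len(row)}")
            if lineno == 1 and not row[2].strip().isdigit() and row[2].strip() != "NA":
                continue  # header
            assignment = row[2].strip()
            taxid = 0 if assignment in ("NA", "") else _num(assignment, path, lineno, int)
            yield ClassifiedRead(row[0], taxid, 0.0, _num(row[1], path, lineno, int))


def _iter_generic(path: str | Path, colspec: GenericColspec) -> Iterator[ClassifiedRead]:
    delim = _infer_delimiter(path, colspec)
    need = max(c for c in (colspec.taxid_col, colspec.score_col,
                           colspec.length_col, colspec.read_id_col) if c)
    with open(path, encoding="utf-8") as handle:
        for lineno, row in enumerate(csv.reader(handle, delimiter=delim), start=1):
            if not row:
                continue
            if len(row) < need:
                raise ParseError(f"{path}:{lineno}: expected >={need} fields, got {len(row)}")
            raw_taxid = row[colspec.taxid_col - 1].strip()
            if lineno == 1 and not raw_taxid.lstrip("-").isdigit():
                continue  # header tolerated
            taxid = _num(raw_taxid, path, lineno, int)
            score = (_num(row[colspec.score_col - 1], path, lineno)
                     if colspec.score_col else 0.0)
            length = (_num(row[colspec.length_col - 1], path, lineno, int)
                      if colspec.length_col else 0)
            read_id = (row[colspec.read_id_col - 1]
                       if colspec.read_id_col else f"row{lineno}")
            yield ClassifiedRead(read_id, taxid, score, length)


def iter_reads(path: str | Path, format: Format,
               taxonomy: Taxonomy | None = None,
               colspec: GenericColspec | None = None) -> Iterator[ClassifiedRead]:
    """Yield every read record of a classifier output file (taxid 0 when
    unclassified)."""
    format = Format(format)
    if format is Format.CENTRIFUGE:
        return _iter_centrifuge(path)
    if format is Format.KRAKEN:
        return _iter_kraken(path, taxonomy)
    if format is Format.CLARK:
        return _iter_clark(path)
    if format is Format.GENERIC:
        if colspec is None:
            raise UsageError("GENERIC format requires a column spec")
        return _iter_generic(path, colspec)
    raise UsageError(f"unknown format: {format}")


def parse_sample(path: str | Path, format: Format, taxonomy: Taxonomy,
                 minscore: float = 0.0, scheme: Scheme = Scheme.RAW,
                 colspec: GenericColspec | None = None,
                 sample_name: str | None = None,
                 is_control: bool = False) -> SampleProfile:
    """Parse one classifier output file into a :class:`SampleProfile`.

    Reads with scheme score below ``minscore`` are excluded from counts but
    tallied; unknown taxids (not even in merged.dmp) increment ``n_lost``
    with a warning rather than aborting the run.  ``mean_score`` is the
    arithmetic mean of the scheme scores of each taxon's passing reads.
    """
    name = sample_name if sample_name is not None else Path(path).stem
    profile = SampleProfile(sample_name=name, is_control=is_control)
    sums: dict[int, float] = {}
    for read in iter_reads(path, format, taxonomy=taxonomy, colspec=colspec):
        profile.n_total += 1
        if read.taxid == 0:
            continue
        try:
            taxid = taxonomy.resolve(read.taxid)
        except UnknownTaxonError:
            profile.n_lost += 1
            logger.warning("%s: unknown taxid %d for read %s (counted as lost)",
                           path, read.taxid, read.read_id)
            continue
        profile.n_classified += 1
        score = scheme_score(read, scheme)
        if score < minscore:
            continue
        profile.n_passing += 1
        profile.counts[taxid] = profile.counts.get(taxid, 0) + 1
        sums[taxid] = sums.get(taxid, 0.0) + score
    for taxid, total in sums.items():
        profile.mean_score[taxid] = total / profile.counts[taxid]
    # Canonical ordering: a permutation of input rows yields identical profiles.
    profile.counts = dict(sorted(profile.counts.items()))
    profile.mean_score = dict(sorted(profile.mean_score.items()))
    return profile


def _base_id(title: str) -> str:
    rid = title.split()[0]
    if rid.endswith("/1") or rid.endswith("/2"):
        rid = rid[:-2]
    return rid


def extract_reads(classifier_output: str | Path, format: Format,
                  fastq_paths: Iterable[str | Path],
                  target_taxa: set[int], taxonomy: Taxonomy,
                  include_descendants: bool = True,
                  out_paths: Iterable[str | Path] | None = None,
                  colspec: GenericColspec | None = None) -> int:
    """Write the FASTQ reads assigned to ``target_taxa`` to the output files.

    With ``include_descendants`` a read matches when any ancestor of its
    assigned taxid is a target.  In paired mode both mates of a fragment are
    kept iff the fragment matches (ids may carry /1 /2 suffixes); output
    order follows input order.  Returns the number of records written.
    """
    if not target_taxa:
        raise UsageError("empty target taxid set")
    fastq_paths = [Path(p) for p in fastq_paths]
    if len(fastq_paths) not in (1, 2):
        raise UsageError("expected 1 or 2 FASTQ files")
    if out_paths is None:
        out_paths = [p.with_suffix(p.suffix + ".extracted") for p in fastq_paths]
    out_paths = [Path(p) for p in out_paths]
    if len(out_paths) != len(fastq_paths):
        raise UsageError("one output path per FASTQ input required")

    match_cache: dict[int, bool] = {}

    def matches(taxid: int) -> bool:
        if taxid == 0:
            return False
        hit = match_cache.get(taxid)
        if hit is None:
            if not include_descendants:
                hit = taxid in target_taxa
            else:
                hit = (taxid in taxonomy
                       and any(t in target_taxa for t in taxonomy.lineage(taxid)))
            match_cache[taxid] = hit
        return hit

    wanted = {
        _base_id(read.read_id)
        for read in iter_reads(classifier_output, format, taxonomy=taxonomy,
                               colspec=colspec)
        if matches(read.taxid)
    }

    written = 0
    handles = [open(p, "w", encoding="utf-8") for p in out_paths]
    try:
        iters = [FastqGeneralIterator(open(p, encoding="utf-8")) for p in fastq_paths]
        if len(iters) == 1:
            for title, seq, qual in iters[0]:
                if _base_id(title) in wanted:
                    handles[0].write(f"@{title}\n{seq}\n+\n{qual}\n")
                    written += 1
        else:
            for rec1, rec2 in zip(*iters):
                id1, id2 = _base_id(rec1[0]), _base_id(rec2[0])
                if id1 != id2:
                    raise PairingError(f"mate id mismatch: {id1!r} vs {id2!r}")
                if id1 in wanted:
                    for handle, (title, seq, qual) in zip(handles, (rec1, rec2)):
                        handle.write(f"@{title}\n{seq}\n+\n{qual}\n")
                    written += 2
    finally:
        for handle in handles:
            handle.close()
    return written
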