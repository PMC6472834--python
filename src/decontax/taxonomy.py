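"""NCBI-style taxonomy: taxid tree, ranks, names, loaded from dump files.

The taxonomy is a rooted tree of integer taxids (root's parent is itself, per
the NCBI convention for taxid 1).  Each node carries a rank drawn from a
strictly ordered rank vocabulary (*form* < *variety* < *subspecies* < ... <
*domain*) plus a ``no rank`` sentinel that is excluded from order comparisons.
The rank vocabulary is configurable because taxonomy releases change rank sets.

Dump dialect: fields separated by ``\\t|\\t``, records terminated by ``\\t|``.
``nodes.dmp`` fields 1-3 are taxid, parent, rank; ``names.dmp`` fields 1, 2, 4
are taxid, name, name class (only ``scientific name`` rows are kept);
``merged.dmp`` fields 1-2 map an obsolete taxid to its replacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .errors import ParseError, RankOrderError, StructuralError, UnknownTaxonError

#: Canonical rank labels from most specific to most general.  Releases of the
#: NCBI Taxonomy add and remove ranks, so this list is a default, not a law:
#: pass a custom ordered list (or file) to :class:`RankOrder` to override it.
DEFAULT_RANK_LABELS: tuple[str, ...] = (
    "isolate",
    "strain",
    "forma",
    "forma specialis",
    "varietas",
    "subvariety",
    "subspecies",
    "species",
    "species subgroup",
    "species group",
    "series",
    "subsection",
    "section",
    "subgenus",
    "genus",
    "subtribe",
    "tribe",
    "subfamily",
    "family",
    "superfamily",
    "parvorder",
    "infraorder",
    "suborder",
    "order",
    "superorder",
    "subcohort",
    "cohort",
    "infraclass",
    "subclass",
    "class",
    "superclass",
    "subphylum",
    "phylum",
    "superphylum",
    "subkingdom",
    "kingdom",
    "superkingdom",
    "domain",
)

_SYNONYMS = {"form": "forma", "variety": "varietas"}


@dataclass(frozen=True)
class Rank:
    """A taxonomic rank with its position in the strict rank order.

    ``order_index`` is -1 for the NO_RANK sentinel, which is excluded from
    all order comparisons.
    """

    label: str
    order_index: int

    @property
    def is_no_rank(self) -> bool:
        return self.order_index < 0

    def _check(self, other: "Rank") -> None:
        if self.is_no_rank or other.is_no_rank:
            raise RankOrderError("NO_RANK is not comparable in the rank order")

    def __lt__(self, other: "Rank") -> bool:
        self._check(other)
        return self.order_index < other.order_index

    def __le__(self, other: "Rank") -> bool:
        self._check(other)
        return self.order_index <= other.order_index

    def __gt__(self, other: "Rank") -> bool:
        self._check(other)
        return self.order_index > other.order_index

    def __ge__(self, other: "Rank") -> bool:
        self._check(other)
        return self.order_index >= other.order_index

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Rank({self.label!r})"


#: Sentinel for nodes without a defined rank (NCBI "no rank", "clade", ...).
NO_RANK = Rank("no rank", -1)


def rank_ge(a: Rank, b: Rank) -> bool:
    """True iff ``a`` is equal to or more general than ``b``.

    Raises :class:`RankOrderError` if either operand is NO_RANK.
    """
    return a >= b


class RankOrder:
    """An ordered rank vocabulary mapping labels to :class:`Rank` objects.

    Labels not in the vocabulary (e.g. ``clade``) map to :data:`NO_RANK`.
    """

    def __init__(self, labels: Iterable[str] = DEFAULT_RANK_LABELS):
        self._ranks: dict[str, Rank] = {}
        for i, label in enumerate(labels):
            label = label.strip().lower()
            self._ranks[label] = Rank(label, i)

    @classmethod
    def from_file(cls, path: str | Path) -> "RankOrder":
        """Read one rank label per line, most specific first; '#' comments."""
        labels = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if line and not line.startswith("#"):
                labels.append(line)
        return cls(labels)

    def __getitem__(self, label: str) -> Rank:
        label = label.strip().lower()
        label = _SYNONYMS.get(label, label)
        return self._ranks.get(label, NO_RANK)

    def require(self, label: str) -> Rank:
        rank = self[label]
        if rank.is_no_rank:
            raise RankOrderError(f"unknown rank label: {label!r}")
        return rank

    def __len__(self) -> int:
        return len(self._ranks)

    def labels(self) -> list[str]:
        return list(self._ranks)


DEFAULT_RANKS = RankOrder()


@dataclass
class Taxonomy:
    """In-memory taxid tree with per-node rank and scientific name."""

    parent: dict[int, int]
    rank: dict[int, Rank]
    name: dict[int, str]
    merged: dict[int, int] = field(default_factory=dict)
    root: int = 1
    rank_order: RankOrder = field(default_factory=lambda: DEFAULT_RANKS)

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.parent or taxid in self.merged

    def resolve(self, taxid: int) -> int:
        """Map an obsolete taxid through merged.dmp; raise if unknown."""
        if taxid in self.parent:
            return taxid
        if taxid in self.merged:
            new = self.merged[taxid]
            if new in self.parent:
                return new
        raise UnknownTaxonError(f"unknown taxid: {taxid}")

    def lineage(self, taxid: int) -> list[int]:
        """Taxids from root down to (and including) ``taxid``."""
        taxid = self.resolve(taxid)
        path = [taxid]
        while taxid != self.parent[taxid]:
            taxid = self.parent[taxid]
            path.append(taxid)
        path.reverse()
        return path

    def is_ancestor(self, ancestor: int, taxid: int) -> bool:
        """True iff ``ancestor`` is ``taxid`` itself or on its root path."""
        taxid = self.resolve(taxid)
        while True:
            if taxid == ancestor:
                return True
            up = self.parent[taxid]
            if up == taxid:
                return False
            taxid = up

    def ancestor_at_or_above(self, taxid: int, rank_floor: Rank) -> int:
        """Nearest ancestor (or self) with a defined rank >= ``rank_floor``.

        NO_RANK nodes are skipped upward.
        """
        if rank_floor.is_no_rank:
            raise RankOrderError("rank_floor must be a defined rank")
        node = self.resolve(taxid)
        while True:
            rank = self.rank[node]
            if not rank.is_no_rank and rank >= rank_floor:
                return node
            up = self.parent[node]
            if up == node:
                return node  # fell through to root
            node = up


def ancestor_at_or_above(taxonomy: Taxonomy, taxid: int, rank_floor: Rank) -> int:
    return taxonomy.ancestor_at_or_above(taxid, rank_floor)


def _dmp_records(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.endswith("\t|"):
                line = line[:-2]
            yield lineno, line.split("\t|\t")


def load_taxdump(
    nodes_path: str | Path,
    names_path: str | Path,
    merged_path: str | Path | None = None,
    rank_order: RankOrder = DEFAULT_RANKS,
) -> Taxonomy:
    """Load a Taxonomy from NCBI dump-format files.

    Names are restricted to the ``scientific name`` class; obsolete taxids
    resolve through ``merged.dmp`` when provided.  Malformed records raise
    :class:`ParseError` naming the line; a node whose parent is missing from
    ``nodes.dmp`` raises :class:`StructuralError`.
    """
    parent: dict[int, int] = {}
    rank: dict[int, Rank] = {}
    for lineno, fields in _dmp_records(nodes_path):
        if len(fields) < 3:
            raise ParseError(f"{nodes_path}:{lineno}: expected >=3 fields, got {len(fields)}")
        try:
            taxid, up = int(fields[0]), int(fields[1])
        except ValueError as exc:
            raise ParseError(f"{nodes_path}:{lineno}: non-numeric taxid field: {exc}") from None
        parent[taxid] = up
        rank[taxid] = rank_order[fields[2]]

    name: dict[int, str] = {}
    for lineno, fields in _dmp_records(names_path):
        if len(fields) < 4:
            raise ParseError(f"{names_path}:{lineno}: expected >=4 fields, got {len(fields)}")
        try:
            taxid = int(fields[0])
        except ValueError as exc:
            raise ParseError(f"{names_path}:{lineno}: non-numeric taxid field: {exc}") from None
        if fields[3].strip() == "scientific name":
            name[taxid] = fields[1]

    merged: dict[int, int] = {}
    if merged_path is not None:
        for lineno, fields in _dmp_records(merged_path):
            if len(fields) < 2:
                raise ParseError(f"{merged_path}:{lineno}: expected >=2 fields")
            try:
                merged[int(fields[0])] = int(fields[1])
            except ValueError as exc:
                raise ParseError(f"{merged_path}:{lineno}: non-numeric taxid field: {exc}") from None

    root = None
    for taxid, up in parent.items():
        if up not in parent:
            raise StructuralError(f"node {taxid} references unknown parent {up}")
        if up == taxid:
            if root is not None:
                raise StructuralError(f"multiple roots: {root} and {taxid}")
            root = taxid
    if root is None:
        raise StructuralError("no root node (taxid whose parent is itself)")
    for taxid in parent:
        name.setdefault(taxid, str(taxid))
        rank.setdefault(taxid, NO_RANK)
    return Taxonomy(parent=parent, rank=rank, name=name, merged=merged, root=root,
                    rank_order=rank_order)


def write_taxdump(
    taxonomy: Taxonomy,
    nodes_path: str | Path,
    names_path: str | Path,
    merged_path: str | Path | None = None,
) -> None:
    """Serialize a Taxonomy back to dump format (round-trips load_taxdump)."""
    with open(nodes_path, "w", encoding="utf-8") as out:
        for taxid in sorted(taxonomy.parent):
            rank = taxonomy.rank[taxid]
            out.write(f"{taxid}\t|\t{taxonomy.parent[taxid]}\t|\t{rank.label}\t|\n")
    with open(names_path, "w", encoding="utf-8") as out:
        for taxid in sorted(taxonomy.parent):
            out.write(f"{taxid}\t|\t{taxonomy.name[taxid]}\t|\t\t|\tscientific name\t|\n")
    if merged_path is not None:
        with open(merged_path, "w", encoding="utf-8") as out:
            for old in sorted(taxonomy.merged):
                out.write(f"{old}\t|\t{taxonomy.merged[old]}\t|\n")
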