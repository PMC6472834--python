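"""Deterministic serialization of raw and derived samples.

Three writers: a per-taxon stats TSV (one row per sample x taxon), a
Krona-compatible two-part text (count + lineage names, importable by the
standard Krona text importer), and a nested JSON tree for any renderer.
All output is UTF-8 with LF line endings, fixed ordering and fixed float
formatting (scores at 6 significant digits, frequencies in scientific
notation), so identical inputs always produce identical bytes.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

from .decontam import ContaminationReport
from .scored_tree import ScoredNode
from .taxonomy import Taxonomy


def _fmt_score(value: float) -> str:
    return f"{value:.6g}"


def _fmt_freq(value: float) -> str:
    return f"{value:.6e}"


def write_stats(samples: Mapping[str, ScoredNode], taxonomy: Taxonomy,
                path: str | Path) -> None:
    """One row per (sample, taxon): self/subtree counts, mean score, rel freq.

    ``self_count`` is the number of reads assigned exactly to the taxon
    ("unassigned" to any deeper level); ``subtree_count`` includes all
    descendants.  Rows are sorted by (sample, descending subtree count,
    ascending taxid).
    """
    with open(path, "w", encoding="utf-8", newline="\n") as out:
        out.write("sample\ttaxid\tname\trank\tself_count\tsubtree_count\t"
                  "mean_score\trel_freq\n")
        for sample in sorted(samples):
            tree = samples[sample]
            total = tree.subtree_count()
            rows = []
            for node in tree.iter_nodes():
                subtree = node.subtree_count()
                rows.append((subtree, node.taxid, node))
            rows.sort(key=lambda r: (-r[0], r[1]))
            for subtree, taxid, node in rows:
                rel = subtree / total if total else 0.0
                out.write(
                    f"{sample}\t{taxid}\t{taxonomy.name.get(taxid, str(taxid))}\t"
                    f"{node.rank.label}\t{node.self_count}\t{subtree}\t"
                    f"{_fmt_score(node.subtree_score())}\t{_fmt_freq(rel)}\n")


def write_krona_text(tree: ScoredNode, taxonomy: Taxonomy,
                     path: str | Path) -> None:
    """Krona text dialect: ``<self_count>\\t<name1>\\t...\\t<nameK>`` per node.

    One line per node with reads of its own, lineage names from root to the
    node; the column-1 total equals the folded root's subtree count.
    """
    with open(path, "w", encoding="utf-8", newline="\n") as out:
        def walk(node: ScoredNode, lineage: list[str]) -> None:
            names = lineage + [taxonomy.name.get(node.taxid, str(node.taxid))]
            if node.self_count > 0:
                out.write(str(node.self_count) + "\t" + "\t".join(names) + "\n")
            for child in node.children:
                walk(child, names)

        walk(tree, [])


def node_to_dict(node: ScoredNode, taxonomy: Taxonomy) -> dict:
    return {
        "taxid": node.taxid,
        "name": taxonomy.name.get(node.taxid, str(node.taxid)),
        "rank": node.rank.label,
        "self_count": node.self_count,
        "subtree_count": node.subtree_count(),
        "mean_score": float(_fmt_score(node.self_score)),
        "children": [node_to_dict(c, taxonomy) for c in node.children],
    }


def node_from_dict(data: dict, taxonomy: Taxonomy) -> ScoredNode:
    """Inverse of :func:`node_to_dict` (scores within 1e-6 relative)."""
    return ScoredNode(
        taxid=data["taxid"],
        rank=taxonomy.rank_order[data["rank"]],
        self_count=data["self_count"],
        self_score=data["mean_score"],
        children=[node_from_dict(c, taxonomy) for c in data["children"]],
    )


def report_to_records(report: ContaminationReport, taxonomy: Taxonomy) -> list[dict]:
    records = []
    for taxid in sorted(report.decisions):
        decision = report.decisions[taxid]
        records.append({
            "taxid": taxid,
            "name": taxonomy.name.get(taxid, str(taxid)),
            "rank": report.rank.label,
            "level": decision.level,
            "crossover": decision.crossover,
            "sources": sorted(decision.source_samples),
            "removed_from": sorted(decision.removed_from),
            "max_control_freq": float(_fmt_freq(decision.max_control_freq)),
        })
    return records


def write_json_tree(trees: Mapping[str, ScoredNode],
                    report: ContaminationReport | None,
                    taxonomy: Taxonomy, path: str | Path) -> None:
    """Nested JSON mirror of the scored trees plus the contamination report."""
    payload = {
        "samples": {name: node_to_dict(tree, taxonomy)
                    for name, tree in trees.items()},
        "contamination": (report_to_records(report, taxonomy)
                          if report is not None else None),
    }
    with open(path, "w", encoding="utf-8", newline="\n") as out:
        json.dump(payload, out, sort_keys=True, indent=1)
        out.write("\n")


def write_contamination_tsv(report: ContaminationReport, taxonomy: Taxonomy,
                            path: str | Path) -> None:
    """Audit-trail TSV: one row per candidate taxon and its fate."""
    with open(path, "w", encoding="utf-8", newline="\n") as out:
        out.write("taxid\tname\trank\tlevel\tcrossover\tsources\t"
                  "removed_from\tmax_control_freq\n")
        for record in report_to_records(report, taxonomy):
            out.write(
                f"{record['taxid']}\t{record['name']}\t{record['rank']}\t"
                f"{record['level']}\t{str(record['crossover']).lower()}\t"
                f"{','.join(record['sources'])}\t"
                f"{','.join(record['removed_from'])}\t"
                f"{_fmt_freq(record['max_control_freq'])}\n")
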