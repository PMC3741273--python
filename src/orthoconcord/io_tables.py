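"""Readers and writers for the pipeline's tabular formats.

Dialect is deliberately rigid for reproducibility: tab-separated, decimal
point, no NA in expression matrices, floats written with shortest
round-trip (repr) formatting. JSON reports are UTF-8 with sorted keys.
"""
from __future__ import annotations

import csv
import json
import warnings
from pathlib import Path

import numpy as np

from .containers import (
    CtTable,
    DesignTable,
    ExprMatrix,
    FormatError,
    GroupMeanMatrix,
    LinkageTree,
    OrthologTable,
)

_NEWICK_UNSAFE = set(" \t()[]:;,'\"")


def _rows(path) -> list[list[str]]:
    with open(path, newline="", encoding="utf-8") as fh:
        return [row for row in csv.reader(fh, delimiter="\t")]


def _parse_cell(cell: str, row_label: str, col_label: str) -> float:
    try:
        v = float(cell)
    except ValueError:
        raise FormatError(
            f"non-numeric cell {cell!r} at row {row_label!r}, column {col_label!r}"
        ) from None
    if not np.isfinite(v):
        raise FormatError(f"non-finite value at row {row_label!r}, column {col_label!r}")
    return v


def read_expr_matrix(path) -> ExprMatrix:
    """Read a features x samples TSV (header: feature_id, then sample ids)."""
    rows = _rows(path)
    if not rows:
        raise FormatError(f"{path}: empty file")
    header = rows[0]
    if len(header) < 3 or header[0] != "feature_id":
        raise FormatError(f"{path}: header must be 'feature_id' plus >=2 sample columns")
    sample_ids = header[1:]
    feature_ids: list[str] = []
    seen: set[str] = set()
    values = []
    for row in rows[1:]:
        if len(row) != len(header):
            raise FormatError(
                f"{path}: ragged row {row[0] if row else '<empty>'!r} "
                f"({len(row)} fields, expected {len(header)})"
            )
        fid = row[0]
        if fid in seen:
            raise FormatError(f"{path}: duplicate feature id {fid!r}")
        seen.add(fid)
        feature_ids.append(fid)
        values.append([_parse_cell(c, fid, sample_ids[j]) for j, c in enumerate(row[1:])])
    return ExprMatrix(feature_ids, sample_ids, np.array(values, dtype=float))


def write_expr_matrix(m: ExprMatrix, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write("feature_id\t" + "\t".join(m.sample_ids) + "\n")
        for fid, row in zip(m.feature_ids, m.values):
            fh.write(fid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_design_table(path, vocabulary: list[str] | None = None) -> DesignTable:
    """Read a sample design TSV (sample_id, species, group, replicate).

    Group labels outside `vocabulary` (when given) raise a warning, not an
    error, so exploratory designs still load.
    """
    rows = _rows(path)
    if not rows:
        raise FormatError(f"{path}: empty file")
    header = rows[0]
    required = ["sample_id", "species", "group", "replicate"]
    if header[: len(required)] != required:
        raise FormatError(f"{path}: header must start with {required}")
    sample_ids, species, groups, reps = [], [], [], []
    for row in rows[1:]:
        if len(row) < len(required):
            raise FormatError(f"{path}: ragged design row {row!r}")
        sample_ids.append(row[0])
        species.append(row[1])
        groups.append(row[2])
        try:
            reps.append(int(row[3]))
        except ValueError:
            raise FormatError(f"{path}: non-integer replicate {row[3]!r}") from None
    if not sample_ids:
        raise FormatError(f"{path}: design table has no samples")
    table = DesignTable(sample_ids, species, groups, reps)
    if vocabulary is not None:
        unknown = sorted(set(groups) - set(vocabulary))
        if unknown:
            warnings.warn(f"unknown group labels {unknown} not in declared vocabulary")
    return table


def write_design_table(d: DesignTable, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write("sample_id\tspecies\tgroup\treplicate\n")
        for s, sp, g, r in zip(d.sample_ids, d.species, d.groups, d.replicates):
            fh.write(f"{s}\t{sp}\t{g}\t{r}\n")


def read_ortholog_table(path) -> OrthologTable:
    """Read probe->gene links; blank gene symbols are dropped and counted."""
    rows = _rows(path)
    if not rows:
        raise FormatError(f"{path}: empty file")
    header = rows[0]
    if header[:2] != ["probe_id", "gene_symbol"]:
        raise FormatError(f"{path}: header must start with ['probe_id', 'gene_symbol']")
    records = []
    dropped = 0
    for row in rows[1:]:
        if len(row) < 1:
            continue
        probe = row[0]
        gene = row[1].strip() if len(row) > 1 else ""
        if gene == "":
            dropped += 1
            continue
        records.append((probe, gene))
    return OrthologTable(records, n_dropped=dropped)


def write_ortholog_table(t: OrthologTable, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write("probe_id\tgene_symbol\n")
        for p, g in t.records:
            fh.write(f"{p}\t{g}\n")


def read_ct_table(path, housekeeping: list[str]) -> CtTable:
    """Read a qPCR Ct TSV shaped like an expression matrix (gene_id header)."""
    rows = _rows(path)
    if not rows:
        raise FormatError(f"{path}: empty file")
    header = rows[0]
    if len(header) < 2 or header[0] not in ("gene_id", "feature_id"):
        raise FormatError(f"{path}: header must be 'gene_id' plus sample columns")
    sample_ids = header[1:]
    gene_ids, values = [], []
    for row in rows[1:]:
        if len(row) != len(header):
            raise FormatError(f"{path}: ragged row {row[0] if row else ''!r}")
        gene_ids.append(row[0])
        values.append([_parse_cell(c, row[0], sample_ids[j]) for j, c in enumerate(row[1:])])
    return CtTable(gene_ids, sample_ids, np.array(values, dtype=float), list(housekeeping))


def write_group_means(g: GroupMeanMatrix, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write("feature_id\t" + "\t".join(g.group_labels) + "\n")
        for fid, row in zip(g.feature_ids, g.means):
            fh.write(fid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def _quote_label(label: str) -> str:
    if any(c in _NEWICK_UNSAFE for c in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def newick_string(tree: LinkageTree, labels: list[str]) -> str:
    """Render an ultrametric dendrogram as Newick with branch lengths.

    Merge heights are cophenetic distances: the two children of a node merged
    at height h each sit h/2 below it, so a pair merged at 0.4 renders as
    (A:0.2,B:0.2);.
    """
    n = tree.leaf_count
    if len(labels) != n:
        raise ValueError("label count does not match leaf count")
    if n == 1:
        return _quote_label(labels[0]) + ";"
    height = {i: 0.0 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for t, (i, j, h, _size) in enumerate(tree.merges):
        node = n + t
        height[node] = h
        children[node] = (i, j)

    def render(node: int, parent_h: float) -> str:
        blen = (parent_h - height[node]) / 2.0
        if node < n:
            return f"{_quote_label(labels[node])}:{repr(blen)}"
        i, j = children[node]
        return f"({render(i, height[node])},{render(j, height[node])}):{repr(blen)}"

    root = n + len(tree.merges) - 1
    i, j = children[root]
    rh = height[root]
    return f"({render(i, rh)},{render(j, rh)});"


def write_newick(tree: LinkageTree, labels: list[str], path) -> str:
    s = newick_string(tree, labels)
    Path(path).write_text(s + "\n", encoding="utf-8")
    return s


def write_json_report(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, sort_keys=True, indent=2)
        fh.write("\n")
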