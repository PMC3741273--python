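"""Core in-memory containers shared across the pipeline.

All expression values are log2-scale intensities unless a function states
otherwise. Matrices are dense numpy arrays shaped (features, samples).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class FormatError(ValueError):
    """A tabular input violates the expected dialect or an invariant."""


def _check_unique(ids, kind: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {kind} {x!r}")
        seen.add(x)


@dataclass
class ExprMatrix:
    """Features x samples matrix of log2-scale expression intensities."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise FormatError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(self.feature_ids) < 1:
            raise FormatError("expression matrix needs at least 1 feature")
        if len(self.sample_ids) < 2:
            raise FormatError("expression matrix needs at least 2 samples")
        _check_unique(self.feature_ids, "feature id")
        _check_unique(self.sample_ids, "sample id")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("expression matrix contains non-finite values")

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def subset_samples(self, sample_ids: list[str]) -> "ExprMatrix":
        idx = [self.sample_index(s) for s in sample_ids]
        return ExprMatrix(list(self.feature_ids), list(sample_ids), self.values[:, idx])

    def subset_features(self, feature_ids: list[str]) -> "ExprMatrix":
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        idx = [pos[f] for f in feature_ids]
        return ExprMatrix(list(feature_ids), list(self.sample_ids), self.values[idx, :])


@dataclass
class DesignTable:
    """Sample metadata: species, experimental group, replicate number."""

    sample_ids: list[str]
    species: list[str]
    groups: list[str]
    replicates: list[int]

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if not (len(self.species) == len(self.groups) == len(self.replicates) == n):
            raise FormatError("design table columns have unequal lengths")
        if n == 0:
            raise FormatError("design table is empty")
        _check_unique(self.sample_ids, "sample id")
        for r in self.replicates:
            if int(r) < 1:
                raise FormatError(f"replicate must be >= 1, got {r}")

    def samples_in(self, group) -> list[str]:
        """Sample ids whose group is `group` (a label or a collection of labels)."""
        if isinstance(group, str):
            wanted = {group}
        else:
            wanted = set(group)
        return [s for s, g in zip(self.sample_ids, self.groups) if g in wanted]

    def group_labels(self) -> list[str]:
        """Unique group labels in order of first appearance."""
        out: list[str] = []
        for g in self.groups:
            if g not in out:
                out.append(g)
        return out

    def group_of(self, sample_id: str) -> str:
        return self.groups[self.sample_ids.index(sample_id)]

    def species_of(self, sample_id: str) -> str:
        return self.species[self.sample_ids.index(sample_id)]


@dataclass
class OrthologTable:
    """Many-to-many (probe_id, gene_symbol) links; records deduplicated and sorted."""

    records: list[tuple[str, str]]
    n_dropped: int = 0

    def __post_init__(self) -> None:
        for p, g in self.records:
            if not g:
                raise FormatError(f"empty gene symbol for probe {p!r}")
        self.records = sorted(set(self.records))

    def genes_for_probe(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for p, g in self.records:
            out.setdefault(p, []).append(g)
        return out


@dataclass
class GroupMeanMatrix:
    """Per-feature, per-group arithmetic means of log2 expression."""

    feature_ids: list[str]
    group_labels: list[str]
    means: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        if self.means.shape != (len(self.feature_ids), len(self.group_labels)):
            raise FormatError("group mean matrix shape mismatch")
        if not np.all(np.isfinite(self.means)):
            raise FormatError("group means contain non-finite values")


@dataclass
class GeneMatrix:
    """Gene-symbol level expression produced by collapsing probes onto orthologs.

    `provenance` maps each gene to the (probe_id, split_factor) contributions
    that were averaged into it.
    """

    gene_symbols: list[str]
    sample_ids: list[str]
    values: np.ndarray
    provenance: dict[str, list[tuple[str, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_symbols, "gene symbol")
        if self.values.shape != (len(self.gene_symbols), len(self.sample_ids)):
            raise FormatError("gene matrix shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("gene matrix contains non-finite values")


@dataclass
class IntegratedSet:
    """Cross-species integrated matrix over shared ortholog genes.

    Columns are mouse samples followed by human samples; each species block is
    row-standardized before concatenation and values are clipped to a common
    range so the two platforms are on a comparable scale.
    """

    gene_symbols: list[str]
    sample_ids: list[str]
    values: np.ndarray
    species_of_sample: dict[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_symbols), len(self.sample_ids)):
            raise FormatError("integrated matrix shape mismatch")


@dataclass
class LinkageTree:
    """Agglomerative dendrogram in scipy convention.

    Leaves are numbered 0..leaf_count-1; the cluster created by merge t gets
    id leaf_count + t. Each merge is (node_i, node_j, height, size).
    """

    merges: list[tuple[int, int, float, int]]
    leaf_count: int

    def __post_init__(self) -> None:
        if self.leaf_count >= 2 and len(self.merges) != self.leaf_count - 1:
            raise ValueError("tree must contain exactly leaf_count - 1 merges")


@dataclass
class CtTable:
    """qPCR cycle-threshold table (genes x samples) with a housekeeping set."""

    gene_ids: list[str]
    sample_ids: list[str]
    ct: np.ndarray
    housekeeping: list[str]

    def __post_init__(self) -> None:
        self.ct = np.asarray(self.ct, dtype=float)
        _check_unique(self.gene_ids, "gene id")
        if self.ct.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError("Ct table shape mismatch")
        missing = [h for h in self.housekeeping if h not in self.gene_ids]
        if missing:
            raise FormatError(f"housekeeping gene {missing[0]!r} missing from Ct table")
        if np.any((self.ct <= 0) | (self.ct > 45)):
            raise FormatError("Ct values must lie in (0, 45]")
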