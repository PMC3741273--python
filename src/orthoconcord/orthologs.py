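"""Collapse probe-level expression onto ortholog gene symbols and build the
integrated cross-species matrix.

The mapping follows two composable rules applied on the (log2) expression
values as given: a probe linked to m genes splits its value evenly,
contributing value/m to each linked gene; a gene receiving several
contributions takes their arithmetic mean. Probes with no link are excluded.
The closed form is order-independent, unlike a literal sequential sweep.
"""
from __future__ import annotations

import numpy as np

from .containers import ExprMatrix, GeneMatrix, IntegratedSet, OrthologTable
from .preprocess import standardize_matrix


def map_probes_to_genes(
    m: ExprMatrix, table: OrthologTable, split_mode: str = "divide"
) -> GeneMatrix:
    """Average-and-split collapse of probes onto gene symbols.

    split_mode 'divide' (default) assigns value/m to each of a probe's m
    linked genes; 'replicate' assigns the full value to each (no split).
    """
    if split_mode not in ("divide", "replicate"):
        raise ValueError(f"unknown split_mode {split_mode!r}")
    links = table.genes_for_probe()
    probe_rows = {p: i for i, p in enumerate(m.feature_ids)}
    mapped = [p for p in m.feature_ids if p in links]
    if not mapped:
        raise ValueError("no mappable probes: matrix and ortholog table are disjoint")

    contributions: dict[str, list[tuple[str, float]]] = {}
    for p in mapped:
        genes = links[p]
        factor = 1.0 / len(genes) if split_mode == "divide" else 1.0
        for g in genes:
            contributions.setdefault(g, []).append((p, factor))

    gene_symbols = sorted(contributions)
    values = np.empty((len(gene_symbols), len(m.sample_ids)))
    for gi, g in enumerate(gene_symbols):
        rows = np.array([probe_rows[p] for p, _f in contributions[g]])
        factors = np.array([f for _p, f in contributions[g]])
        values[gi] = (m.values[rows] * factors[:, None]).mean(axis=0)
    return GeneMatrix(gene_symbols, list(m.sample_ids), values, contributions)


def intersect_and_integrate(
    mouse: GeneMatrix, human: GeneMatrix, clip: tuple[float, float] = (-3.0, 3.0)
) -> tuple[IntegratedSet, dict[str, int]]:
    """Keep genes present on both platforms, standardize per species, clip.

    Gene symbols match case-insensitively (canonical form: trimmed upper
    case). Columns are mouse samples then human samples. Returns the
    integrated set plus counts (per-species inputs and intersection size).
    """
    lo, hi = clip
    if lo >= hi:
        raise ValueError(f"clip range requires lo < hi, got {clip}")

    def canon(sym: str) -> str:
        return sym.strip().upper()

    m_index = {canon(g): i for i, g in enumerate(mouse.gene_symbols)}
    h_index = {canon(g): i for i, g in enumerate(human.gene_symbols)}
    shared = sorted(set(m_index) & set(h_index))
    counts = {
        "n_mouse_genes": len(mouse.gene_symbols),
        "n_human_genes": len(human.gene_symbols),
        "n_intersection": len(shared),
    }
    if not shared:
        raise ValueError(
            f"no shared ortholog genes (mouse has {counts['n_mouse_genes']}, "
            f"human has {counts['n_human_genes']})"
        )
    m_block = standardize_matrix(mouse.values[[m_index[g] for g in shared]])
    h_block = standardize_matrix(human.values[[h_index[g] for g in shared]])
    values = np.clip(np.concatenate([m_block, h_block], axis=1), lo, hi)
    sample_ids = list(mouse.sample_ids) + list(human.sample_ids)
    species = {s: "mouse" for s in mouse.sample_ids}
    species.update({s: "human" for s in human.sample_ids})
    return IntegratedSet(shared, sample_ids, values, species), counts
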