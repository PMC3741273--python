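"""Mouse-to-human fold-change concordance and cross-species sample clustering.

Concordance of a shared ortholog gene is direction agreement of its
tumor-vs-normal log2 fold change in the two species. The report carries the
raw rate, the raw percent, and a display percent that rounds the percentage
up at half-percent resolution before integer rounding (so 117/151 = 77.48%
displays as 78). An optional stricter mode additionally requires a minimum
fold-change magnitude in both species.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cluster import average_linkage, correlation_distance, cut_tree
from .containers import DesignTable, GeneMatrix, IntegratedSet, LinkageTree
from .io_tables import newick_string


@dataclass
class ConcordanceReport:
    gene_symbols: list[str]
    log2fc_mouse: np.ndarray
    log2fc_human: np.ndarray
    concordant: np.ndarray
    n_total: int
    n_concordant: int
    rate: float
    rate_pct_raw: float
    rate_pct_rounded: int
    zero_fc_genes: list[str] = field(default_factory=list)


def fold_change_by_species(
    g: GeneMatrix, d: DesignTable, tumor_group, normal_group
) -> np.ndarray:
    """Per-gene log2 fold change: mean over tumor samples - mean over normal."""
    tumor = [s for s in d.samples_in(tumor_group) if s in set(g.sample_ids)]
    normal = [s for s in d.samples_in(normal_group) if s in set(g.sample_ids)]
    if not tumor:
        raise ValueError(f"unknown or empty tumor group {tumor_group!r}")
    if not normal:
        raise ValueError(f"unknown or empty normal group {normal_group!r}")
    it = [g.sample_ids.index(s) for s in tumor]
    ig = [g.sample_ids.index(s) for s in normal]
    return g.values[:, it].mean(axis=1) - g.values[:, ig].mean(axis=1)


def display_percent(rate: float) -> int:
    """Integer percent via ceiling at 0.5% resolution, then half-up rounding."""
    half_resolution = math.ceil(rate * 200.0 - 1e-9) / 2.0  # guard float fuzz
    return int(math.floor(half_resolution + 0.5))


def concordance_rate(
    gene_symbols: list[str],
    fc_mouse: np.ndarray,
    fc_human: np.ndarray,
    mode: str = "sign",
    magnitude_cutoff: float = 2.0,
) -> ConcordanceReport:
    """Fraction of genes whose fold changes agree in direction across species.

    A gene with exactly zero fold change in either species is counted
    non-concordant and flagged. mode='sign_and_magnitude' additionally
    requires |log2fc| >= log2(magnitude_cutoff) in both species.
    """
    fc_mouse = np.asarray(fc_mouse, dtype=float)
    fc_human = np.asarray(fc_human, dtype=float)
    if not (len(gene_symbols) == len(fc_mouse) == len(fc_human)):
        raise ValueError("gene list and fold-change vectors must have equal length")
    if mode not in ("sign", "sign_and_magnitude"):
        raise ValueError(f"unknown concordance mode {mode!r}")
    sm = np.sign(fc_mouse)
    sh = np.sign(fc_human)
    concordant = (sm == sh) & (sm != 0)
    if mode == "sign_and_magnitude":
        thr = math.log2(magnitude_cutoff)
        concordant &= (np.abs(fc_mouse) >= thr) & (np.abs(fc_human) >= thr)
    zeros = [g for g, a, b in zip(gene_symbols, sm, sh) if a == 0 or b == 0]
    n_total = len(gene_symbols)
    n_conc = int(concordant.sum())
    rate = n_conc / n_total if n_total else 0.0
    return ConcordanceReport(
        gene_symbols=list(gene_symbols),
        log2fc_mouse=fc_mouse,
        log2fc_human=fc_human,
        concordant=concordant,
        n_total=n_total,
        n_concordant=n_conc,
        rate=rate,
        rate_pct_raw=100.0 * rate,
        rate_pct_rounded=display_percent(rate),
        zero_fc_genes=zeros,
    )


def cross_species_sample_clusters(
    s: IntegratedSet,
    k: int,
    design: DesignTable | None = None,
    mouse_tumor_group: str = "KO24",
) -> tuple[LinkageTree, np.ndarray, str, dict]:
    """Cluster samples (columns) of the integrated set and report co-clustering.

    Returns (tree, flat assignment at k, Newick string, report). The report
    lists, for every mouse tumor sample, the human samples sharing its flat
    cluster together with their disease-stage group labels -- the readout of
    which human group the mouse tumors join.
    """
    n_samples = len(s.sample_ids)
    if n_samples < 3:
        raise ValueError("need at least 3 samples to cluster")
    if not (1 <= k <= n_samples):
        raise ValueError(f"k must lie in [1, {n_samples}], got {k}")
    profiles = s.values.T  # samples x genes
    D = correlation_distance(profiles, s.sample_ids)
    tree = average_linkage(D)
    assign = cut_tree(tree, k)
    nwk = newick_string(tree, s.sample_ids)

    mouse_tumor_samples = [
        sid
        for sid in s.sample_ids
        if s.species_of_sample.get(sid) == "mouse"
        and (design is None or design.group_of(sid) == mouse_tumor_group)
    ]
    report: dict = {"k": k, "mouse_tumor_samples": {}}
    label_of = dict(zip(s.sample_ids, assign.tolist()))
    for sid in mouse_tumor_samples:
        lab = label_of[sid]
        mates = [
            {
                "sample_id": other,
                "group": design.group_of(other) if design is not None else None,
            }
            for other in s.sample_ids
            if other != sid
            and label_of[other] == lab
            and s.species_of_sample.get(other) == "human"
        ]
        report["mouse_tumor_samples"][sid] = {
            "cluster": int(lab),
            "human_co_members": mates,
        }
    return tree, assign, nwk, report
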