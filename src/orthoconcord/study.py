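"""In-memory synthetic study workflows.

Convenience drivers that run the cross-species analysis end to end on a
generated study without touching the filesystem; the file-based pipeline in
`pipeline` wraps the same library calls around on-disk tables.
"""
from __future__ import annotations

import numpy as np

from .concordance import concordance_rate, cross_species_sample_clusters, fold_change_by_species
from .orthologs import intersect_and_integrate, map_probes_to_genes
from .sam import SamParams, run_sam
from .simulate import SimConfig, simulate_two_species


def two_species_concordance_study(
    sim_cfg: SimConfig,
    sam_params: SamParams | None = None,
    sample_cluster_k: int = 2,
    mouse_tumor_group: str = "KO24",
    mouse_normal_group: str = "WT24",
    human_tumor_groups: tuple[str, ...] = ("T1", "T3"),
    human_normal_group: str = "normal",
) -> dict:
    """Generate a dual-species study and score mouse-to-human concordance.

    Runs per-species SAM at the cross-species fold-change cutoff, maps
    significant probes onto ortholog genes, integrates the shared set, and
    returns the concordance report, co-clustering readout, intersection
    counts and the generator's truth ledger.
    """
    params = sam_params or SamParams(fc_cutoff=2.0, seed=sim_cfg.seed)
    mouse, human, orth, design, truth = simulate_two_species(sim_cfg)

    mouse_24 = mouse.subset_samples(
        design.samples_in([mouse_normal_group, mouse_tumor_group])
    )
    res_m = run_sam(mouse_24, design, mouse_normal_group, mouse_tumor_group, params)
    res_h = run_sam(human, design, human_normal_group, list(human_tumor_groups), params)

    gm_mouse = map_probes_to_genes(mouse_24.subset_features(res_m.significant_ids()), orth)
    gm_human = map_probes_to_genes(human.subset_features(res_h.significant_ids()), orth)
    integrated, counts = intersect_and_integrate(gm_mouse, gm_human)

    genes = integrated.gene_symbols
    midx = {s.upper(): i for i, s in enumerate(gm_mouse.gene_symbols)}
    hidx = {s.upper(): i for i, s in enumerate(gm_human.gene_symbols)}
    fc_m = fold_change_by_species(gm_mouse, design, mouse_tumor_group, mouse_normal_group)
    fc_h = fold_change_by_species(gm_human, design, list(human_tumor_groups), human_normal_group)
    report = concordance_rate(
        genes,
        np.array([fc_m[midx[g]] for g in genes]),
        np.array([fc_h[hidx[g]] for g in genes]),
    )
    tree, assign, nwk, co_report = cross_species_sample_clusters(
        integrated, sample_cluster_k, design, mouse_tumor_group
    )
    return {
        "concordance": report,
        "counts": counts,
        "co_clustering": co_report,
        "integrated": integrated,
        "truth": truth,
        "sam_mouse": res_m,
        "sam_human": res_h,
        "newick": nwk,
    }
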