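"""End-to-end orchestration of the comparative transcriptomics workflow.

Stages: within-species SAM across group pairs and their union -> consensus
clustering of group-mean profiles -> per-species SAM at the cross-species
fold-change cutoff -> probe-to-ortholog mapping -> integration -> sample
clustering and concordance. Each stage logs feature counts in/out and the
bundle is written with a manifest (config hash, seed, library versions).
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .concordance import concordance_rate, cross_species_sample_clusters, fold_change_by_species
from .containers import DesignTable, ExprMatrix
from .io_tables import (
    read_design_table,
    read_expr_matrix,
    read_ortholog_table,
    write_json_report,
    write_newick,
)
from .orthologs import intersect_and_integrate, map_probes_to_genes
from .cluster import consensus_cluster_count
from .preprocess import group_means, standardize_rows
from .sam import SamParams, pairwise_union, result_records, run_sam

log = logging.getLogger("orthoconcord.pipeline")

DEFAULT_MOUSE_PAIRS = [
    ("WT6", "KO6"),
    ("WT24", "KO24"),
    ("KO6", "KO24"),
    ("WT6", "WT24"),
]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, fingerprint: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on input {fingerprint}: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    mouse_matrix: str
    mouse_design: str
    human_matrix: str
    human_design: str
    orthologs: str
    outdir: str
    fc_cutoff_within: float = 3.0
    fc_cutoff_cross: float = 2.0
    fdr_max: float = 0.05
    n_perm: int = 200
    seed: int = 0
    k_range: tuple[int, int] = (2, 15)
    clip: tuple[float, float] = (-3.0, 3.0)
    split_mode: str = "divide"
    concordance_mode: str = "sign"
    mouse_group_pairs: list[tuple[str, str]] = field(
        default_factory=lambda: [tuple(p) for p in DEFAULT_MOUSE_PAIRS]
    )
    mouse_tumor_group: str = "KO24"
    mouse_normal_group: str = "WT24"
    human_tumor_groups: list[str] = field(default_factory=lambda: ["T1", "T3"])
    human_normal_group: str = "normal"
    sample_cluster_k: int = 2
    extra: dict = field(default_factory=dict)  # unknown config keys; hashed, unused

    def __post_init__(self) -> None:
        if self.fc_cutoff_within < 1 or self.fc_cutoff_cross < 1:
            raise ValueError("fold-change cutoffs must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in raw.items() if k in known}
        kwargs["extra"] = {k: v for k, v in raw.items() if k not in known}
        if "mouse_group_pairs" in kwargs:
            kwargs["mouse_group_pairs"] = [tuple(p) for p in kwargs["mouse_group_pairs"]]
        for key in ("k_range", "clip"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def config_hash(self) -> str:
        canonical = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(canonical.encode()).hexdigest()


def _canon(symbol: str) -> str:
    return symbol.strip().upper()


def _fingerprint(*paths) -> str:
    h = hashlib.sha256()
    for p in paths:
        p = Path(p)
        h.update(p.name.encode())
        if p.exists():
            h.update(str(p.stat().st_size).encode())
    return h.hexdigest()[:12]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full workflow and write the report bundle under outdir."""
    out = Path(cfg.outdir)
    for sub in ("sam", "clusters", "orthologs", "integrated", "concordance"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    fp = _fingerprint(cfg.mouse_matrix, cfg.human_matrix, cfg.orthologs)
    bundle: dict = {}

    def stage(name):
        def deco(fn):
            try:
                log.info("stage %s: start", name)
                return fn()
            except Exception as exc:  # re-raise with stage context
                raise PipelineError(name, fp, exc) from exc
        return deco

    @stage("load_inputs")
    def inputs():
        mouse = read_expr_matrix(cfg.mouse_matrix)
        human = read_expr_matrix(cfg.human_matrix)
        mouse_d = read_design_table(cfg.mouse_design)
        human_d = read_design_table(cfg.human_design)
        orth = read_ortholog_table(cfg.orthologs)
        return mouse, human, mouse_d, human_d, orth

    mouse, human, mouse_d, human_d, orth = inputs

    @stage("sam_within_species")
    def sam_union():
        params = SamParams(
            n_perm=cfg.n_perm,
            seed=cfg.seed,
            fdr_max=cfg.fdr_max,
            fc_cutoff=cfg.fc_cutoff_within,
        )
        union, provenance, per_pair = pairwise_union(
            mouse, mouse_d, cfg.mouse_group_pairs, params
        )
        log.info("SAM union: %d features across %d comparisons", len(union), len(per_pair))
        for (ga, gb), res in per_pair.items():
            write_json_report(
                {
                    "run": {
                        "s0": res.s0,
                        "delta": res.delta,
                        "fdr_est": res.fdr_est,
                        "n_perm_used": res.n_perm_used,
                        "group_a": ga,
                        "group_b": gb,
                    },
                    "features": result_records(res),
                },
                out / "sam" / f"sam_{gb}_vs_{ga}.json",
            )
        write_json_report(
            {"union": union, "provenance": {k: [list(x) for x in v] for k, v in provenance.items()}},
            out / "sam" / "union.json",
        )
        return union, provenance

    union, provenance = sam_union

    @stage("cluster_group_means")
    def clusters():
        if len(union) < 4:
            log.info("too few union features (%d) for clustering; skipping", len(union))
            return None
        sub = mouse.subset_features(union)
        gm = group_means(sub, mouse_d)
        std, flagged = standardize_rows(
            ExprMatrix(gm.feature_ids, gm.group_labels, gm.means)
        )
        keep = [f for f in std.feature_ids if f not in set(flagged)]
        profiles = std.subset_features(keep)
        kmax = min(cfg.k_range[1], len(keep) - 1)
        ks = list(range(cfg.k_range[0], kmax + 1))
        k_star, table, nominations, assign = consensus_cluster_count(
            profiles.values, ks, keep
        )
        log.info("consensus cluster count k*=%d from nominations %s", k_star, nominations)
        write_json_report(
            {
                "k_star": k_star,
                "nominations": nominations,
                "per_k": [
                    {
                        "k": q.k,
                        "silhouette": q.silhouette,
                        "inter_intra_ratio": q.inter_intra_ratio,
                        "homogeneity": q.homogeneity,
                        "separation": q.separation,
                        "combined_hs": q.combined_hs,
                    }
                    for q in table
                ],
                "assignment": {f: int(a) for f, a in zip(keep, assign)},
            },
            out / "clusters" / "clusters.json",
        )
        from .cluster import average_linkage, correlation_distance

        tree = average_linkage(correlation_distance(profiles.values, keep))
        write_newick(tree, keep, out / "clusters" / "gene_tree.nwk")
        return k_star

    consensus_k = clusters

    @stage("sam_cross_species")
    def cross_de():
        params = SamParams(
            n_perm=cfg.n_perm,
            seed=cfg.seed,
            fdr_max=cfg.fdr_max,
            fc_cutoff=cfg.fc_cutoff_cross,
        )
        mouse_24 = mouse.subset_samples(
            mouse_d.samples_in([cfg.mouse_normal_group, cfg.mouse_tumor_group])
        )
        res_m = run_sam(
            mouse_24, mouse_d, cfg.mouse_normal_group, cfg.mouse_tumor_group, params
        )
        res_h = run_sam(
            human, human_d, cfg.human_normal_group, cfg.human_tumor_groups, params
        )
        sig_m = res_m.significant_ids()
        sig_h = res_h.significant_ids()
        log.info("cross-species DE: %d mouse probes, %d human probes", len(sig_m), len(sig_h))
        return mouse_24, sig_m, sig_h

    mouse_24, sig_m, sig_h = cross_de

    @stage("ortholog_integration")
    def integrate():
        gm_mouse = map_probes_to_genes(
            mouse_24.subset_features(sig_m), orth, cfg.split_mode
        )
        gm_human = map_probes_to_genes(
            human.subset_features(sig_h), orth, cfg.split_mode
        )
        integrated, counts = intersect_and_integrate(gm_mouse, gm_human, cfg.clip)
        log.info(
            "integration: %d mouse genes x %d human genes -> %d shared",
            counts["n_mouse_genes"], counts["n_human_genes"], counts["n_intersection"],
        )
        write_json_report(
            {"counts": counts, "genes": integrated.gene_symbols},
            out / "orthologs" / "intersection.json",
        )
        np.savetxt(
            out / "integrated" / "integrated.tsv",
            integrated.values,
            delimiter="\t",
            header="\t".join(integrated.sample_ids),
            comments="",
        )
        return gm_mouse, gm_human, integrated, counts

    gm_mouse, gm_human, integrated, counts = integrate

    @stage("sample_clustering")
    def sample_clusters():
        tree, assign, nwk, report = cross_species_sample_clusters(
            integrated,
            cfg.sample_cluster_k,
            design=DesignTable(
                mouse_d.sample_ids + human_d.sample_ids,
                mouse_d.species + human_d.species,
                mouse_d.groups + human_d.groups,
                mouse_d.replicates + human_d.replicates,
            ),
            mouse_tumor_group=cfg.mouse_tumor_group,
        )
        (out / "integrated" / "samples.nwk").write_text(nwk + "\n", encoding="utf-8")
        write_json_report(report, out / "integrated" / "co_clustering.json")
        return report

    co_clustering = sample_clusters

    @stage("concordance")
    def concord():
        genes = integrated.gene_symbols
        midx = {_canon(g): i for i, g in enumerate(gm_mouse.gene_symbols)}
        hidx = {_canon(g): i for i, g in enumerate(gm_human.gene_symbols)}
        fc_m_all = fold_change_by_species(
            gm_mouse, mouse_d, cfg.mouse_tumor_group, cfg.mouse_normal_group
        )
        fc_h_all = fold_change_by_species(
            gm_human, human_d, cfg.human_tumor_groups, cfg.human_normal_group
        )
        fc_m = np.array([fc_m_all[midx[g]] for g in genes])
        fc_h = np.array([fc_h_all[hidx[g]] for g in genes])
        report = concordance_rate(genes, fc_m, fc_h, mode=cfg.concordance_mode)
        log.info(
            "concordance: %d/%d = %.2f%% (displayed %d%%)",
            report.n_concordant, report.n_total, report.rate_pct_raw, report.rate_pct_rounded,
        )
        per_stage = {}
        for stage_label in cfg.human_tumor_groups:
            fc_stage = fold_change_by_species(
                gm_human, human_d, stage_label, cfg.human_normal_group
            )
            per_stage[stage_label] = {
                g: float(fc_stage[hidx[g]]) for g in genes
            }
        write_json_report(
            {
                "n_total": report.n_total,
                "n_concordant": report.n_concordant,
                "rate": report.rate,
                "rate_pct_raw": report.rate_pct_raw,
                "rate_pct_rounded": report.rate_pct_rounded,
                "zero_fc_genes": report.zero_fc_genes,
                "per_gene": {
                    g: {
                        "log2fc_mouse": float(a),
                        "log2fc_human": float(b),
                        "concordant": bool(c),
                    }
                    for g, a, b, c in zip(genes, fc_m, fc_h, report.concordant)
                },
                "human_per_stage_log2fc": per_stage,
            },
            out / "concordance" / "concordance.json",
        )
        return report

    report = concord

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "counts": {
            "sam_union": len(union),
            "consensus_k": consensus_k,
            "mouse_de_probes": len(sig_m),
            "human_de_probes": len(sig_h),
            **counts,
            "n_concordant": report.n_concordant,
        },
    }
    write_json_report(manifest, out / "manifest.json")
    bundle.update(
        manifest=manifest,
        union=union,
        consensus_k=consensus_k,
        integrated=integrated,
        concordance=report,
        co_clustering=co_clustering,
    )
    return bundle
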