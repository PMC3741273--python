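"""Seeded generators for synthetic dual-species studies, four-group mouse
studies, and qPCR Ct tables.

The generators emulate the statistical structure the analysis assumes:
log2-scale intensities with Gaussian noise, a four-group mouse design
(wild-type/knockout x 6/24 months, 3 replicates each), a human cohort of
2 normal + 4 early-tumor (T1) + 6 advanced-tumor (T3) samples, and a
many-to-many probe-to-ortholog wiring between two probe namespaces. Every
generator emits a truth ledger (JSON-serializable dict) recording planted
effects and mappings; recovery tests read truth only from that ledger.

One global seed drives everything; per-stream child generators are derived
with numpy's SeedSequence.spawn so each output block is independently
reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import CtTable, DesignTable, ExprMatrix, OrthologTable

HOUSEKEEPING_GENES = ["Gusb", "Hprt1", "Hsp90ab1", "Gapdh", "Actb"]

# group-mean expression patterns over (WT6, KO6, WT24, KO24), unit amplitude
ARCHETYPES: list[tuple[str, tuple[float, float, float, float]]] = [
    ("ko24_up", (0, 0, 0, 1)),
    ("ko24_down", (0, 0, 0, -1)),
    ("age_up_both", (0, 0, 1, 1)),
    ("age_down_both", (1, 1, 0, 0)),
    ("ko_up_both_ages", (0, 1, 0, 1)),
    ("ko_down_with_age", (0, 1, 0, -1)),
    ("wt_age_up_only", (0, 0, 1, 0)),
    ("ko6_up", (0, 1, 0, 0)),
]


@dataclass
class SimConfig:
    seed: int = 0
    n_probes_mouse: int = 1200
    n_probes_human: int = 1200
    n_shared_genes: int = 400
    frac_multi_map: float = 0.15
    frac_unlinked: float = 0.05
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    noise_sd: float = 0.25
    n_de: int = 160
    log2fc_range: tuple[float, float] = (1.6, 4.4)
    concordance_frac: float = 0.78
    t1_effect_fraction: float = 0.5
    mouse_design: dict[str, int] = field(
        default_factory=lambda: {"WT6": 3, "KO6": 3, "WT24": 3, "KO24": 3}
    )
    human_design: dict[str, int] = field(
        default_factory=lambda: {"normal": 2, "T1": 4, "T3": 6}
    )
    n_archetypes: int = 5
    n_qpcr_genes: int = 84
    n_de_qpcr: int = 11
    ct_noise_sd: float = 0.2

    def __post_init__(self) -> None:
        for name in (
            "n_probes_mouse",
            "n_probes_human",
            "n_shared_genes",
            "n_archetypes",
            "n_qpcr_genes",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_de < 0 or self.n_de_qpcr < 0:
            raise ValueError("planted effect counts must be >= 0")
        for name in ("frac_multi_map", "frac_unlinked", "concordance_frac"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        lo, hi = self.log2fc_range
        if lo <= 0 or hi < lo:
            raise ValueError("log2fc_range must be a positive interval")
        if any(n < 1 for n in self.mouse_design.values()):
            raise ValueError("mouse design group sizes must be >= 1")
        if any(n < 1 for n in self.human_design.values()):
            raise ValueError("human design group sizes must be >= 1")


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _design(prefix: str, species: str, groups: dict[str, int]):
    sample_ids, species_col, group_col, reps = [], [], [], []
    for g, n in groups.items():
        for r in range(1, n + 1):
            sample_ids.append(f"{prefix}_{g}_{r}")
            species_col.append(species)
            group_col.append(g)
            reps.append(r)
    return sample_ids, species_col, group_col, reps


def _wire_probes(
    rng: np.random.Generator,
    n_probes: int,
    n_genes: int,
    c: SimConfig,
    prefix: str,
    de_mask: np.ndarray | None = None,
) -> dict[str, list[int]]:
    """Probe -> gene-index wiring: first n_genes probes map 1:1 so every gene
    has a dedicated probe; extra probes are unlinked, single- or double-linked.

    Double-linked probes pair genes of the same regulation stratum (DE with
    DE, flat with flat), the way cross-hybridizing probe sets hit homologous,
    co-regulated gene families rather than arbitrary gene pairs.
    """
    strata: dict[bool, np.ndarray] = {}
    if de_mask is not None:
        strata = {True: np.nonzero(de_mask)[0], False: np.nonzero(~de_mask)[0]}
    wiring: dict[str, list[int]] = {}
    for i in range(n_probes):
        probe = f"{prefix}{i + 1:05d}"
        if i < n_genes:
            genes = [i]
        elif rng.random() < c.frac_unlinked:
            wiring[probe] = []
            continue
        else:
            genes = [int(rng.integers(n_genes))]
        if rng.random() < c.frac_multi_map:
            if de_mask is not None:
                pool = strata[bool(de_mask[genes[0]])]
                extra = int(pool[rng.integers(len(pool))]) if len(pool) else genes[0]
            else:
                extra = int(rng.integers(n_genes))
            if extra not in genes:
                genes.append(extra)
        wiring[probe] = genes
    return wiring


def simulate_two_species(c: SimConfig):
    """Dual-species study: (mouse ExprMatrix, human ExprMatrix, OrthologTable,
    DesignTable, truth ledger).

    Shared ortholog genes carry a common log2 baseline; planted tumor genes
    get an effect in the mouse tumor group (KO24) and in the human tumor
    stages (full in T3, attenuated in T1), with cross-species direction
    agreement drawn per concordance_frac.
    """
    if c.n_de > c.n_shared_genes:
        raise ValueError("n_de cannot exceed n_shared_genes")
    if c.n_probes_mouse < c.n_shared_genes or c.n_probes_human < c.n_shared_genes:
        raise ValueError("each platform needs at least one probe per shared gene")
    rng_gene, rng_mouse, rng_human, rng_wire = _streams(c.seed, 4)

    base_symbols = [f"GENE{i + 1:04d}" for i in range(c.n_shared_genes)]
    mouse_symbol = [s.capitalize() for s in base_symbols]
    human_symbol = list(base_symbols)

    baseline = rng_gene.normal(c.baseline_mean, c.baseline_sd, c.n_shared_genes)
    de_idx = np.sort(rng_gene.choice(c.n_shared_genes, size=c.n_de, replace=False))
    lo, hi = c.log2fc_range
    mouse_sign = rng_gene.choice([-1.0, 1.0], size=c.n_de)
    mouse_mag = rng_gene.uniform(lo, hi, c.n_de)
    human_mag = rng_gene.uniform(lo, hi, c.n_de)
    agree = rng_gene.random(c.n_de) < c.concordance_frac
    human_sign = np.where(agree, mouse_sign, -mouse_sign)

    mouse_fc = np.zeros(c.n_shared_genes)
    human_fc = np.zeros(c.n_shared_genes)
    mouse_fc[de_idx] = mouse_sign * mouse_mag
    human_fc[de_idx] = human_sign * human_mag

    def gene_signal(species: str, group: str) -> np.ndarray:
        sig = baseline.copy()
        if species == "mouse" and group == "KO24":
            sig = sig + mouse_fc
        elif species == "human" and group == "T3":
            sig = sig + human_fc
        elif species == "human" and group == "T1":
            sig = sig + c.t1_effect_fraction * human_fc
        return sig

    de_mask = np.zeros(c.n_shared_genes, dtype=bool)
    de_mask[de_idx] = True
    wiring_m = _wire_probes(rng_wire, c.n_probes_mouse, c.n_shared_genes, c, "m_p", de_mask)
    wiring_h = _wire_probes(rng_wire, c.n_probes_human, c.n_shared_genes, c, "h_p", de_mask)

    def build_matrix(species, wiring, groups, rng, prefix):
        sample_ids, sp, gr, reps = _design(prefix, species, groups)
        signals = {g: gene_signal(species, g) for g in groups}
        probe_ids = list(wiring)
        probe_mu = {g: np.empty(len(probe_ids)) for g in groups}
        for pi, p in enumerate(probe_ids):
            genes = wiring[p]
            if not genes:
                flat = rng.normal(c.baseline_mean, c.baseline_sd)
                for g in groups:
                    probe_mu[g][pi] = flat
            else:
                for g in groups:
                    probe_mu[g][pi] = float(np.mean(signals[g][genes]))
        mu = np.column_stack([probe_mu[g] for g in gr])
        values = mu + rng.normal(0.0, c.noise_sd, mu.shape)
        matrix = ExprMatrix(probe_ids, sample_ids, values)
        return matrix, (sample_ids, sp, gr, reps)

    mouse_matrix, md = build_matrix("mouse", wiring_m, c.mouse_design, rng_mouse, "ms")
    human_matrix, hd = build_matrix("human", wiring_h, c.human_design, rng_human, "hs")
    design = DesignTable(
        md[0] + hd[0], md[1] + hd[1], md[2] + hd[2], md[3] + hd[3]
    )

    records = []
    for p, genes in wiring_m.items():
        records.extend((p, mouse_symbol[g]) for g in genes)
    for p, genes in wiring_h.items():
        records.extend((p, human_symbol[g]) for g in genes)
    table = OrthologTable(records)

    de_set = set(de_idx.tolist())
    pos = {int(g): i for i, g in enumerate(de_idx)}
    truth = {
        "genes": [
            {
                "symbol": base_symbols[g],
                "de": g in de_set,
                "mouse_log2fc": float(mouse_fc[g]),
                "human_log2fc": float(human_fc[g]),
                "agree": bool(agree[pos[g]]) if g in de_set else None,
            }
            for g in range(c.n_shared_genes)
        ],
        "probe_map_mouse": {p: [base_symbols[g] for g in gs] for p, gs in wiring_m.items()},
        "probe_map_human": {p: [base_symbols[g] for g in gs] for p, gs in wiring_h.items()},
        "n_de": int(c.n_de),
        "concordance_frac": float(c.concordance_frac),
    }
    return mouse_matrix, human_matrix, table, design, truth


def simulate_four_group(c: SimConfig):
    """Four-group mouse study with planted group-mean pattern archetypes.

    Differentially expressed features draw their group-mean profile from
    n_archetypes distinct patterns; the rest are flat. Returns
    (ExprMatrix, DesignTable, truth ledger).
    """
    if c.n_archetypes < 2:
        raise ValueError("n_archetypes must be >= 2")
    if c.n_archetypes > len(ARCHETYPES):
        raise ValueError(f"at most {len(ARCHETYPES)} archetypes are defined")
    group_names = list(c.mouse_design)
    if len(group_names) != 4:
        raise ValueError("four-group simulation needs exactly 4 design groups")
    rng, = _streams(c.seed, 1)

    sample_ids, sp, gr, reps = _design("ms", "mouse", c.mouse_design)
    design = DesignTable(sample_ids, sp, gr, reps)

    n_features = c.n_probes_mouse
    n_de = min(c.n_de, n_features)
    de_idx = np.sort(rng.choice(n_features, size=n_de, replace=False))
    arch_names = [name for name, _pat in ARCHETYPES[: c.n_archetypes]]
    arch_pattern = dict(ARCHETYPES[: c.n_archetypes])
    assigned = [arch_names[i % c.n_archetypes] for i in range(n_de)]
    lo, hi = c.log2fc_range
    amplitudes = rng.uniform(lo, hi, n_de)

    feature_ids = [f"m_p{i + 1:05d}" for i in range(n_features)]
    baseline = rng.normal(c.baseline_mean, c.baseline_sd, n_features)
    group_index = {g: i for i, g in enumerate(group_names)}
    values = np.empty((n_features, len(sample_ids)))
    effect = np.zeros((n_features, 4))
    for j, fi in enumerate(de_idx):
        pat = arch_pattern[assigned[j]]
        effect[fi] = amplitudes[j] * np.asarray(pat, dtype=float)
    for si, g in enumerate(gr):
        mu = baseline + effect[:, group_index[g]]
        values[:, si] = mu + rng.normal(0.0, c.noise_sd, n_features)
    matrix = ExprMatrix(feature_ids, sample_ids, values)

    de_set = {int(i) for i in de_idx}
    truth = {
        "features": {
            feature_ids[i]: {
                "de": i in de_set,
                "archetype": assigned[list(de_idx).index(i)] if i in de_set else None,
                "amplitude": float(amplitudes[list(de_idx).index(i)]) if i in de_set else 0.0,
            }
            for i in range(n_features)
        },
        "archetypes": {name: list(arch_pattern[name]) for name in arch_names},
        "group_order": group_names,
        "n_archetypes": int(c.n_archetypes),
    }
    return matrix, design, truth


def simulate_qpcr(c: SimConfig):
    """qPCR panel: pathway genes plus flat housekeeping genes.

    Planted genes are shifted by -log2fc cycles in the test group (KO24), so
    up-regulation lowers Ct. A per-sample loading offset is added to every
    well; housekeeping normalization removes it. Returns
    (CtTable, DesignTable, truth ledger).
    """
    rng, = _streams(c.seed, 1)
    genes = [f"Wnt{i + 1:03d}" for i in range(c.n_qpcr_genes)] + HOUSEKEEPING_GENES
    groups = {"WT24": 3, "KO24": 3}
    sample_ids, sp, gr, reps = _design("qs", "mouse", groups)
    design = DesignTable(sample_ids, sp, gr, reps)

    n_de = min(c.n_de_qpcr, c.n_qpcr_genes)
    de_idx = np.sort(rng.choice(c.n_qpcr_genes, size=n_de, replace=False))
    lo, hi = c.log2fc_range
    log2fc = rng.uniform(lo, hi, n_de) * rng.choice([-1.0, 1.0], size=n_de)

    base_ct = np.concatenate(
        [rng.uniform(22.0, 30.0, c.n_qpcr_genes), rng.uniform(18.0, 22.0, 5)]
    )
    shift = np.zeros(len(genes))
    shift[de_idx] = -log2fc  # cycles in the test group
    sample_offset = rng.normal(0.0, 0.3, len(sample_ids))

    ct = np.empty((len(genes), len(sample_ids)))
    for si, g in enumerate(gr):
        mu = base_ct + (shift if g == "KO24" else 0.0) + sample_offset[si]
        ct[:, si] = mu + rng.normal(0.0, c.ct_noise_sd, len(genes))
    ct = np.clip(ct, 5.0, 40.0)
    table = CtTable(genes, sample_ids, ct, list(HOUSEKEEPING_GENES))

    truth = {
        "planted": {
            genes[int(i)]: {"log2fc": float(f)} for i, f in zip(de_idx, log2fc)
        },
        "housekeeping": list(HOUSEKEEPING_GENES),
        "test_group": "KO24",
        "ref_group": "WT24",
    }
    return table, design, truth
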