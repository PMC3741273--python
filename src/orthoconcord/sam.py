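"""Significance Analysis of Microarrays (two-class, unpaired).

The per-feature statistic is the regularized relative difference

    d_i = (mean_b - mean_a) / (s_i + s0),
    s_i = sqrt((1/n_a + 1/n_b) * (SS_a + SS_b) / (n_a + n_b - 2)),

with the exchangeability factor s0 chosen to minimize the coefficient of
variation of the windowed median absolute deviation of d across the scatter
distribution. Significance is assessed by comparing observed order
statistics d_(i) against their expected values over balanced label
permutations, with an asymmetric exceedance threshold delta; the FDR at a
threshold is the median permuted exceedance count over the observed called
count (times pi0). A linear fold-change gate is applied after threshold
selection, so the gate never influences delta.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .containers import DesignTable, ExprMatrix


@dataclass
class SamParams:
    s0: float | None = None  # None -> tune from the data
    n_perm: int = 200
    seed: int = 0
    fdr_max: float = 0.05
    fc_cutoff: float = 3.0
    pi0: float = 1.0

    def __post_init__(self) -> None:
        if self.s0 is not None and self.s0 < 0:
            raise ValueError("s0 must be nonnegative")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not (0 < self.fdr_max < 1):
            raise ValueError("fdr_max must lie in (0, 1)")
        if self.fc_cutoff < 1:
            raise ValueError("fc_cutoff must be >= 1")
        if not (0 < self.pi0 <= 1):
            raise ValueError("pi0 must lie in (0, 1]")


@dataclass
class SamResult:
    feature_ids: list[str]
    d: np.ndarray
    s: np.ndarray
    mean_a: np.ndarray
    mean_b: np.ndarray
    fc: np.ndarray
    s0: float
    group_a: str
    group_b: str
    # filled by permutation_fdr
    rank_order: np.ndarray | None = None  # feature indices sorted by (d, id)
    dbar: np.ndarray | None = None  # expected null order statistics
    delta: float | None = None
    fdr_est: float | None = None
    n_perm_used: int | None = None
    significant: np.ndarray | None = None
    direction: list[str] = field(default_factory=list)

    def significant_ids(self) -> list[str]:
        if self.significant is None:
            raise ValueError("permutation_fdr has not been run")
        return [f for f, s in zip(self.feature_ids, self.significant) if s]


def _group_arrays(m: ExprMatrix, d: DesignTable, group_a, group_b):
    sa = [s for s in d.samples_in(group_a) if s in set(m.sample_ids)]
    sb = [s for s in d.samples_in(group_b) if s in set(m.sample_ids)]
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError(
            f"both groups need >=2 samples (got {len(sa)} in {group_a!r}, "
            f"{len(sb)} in {group_b!r})"
        )
    ia = [m.sample_index(s) for s in sa]
    ib = [m.sample_index(s) for s in sb]
    return m.values[:, ia], m.values[:, ib]


def _d_stat(A: np.ndarray, B: np.ndarray, s0: float):
    na, nb = A.shape[1], B.shape[1]
    mean_a = A.mean(axis=1)
    mean_b = B.mean(axis=1)
    ss_a = ((A - mean_a[:, None]) ** 2).sum(axis=1)
    ss_b = ((B - mean_b[:, None]) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / na + 1.0 / nb) * (ss_a + ss_b) / (na + nb - 2))
    d = (mean_b - mean_a) / (s + s0)
    return d, s, mean_a, mean_b


def sam_statistic(
    m: ExprMatrix, design: DesignTable, group_a, group_b, s0: float
) -> SamResult:
    """Compute d, pooled scatter, group means and linear fold change."""
    if s0 < 0:
        raise ValueError("s0 must be nonnegative")
    A, B = _group_arrays(m, design, group_a, group_b)
    d, s, mean_a, mean_b = _d_stat(A, B, s0)
    fc = 2.0 ** (mean_b - mean_a)
    return SamResult(
        feature_ids=list(m.feature_ids),
        d=d,
        s=s,
        mean_a=mean_a,
        mean_b=mean_b,
        fc=fc,
        s0=float(s0),
        group_a=str(group_a),
        group_b=str(group_b),
    )


def tune_s0(m: ExprMatrix, design: DesignTable, group_a, group_b) -> float:
    """Choose s0 among percentiles of the scatter distribution.

    Candidates are the {0, 5, ..., 95} percentiles of s; the winner minimizes
    the coefficient of variation of mad(d) across s-quantile windows. With
    fewer than 50 features the windowed estimate is unstable and median(s)
    is returned instead.
    """
    A, B = _group_arrays(m, design, group_a, group_b)
    _, s, mean_a, mean_b = _d_stat(A, B, 0.0)
    diff = mean_b - mean_a
    n = len(s)
    if n < 50:
        return float(np.median(s))
    candidates = np.percentile(s, np.arange(0, 100, 5))
    order = np.argsort(s, kind="stable")
    n_win = 100 if n >= 500 else max(2, n // 25)
    windows = np.array_split(order, n_win)
    best_cv = math.inf
    best_s0 = float(candidates[0])
    for cand in candidates:
        cand = float(cand)
        dvals = diff / (s + cand)
        mads = np.array(
            [np.median(np.abs(dvals[w] - np.median(dvals[w]))) for w in windows]
        )
        mean_mad = mads.mean()
        cv = math.inf if mean_mad == 0 else mads.std() / mean_mad
        if cv < best_cv - 1e-12:
            best_cv = cv
            best_s0 = cand
        elif abs(cv - best_cv) <= 1e-12 and cand < best_s0:
            best_s0 = cand
    return best_s0


def _balanced_assignments(n: int, na: int, n_perm: int, seed: int) -> list[np.ndarray]:
    """Index sets for group a over the pooled samples.

    All C(n, na) distinct assignments are enumerated when that count fits in
    n_perm; otherwise n_perm assignments are drawn with a seeded generator.
    """
    total = math.comb(n, na)
    if total <= n_perm:
        return [np.array(c, dtype=int) for c in itertools.combinations(range(n), na)]
    rng = np.random.default_rng(seed)
    return [rng.permutation(n)[:na] for _ in range(n_perm)]


def _exceedance_counts(sorted_vals: np.ndarray, dbar: np.ndarray, grid: np.ndarray):
    """#(i : v_(i) - dbar_(i) > delta or < -delta) for every delta in grid."""
    e = np.sort(sorted_vals - dbar)
    hi = len(e) - np.searchsorted(e, grid, side="right")
    lo = np.searchsorted(e, -grid, side="left")
    return hi + lo


def permutation_fdr(
    result: SamResult,
    m: ExprMatrix,
    design: DesignTable,
    group_a,
    group_b,
    params: SamParams,
) -> SamResult:
    """Fill dbar, delta, fdr_est and the significant/direction calls."""
    A, B = _group_arrays(m, design, group_a, group_b)
    X = np.concatenate([A, B], axis=1)
    n = X.shape[1]
    na = A.shape[1]

    assignments = _balanced_assignments(n, na, params.n_perm, params.seed)
    n_perm_used = len(assignments)

    perm_sorted = np.empty((n_perm_used, X.shape[0]))
    all_idx = np.arange(n)
    for p, ia in enumerate(assignments):
        mask = np.zeros(n, dtype=bool)
        mask[ia] = True
        dp, _, _, _ = _d_stat(X[:, all_idx[mask]], X[:, all_idx[~mask]], result.s0)
        perm_sorted[p] = np.sort(dp)
    dbar = perm_sorted.mean(axis=0)

    # observed order statistics; ties broken by feature id for reproducibility
    ids = np.array(result.feature_ids)
    rank_order = np.lexsort((ids, result.d))
    d_sorted = result.d[rank_order]
    e_obs = d_sorted - dbar

    grid = np.unique(np.concatenate([[0.0], np.abs(e_obs)]))
    called = _exceedance_counts(d_sorted, dbar, grid)
    perm_counts = np.empty((n_perm_used, len(grid)))
    for p in range(n_perm_used):
        perm_counts[p] = _exceedance_counts(perm_sorted[p], dbar, grid)
    med_false = np.median(perm_counts, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(called > 0, params.pi0 * med_false / np.maximum(called, 1), 0.0)

    ok = np.nonzero(fdr <= params.fdr_max)[0]
    if len(ok) == 0:
        delta = math.inf
        fdr_at_delta = math.inf
    else:
        delta = float(grid[ok[0]])
        fdr_at_delta = float(fdr[ok[0]])

    called_mask_sorted = (e_obs > delta) | (e_obs < -delta)
    called_mask = np.zeros(len(ids), dtype=bool)
    called_mask[rank_order] = called_mask_sorted

    fc_gate = (result.fc >= params.fc_cutoff) | (result.fc <= 1.0 / params.fc_cutoff)
    significant = called_mask & fc_gate
    direction = [
        "up" if sig and mb > ma else "down" if sig and mb < ma else "none"
        for sig, ma, mb in zip(significant, result.mean_a, result.mean_b)
    ]

    result.rank_order = rank_order
    result.dbar = dbar
    result.delta = delta
    result.fdr_est = 0.0 if not np.isfinite(fdr_at_delta) else fdr_at_delta
    result.n_perm_used = n_perm_used
    result.significant = significant
    result.direction = direction
    return result


def run_sam(
    m: ExprMatrix, design: DesignTable, group_a, group_b, params: SamParams
) -> SamResult:
    """Convenience wrapper: tune s0 if unset, then statistic + permutation FDR."""
    s0 = params.s0 if params.s0 is not None else tune_s0(m, design, group_a, group_b)
    result = sam_statistic(m, design, group_a, group_b, s0)
    return permutation_fdr(result, m, design, group_a, group_b, params)


def pairwise_union(
    m: ExprMatrix,
    design: DesignTable,
    group_pairs: list[tuple],
    params: SamParams,
) -> tuple[list[str], dict[str, list[tuple[str, str]]], dict[tuple, SamResult]]:
    """Union of significant features across pairwise comparisons.

    Returns (sorted union ids, provenance {feature: [(comparison, direction)]},
    per-pair SamResult).
    """
    if not group_pairs:
        raise ValueError("group_pairs must not be empty")
    per_pair: dict[tuple, SamResult] = {}
    provenance: dict[str, list[tuple[str, str]]] = {}
    for pair in group_pairs:
        ga, gb = pair
        key = (ga, gb)
        if key in per_pair:
            continue
        res = run_sam(m, design, ga, gb, params)
        per_pair[key] = res
        tag = f"{gb}_vs_{ga}"
        for fid, sig, dirn in zip(res.feature_ids, res.significant, res.direction):
            if sig:
                provenance.setdefault(fid, []).append((tag, dirn))
    union = sorted(provenance)
    return union, provenance, per_pair


def result_records(res: SamResult) -> list[dict]:
    """Per-feature JSON-friendly records for reporting."""
    out = []
    sig = res.significant if res.significant is not None else [False] * len(res.feature_ids)
    dirn = res.direction if res.direction else ["none"] * len(res.feature_ids)
    for i, fid in enumerate(res.feature_ids):
        out.append(
            {
                "id": fid,
                "d": float(res.d[i]),
                "fc": float(res.fc[i]),
                "direction": dirn[i],
                "significant": bool(sig[i]),
            }
        )
    return out
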