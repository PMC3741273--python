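"""Hierarchical clustering with 1 - Pearson distance and average linkage,
tree cutting, three cluster-quality indices, and a consensus estimate of the
number of clusters.

Average linkage defines the distance between clusters as the mean of all
cross-cluster pairwise distances. Cluster-pair distances are recomputed from
the raw distance matrix at every merge with exactly rounded summation
(math.fsum), so heights do not depend on the order in which clusters were
built and are bit-identical to a direct definition-based evaluation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .containers import LinkageTree


@dataclass
class ClusterQuality:
    k: int
    silhouette: float | None = None
    inter_intra_ratio: float | None = None
    homogeneity: float | None = None
    separation: float | None = None
    combined_hs: float | None = None


def correlation_distance(profiles: np.ndarray, ids: list[str] | None = None) -> np.ndarray:
    """D_ij = 1 - Pearson r(x_i, x_j); symmetric, zero diagonal, range [0, 2]."""
    X = np.asarray(profiles, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("profiles must be 2-D with at least 2 coordinates")
    sd = X.std(axis=1)
    flat = np.nonzero(sd < 1e-12)[0]
    if len(flat):
        name = ids[flat[0]] if ids is not None else f"row {flat[0]}"
        raise ValueError(f"constant profile {name!r} has undefined correlation")
    R = np.corrcoef(X)
    R = (R + R.T) / 2.0
    D = np.clip(1.0 - R, 0.0, 2.0)
    np.fill_diagonal(D, 0.0)
    return D


def _cluster_pair_distance(D: np.ndarray, members_a: list[int], members_b: list[int]) -> float:
    """Mean raw distance over all cross pairs, exactly rounded."""
    sub = D[np.ix_(members_a, members_b)]
    return math.fsum(sub.ravel().tolist()) / sub.size


def average_linkage(D: np.ndarray) -> LinkageTree:
    """Agglomerate by minimal average inter-cluster distance.

    Ties are broken toward the lexicographically smallest (node_i, node_j)
    id pair; leaves are 0..n-1 and merge t creates node n+t.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items to cluster")
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    dist: dict[tuple[int, int], float] = {}
    active = sorted(members)
    for ai in range(len(active)):
        for aj in range(ai + 1, len(active)):
            i, j = active[ai], active[aj]
            dist[(i, j)] = float(D[i, j])

    merges: list[tuple[int, int, float, int]] = []
    for t in range(n - 1):
        best_pair = None
        best_val = math.inf
        for pair in sorted(dist):
            v = dist[pair]
            if v < best_val:
                best_val = v
                best_pair = pair
        i, j = best_pair
        new_id = n + t
        new_members = sorted(members[i] + members[j])
        merges.append((i, j, best_val, len(new_members)))

        others = [c for c in members if c not in (i, j)]
        del members[i], members[j]
        for pair in list(dist):
            if i in pair or j in pair:
                del dist[pair]
        for c in others:
            d_new = _cluster_pair_distance(D, new_members, members[c])
            key = (c, new_id) if c < new_id else (new_id, c)
            dist[key] = d_new
        members[new_id] = new_members
    return LinkageTree(merges, n)


def cut_tree(tree: LinkageTree, k: int) -> np.ndarray:
    """Flat assignment with exactly k clusters (undo the last k-1 merges).

    Labels are 1..k in order of first leaf appearance.
    """
    n = tree.leaf_count
    if not (1 <= k <= n):
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    parent: dict[int, int] = {}
    for t, (i, j, _h, _s) in enumerate(tree.merges[: n - k]):
        parent[i] = n + t
        parent[j] = n + t

    def root(x: int) -> int:
        while x in parent:
            x = parent[x]
        return x

    label_of_root: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    nxt = 1
    for leaf in range(n):
        r = root(leaf)
        if r not in label_of_root:
            label_of_root[r] = nxt
            nxt += 1
        out[leaf] = label_of_root[r]
    return out


def silhouette_index(assign: np.ndarray, D: np.ndarray) -> float:
    """Mean silhouette s(i) = (b - a)/max(a, b); singleton clusters score 0."""
    assign = np.asarray(assign)
    labels = np.unique(assign)
    if len(labels) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    n = len(assign)
    scores = np.zeros(n)
    masks = {lab: assign == lab for lab in labels}
    for i in range(n):
        own = masks[assign[i]]
        size_own = own.sum()
        if size_own == 1:
            scores[i] = 0.0
            continue
        a = D[i, own].sum() / (size_own - 1)
        b = min(D[i, masks[lab]].mean() for lab in labels if lab != assign[i])
        denom = max(a, b)
        scores[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(scores.mean())


def inter_intra_ratio(assign: np.ndarray, D: np.ndarray) -> float:
    """Pair-count-weighted mean inter-cluster distance over mean intra-cluster
    distance."""
    assign = np.asarray(assign)
    same = assign[:, None] == assign[None, :]
    iu = np.triu_indices(len(assign), k=1)
    intra = D[iu][same[iu]]
    inter = D[iu][~same[iu]]
    if intra.size == 0:
        raise ValueError("no intra-cluster pairs (all clusters are singletons)")
    if inter.size == 0:
        raise ValueError("no inter-cluster pairs (k must be >= 2)")
    return float(inter.mean() / intra.mean())


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.sqrt((xc**2).sum())
    ny = np.sqrt((yc**2).sum())
    if nx == 0 or ny == 0:
        return 0.0
    return float((xc * yc).sum() / (nx * ny))


def homogeneity_separation(
    assign: np.ndarray, profiles: np.ndarray
) -> tuple[float, float, float]:
    """(H, S, H - S) on standardized profiles.

    H is the mean Pearson similarity of items to their cluster centroid; S is
    the pair-count (n_i * n_j) weighted mean similarity between centroids.
    Items of a zero-variance centroid contribute similarity 0.
    """
    assign = np.asarray(assign)
    X = np.asarray(profiles, dtype=float)
    labels = list(np.unique(assign))
    if len(labels) < 2:
        raise ValueError("homogeneity/separation requires at least 2 clusters")
    centroids = {lab: X[assign == lab].mean(axis=0) for lab in labels}
    sims = [ _pearson(X[i], centroids[assign[i]]) for i in range(len(assign)) ]
    H = float(np.mean(sims))
    num = 0.0
    den = 0.0
    sizes = {lab: int((assign == lab).sum()) for lab in labels}
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            la, lb = labels[a], labels[b]
            w = sizes[la] * sizes[lb]
            num += w * _pearson(centroids[la], centroids[lb])
            den += w
    S = num / den
    return H, S, H - S


def _argmax_smallest_k(ks: list[int], vals: list[float]) -> int:
    best_k = ks[0]
    best_v = vals[0]
    for k, v in zip(ks[1:], vals[1:]):
        if v > best_v + 1e-12:
            best_v, best_k = v, k
    return best_k


def _knee_k(ks: list[int], vals: list[float]) -> int:
    """Elbow of a monotone-ish curve: largest drop in marginal gain.

    Maximizes 2 f(k) - f(k-1) - f(k+1) over interior points; falls back to
    the argmax of f when fewer than 3 grid points exist.
    """
    if len(ks) < 3:
        return _argmax_smallest_k(ks, vals)
    sec = [2 * vals[i] - vals[i - 1] - vals[i + 1] for i in range(1, len(ks) - 1)]
    return _argmax_smallest_k(ks[1:-1], sec)


def consensus_cluster_count(
    profiles: np.ndarray,
    k_range: list[int],
    ids: list[str] | None = None,
) -> tuple[int, list[ClusterQuality], dict[str, int], np.ndarray]:
    """Estimate the number of clusters by consensus of three indices.

    Each index nominates a k (silhouette: argmax; homogeneity-separation:
    argmax of H - S; inter/intra ratio: elbow). The consensus is the majority
    nomination; if all three differ, the median; ties resolve toward the
    silhouette nominee. Returns (k*, per-k quality table, nominations,
    assignment at k*).
    """
    ks = sorted(set(int(k) for k in k_range))
    n = np.asarray(profiles).shape[0]
    if not ks:
        raise ValueError("k_range must not be empty")
    if ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    D = correlation_distance(profiles, ids)
    tree = average_linkage(D)
    table: list[ClusterQuality] = []
    sil_vals, hs_vals, ratio_vals = [], [], []
    for k in ks:
        assign = cut_tree(tree, k)
        sil = silhouette_index(assign, D)
        ratio = inter_intra_ratio(assign, D)
        H, S, hs = homogeneity_separation(assign, profiles)
        table.append(
            ClusterQuality(
                k=k,
                silhouette=sil,
                inter_intra_ratio=ratio,
                homogeneity=H,
                separation=S,
                combined_hs=hs,
            )
        )
        sil_vals.append(sil)
        hs_vals.append(hs)
        ratio_vals.append(ratio)

    nominations = {
        "silhouette": _argmax_smallest_k(ks, sil_vals),
        "combined_hs": _argmax_smallest_k(ks, hs_vals),
        "inter_intra_ratio": _knee_k(ks, ratio_vals),
    }
    k_star = consensus_vote(nominations)
    assignment = cut_tree(tree, k_star)
    return k_star, table, nominations, assignment


def consensus_vote(nominations: dict[str, int]) -> int:
    """Combine index nominations: majority wins; three distinct values fall
    back to the median; ties resolve toward the silhouette nominee."""
    votes = list(nominations.values())
    counts = {k: votes.count(k) for k in set(votes)}
    top = max(counts.values())
    if top >= 2:
        winners = sorted(k for k, c in counts.items() if c == top)
        if nominations.get("silhouette") in winners:
            return nominations["silhouette"]
        return winners[0]
    return sorted(votes)[len(votes) // 2]
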