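"""Normalization and scaling steps applied before selection and clustering.

Quantile normalization stands in for the normalization step of RMA-style
preprocessing on an already-summarized probe-set matrix; probe-level
background correction and median-polish summarization need raw probe data
and are out of scope here. Row standardization uses the population (n)
standard deviation; since it only rescales each row, any downstream
correlation-based analysis is unaffected by this convention.
"""
from __future__ import annotations

import numpy as np

from .containers import DesignTable, ExprMatrix, GroupMeanMatrix

CONSTANT_ROW_TOL = 1e-12


def log2_transform(m: ExprMatrix) -> ExprMatrix:
    """Log2 of linear-scale intensities (floor at 1 to avoid -inf)."""
    return ExprMatrix(
        list(m.feature_ids), list(m.sample_ids), np.log2(np.maximum(m.values, 1.0))
    )


def quantile_normalize(m: ExprMatrix) -> ExprMatrix:
    """Force every sample column onto the mean order-statistic distribution.

    Ties within a column receive the mean of the reference quantile values
    their rank span covers, so tied inputs stay tied.
    """
    if len(m.sample_ids) < 2:
        raise ValueError("quantile normalization requires at least 2 samples")
    X = m.values
    order = np.argsort(X, axis=0, kind="stable")
    sorted_cols = np.take_along_axis(X, order, axis=0)
    reference = sorted_cols.mean(axis=1)

    out = np.empty_like(X)
    n = X.shape[0]
    for j in range(X.shape[1]):
        col = np.empty(n)
        col[order[:, j]] = reference
        # average reference values over tie groups of the input column
        vals = X[:, j]
        uniq, inv = np.unique(vals, return_inverse=True)
        sums = np.bincount(inv, weights=col, minlength=len(uniq))
        counts = np.bincount(inv, minlength=len(uniq))
        out[:, j] = (sums / counts)[inv]
    return ExprMatrix(list(m.feature_ids), list(m.sample_ids), out)


def standardize_rows(m: ExprMatrix) -> tuple[ExprMatrix, list[str]]:
    """Center each row to mean 0 and scale to population sd 1.

    Rows with sd below ``CONSTANT_ROW_TOL`` cannot be standardized; they are
    set to all-zero and their feature ids returned as the flagged list.
    """
    X = m.values
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)  # population (n) denominator
    flat = sd[:, 0] < CONSTANT_ROW_TOL
    safe_sd = np.where(flat[:, None], 1.0, sd)
    Z = (X - mu) / safe_sd
    Z[flat, :] = 0.0
    flagged = [f for f, is_flat in zip(m.feature_ids, flat) if is_flat]
    return ExprMatrix(list(m.feature_ids), list(m.sample_ids), Z), flagged


def standardize_matrix(values: np.ndarray) -> np.ndarray:
    """Row-standardize a bare array (flat rows become zero); helper form."""
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    flat = sd < CONSTANT_ROW_TOL
    Z = (values - mu) / np.where(flat, 1.0, sd)
    return np.where(flat, 0.0, Z)


def clip_values(m: ExprMatrix, lo: float, hi: float) -> ExprMatrix:
    """Confine values to [lo, hi] (the comparable-scale step, e.g. -3..3)."""
    if lo >= hi:
        raise ValueError(f"clip range requires lo < hi, got ({lo}, {hi})")
    return ExprMatrix(list(m.feature_ids), list(m.sample_ids), np.clip(m.values, lo, hi))


def group_means(
    m: ExprMatrix, d: DesignTable, group_order: list[str] | None = None
) -> GroupMeanMatrix:
    """Arithmetic mean per feature per design group.

    Column order follows ``group_order`` when given (the declared vocabulary),
    otherwise the design table's order of first appearance.
    """
    design_samples = set(d.sample_ids)
    for s in m.sample_ids:
        if s not in design_samples:
            raise ValueError(f"sample {s!r} has no design row")
    labels = group_order if group_order is not None else d.group_labels()
    cols = []
    for g in labels:
        members = [s for s in d.samples_in(g) if s in set(m.sample_ids)]
        if not members:
            raise ValueError(f"group {g!r} has no samples in the matrix")
        idx = [m.sample_ids.index(s) for s in members]
        cols.append(m.values[:, idx].mean(axis=1))
    return GroupMeanMatrix(list(m.feature_ids), list(labels), np.column_stack(cols))
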