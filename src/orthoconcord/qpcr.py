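"""Relative quantification of qPCR array data by the delta-delta-Ct method.

Each sample's Ct values are normalized against the arithmetic mean Ct of the
housekeeping genes (equivalent to the geometric mean of the linear
quantities). The group contrast is

    ddCt(g) = mean dCt_test(g) - mean dCt_ref(g),   FC(g) = 2^(-ddCt(g)),

with a two-sided Welch t-test on per-sample dCt values. Selection requires
both the fold-change gate (FC >= cutoff or <= 1/cutoff) and p below p_max.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CtTable, DesignTable

UNDETERMINED_CT = 40.0  # ceiling substituted for undetermined wells


def delta_ct(t: CtTable) -> np.ndarray:
    """Ct minus the per-sample mean housekeeping Ct (genes x samples)."""
    hk_rows = [t.gene_ids.index(h) for h in t.housekeeping]
    hk_mean = t.ct[hk_rows, :].mean(axis=0)
    return t.ct - hk_mean[None, :]


def ddct_analysis(
    t: CtTable,
    d: DesignTable,
    group_test: str,
    group_ref: str,
    fc_cutoff: float = 3.0,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Per-gene delta-delta-Ct report (housekeeping genes excluded).

    Columns: gene, delta_delta_ct, fc, direction, p_value, selected.
    """
    test = [s for s in d.samples_in(group_test) if s in set(t.sample_ids)]
    ref = [s for s in d.samples_in(group_ref) if s in set(t.sample_ids)]
    if len(test) < 2 or len(ref) < 2:
        raise ValueError(
            f"both groups need >=2 samples (got {len(test)} in {group_test!r}, "
            f"{len(ref)} in {group_ref!r})"
        )
    dct = delta_ct(t)
    it = [t.sample_ids.index(s) for s in test]
    ir = [t.sample_ids.index(s) for s in ref]
    hk = set(t.housekeeping)

    rows = []
    for gi, gene in enumerate(t.gene_ids):
        if gene in hk:
            continue
        a = dct[gi, it]
        b = dct[gi, ir]
        ddct = a.mean() - b.mean()
        fc = 2.0 ** (-ddct)
        if a.var() < 1e-24 and b.var() < 1e-24:
            p = 0.0 if ddct != 0 else 1.0  # degenerate zero-variance guard
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        selected = (fc >= fc_cutoff or fc <= 1.0 / fc_cutoff) and p < p_max
        direction = "up" if fc > 1 else "down" if fc < 1 else "none"
        rows.append(
            {
                "gene": gene,
                "delta_delta_ct": float(ddct),
                "fc": float(fc),
                "direction": direction,
                "p_value": p,
                "selected": bool(selected),
            }
        )
    return pd.DataFrame(rows)
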