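"""Univariate ROC-AUC screening of indices between two labelled cohorts.

The AUC is computed rank-based (Mann-Whitney with midranks for ties),
which equals the trapezoidal area under the empirical ROC curve:
AUC = P(b > a) + 0.5 P(b = a). Because the polarity of an index is
arbitrary across the catalogue, both the raw AUC and its folded value
max(AUC, 1 - AUC) are reported; significance is flagged on the folded
value against a single threshold (default 0.85), with an optional
Benjamini-Hochberg correction available but off by default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from .errors import InsufficientDataError

__all__ = ["roc_auc", "compare_cohorts", "AUC_THRESHOLD"]

AUC_THRESHOLD = 0.85


def roc_auc(values_a, values_b) -> float:
    """Probability that a random member of b exceeds one of a (ties half).

    NaNs are dropped; an empty group after dropping raises
    InsufficientDataError.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("empty group after dropping missing"
                                    " values")
    ranks = rankdata(np.concatenate([a, b]))
    rb = ranks[a.size:].sum()
    u_b = rb - b.size * (b.size + 1) / 2.0
    return float(u_b / (a.size * b.size))


def roc_auc_scipy(values_a, values_b) -> float:
    """Independent cross-check of :func:`roc_auc` via scipy's U statistic."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    u = mannwhitneyu(b, a, alternative="two-sided").statistic
    return float(u / (a.size * b.size))


def compare_cohorts(index_table: pd.DataFrame, label_a: str, label_b: str,
                    threshold: float = AUC_THRESHOLD,
                    bh_correction: bool = False) -> pd.DataFrame:
    """Screen every index between two labelled groups.

    ``index_table`` is the long-format table (subject_id, window_id,
    method, index_name, value) with a ``group`` column. Returns one row
    per index present in both groups: n_a, n_b (after missing-drop), raw
    and folded AUC, and the significance flag folded-AUC > threshold.

    With ``bh_correction`` the flag is additionally gated by a
    Benjamini-Hochberg-adjusted Mann-Whitney p-value < 0.05.
    """
    if "group" not in index_table.columns:
        raise KeyError("index table needs a 'group' column")
    for lab in (label_a, label_b):
        if lab not in set(index_table["group"]):
            raise KeyError(f"label {lab!r} not present in table")
    rows = []
    pvals = []
    for (name, method), sub in index_table.groupby(["index_name", "method"],
                                                   sort=True):
        va = sub.loc[sub["group"] == label_a, "value"].to_numpy(float)
        vb = sub.loc[sub["group"] == label_b, "value"].to_numpy(float)
        va, vb = va[np.isfinite(va)], vb[np.isfinite(vb)]
        if va.size == 0 or vb.size == 0:
            continue
        auc = roc_auc(va, vb)
        folded = max(auc, 1.0 - auc)
        if bh_correction:
            pvals.append(mannwhitneyu(vb, va,
                                      alternative="two-sided").pvalue)
        rows.append(dict(index_name=name, method=method,
                         n_a=int(va.size), n_b=int(vb.size),
                         auc=auc, auc_folded=folded,
                         significant=bool(folded > threshold)))
    report = pd.DataFrame(rows)
    if bh_correction and len(report):
        p = np.asarray(pvals)
        order = np.argsort(p)
        m = p.size
        adj = np.empty(m)
        running = 1.0
        for rank_i in range(m - 1, -1, -1):
            i = order[rank_i]
            running = min(running, p[i] * m / (rank_i + 1))
            adj[i] = running
        report["p_bh"] = adj
        report["significant"] &= adj < 0.05
    return report
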