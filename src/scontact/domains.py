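"""Domain-boundary probability and the chi-square variable-boundary test.

Operates on externally produced per-cell boundary calls (e.g. TopDom on
imputed 25 kb matrices): a boolean cells x bins matrix plus cell-type
labels.  The boundary probability of a bin in a type is the fraction of
that type's cells calling it a boundary; a bin is a *variable* boundary
when an n-types x 2 chi-square test survives Benjamini-Hochberg FDR
control and the max-min probability spread exceeds a minimum difference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["boundary_probability", "variable_boundary_test"]


def _validate(matrix, labels):
    m = np.asarray(matrix, dtype=bool)
    labels = np.asarray(labels)
    if m.shape[0] != len(labels):
        raise ValueError("label count != matrix rows (cells)")
    types = np.unique(labels)
    if any((labels == t).sum() == 0 for t in types):  # pragma: no cover
        raise ValueError("empty cell type")
    return m, labels, types


def boundary_probability(matrix, labels) -> pd.DataFrame:
    """Per-(cell type, bin) boundary probability: positives / cells of type."""
    m, labels, types = _validate(matrix, labels)
    if len(types) == 0 or m.shape[0] == 0:
        raise ValueError("no labelled cells")
    out = {t: m[labels == t].mean(axis=0) for t in types}
    df = pd.DataFrame(out)
    df.insert(0, "bin", np.arange(m.shape[1]))
    return df


def variable_boundary_test(
    matrix,
    labels,
    fdr: float = 0.001,
    min_diff: float = 0.05,
) -> pd.DataFrame:
    """Chi-square test for cell-type-variable domain boundaries.

    Per bin, an n x 2 contingency table (types x boundary
    presence/absence) is tested without continuity correction; BH FDR is
    computed across tested bins.  A bin is variable iff
    ``FDR < fdr`` and ``max - min boundary probability > min_diff``.
    Bins with zero positives in every type are skipped (``tested=False``).
    """
    m, labels, types = _validate(matrix, labels)
    if len(types) < 2:
        raise ValueError("need >= 2 cell types")
    n_bins = m.shape[1]
    groups = [m[labels == t] for t in types]
    pos = np.vstack([g.sum(axis=0) for g in groups]).T  # bins x types
    tot = np.array([g.shape[0] for g in groups])
    neg = tot[None, :] - pos
    probs = pos / tot[None, :]
    diff = probs.max(axis=1) - probs.min(axis=1)

    tested = pos.sum(axis=1) > 0
    chi2 = np.full(n_bins, np.nan)
    pval = np.full(n_bins, np.nan)
    low_expected = np.zeros(n_bins, dtype=bool)
    for b in np.flatnonzero(tested):
        table = np.stack([pos[b], neg[b]], axis=1)
        if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
            tested[b] = False
            continue
        res = stats.chi2_contingency(table, correction=False)
        chi2[b], pval[b] = res.statistic, res.pvalue
        low_expected[b] = (res.expected_freq < 5).any()

    fdr_vals = np.full(n_bins, np.nan)
    if tested.any():
        fdr_vals[tested] = multipletests(pval[tested], method="fdr_bh")[1]
    variable = tested & (fdr_vals < fdr) & (diff > min_diff)
    out = pd.DataFrame({
        "bin": np.arange(n_bins), "chi2": chi2, "p_value": pval, "fdr": fdr_vals,
        "prob_diff": diff, "tested": tested, "low_expected_count": low_expected,
        "variable": variable,
    })
    for i, t in enumerate(types):
        out[f"prob_{t}"] = probs[:, i]
    return out
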