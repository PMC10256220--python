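"""Agreement between this pipeline's subgroups and external stratifications.

Cross-tabulates two labelings over their shared samples and tests
association with Pearson's chi-squared (Yates continuity correction for
2x2 tables only).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

__all__ = ["cross_tabulate", "chi_squared_test"]

logger = logging.getLogger(__name__)


def cross_tabulate(labelsA: dict, labelsB: dict) -> pd.DataFrame:
    """Contingency table of two sample -> label mappings.

    Samples present in only one labeling are dropped (count logged). Rows
    are the first labeling's categories, columns the second's;
    ``df.attrs["row_pct"]`` and ``df.attrs["col_pct"]`` hold percentages.
    """
    shared = sorted(set(labelsA) & set(labelsB))
    dropped = len(set(labelsA) ^ set(labelsB))
    if not shared:
        raise ValueError("no shared samples between the two labelings")
    if dropped:
        logger.info("dropped %d samples not labeled by both methods", dropped)
    df = pd.crosstab(
        pd.Series({s: labelsA[s] for s in shared}, name="ours"),
        pd.Series({s: labelsB[s] for s in shared}, name="theirs"),
    )
    totals = df.to_numpy().sum()
    df.attrs["row_pct"] = df.div(df.sum(axis=1), axis=0) * 100.0
    df.attrs["col_pct"] = df.div(df.sum(axis=0), axis=1) * 100.0
    df.attrs["n"] = int(totals)
    df.attrs["dropped"] = dropped
    return df


def chi_squared_test(tbl: pd.DataFrame, yates_for_2x2: bool = True):
    """Pearson chi-squared test of independence.

    Returns (statistic, df, p). Yates continuity correction is applied for
    2x2 tables only (toggle with ``yates_for_2x2``). Zero row or column
    margins raise a ValueError.
    """
    counts = np.asarray(tbl, dtype=float)
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("zero row/column margin")
    correction = yates_for_2x2 and counts.shape == (2, 2)
    res = chi2_contingency(counts, correction=correction)
    return float(res.statistic), int(res.dof), float(res.pvalue)
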