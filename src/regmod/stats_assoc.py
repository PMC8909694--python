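"""Contingency-table association tests and multiplicity utilities.

Used for the clinical-style association tables (e.g. protein-staining level
vs tumor stage) and for adjusting the per-regulator selection-frequency
p-values.  Published tables often print only a cohort size and per-category
percentages; ``counts_from_percentages`` reconstructs integer cell counts
from those so the tests can be run on them.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable",
    "chi_square_test",
    "counts_from_percentages",
    "benjamini_hochberg",
]


class ContingencyTable:
    """Labelled non-negative integer counts, at least 2x2."""

    def __init__(
        self,
        counts,
        row_labels: list[str] | None = None,
        col_labels: list[str] | None = None,
    ) -> None:
        arr = np.asarray(counts)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("contingency table must be at least 2x2")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            arr = np.round(arr).astype(int)
        self.counts = arr
        self.row_labels = row_labels or [f"r{i}" for i in range(arr.shape[0])]
        self.col_labels = col_labels or [f"c{j}" for j in range(arr.shape[1])]


def chi_square_test(
    t: ContingencyTable, continuity_correction: bool = False
) -> tuple[float, int, float]:
    """Pearson chi-square test of independence: (statistic, df, p).

    Yates continuity correction is off by default (large-sample clinical
    tables); enable it via ``continuity_correction`` for small 2x2 tables.
    """
    if (t.counts.sum(axis=0) == 0).any() or (t.counts.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    res = stats.chi2_contingency(t.counts, correction=continuity_correction)
    if (res.expected_freq <= 0).any():
        raise ValueError("expected counts must all be positive")
    return float(res.statistic), int(res.dof), float(res.pvalue)


def counts_from_percentages(n: int, percents: list[float]) -> list[int]:
    """Integer cell counts from a cohort size and printed percentages.

    Each cell is round(n * p / 100); any rounding residual against ``n`` is
    assigned to the largest cell so the counts sum to ``n`` exactly.
    """
    percents = [float(p) for p in percents]
    if abs(sum(percents) - 100.0) > 0.5:
        raise ValueError(f"percentages sum to {sum(percents)}, expected ~100")
    counts = [int(round(n * p / 100.0)) for p in percents]
    residual = n - sum(counts)
    if residual:
        counts[int(np.argmax(counts))] += residual
    assert sum(counts) == n
    return counts


def benjamini_hochberg(p: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p_arr = np.asarray(p, dtype=float)
    if p_arr.size == 0:
        return []
    if (p_arr < 0).any() or (p_arr > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p_arr, method="fdr_bh")
    return [float(v) for v in p_adj]
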