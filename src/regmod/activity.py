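"""Regulator-activity inference from target-gene expression.

A transcription factor's protein-level activity is only partially reflected
by its own transcript, so the activity of regulator t in sample k is
estimated as the edge-score-weighted mean of the z-scored expression of its
target genes:

    act_tk = sum_i es_ti * g_ik / sum_i es_ti

with the modeling target gene itself excluded from every regulator's sum
(otherwise the regression below would see its own response among the
predictors).  Targets missing a value in a sample are dropped pairwise from
both sums for that sample, keeping the activity defined wherever at least
one scored target was measured.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix
from .regnet import RegulatoryNetwork, targets_of

logger = logging.getLogger(__name__)

__all__ = ["ActivityMatrix", "compute_activity"]


@dataclass
class ActivityMatrix:
    """Regulators x samples activity values (NaN where undefined)."""

    act: pd.DataFrame

    @property
    def regulator_ids(self) -> list[str]:
        return list(self.act.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.act.columns)

    def defined_regulators(self) -> list[str]:
        """Regulators with an activity value in every sample."""
        return list(self.act.index[self.act.notna().all(axis=1)])

    def subset_samples(self, samples: list[str]) -> "ActivityMatrix":
        return ActivityMatrix(self.act[samples])

    def to_tsv(self, path, na_token: str = "NA") -> None:
        self.act.to_csv(path, sep="\t", na_rep=na_token)


def compute_activity(
    x: ExpressionMatrix,
    net: RegulatoryNetwork,
    regulators: list[str],
    exclude_gene: str | None = None,
) -> ActivityMatrix:
    """Weighted-mean activities of ``regulators`` over the samples of ``x``.

    Targets absent from the (filtered) expression matrix are skipped; a
    regulator with no scored, measured target in any sample is flagged and
    left all-NaN so downstream stages can exclude it.
    """
    values = x.values
    out = np.full((len(regulators), values.shape[1]), np.nan)
    for i, reg in enumerate(regulators):
        pairs = [(t, es) for t, es in targets_of(net, reg, exclude=exclude_gene) if t in values.index]
        if not pairs:
            logger.warning("regulator %r has no measured targets; activity undefined", reg)
            continue
        genes = [t for t, _ in pairs]
        es = np.array([w for _, w in pairs])
        g = values.loc[genes].to_numpy()  # targets x samples
        present = ~np.isnan(g)
        num = np.nansum(es[:, None] * np.where(present, g, 0.0), axis=0)
        den = (es[:, None] * present).sum(axis=0)
        with np.errstate(invalid="ignore"):
            out[i] = np.where(den > 0, num / den, np.nan)
        if np.isnan(out[i]).all():
            logger.warning("regulator %r activity undefined in every sample", reg)
    return ActivityMatrix(pd.DataFrame(out, index=list(regulators), columns=values.columns))
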