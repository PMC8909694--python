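"""Expression-matrix I/O and preprocessing.

Expression arrives as a genes x samples TSV (first column gene id, header row
of sample ids, a configurable token for missing values).  Preprocessing
mirrors the standard pipeline for regulatory modeling on log-scale RNA-seq
matrices: drop genes with too many missing values, drop near-constant genes,
z-score each remaining gene across all samples of both conditions jointly,
then drop samples in which the modeling target gene itself is unmeasured.
The target gene is exempt from the gene-level filters (it must survive for
modeling), and an explicit override list can rescue additional genes whose
unfiltered values are wanted as-is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "read_expression",
    "read_conditions",
    "preprocess_expression",
    "write_expression",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with an NA mask and condition labels.

    ``values`` is a pandas DataFrame indexed by gene id with sample-id
    columns; missing entries are NaN.  ``condition`` maps sample id ->
    condition label (may be empty when no labels were supplied).
    """

    values: pd.DataFrame
    condition: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        """Number of samples currently in the matrix."""
        return self.values.shape[1]

    def samples_for(self, label: str) -> list[str]:
        return [s for s in self.sample_ids if self.condition.get(s) == label]

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        cond = {s: self.condition[s] for s in samples if s in self.condition}
        return ExpressionMatrix(self.values[samples].copy(), cond)

    def gene_values(self, gene: str) -> pd.Series:
        if gene not in self.values.index:
            raise KeyError(f"gene {gene!r} not in expression matrix")
        return self.values.loc[gene]


def read_expression(path: str | Path, na_token: str = "NA") -> ExpressionMatrix:
    """Read a genes x samples TSV; ``na_token`` cells become NaN.

    Hard errors on an empty file, duplicate gene ids, and any cell that is
    neither numeric nor the NA token (the offending gene/sample is named).
    """
    path = Path(path)
    raw = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False, header=0
    )
    if raw.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns found (malformed header?)")
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene ids {dups}")

    def parse_cell(v: str, gene: str, sample: str) -> float:
        if v == na_token or v == "":
            return np.nan
        try:
            return float(v)
        except ValueError:
            raise ValueError(
                f"{path}: non-numeric value {v!r} at gene {gene!r}, sample {sample!r}"
            ) from None

    values = pd.DataFrame(
        [
            [parse_cell(raw.iat[i, j], raw.index[i], raw.columns[j]) for j in range(raw.shape[1])]
            for i in range(raw.shape[0])
        ],
        index=raw.index.astype(str),
        columns=raw.columns.astype(str),
        dtype=float,
    )
    return ExpressionMatrix(values)


def read_conditions(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV (sample id, condition label) into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected 2 columns (sample, label)")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_expression(x: ExpressionMatrix, path: str | Path, na_token: str = "NA") -> None:
    x.values.to_csv(path, sep="\t", na_rep=na_token)


def preprocess_expression(
    x: ExpressionMatrix,
    target_gene: str,
    na_frac: float = 0.25,
    sd_min: float = 0.5,
    override: list[str] | None = None,
) -> ExpressionMatrix:
    """Filter, z-score, and drop samples missing the target gene.

    Samples without a value for ``target_gene`` are dropped first.  Then
    genes with a missing fraction strictly above ``na_frac`` are removed, as
    are genes whose sample standard deviation (ddof=1, non-missing entries,
    computed before z-scoring) is <= ``sd_min``.  ``target_gene`` and any
    gene listed in ``override`` bypass both filters.  Every retained gene is
    finally z-scored across all retained samples of both conditions jointly,
    so each retained gene ends with mean 0 and SD 1 over its non-missing
    entries.
    """
    if target_gene not in x.values.index:
        raise ValueError(f"target gene {target_gene!r} absent from expression matrix")
    exempt = {target_gene} | set(override or [])

    target_present = x.values.loc[target_gene].notna()
    samples = list(x.values.columns[target_present])
    if not samples:
        raise ValueError(f"all samples lack a value for target gene {target_gene!r}")
    vals = x.values[samples]

    n = vals.shape[1]
    na_ok = vals.isna().sum(axis=1) / n <= na_frac
    sd = vals.std(axis=1, ddof=1, skipna=True)
    sd_ok = sd > sd_min
    keep = (na_ok & sd_ok) | vals.index.isin(exempt)
    filtered = vals.loc[keep]

    mean = filtered.mean(axis=1, skipna=True)
    std = filtered.std(axis=1, ddof=1, skipna=True)
    # a zero-SD exempt gene cannot be z-scored; leave it centered only
    std = std.replace(0.0, 1.0).fillna(1.0)
    zscored = filtered.sub(mean, axis=0).div(std, axis=0)

    cond = {s: x.condition[s] for s in samples if s in x.condition}
    return ExpressionMatrix(zscored, cond)
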