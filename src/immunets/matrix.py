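"""The genes x samples expression container shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ExpressionMatrix:
    """A genes x samples numeric expression matrix with sample annotations.

    Attributes
    ----------
    values : pandas.DataFrame
        Numeric matrix, index = gene ids, columns = sample ids. Units are
        whatever the source provides (log2 intensity for microarray-like
        compendia, FPKM/TPM for RNA-seq cohorts).
    annotations : pandas.DataFrame
        One row per sample (index = sample ids), arbitrary key -> value
        columns (cell type / state, cohort / response, survival fields).
    """

    values: pd.DataFrame
    annotations: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.annotations is None:
            self.annotations = pd.DataFrame(index=self.values.columns)
        self.validate()

    def validate(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dupes = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if v.columns.duplicated().any():
            dupes = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes[:5]}")
        arr = v.to_numpy(dtype=float, copy=False)
        if arr.size and not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite")
        if not self.annotations.index.equals(v.columns):
            missing = v.columns.difference(self.annotations.index)
            if len(missing):
                raise ValueError(
                    f"samples missing from annotations: {list(missing)[:5]}"
                )
            self.annotations = self.annotations.loc[v.columns]

    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        ids = list(sample_ids)
        return ExpressionMatrix(
            self.values[ids].copy(), self.annotations.loc[ids].copy()
        )

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        ids = [g for g in gene_ids if g in self.values.index]
        return ExpressionMatrix(
            self.values.loc[ids].copy(), self.annotations.copy()
        )

    def samples_where(self, key: str, value) -> "ExpressionMatrix":
        """Subset to samples whose annotation `key` equals `value`."""
        mask = self.annotations[key] == value
        return self.subset_samples(self.annotations.index[mask])
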