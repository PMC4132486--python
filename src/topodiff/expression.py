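"""Gene-by-sample expression matrices with per-sample group/region labels."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

SAMPLE_COLUMNS = ("group", "region")


@dataclass
class ExpressionMatrix:
    """An expression matrix (rows = genes, columns = samples) plus sample metadata.

    Parameters
    ----------
    data:
        DataFrame of expression values; index = gene ids, columns = sample ids.
    samples:
        DataFrame indexed by sample id with at least a ``group`` column and
        optionally a ``region`` column. Column order must match ``data``.
    """

    data: pd.DataFrame
    samples: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if list(self.data.columns) != list(self.samples.index):
            raise ValueError("sample metadata index must match data columns")
        if "group" not in self.samples.columns:
            raise ValueError("sample metadata needs a 'group' column")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def groups(self) -> pd.Series:
        return self.samples["group"]

    def group_values(self, gene: str, group: str):
        """Expression values of one gene restricted to one sample group."""
        mask = (self.samples["group"] == group).to_numpy()
        return self.data.loc[gene].to_numpy()[mask]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        keep = [g for g in self.genes if g in set(genes)]
        return ExpressionMatrix(self.data.loc[keep], self.samples)

    def subset_group(self, group: str) -> "ExpressionMatrix":
        mask = (self.samples["group"] == group).to_numpy()
        return ExpressionMatrix(self.data.loc[:, mask], self.samples.loc[mask])

    # -- I/O: tab-delimited matrix + sample-metadata TSV ---------------------

    def to_tsv(self, matrix_path, samples_path) -> None:
        self.data.to_csv(matrix_path, sep="\t", index_label="gene")
        self.samples.to_csv(samples_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, matrix_path, samples_path) -> "ExpressionMatrix":
        data = pd.read_csv(Path(matrix_path), sep="\t", index_col="gene")
        samples = pd.read_csv(Path(samples_path), sep="\t", index_col="sample_id")
        return cls(data, samples.loc[data.columns])
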