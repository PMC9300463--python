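"""FPKM quantification, tissue summaries and expression-threshold filtering.

FPKM (fragments per kilobase of transcript per million mapped reads) is the
unit in which candidate thresholds are expressed throughout the discovery
pipeline; the library size used for normalization is the column sum of the
supplied gene-level counts, which makes the computation self-contained.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class CountsMatrix:
    """Gene-level counts with lengths and a sample-to-tissue design.

    values : genes x samples DataFrame of non-negative integers.
    gene_lengths : transcript length in bp per gene (same index as values).
    design : Series mapping sample id -> tissue label.
    """

    values: pd.DataFrame
    gene_lengths: pd.Series
    design: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("duplicate gene or sample identifiers")
        if not self.values.index.equals(self.gene_lengths.index):
            self.gene_lengths = self.gene_lengths.reindex(self.values.index)
        if self.gene_lengths.isna().any() or (self.gene_lengths <= 0).any():
            raise ValueError("every gene needs a positive length")
        missing = set(self.values.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"samples missing from design: {sorted(missing)}")
        if (np.asarray(self.values) < 0).any():
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_tsv(cls, counts_path: str | Path, design_path: str | Path) -> "CountsMatrix":
        """Read a counts TSV (gene_id, length, samples...) and a design TSV."""
        df = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
        lengths = df.pop("length")
        design = pd.read_csv(design_path, sep="\t", index_col="sample")["tissue"]
        return cls(values=df, gene_lengths=lengths, design=design)


@dataclass
class ExpressionMatrix:
    """Genes x samples FPKM values sharing ids and design with the source counts."""

    fpkm: pd.DataFrame
    design: pd.Series

    @property
    def gene_ids(self) -> pd.Index:
        return self.fpkm.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.fpkm.columns

    def log2(self, pseudocount: float = 1.0) -> pd.DataFrame:
        return np.log2(self.fpkm + pseudocount)

    def to_tsv(self, path: str | Path) -> None:
        self.fpkm.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, fpkm_path: str | Path, design_path: str | Path) -> "ExpressionMatrix":
        fpkm = pd.read_csv(fpkm_path, sep="\t", index_col="gene_id")
        design = pd.read_csv(design_path, sep="\t", index_col="sample")["tissue"]
        return cls(fpkm=fpkm, design=design)


def compute_fpkm(counts: CountsMatrix) -> ExpressionMatrix:
    """fpkm[g, s] = counts[g, s] * 1e9 / (length[g] * column_sum[s]).

    Raises if any sample has zero total counts (depth normalization undefined).
    """
    col_sums = counts.values.sum(axis=0)
    zero = col_sums[col_sums == 0]
    if len(zero):
        raise ValueError(f"zero mapped reads in sample(s): {list(zero.index)}")
    fpkm = (
        counts.values
        .div(counts.gene_lengths, axis=0)
        .div(col_sums, axis=1)
        * 1e9
    )
    return ExpressionMatrix(fpkm=fpkm, design=counts.design)


def tissue_mean(expr: ExpressionMatrix, tissue: str) -> pd.Series:
    """Arithmetic mean FPKM over the replicate columns of one tissue."""
    cols = [s for s in expr.sample_ids if expr.design.get(s) == tissue]
    if not cols:
        known = sorted(set(expr.design.loc[list(expr.sample_ids)]))
        raise ValueError(f"unknown tissue {tissue!r}; design has {known}")
    return expr.fpkm[cols].mean(axis=1)


def filter_expressed(expr: ExpressionMatrix, tissue: str, min_fpkm: float) -> set[str]:
    """Genes whose mean FPKM in ``tissue`` is >= ``min_fpkm`` (inclusive)."""
    if min_fpkm < 0:
        raise ValueError("min_fpkm must be >= 0")
    means = tissue_mean(expr, tissue)
    return set(means.index[means >= min_fpkm])
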