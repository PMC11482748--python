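"""Shared in-memory containers for expression data.

Matrices are plain pandas DataFrames (genes in rows, samples in columns,
log2 values) with companion metadata tables, mirroring the on-disk TSV
layout used throughout the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

PRE = "pre"
POST = "post"


@dataclass
class PairedExpressionSet:
    """A genes x samples log2 matrix with pre/post pairing metadata.

    ``samples`` is indexed by sample id with columns ``subject_id``,
    ``study_id`` and ``timepoint`` (pre|post); ``genes`` is indexed by
    gene id with at least ``symbol`` and ``biotype`` columns.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    genes: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("sample metadata must match matrix columns in order")
        missing = {"subject_id", "timepoint"} - set(self.samples.columns)
        if missing:
            raise ValueError(f"sample metadata missing columns: {sorted(missing)}")
        if self.genes is None:
            self.genes = pd.DataFrame(index=self.values.index)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    def subset_genes(self, gene_ids) -> "PairedExpressionSet":
        return PairedExpressionSet(
            self.values.loc[gene_ids], self.samples, self.genes.loc[gene_ids]
        )

    def paired_delta(self, subjects=None) -> pd.DataFrame:
        """Per-subject post-minus-pre log2 matrix (genes x subjects).

        Raises if any requested subject does not have exactly one pre and
        one post sample.
        """
        meta = self.samples
        if subjects is None:
            subjects = meta["subject_id"].unique().tolist()
        pre_cols, post_cols = [], []
        for subj in subjects:
            rows = meta[meta["subject_id"] == subj]
            pre = rows.index[rows["timepoint"] == PRE]
            post = rows.index[rows["timepoint"] == POST]
            if len(pre) != 1 or len(post) != 1:
                raise ValueError(
                    f"subject {subj!r} must have exactly one pre and one post sample "
                    f"(found {len(pre)} pre, {len(post)} post)"
                )
            pre_cols.append(pre[0])
            post_cols.append(post[0])
        delta = (
            self.values[post_cols].to_numpy() - self.values[pre_cols].to_numpy()
        )
        return pd.DataFrame(delta, index=self.values.index, columns=list(subjects))
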