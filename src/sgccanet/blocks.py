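"""Omics data blocks: samples x features matrices with identifiers and an omic type.

A block wraps a pandas DataFrame whose index holds sample identifiers and whose
columns hold feature identifiers.  Missing values are ordinary NaN and are
written to disk as ``NA``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError

OMIC_TYPES = ("cpg", "transcript", "mirna")


@dataclass
class OmicsBlock:
    """One omic's samples x features matrix.

    Parameters
    ----------
    data : pandas.DataFrame
        Samples in rows (index = sample ids), features in columns.
    omic_type : str
        One of ``cpg``, ``transcript``, ``mirna``.
    """

    data: pd.DataFrame
    omic_type: str

    def __post_init__(self) -> None:
        if self.omic_type not in OMIC_TYPES:
            raise ValidationError(f"unknown omic_type {self.omic_type!r}; expected one of {OMIC_TYPES}")
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.data.index.has_duplicates:
            raise ValidationError("duplicated sample identifiers")
        if self.data.columns.has_duplicates:
            raise ValidationError("duplicated feature identifiers")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids) -> "OmicsBlock":
        """Return a block restricted to the given samples, in the given order."""
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise ValidationError(f"samples not in block: {missing[:5]}")
        return OmicsBlock(self.data.loc[list(sample_ids)], self.omic_type)

    def copy(self) -> "OmicsBlock":
        return OmicsBlock(self.data.copy(), self.omic_type)

    def to_tsv(self, path) -> None:
        write_matrix_tsv(self.data, path)

    @classmethod
    def from_tsv(cls, path, omic_type: str) -> "OmicsBlock":
        return cls(read_matrix_tsv(path), omic_type)


def write_matrix_tsv(df: pd.DataFrame, path) -> None:
    """Write a samples x features matrix as TSV (first column sample id, NA for missing)."""
    df.to_csv(path, sep="\t", index_label="sample_id", na_rep="NA")


def read_matrix_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
    df.index.name = None
    return df


def write_table_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_table_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)


def check_aligned(blocks) -> None:
    """Raise unless all blocks share identical, identically ordered sample ids."""
    blocks = list(blocks)
    if not blocks:
        raise ValidationError("no blocks given")
    ref = blocks[0].sample_ids
    for b in blocks[1:]:
        if b.sample_ids != ref:
            raise ValidationError("blocks are not sample-aligned (ids or order differ)")
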