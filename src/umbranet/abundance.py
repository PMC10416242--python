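"""Sample-by-taxon count tables.

The :class:`AbundanceTable` is the pipeline's universal currency: a
non-negative integer (or real) matrix with samples as rows and taxa as
columns, wrapped around a :class:`pandas.DataFrame` so that standard
pandas idioms remain available via ``table.data``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AbundanceTable"]


@dataclass(frozen=True)
class AbundanceTable:
    """A samples x taxa abundance matrix.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are samples, columns are taxa. Entries must be non-negative
        and identifiers unique on both axes.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if not isinstance(df, pd.DataFrame):
            raise TypeError("AbundanceTable wraps a pandas DataFrame")
        dup_taxa = df.columns[df.columns.duplicated()].unique().tolist()
        if dup_taxa:
            raise ValueError(f"duplicate taxon identifiers: {dup_taxa}")
        dup_samples = df.index[df.index.duplicated()].unique().tolist()
        if dup_samples:
            raise ValueError(f"duplicate sample identifiers: {dup_samples}")
        values = df.to_numpy()
        if values.size and np.isnan(values.astype(float)).any():
            raise ValueError("abundance table contains missing values (ragged input?)")
        if values.size and (values.astype(float) < 0).any():
            bad = df.columns[(df < 0).any(axis=0)].tolist()
            raise ValueError(f"negative abundances in taxa: {bad}")

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def taxon_ids(self) -> list[str]:
        return [str(t) for t in self.data.columns]

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def counts(self) -> np.ndarray:
        """Return the underlying matrix as a numpy array (samples x taxa)."""
        return self.data.to_numpy()

    def select_taxa(self, taxa) -> "AbundanceTable":
        """Return a new table restricted to ``taxa`` (order preserved)."""
        missing = [t for t in taxa if t not in self.data.columns]
        if missing:
            raise KeyError(f"unknown taxa: {missing}")
        return AbundanceTable(self.data.loc[:, list(taxa)].copy())

    def prevalence(self) -> pd.Series:
        """Number of samples in which each taxon has nonzero abundance."""
        return (self.data > 0).sum(axis=0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AbundanceTable):
            return NotImplemented
        return self.data.equals(other.data)
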