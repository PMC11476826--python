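"""Gene-by-sample expression container with an explicit unit.

The central in-memory object is :class:`ExpressionMatrix`: a pandas DataFrame
of non-negative expression values (genes as rows, samples as columns) tagged
with the unit it is expressed in (``counts``, ``RPKM``, ``TPM`` or
``logTPM``), optional per-gene lengths (needed for RPKM) and optional
per-sample metadata (cell type, lot, passage).  Unit transitions happen only
through the operations in :mod:`panelqc.quantify`, so the tag can be trusted
downstream: correlation and clustering refuse anything but ``logTPM``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, UnitError

UNITS = ("counts", "RPKM", "TPM", "logTPM")

#: TPM columns must sum to one million within this relative tolerance.
TPM_SCALE = 1e6
TPM_RTOL = 1e-6


@dataclass
class ExpressionMatrix:
    """A gene-by-sample expression table with a declared unit.

    Parameters
    ----------
    values
        DataFrame with gene identifiers as the index and sample identifiers
        as columns.  Values must be non-negative except in ``logTPM`` unit.
    unit
        One of ``counts``, ``RPKM``, ``TPM``, ``logTPM``.
    gene_lengths
        Optional per-gene length in bases, indexed like ``values``; required
        by RPKM computation.
    sample_meta
        Optional per-sample metadata (index = sample ids); conventional
        columns are ``cell_type``, ``lot`` and ``passage``.
    attrs
        Free-form provenance (e.g. the log-imputation value, panel-subset
        bookkeeping).
    """

    values: pd.DataFrame
    unit: str
    gene_lengths: pd.Series | None = None
    sample_meta: pd.DataFrame | None = None
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise UnitError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise FormatError(f"duplicate gene identifiers: {list(dups[:5])}")
        arr = self.values.to_numpy()
        if self.unit != "logTPM" and arr.size and np.nanmin(arr) < 0:
            raise FormatError(f"negative values not allowed in unit {self.unit!r}")
        if self.unit == "TPM" and arr.size:
            sums = np.nansum(arr, axis=0)
            if not np.allclose(sums, TPM_SCALE, rtol=TPM_RTOL):
                bad = self.values.columns[~np.isclose(sums, TPM_SCALE, rtol=TPM_RTOL)]
                raise FormatError(
                    f"TPM columns must sum to 1e6; offending samples: {list(bad[:5])}"
                )
        if self.gene_lengths is not None:
            self.gene_lengths = self.gene_lengths.reindex(self.values.index)

    # -- basic accessors ---------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        """Restrict to the given genes, in the given order (all must exist)."""
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        return self.replace(values=self.values.loc[list(gene_ids)])

    def replace(self, **changes) -> "ExpressionMatrix":
        """Return a copy with the given fields replaced (attrs are copied)."""
        changes.setdefault("attrs", dict(self.attrs))
        return dataclasses.replace(self, **changes)

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_tsv(
        cls,
        path,
        unit: str,
        lengths_path=None,
        meta_path=None,
    ) -> "ExpressionMatrix":
        """Read a TSV with gene ids in the first column, samples as columns.

        ``lengths_path`` points to a 2-column TSV (gene id, length in bases);
        ``meta_path`` to a TSV of per-sample metadata with sample ids in the
        first column.
        """
        try:
            values = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        except pd.errors.EmptyDataError as exc:
            raise FormatError(f"empty expression table: {path}") from exc
        values.index = values.index.astype(str)
        lengths = None
        if lengths_path is not None:
            tbl = pd.read_csv(lengths_path, sep="\t", index_col=0, comment="#")
            if tbl.shape[1] != 1:
                raise FormatError("gene-length table must have exactly two columns")
            lengths = tbl.iloc[:, 0].astype(float)
            lengths.index = lengths.index.astype(str)
        meta = None
        if meta_path is not None:
            meta = pd.read_csv(meta_path, sep="\t", index_col=0, comment="#")
            meta.index = meta.index.astype(str)
        return cls(values=values, unit=unit, gene_lengths=lengths, sample_meta=meta)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")
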