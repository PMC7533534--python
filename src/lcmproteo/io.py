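"""Shared data model and tab-delimited I/O.

Intensity tables follow the MaxQuant ``proteinGroups.txt`` dialect: one row
per protein group, an identifier column, optional gene-symbol column, and one
intensity column per sample in which ``0`` (or an empty cell) encodes
non-detection.  Internally intensities are always log2-scale and missingness
is carried as an explicit boolean mask — a non-detection is never a number.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IntensityMatrix",
    "SampleMetadata",
    "SpectralCountTable",
    "FormatError",
    "read_intensity_table",
    "read_metadata",
    "write_results",
    "write_intensity_table",
    "write_metadata",
]

COMPARTMENTS = ("Glom", "PT", "Bulk")
PRESERVATIONS = ("OCT", "FFPE")

#: MaxQuant marker prefixes for decoy (reverse) and contaminant rows.
DECOY_PREFIXES = ("REV__", "CON__")


class FormatError(ValueError):
    """Raised when an input table does not match the expected dialect."""


@dataclass
class IntensityMatrix:
    """Protein-by-sample log2 relative intensities with an explicit missing mask.

    Parameters
    ----------
    values
        ``(n_proteins, n_samples)`` float array of log2 relative intensities.
        Entries where ``mask`` is True are non-detections and are stored as
        NaN so they can never silently enter arithmetic.
    mask
        Boolean array of the same shape; True marks *missing* (not detected).
    protein_ids
        Unique protein (group) identifiers, one per row.
    sample_ids
        Sample identifiers, one per column.
    gene_symbols
        Optional parallel list of gene symbols.
    """

    values: np.ndarray
    mask: np.ndarray
    protein_ids: list[str]
    sample_ids: list[str]
    gene_symbols: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.protein_ids = [str(p) for p in self.protein_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        n, m = self.values.shape
        if self.mask.shape != (n, m):
            raise ValueError("values and mask shapes differ")
        if len(self.protein_ids) != n or len(self.sample_ids) != m:
            raise ValueError("axis labels inconsistent with value grid")
        dup = _duplicates(self.protein_ids)
        if dup:
            raise ValueError(f"duplicate protein ids: {sorted(dup)}")
        if self.gene_symbols is not None and len(self.gene_symbols) != n:
            raise ValueError("gene_symbols length mismatch")
        if not np.all(np.isfinite(self.values[~self.mask])):
            raise ValueError("non-finite intensity outside the missing mask")
        # canonical representation: masked cells are NaN
        self.values = self.values.copy()
        self.values[self.mask] = np.nan

    # ------------------------------------------------------------------
    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def observed(self) -> np.ndarray:
        """Boolean grid, True where the protein was detected."""
        return ~self.mask

    def to_frame(self) -> pd.DataFrame:
        """Values as a DataFrame (NaN at missing), proteins as index."""
        return pd.DataFrame(self.values, index=self.protein_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "IntensityMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return IntensityMatrix(
            self.values[:, idx],
            self.mask[:, idx],
            list(self.protein_ids),
            [self.sample_ids[i] for i in idx],
            self.gene_symbols,
        )

    def subset_proteins(self, protein_ids: Sequence[str]) -> "IntensityMatrix":
        pos = {p: i for i, p in enumerate(self.protein_ids)}
        idx = [pos[p] for p in protein_ids]
        genes = [self.gene_symbols[i] for i in idx] if self.gene_symbols else None
        return IntensityMatrix(
            self.values[idx], self.mask[idx], list(protein_ids), list(self.sample_ids), genes
        )


@dataclass
class SampleMetadata:
    """Validated per-sample annotations (kidney, compartment, batch, preservation)."""

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("sample_id", "kidney_id", "compartment", "batch")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.table).copy()
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"metadata missing required columns: {missing}")
        if "preservation" not in df.columns:
            df["preservation"] = "OCT"
        for col in ("sample_id", "kidney_id", "compartment", "preservation"):
            df[col] = df[col].astype(str)
        df["batch"] = df["batch"].astype(str)
        dup = _duplicates(df["sample_id"].tolist())
        if dup:
            raise FormatError(f"duplicate sample ids: {sorted(dup)}")
        bad = sorted(set(df["compartment"]) - set(COMPARTMENTS))
        if bad:
            raise FormatError(
                f"unknown compartment labels {bad}; expected one of {list(COMPARTMENTS)}"
            )
        bad = sorted(set(df["preservation"]) - set(PRESERVATIONS))
        if bad:
            raise FormatError(f"unknown preservation labels {bad}")
        # a kidney may contribute at most one sample per compartment per batch
        counts = df.groupby(["kidney_id", "compartment", "batch"]).size()
        clashes = counts[counts > 1]
        if len(clashes):
            raise FormatError(
                "kidney contributes more than one sample per compartment per batch: "
                + ", ".join(map(str, clashes.index.tolist()))
            )
        self.table = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def kidneys(self) -> list[str]:
        return sorted(self.table["kidney_id"].unique())

    @property
    def batches(self) -> list[str]:
        return sorted(self.table["batch"].unique())

    def samples_for(
        self,
        compartment: str | None = None,
        batch: str | None = None,
        kidney: str | None = None,
    ) -> list[str]:
        df = self.table
        if compartment is not None:
            df = df[df["compartment"] == compartment]
        if batch is not None:
            df = df[df["batch"] == str(batch)]
        if kidney is not None:
            df = df[df["kidney_id"] == str(kidney)]
        return df["sample_id"].tolist()

    def require_samples(self, matrix: IntensityMatrix) -> None:
        """Check that every matrix sample has exactly one metadata row."""
        missing = set(matrix.sample_ids) - set(self.sample_ids)
        if missing:
            raise FormatError(f"samples without metadata: {sorted(missing)}")


@dataclass
class SpectralCountTable:
    """Protein-by-run spectral counts (non-negative integers)."""

    counts: np.ndarray
    protein_ids: list[str]
    run_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.allclose(self.counts, rounded):
                raise ValueError("spectral counts must be integral")
            self.counts = rounded.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("spectral counts must be non-negative")
        n, m = self.counts.shape
        if len(self.protein_ids) != n or len(self.run_ids) != m:
            raise ValueError("axis labels inconsistent with count grid")
        dup = _duplicates(self.protein_ids)
        if dup:
            raise ValueError(f"duplicate protein ids: {sorted(dup)}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.protein_ids, columns=self.run_ids)

    def run(self, run_id: str) -> pd.Series:
        return self.to_frame()[run_id]


# ----------------------------------------------------------------------
# readers / writers


def read_intensity_table(
    path: str | Path,
    id_column: str = "Protein IDs",
    intensity_columns: Sequence[str] | None = None,
    gene_column: str | None = None,
    raw_scale: bool = False,
    intensity_prefix: str = "Intensity ",
) -> IntensityMatrix:
    """Read a MaxQuant-style wide intensity table.

    Rows flagged as decoys or contaminants (``REV__``/``CON__`` identifier
    prefix, or a ``+`` in a ``Reverse`` / ``Potential contaminant`` column)
    are dropped.  Zero or empty intensity cells become masked non-detections.
    If ``raw_scale`` is true the retained intensities are log2-transformed at
    ingest; matrices always carry log2 values internally.

    ``intensity_columns`` defaults to every column starting with
    ``intensity_prefix`` (sample id = the remainder of the column name).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if id_column not in df.columns:
        raise FormatError(f"id column {id_column!r} not in table")
    if intensity_columns is None:
        intensity_columns = [c for c in df.columns if c.startswith(intensity_prefix)]
        sample_ids = [c[len(intensity_prefix):] for c in intensity_columns]
        if not intensity_columns:
            raise FormatError(
                f"no intensity columns found with prefix {intensity_prefix!r}"
            )
    else:
        absent = [c for c in intensity_columns if c not in df.columns]
        if absent:
            raise FormatError(f"intensity columns not in table: {absent}")
        sample_ids = [
            c[len(intensity_prefix):] if c.startswith(intensity_prefix) else c
            for c in intensity_columns
        ]

    keep = ~df[id_column].fillna("").str.startswith(DECOY_PREFIXES)
    for flag_col in ("Reverse", "Potential contaminant"):
        if flag_col in df.columns:
            keep &= df[flag_col].fillna("") != "+"
    df = df[keep]

    ids = df[id_column].tolist()
    dup = _duplicates(ids)
    if dup:
        raise FormatError(f"duplicate protein ids in input: {sorted(dup)}")

    raw = df[list(intensity_columns)].apply(pd.to_numeric, errors="coerce")
    values = raw.to_numpy(dtype=float)
    mask = ~np.isfinite(values) | (values == 0)
    values = np.where(mask, np.nan, values)
    if raw_scale:
        values = np.log2(values)

    genes = df[gene_column].tolist() if gene_column and gene_column in df.columns else None
    return IntensityMatrix(values, mask, ids, sample_ids, genes)


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read and validate a sample-metadata TSV.

    Required columns: sample_id, kidney_id, compartment, batch; an optional
    preservation column defaults to OCT.  An empty file yields an empty
    collection with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        warnings.warn(f"metadata file {path} contains no samples", stacklevel=2)
        for c in SampleMetadata.REQUIRED:
            if c not in df.columns:
                df[c] = pd.Series(dtype=str)
    return SampleMetadata(df)


def write_results(table: pd.DataFrame | Iterable, path: str | Path) -> None:
    """Write any result table as TSV: NA for missing, 6 significant digits."""
    if table is None:
        raise ValueError("table is None")
    df = pd.DataFrame(table)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def write_intensity_table(
    matrix: IntensityMatrix, path: str | Path, id_column: str = "Protein IDs"
) -> None:
    """Write a matrix back to the wide dialect (missing as empty cells)."""
    df = matrix.to_frame()
    df.columns = [f"Intensity {s}" for s in matrix.sample_ids]
    out = df.reset_index().rename(columns={"index": id_column})
    if matrix.gene_symbols is not None:
        out.insert(1, "Gene names", matrix.gene_symbols)
    out.to_csv(path, sep="\t", index=False, na_rep="", float_format="%.10g")


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    metadata.table.to_csv(path, sep="\t", index=False)


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for it in items:
        if it in seen:
            dup.add(it)
        seen.add(it)
    return dup
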