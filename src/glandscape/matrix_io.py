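"""Count-matrix containers and readers/writers for the supported dialects.

Conventions: genes are rows and cells are columns everywhere (the counts-table
convention of upstream read counters); files are UTF-8, tab-separated, with
"." as the decimal mark. MatrixMarket coordinate files are 1-based on disk;
all in-memory indexing is 0-based and the conversion is confined to this
module.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import FormatError

WELL_TYPES = ("sample", "neg_control", "pos_control")

GENE_COLUMNS = ("length_bp", "is_spikein")
CELL_COLUMNS = ("patient", "tissue", "well_type", "group")


def _spike_flag_from_ids(gene_ids) -> np.ndarray:
    """Spike-in flag derived from the conventional ``ERCC-`` id prefix."""
    return np.array([str(g).startswith("ERCC-") for g in gene_ids], dtype=bool)


@dataclass
class CountMatrix:
    """Genes × cells integer counts with gene and cell annotation tables.

    ``values`` is a DataFrame indexed by gene_id with cell_id columns.
    ``gene_table`` (indexed by gene_id) carries ``length_bp`` and
    ``is_spikein``; ``cell_table`` (indexed by cell_id) carries ``patient``,
    ``tissue``, ``well_type`` and ``group``.
    """

    values: pd.DataFrame
    gene_table: pd.DataFrame
    cell_table: pd.DataFrame

    def __post_init__(self):
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise FormatError(f"duplicate gene ids: {dupes[:5]}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise FormatError(f"duplicate cell ids: {dupes[:5]}")
        if list(self.values.index) != list(self.gene_table.index):
            raise FormatError("gene_table rows do not match matrix rows")
        if list(self.values.columns) != list(self.cell_table.index):
            raise FormatError("cell_table rows do not match matrix columns")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            raise FormatError("count matrix entries must be integers")
        if (arr < 0).any():
            raise FormatError("count matrix entries must be non-negative")

    # -- convenience views -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def spike_mask(self) -> pd.Series:
        return self.gene_table["is_spikein"].astype(bool)

    @property
    def well_type(self) -> pd.Series:
        return self.cell_table["well_type"]

    def nonspike_totals(self) -> pd.Series:
        """Per-well total count over biological (non-spike-in) genes."""
        return self.values.loc[~self.spike_mask].sum(axis=0)

    def subset_genes(self, gene_ids) -> "CountMatrix":
        gene_ids = list(gene_ids)
        return CountMatrix(
            self.values.loc[gene_ids],
            self.gene_table.loc[gene_ids],
            self.cell_table,
        )

    def subset_cells(self, cell_ids) -> "CountMatrix":
        cell_ids = list(cell_ids)
        return CountMatrix(
            self.values[cell_ids],
            self.gene_table,
            self.cell_table.loc[cell_ids],
        )

    def with_counts(self, new_values: np.ndarray) -> "CountMatrix":
        """Same annotations, new count array (used by the replicate simulator)."""
        df = pd.DataFrame(
            np.asarray(new_values, dtype=np.int64),
            index=self.values.index,
            columns=self.values.columns,
        )
        return CountMatrix(df, self.gene_table, self.cell_table)

    def equals(self, other: "CountMatrix") -> bool:
        return (
            self.values.equals(other.values)
            and list(self.gene_table.index) == list(other.gene_table.index)
            and list(self.cell_table.index) == list(other.cell_table.index)
        )


@dataclass
class ExpressionMatrix:
    """Genes × cells non-negative reals tagged with their unit."""

    values: pd.DataFrame
    unit: str  # one of {"counts", "FPKM", "TPM", "log2TPM"}

    VALID_UNITS = ("counts", "FPKM", "TPM", "log2TPM")

    def __post_init__(self):
        if self.unit not in self.VALID_UNITS:
            raise FormatError(f"unknown unit {self.unit!r}; expected one of {self.VALID_UNITS}")
        if (self.values.to_numpy() < 0).any():
            raise FormatError("expression values must be non-negative")


def _default_gene_table(gene_ids, lengths=None) -> pd.DataFrame:
    flags = _spike_flag_from_ids(gene_ids)
    table = pd.DataFrame(
        {"length_bp": np.nan, "is_spikein": flags},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    if lengths is not None:
        table["length_bp"] = [lengths.get(g, np.nan) for g in gene_ids]
    return table


def _default_cell_table(cell_ids, metadata: pd.DataFrame | None = None) -> pd.DataFrame:
    table = pd.DataFrame(
        {"patient": "NA", "tissue": "NA", "well_type": "sample", "group": "NA"},
        index=pd.Index(cell_ids, name="cell_id"),
    )
    if metadata is not None:
        missing = [c for c in cell_ids if c not in metadata.index]
        if missing:
            raise FormatError(f"cell metadata missing ids: {missing[:5]}")
        for col in metadata.columns:
            table[col] = metadata.loc[cell_ids, col]
    return table


# -- TSV dialect ----------------------------------------------------------


def read_counts_tsv(path, gene_lengths=None, cell_metadata=None) -> CountMatrix:
    """Read a tab-separated counts table (first column gene_id, header of cell ids).

    Entries must parse as non-negative integers; a non-integer or ragged row
    raises :class:`FormatError` naming the offending line (1-based, counting
    the header as line 1).
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    cell_ids = header[1:]
    n_cols = len(header)
    gene_ids: list[str] = []
    rows: list[list[int]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != n_cols:
            raise FormatError(
                f"{path}: line {lineno}: expected {n_cols} fields, found {len(fields)}"
            )
        gene_ids.append(fields[0])
        row = []
        for entry in fields[1:]:
            try:
                value = int(entry)
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer count {entry!r}"
                ) from exc
            if value < 0:
                raise FormatError(f"{path}: line {lineno}: negative count {entry!r}")
            row.append(value)
        rows.append(row)
    if len(set(gene_ids)) != len(gene_ids):
        seen, dupes = set(), []
        for g in gene_ids:
            if g in seen:
                dupes.append(g)
            seen.add(g)
        raise FormatError(f"{path}: duplicate gene ids: {sorted(set(dupes))[:5]}")
    if len(set(cell_ids)) != len(cell_ids):
        raise FormatError(f"{path}: duplicate cell ids in header")
    values = pd.DataFrame(
        np.array(rows, dtype=np.int64).reshape(len(gene_ids), len(cell_ids)),
        index=pd.Index(gene_ids, name="gene_id"),
        columns=pd.Index(cell_ids, name="cell_id"),
    )
    return CountMatrix(
        values,
        _default_gene_table(gene_ids, gene_lengths),
        _default_cell_table(cell_ids, cell_metadata),
    )


def write_counts_tsv(matrix: CountMatrix, path) -> None:
    df = matrix.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def write_cell_metadata(matrix: CountMatrix, path) -> None:
    table = matrix.cell_table.copy()
    table.index.name = "cell_id"
    table.to_csv(path, sep="\t")


def write_gene_table(matrix: CountMatrix, path) -> None:
    table = matrix.gene_table.copy()
    table.index.name = "gene_id"
    table.to_csv(path, sep="\t")


# -- MatrixMarket dialect -------------------------------------------------


def read_counts_mtx(directory, gene_lengths=None, cell_metadata=None) -> CountMatrix:
    """Read ``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv`` from a directory.

    The coordinate file is 1-based per the MatrixMarket standard; triplets
    absent from the file are zeros.
    """
    directory = Path(directory)
    mtx_path = directory / "matrix.mtx"
    genes_path = directory / "genes.tsv"
    barcodes_path = directory / "barcodes.tsv"
    for p in (mtx_path, genes_path, barcodes_path):
        if not p.exists():
            raise FormatError(f"missing file {p}")
    try:
        sparse = scipy.io.mmread(mtx_path)
    except ValueError as exc:
        raise FormatError(f"{mtx_path}: malformed MatrixMarket file: {exc}") from exc
    dense = np.asarray(sparse.todense() if scipy.sparse.issparse(sparse) else sparse)
    if not np.allclose(dense, np.round(dense)):
        raise FormatError(f"{mtx_path}: non-integer entries")
    dense = dense.astype(np.int64)
    gene_ids = [ln.split("\t")[0] for ln in genes_path.read_text().splitlines() if ln.strip()]
    cell_ids = [ln.split("\t")[0] for ln in barcodes_path.read_text().splitlines() if ln.strip()]
    if dense.shape != (len(gene_ids), len(cell_ids)):
        raise FormatError(
            f"{mtx_path}: declared shape {dense.shape} does not match "
            f"{len(gene_ids)} genes × {len(cell_ids)} barcodes"
        )
    values = pd.DataFrame(
        dense,
        index=pd.Index(gene_ids, name="gene_id"),
        columns=pd.Index(cell_ids, name="cell_id"),
    )
    return CountMatrix(
        values,
        _default_gene_table(gene_ids, gene_lengths),
        _default_cell_table(cell_ids, cell_metadata),
    )


def write_counts_mtx(matrix: CountMatrix, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.coo_matrix(matrix.values.to_numpy())
    scipy.io.mmwrite(str(directory / "matrix.mtx"), sparse, field="integer")
    (directory / "genes.tsv").write_text(
        "".join(f"{g}\n" for g in matrix.values.index), encoding="utf-8"
    )
    (directory / "barcodes.tsv").write_text(
        "".join(f"{c}\n" for c in matrix.values.columns), encoding="utf-8"
    )


# -- annotation tables ----------------------------------------------------


def _read_keyed_table(path, key_col: str, value_cols: list[str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = [key_col] + value_cols
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if df[key_col].isna().any():
        raise FormatError(f"{path}: missing {key_col} value")
    if df[key_col].duplicated().any():
        dupes = df.loc[df[key_col].duplicated(), key_col].tolist()
        raise FormatError(f"{path}: duplicate {key_col}: {dupes[:5]}")
    return df.set_index(key_col)


def read_gene_lengths(path) -> dict[str, int]:
    """Gene-length TSV (gene_id, length_bp) → mapping. '1e3' parses as 1000."""
    df = _read_keyed_table(path, "gene_id", ["length_bp"])
    lengths = {}
    for gene_id, raw in df["length_bp"].items():
        try:
            value = float(raw)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: bad length {raw!r} for {gene_id}") from exc
        if value <= 0 or value != int(value):
            raise FormatError(f"{path}: length for {gene_id} must be a positive integer, got {raw!r}")
        lengths[str(gene_id)] = int(value)
    return lengths


def read_cell_metadata(path) -> pd.DataFrame:
    """Metadata TSV (cell_id, patient, tissue, well_type) → cell table."""
    df = _read_keyed_table(path, "cell_id", ["patient", "tissue", "well_type"])
    bad = sorted(set(df["well_type"]) - set(WELL_TYPES))
    if bad:
        raise FormatError(f"{path}: unknown well_type values {bad}; expected {WELL_TYPES}")
    return df


def read_spike_concentrations(path) -> dict[str, float]:
    """Spike concentration TSV (spike_id, concentration) → mapping."""
    df = _read_keyed_table(path, "spike_id", ["concentration"])
    out = {}
    for spike_id, raw in df["concentration"].items():
        try:
            value = float(raw)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: bad concentration {raw!r} for {spike_id}") from exc
        if value < 0:
            raise FormatError(f"{path}: negative concentration for {spike_id}")
        out[str(spike_id)] = value
    return out
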