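"""Readers and writers for the on-disk formats the pipeline touches.

Count matrices follow the 10x Genomics convention: a Matrix Market
coordinate-integer file (``matrix.mtx``) with genes as rows and cells as
columns, plus ``features.tsv`` (gene id, gene symbol) and ``barcodes.tsv``
line-parallel to the matrix axes.  Gzipped inputs are read transparently;
output is always plain text so round-trips are bit-exact.

Tabular intermediates (sample metadata, DE tables, external DE tables) are
CSV with a header row; schemas are declared in :data:`TABLE_SCHEMAS`.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


class FormatError(Exception):
    """A required file is missing or not in the expected format."""


class CorruptMatrixError(FormatError):
    """Matrix dimensions disagree with the features/barcodes files."""


class NotCountMatrixError(ValueError):
    """Matrix entries are not nonnegative integers."""


class SchemaError(ValueError):
    """A table does not satisfy its declared schema."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Sparse genes x cells UMI count matrix with identifier axes.

    Parameters
    ----------
    values
        Sparse matrix of nonnegative integers, genes as rows.
    gene_ids
        Unique gene identifiers, one per row.
    gene_symbols
        Gene symbols parallel to ``gene_ids`` (need not be unique).
    cell_barcodes
        Unique cell barcodes, one per column.
    """

    values: sp.spmatrix
    gene_ids: list[str]
    gene_symbols: list[str]
    cell_barcodes: list[str]

    def __post_init__(self) -> None:
        self.values = sp.csc_matrix(self.values)
        self.values.eliminate_zeros()
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.gene_symbols = [str(g) for g in self.gene_symbols]
        self.cell_barcodes = [str(b) for b in self.cell_barcodes]
        self.validate()

    def validate(self) -> None:
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise SchemaError(
                f"gene_ids has {len(self.gene_ids)} entries but matrix has "
                f"{n_genes} rows"
            )
        if len(self.gene_symbols) != n_genes:
            raise SchemaError("gene_symbols must be parallel to gene_ids")
        if len(self.cell_barcodes) != n_cells:
            raise SchemaError(
                f"cell_barcodes has {len(self.cell_barcodes)} entries but "
                f"matrix has {n_cells} columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise SchemaError("gene_ids are not unique")
        if len(set(self.cell_barcodes)) != n_cells:
            raise SchemaError("cell_barcodes are not unique")
        data = self.values.data
        if data.size:
            if not np.issubdtype(data.dtype, np.integer):
                if not np.all(data == np.round(data)):
                    raise NotCountMatrixError("matrix entries are not integers")
            if data.min() < 0:
                raise NotCountMatrixError("matrix entries are negative")
        self.values = self.values.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def with_prefixed_barcodes(self, sample_id: str) -> "CountMatrix":
        """Namespace barcodes as ``<sample_id>:<barcode>`` for cohort assembly."""
        return CountMatrix(
            self.values,
            self.gene_ids,
            self.gene_symbols,
            [f"{sample_id}:{b}" for b in self.cell_barcodes],
        )


@dataclass
class SampleMetadata:
    """Per-subject record: condition, demographics, pathology staging."""

    sample_id: str
    condition: str  # "AD" or "NC"
    age_years: float = float("nan")
    sex: str = ""
    postmortem_delay_hours: float = float("nan")
    braak_stage: int | None = None

    def __post_init__(self) -> None:
        if self.condition not in ("AD", "NC"):
            raise SchemaError(
                f"sample {self.sample_id}: condition must be AD or NC, "
                f"got {self.condition!r}"
            )
        if self.braak_stage is not None and not np.isnan(self.braak_stage):
            b = int(self.braak_stage)
            if not 0 <= b <= 6:
                raise SchemaError(
                    f"sample {self.sample_id}: braak_stage must be 0-6, got {b}"
                )
            if self.condition == "AD" and b < 4:
                raise SchemaError(
                    f"sample {self.sample_id}: condition AD requires Braak "
                    f"stage >= 4, got {b}"
                )
            if self.condition == "NC" and b > 2:
                raise SchemaError(
                    f"sample {self.sample_id}: condition NC requires Braak "
                    f"stage <= 2, got {b}"
                )
            self.braak_stage = b


# ---------------------------------------------------------------------------
# 10x matrix reader / writer
# ---------------------------------------------------------------------------

_MTX_NAMES = ("matrix.mtx", "matrix.mtx.gz")
_FEATURE_NAMES = ("features.tsv", "features.tsv.gz", "genes.tsv", "genes.tsv.gz")
_BARCODE_NAMES = ("barcodes.tsv", "barcodes.tsv.gz")


def _find_file(directory: str, candidates: tuple[str, ...], what: str) -> str:
    for name in candidates:
        path = os.path.join(directory, name)
        if os.path.exists(path):
            return path
    raise FormatError(
        f"missing {what} file in {directory!r}: expected one of {candidates}"
    )


def _read_tsv_lines(path: str) -> list[list[str]]:
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "rt") as fh:
        return [line.rstrip("\n").split("\t") for line in fh if line.strip()]


def read_10x_mtx(directory: str) -> CountMatrix:
    """Read a 10x-convention matrix directory into a :class:`CountMatrix`.

    Orientation-safe: if the on-disk matrix is cells x genes it is detected
    via the features/barcodes line counts and transposed to genes x cells.
    """
    mtx_path = _find_file(directory, _MTX_NAMES, "matrix")
    feat_path = _find_file(directory, _FEATURE_NAMES, "features")
    bc_path = _find_file(directory, _BARCODE_NAMES, "barcodes")

    try:
        mat = scipy.io.mmread(mtx_path)
    except Exception as exc:  # pragma: no cover - scipy error text varies
        raise FormatError(f"cannot parse Matrix Market file {mtx_path}: {exc}")
    mat = sp.csc_matrix(mat)

    feat_rows = _read_tsv_lines(feat_path)
    barcodes = [row[0] for row in _read_tsv_lines(bc_path)]
    gene_ids = [row[0] for row in feat_rows]
    gene_symbols = [row[1] if len(row) > 1 else row[0] for row in feat_rows]

    n_feat, n_bc = len(gene_ids), len(barcodes)
    if mat.shape == (n_feat, n_bc):
        pass
    elif mat.shape == (n_bc, n_feat):
        mat = sp.csc_matrix(mat.T)
    else:
        raise CorruptMatrixError(
            f"matrix shape {mat.shape} matches neither (features={n_feat}, "
            f"barcodes={n_bc}) nor its transpose"
        )

    data = mat.data
    if data.size and not np.issubdtype(data.dtype, np.integer):
        if not np.all(data == np.round(data)):
            raise NotCountMatrixError(f"{mtx_path} contains non-integer counts")
    return CountMatrix(mat, gene_ids, gene_symbols, barcodes)


def write_10x_mtx(matrix: CountMatrix, directory: str) -> None:
    """Write a :class:`CountMatrix` as matrix.mtx + features.tsv + barcodes.tsv.

    Matrix Market coordinate integer, 1-based indices, genes as rows.
    ``read_10x_mtx`` inverts this exactly.
    """
    os.makedirs(directory, exist_ok=True)
    data = matrix.values.data
    if data.size and not np.issubdtype(data.dtype, np.integer):
        raise NotCountMatrixError("refusing to write non-integer counts")
    scipy.io.mmwrite(
        os.path.join(directory, "matrix.mtx"),
        sp.coo_matrix(matrix.values),
        field="integer",
    )
    with open(os.path.join(directory, "features.tsv"), "w") as fh:
        for gid, sym in zip(matrix.gene_ids, matrix.gene_symbols):
            fh.write(f"{gid}\t{sym}\tGene Expression\n")
    with open(os.path.join(directory, "barcodes.tsv"), "w") as fh:
        for bc in matrix.cell_barcodes:
            fh.write(bc + "\n")


# ---------------------------------------------------------------------------
# Tabular schemas
# ---------------------------------------------------------------------------

TABLE_SCHEMAS: dict[str, dict] = {
    "sample_metadata": {
        "required": ["sample_id", "condition"],
        "dtypes": {
            "sample_id": str,
            "condition": str,
            "age_years": float,
            "sex": str,
            "postmortem_delay_hours": float,
            "braak_stage": "Int64",
        },
    },
    "de_table": {
        "required": ["gene", "cell_type", "log2fc", "raw_p", "adjusted_p",
                     "direction", "significant"],
        "dtypes": {
            "gene": str,
            "cell_type": str,
            "log2fc": float,
            "raw_p": float,
            "adjusted_p": float,
            "direction": str,
            "significant": bool,
        },
    },
    "external_de": {
        "required": ["gene", "effect", "adjusted_p"],
        "dtypes": {"gene": str, "effect": float, "adjusted_p": float},
    },
}

# Columns accepted as aliases on read, normalized to the schema name.
_COLUMN_ALIASES = {
    "external_de": {"log2fc": "effect", "t_statistic": "effect", "t": "effect",
                    "adj_p": "adjusted_p", "adj_pval": "adjusted_p"},
}


def read_table(path: str, schema_name: str) -> pd.DataFrame:
    """Read a CSV/TSV table and validate it against a named schema.

    Unknown columns are preserved.  Missing required columns raise
    :class:`SchemaError` naming the column and schema.
    """
    if schema_name not in TABLE_SCHEMAS:
        raise SchemaError(
            f"unknown schema {schema_name!r}; known: {sorted(TABLE_SCHEMAS)}"
        )
    schema = TABLE_SCHEMAS[schema_name]
    sep = "\t" if path.endswith((".tsv", ".tsv.gz", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    df = df.rename(columns=_COLUMN_ALIASES.get(schema_name, {}))
    for col in schema["required"]:
        if col not in df.columns:
            raise SchemaError(
                f"table {path!r} is missing required column {col!r} for "
                f"schema {schema_name!r}"
            )
    for col, dtype in schema["dtypes"].items():
        if col in df.columns:
            df[col] = df[col].astype(dtype)
    if schema_name == "sample_metadata":
        for rec in df.to_dict("records"):
            SampleMetadata(
                sample_id=str(rec["sample_id"]),
                condition=str(rec["condition"]),
                age_years=float(rec.get("age_years", np.nan)),
                sex=str(rec.get("sex", "")),
                postmortem_delay_hours=float(
                    rec.get("postmortem_delay_hours", np.nan)
                ),
                braak_stage=rec.get("braak_stage"),
            )
    return df


def write_table(df: pd.DataFrame, path: str) -> None:
    """Write a table as CSV with repr-faithful float precision."""
    df.to_csv(path, index=False, float_format="%.17g")


def samples_to_frame(samples: list[SampleMetadata]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in samples])


def frame_to_samples(df: pd.DataFrame) -> list[SampleMetadata]:
    out = []
    for rec in df.to_dict("records"):
        braak = rec.get("braak_stage")
        if braak is not None and pd.isna(braak):
            braak = None
        out.append(
            SampleMetadata(
                sample_id=str(rec["sample_id"]),
                condition=str(rec["condition"]),
                age_years=float(rec.get("age_years", np.nan)),
                sex=str(rec.get("sex", "")),
                postmortem_delay_hours=float(
                    rec.get("postmortem_delay_hours", np.nan)
                ),
                braak_stage=braak,
            )
        )
    return out
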