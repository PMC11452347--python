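"""Readers and writers for on-disk artifacts, with strict validation.

On-disk layout mirrors the common droplet-scRNA-seq exchange formats:

* counts: MatrixMarket coordinate file (1-based on disk, 0-based in memory)
  with ``genes.tsv`` / ``barcodes.tsv`` sidecars, genes as rows, cells as
  columns;
* per-cell annotation, per-gene annotation, protein-protein interaction
  edges and reference ligand-receptor pairs as UTF-8 tab-delimited tables
  with a header row.

Gene symbols are case-sensitive primary keys throughout: display-case
carries provenance downstream (established pairs are shown in uppercase,
candidates in original case), so case must survive every round trip.
Annotation lookups that need to be forgiving resolve case-insensitively,
but stored identifiers are never re-cased.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "FormatError",
    "SchemaError",
    "CountMatrix",
    "PPINetwork",
    "LOCALIZATION_CLASSES",
    "ELIGIBLE_LOCALIZATIONS",
    "read_counts",
    "write_counts",
    "read_table",
    "write_table",
    "read_cell_annotation",
    "write_cell_annotation",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_ppi",
    "write_ppi",
    "read_reference_pairs",
    "write_reference_pairs",
    "validate_cell_annotation",
    "validate_gene_annotation",
]


class FormatError(ValueError):
    """A file violates its format contract (shape, sign, duplicates...)."""


class SchemaError(ValueError):
    """A table is missing a required column or holds an invalid value."""


#: Controlled vocabulary for predicted subcellular localization. Only the
#: first three classes make a gene eligible as a candidate ligand/receptor.
LOCALIZATION_CLASSES = (
    "plasma_membrane",
    "secreted",
    "extracellular_matrix",
    "other",
    "unknown",
)

ELIGIBLE_LOCALIZATIONS = frozenset(
    {"plasma_membrane", "secreted", "extracellular_matrix"}
)


# ---------------------------------------------------------------------------
# Count matrix
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Sparse genes x cells UMI count matrix with identifier sidecars.

    ``values`` is CSR with nonnegative integer entries; row ``i`` is
    ``gene_ids[i]``, column ``j`` is ``barcodes[j]``.
    """

    values: sp.csr_matrix
    gene_ids: list[str]
    barcodes: list[str]

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = list(self.gene_ids)
        self.barcodes = list(self.barcodes)
        n_genes, n_cells = self.values.shape
        if n_genes != len(self.gene_ids):
            raise FormatError(
                f"matrix has {n_genes} rows but {len(self.gene_ids)} gene ids"
            )
        if n_cells != len(self.barcodes):
            raise FormatError(
                f"matrix has {n_cells} columns but {len(self.barcodes)} barcodes"
            )
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.barcodes, "barcode")
        data = self.values.data
        if data.size:
            if np.any(data < 0):
                raise FormatError("count matrix contains negative entries")
            if not np.issubdtype(data.dtype, np.integer):
                if np.any(data != np.round(data)):
                    raise FormatError("count matrix contains non-integer entries")
                self.values = self.values.astype(np.int64)
        else:
            self.values = self.values.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def barcode_index(self) -> dict[str, int]:
        return {b: j for j, b in enumerate(self.barcodes)}


def _check_unique(items: list[str], what: str) -> None:
    seen: set[str] = set()
    for line_no, item in enumerate(items, start=1):
        if item in seen:
            raise FormatError(f"duplicate {what} {item!r} (entry {line_no})")
        seen.add(item)


def _read_id_column(path: str | Path, what: str) -> list[str]:
    ids: list[str] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            token = line.rstrip("\n").split("\t")[0].strip()
            if not token:
                continue
            if token in seen:
                raise FormatError(f"{path}: duplicate {what} {token!r} at line {line_no}")
            seen.add(token)
            ids.append(token)
    if not ids:
        raise FormatError(f"{path}: no {what}s found")
    return ids


def read_counts(
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
) -> CountMatrix:
    """Read a MatrixMarket coordinate file plus identifier sidecars.

    Coordinates are 1-based on disk (the MatrixMarket convention) and
    converted to the internal 0-based convention. Negative or non-integer
    entries, shape/sidecar mismatches and duplicate identifiers are
    rejected with a :class:`FormatError`.
    """
    gene_ids = _read_id_column(genes_path, "gene id")
    barcodes = _read_id_column(barcodes_path, "barcode")
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # scipy raises ValueError on bad headers
        raise FormatError(f"{matrix_path}: not a valid MatrixMarket file ({exc})")
    mat = sp.coo_matrix(mat)
    if mat.data.size and np.any(mat.data < 0):
        raise FormatError(f"{matrix_path}: negative count entry")
    if mat.data.size and np.any(mat.data != np.round(mat.data)):
        raise FormatError(f"{matrix_path}: non-integer count entry")
    if mat.shape != (len(gene_ids), len(barcodes)):
        raise FormatError(
            f"{matrix_path}: declared shape {mat.shape} does not match "
            f"{len(gene_ids)} genes x {len(barcodes)} barcodes"
        )
    return CountMatrix(mat.tocsr().astype(np.int64), gene_ids, barcodes)


def write_counts(
    counts: CountMatrix,
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
) -> None:
    scipy.io.mmwrite(str(matrix_path), counts.values.tocoo())
    Path(genes_path).write_text(
        "".join(f"{g}\n" for g in counts.gene_ids), encoding="utf-8"
    )
    Path(barcodes_path).write_text(
        "".join(f"{b}\n" for b in counts.barcodes), encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# Generic schema-checked TSV tables
# ---------------------------------------------------------------------------


@dataclass
class ColumnSpec:
    """One column of a TSV schema."""

    dtype: str = "str"  # str | float | int | bool01
    required: bool = True
    allow_missing: bool = False  # empty cells -> NaN (float) / None
    vocabulary: frozenset[str] | None = None
    collapse_to: str | None = None  # out-of-vocabulary values map here


@dataclass
class TableSchema:
    name: str
    columns: dict[str, ColumnSpec] = field(default_factory=dict)


def read_table(path: str | Path, schema: TableSchema) -> pd.DataFrame:
    """Read a tab-delimited table and validate it against ``schema``.

    Malformed numerics are rejected, never coerced; out-of-vocabulary
    labels raise unless the column declares a ``collapse_to`` class.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse as TSV ({exc})")
    for name, spec in schema.columns.items():
        if name not in df.columns:
            if spec.required:
                raise SchemaError(f"{path}: missing required column {name!r}")
            continue
        col = df[name]
        if spec.dtype in ("float", "int"):
            out = np.full(len(col), np.nan)
            for i, raw in enumerate(col):
                raw = raw.strip()
                if raw == "" or raw.upper() in ("NA", "NAN"):
                    if not spec.allow_missing:
                        raise SchemaError(
                            f"{path}: column {name!r} row {i + 2}: missing value"
                        )
                    continue
                try:
                    out[i] = float(raw)
                except ValueError:
                    raise SchemaError(
                        f"{path}: column {name!r} row {i + 2}: "
                        f"malformed numeric {raw!r}"
                    )
            if spec.dtype == "int":
                ok = np.isnan(out) | (out == np.round(out))
                if not ok.all():
                    bad = int(np.flatnonzero(~ok)[0])
                    raise SchemaError(
                        f"{path}: column {name!r} row {bad + 2}: not an integer"
                    )
            df[name] = out
        elif spec.dtype == "bool01":
            mapped = []
            for i, raw in enumerate(col):
                raw = raw.strip()
                if raw not in ("0", "1", "True", "False", "true", "false"):
                    raise SchemaError(
                        f"{path}: column {name!r} row {i + 2}: "
                        f"expected 0/1 boolean, got {raw!r}"
                    )
                mapped.append(raw in ("1", "True", "true"))
            df[name] = mapped
        elif spec.vocabulary is not None:
            mapped = []
            for i, raw in enumerate(col):
                raw = raw.strip()
                if raw in spec.vocabulary:
                    mapped.append(raw)
                elif spec.collapse_to is not None:
                    mapped.append(spec.collapse_to)
                else:
                    raise SchemaError(
                        f"{path}: column {name!r} row {i + 2}: "
                        f"label {raw!r} not in vocabulary"
                    )
            df[name] = mapped
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Cell annotation
# ---------------------------------------------------------------------------

CELL_SCHEMA = TableSchema(
    "cells",
    {
        "barcode": ColumnSpec(),
        "region": ColumnSpec(),
        "subtype": ColumnSpec(),
        "doublet_score": ColumnSpec(dtype="float", required=False, allow_missing=True),
        "empty_fdr": ColumnSpec(dtype="float", required=False, allow_missing=True),
    },
)


def validate_cell_annotation(
    df: pd.DataFrame, barcodes: Iterable[str] | None = None
) -> pd.DataFrame:
    for col in ("barcode", "region", "subtype"):
        if col not in df.columns:
            raise SchemaError(f"cell annotation missing column {col!r}")
        if (df[col].astype(str).str.strip() == "").any():
            raise SchemaError(f"cell annotation has empty {col!r} values")
    if df["barcode"].duplicated().any():
        dup = df.loc[df["barcode"].duplicated(), "barcode"].iloc[0]
        raise SchemaError(f"cell annotation has duplicate barcode {dup!r}")
    for col in ("doublet_score", "empty_fdr"):
        if col not in df.columns:
            df = df.assign(**{col: np.nan})
        vals = pd.to_numeric(df[col], errors="coerce")
        present = vals.notna()
        if ((vals[present] < 0) | (vals[present] > 1)).any():
            raise SchemaError(f"cell annotation column {col!r} outside [0, 1]")
        df[col] = vals
    if barcodes is not None:
        wanted = set(barcodes)
        have = set(df["barcode"])
        if wanted != have:
            missing = sorted(wanted - have)[:3]
            extra = sorted(have - wanted)[:3]
            raise SchemaError(
                "cell annotation barcodes do not match count matrix "
                f"(missing e.g. {missing}, extra e.g. {extra})"
            )
    return df


def read_cell_annotation(
    path: str | Path, barcodes: Iterable[str] | None = None
) -> pd.DataFrame:
    return validate_cell_annotation(read_table(path, CELL_SCHEMA), barcodes)


def write_cell_annotation(df: pd.DataFrame, path: str | Path) -> None:
    write_table(df, path)


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

GENE_SCHEMA = TableSchema(
    "genes_annot",
    {
        "gene": ColumnSpec(),
        # Vocabulary collapse is conservative: anything unrecognized
        # ("nucleus", "cytoplasm"...) maps to "other", never to an
        # eligible class, so it cannot spuriously enter the database.
        "localization_class": ColumnSpec(
            vocabulary=frozenset(LOCALIZATION_CLASSES), collapse_to="other"
        ),
        "is_mito": ColumnSpec(dtype="bool01"),
    },
)


def validate_gene_annotation(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("gene", "localization_class", "is_mito"):
        if col not in df.columns:
            raise SchemaError(f"gene annotation missing column {col!r}")
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
        raise SchemaError(f"gene annotation has duplicate gene {dup!r}")
    bad = ~df["localization_class"].isin(LOCALIZATION_CLASSES)
    if bad.any():
        raise SchemaError(
            f"gene annotation has invalid class "
            f"{df.loc[bad, 'localization_class'].iloc[0]!r}"
        )
    df = df.copy()
    df["is_mito"] = df["is_mito"].astype(bool)
    return df


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    return validate_gene_annotation(read_table(path, GENE_SCHEMA))


def write_gene_annotation(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["is_mito"] = out["is_mito"].astype(int)
    write_table(out, path)


# ---------------------------------------------------------------------------
# Protein-protein interaction network
# ---------------------------------------------------------------------------


@dataclass
class PPINetwork:
    """Undirected PPI edges, each flagged experimental or not.

    Edges are stored once per unordered pair; at most one record per pair,
    no self-edges.
    """

    edges: dict[frozenset, bool] = field(default_factory=dict)

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, bool]]) -> "PPINetwork":
        edges: dict[frozenset, bool] = {}
        for a, b, experimental in records:
            if a == b:
                raise FormatError(f"PPI self-edge on {a!r}")
            key = frozenset((a, b))
            if key in edges:
                raise FormatError(f"duplicate PPI edge {a!r}-{b!r}")
            edges[key] = bool(experimental)
        return cls(edges)

    def neighbors(self, gene: str, experimental_only: bool = False) -> set[str]:
        out: set[str] = set()
        for key, experimental in self.edges.items():
            if gene in key and (experimental or not experimental_only):
                (other,) = key - {gene}
                out.add(other)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(
            (tuple(sorted(key)) + (int(exp),) for key, exp in self.edges.items())
        )
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "experimental"])


PPI_SCHEMA = TableSchema(
    "ppi",
    {
        "gene_a": ColumnSpec(),
        "gene_b": ColumnSpec(),
        "experimental": ColumnSpec(dtype="bool01"),
    },
)


def read_ppi(path: str | Path) -> PPINetwork:
    df = read_table(path, PPI_SCHEMA)
    return PPINetwork.from_records(
        zip(df["gene_a"], df["gene_b"], df["experimental"])
    )


def write_ppi(ppi: PPINetwork, path: str | Path) -> None:
    write_table(ppi.to_frame(), path)


# ---------------------------------------------------------------------------
# Reference ligand-receptor pairs
# ---------------------------------------------------------------------------

REFERENCE_SCHEMA = TableSchema(
    "reference_pairs",
    {"ligand": ColumnSpec(), "receptor": ColumnSpec()},
)


def read_reference_pairs(path: str | Path) -> pd.DataFrame:
    df = read_table(path, REFERENCE_SCHEMA)
    if df.duplicated(subset=["ligand", "receptor"]).any():
        row = df[df.duplicated(subset=["ligand", "receptor"])].iloc[0]
        raise SchemaError(
            f"{path}: duplicate reference pair {row['ligand']}-{row['receptor']}"
        )
    return df


def write_reference_pairs(df: pd.DataFrame, path: str | Path) -> None:
    write_table(df[["ligand", "receptor"]], path)


def case_insensitive_lookup(mapping: Mapping[str, str], gene: str) -> str | None:
    """Resolve ``gene`` in a {lowercased symbol -> value} map.

    Annotation lookups are forgiving about case (Mfsd2a vs MFSD2A), but
    stored identifiers always keep their original case.
    """
    return mapping.get(gene.casefold())
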