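"""Domain containers and readers/writers for signature matrices and metadata.

The canonical in-memory objects are thin wrappers around pandas/numpy:

* :class:`SignatureMatrix` — dense genes x signatures matrix of
  differential-expression z-scores (the L1000 "landmark" feature space).
* :class:`SignatureMeta` — per-signature annotations (compound, cell line,
  dose, time) keyed by signature id.
* :class:`CompoundLabelSet` — positive/negative compound lists defining one
  mechanism-of-action (MOA) training set.

Supported on-disk formats are GCT v1.3 text, plain CSV (gene ids in the
first column, signature ids in the header), and delimited metadata tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SignatureMatrix",
    "SignatureMeta",
    "CompoundLabelSet",
    "FormatError",
    "ValidationError",
    "read_signature_matrix",
    "write_signature_matrix",
    "read_metadata",
    "write_metadata",
    "read_label_set",
    "write_label_set",
    "align",
]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """Inputs violate a domain invariant."""


@dataclass
class SignatureMatrix:
    """Dense genes x signatures matrix of differential-expression z-scores.

    Parameters
    ----------
    gene_ids : list of str
        Row identifiers, unique, order-preserving.
    sig_ids : list of str
        Column (signature) identifiers, unique, order-preserving.
    values : ndarray of shape (n_genes, n_signatures)
        Finite z-scores (dimensionless).
    """

    gene_ids: list[str]
    sig_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sig_ids = [str(s) for s in self.sig_ids]
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids")
        if len(set(self.sig_ids)) != len(self.sig_ids):
            raise ValidationError("duplicate signature ids")
        if self.values.shape != (len(self.gene_ids), len(self.sig_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.gene_ids)}, {len(self.sig_ids)})"
            )
        if not np.isfinite(self.values).all():
            raise ValidationError("matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_signatures(self) -> int:
        return len(self.sig_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sig_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SignatureMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def subset_signatures(self, sig_ids: list[str]) -> "SignatureMatrix":
        """Column subset, in the given order."""
        idx = {s: j for j, s in enumerate(self.sig_ids)}
        missing = [s for s in sig_ids if s not in idx]
        if missing:
            raise ValidationError(f"unknown signature ids: {missing[:5]}")
        cols = [idx[s] for s in sig_ids]
        return SignatureMatrix(self.gene_ids, list(sig_ids), self.values[:, cols])

    def subset_genes(self, gene_ids: list[str]) -> "SignatureMatrix":
        """Row subset, in the given order."""
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in idx]
        if missing:
            raise ValidationError(f"missing feature genes: {missing}")
        rows = [idx[g] for g in gene_ids]
        return SignatureMatrix(list(gene_ids), self.sig_ids, self.values[rows, :])

    def column(self, sig_id: str) -> np.ndarray:
        return self.values[:, self.sig_ids.index(sig_id)]


_META_REQUIRED = ("sig_id", "compound_id", "cell_line")
_META_OPTIONAL = ("dose", "time")


@dataclass
class SignatureMeta:
    """Per-signature annotations, one row per signature id.

    ``table`` has columns sig_id, compound_id, cell_line, dose, time;
    missing optional fields are stored as the explicit string "unknown".
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        for col in _META_REQUIRED:
            if col not in df.columns:
                raise ValidationError(f"metadata missing required column: {col!r}")
        for col in _META_OPTIONAL:
            if col not in df.columns:
                df[col] = "unknown"
        df = df[list(_META_REQUIRED + _META_OPTIONAL)]
        for col in df.columns:
            df[col] = df[col].astype(str)
        df[list(_META_OPTIONAL)] = df[list(_META_OPTIONAL)].replace(
            {"nan": "unknown", "": "unknown"}
        )
        if df["sig_id"].duplicated().any():
            dups = df.loc[df["sig_id"].duplicated(), "sig_id"].tolist()
            raise ValidationError(f"duplicated sig_id(s): {dups[:5]}")
        if (df["compound_id"].isin(("", "nan"))).any():
            raise ValidationError("empty compound_id in metadata")
        if (df["cell_line"].isin(("", "nan"))).any():
            raise ValidationError("empty cell_line in metadata")
        self.table = df.reset_index(drop=True)

    @property
    def sig_ids(self) -> list[str]:
        return self.table["sig_id"].tolist()

    def indexed(self) -> pd.DataFrame:
        return self.table.set_index("sig_id")

    def subset(self, sig_ids: list[str]) -> "SignatureMeta":
        sub = self.indexed().loc[list(sig_ids)].reset_index()
        return SignatureMeta(sub)

    def compound_of(self, sig_id: str) -> str:
        return self.indexed().at[sig_id, "compound_id"]

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class CompoundLabelSet:
    """Positive/negative compound ids for one MOA training set."""

    positives: set[str]
    negatives: set[str]
    moa_name: str = "moa"

    def __post_init__(self) -> None:
        self.positives = {str(c) for c in self.positives}
        self.negatives = {str(c) for c in self.negatives}
        if not self.positives:
            raise ValidationError("positive compound set is empty")
        overlap = self.positives & self.negatives
        if overlap:
            raise ValidationError(
                f"compounds labeled both positive and negative: {sorted(overlap)[:5]}"
            )


# ---------------------------------------------------------------------------
# Signature matrix IO


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "gct" if path.suffix.lower() == ".gct" else "csv"


def read_signature_matrix(path: str | Path, format: str | None = None) -> SignatureMatrix:
    """Read a genes x signatures z-score matrix from GCT v1.3 text or CSV.

    CSV: gene ids in the first column, signature ids in the header row.
    GCT v1.3: ``#1.3`` header, a dimension line ``nrow ncol nrmeta ncmeta``,
    then a header row and data rows; only the data block and row/column ids
    are consumed (metadata rows/columns are skipped).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "gct":
        return _read_gct(path)
    if fmt == "csv":
        with open(path) as fh:
            _check_header_unique(fh.readline().rstrip("\n").split(","), path)
        df = pd.read_csv(path, index_col=0)
        return _frame_to_matrix(df, path)
    raise FormatError(f"unknown format {fmt!r}; expected 'gct' or 'csv'")


def _check_header_unique(fields: list[str], path: Path) -> None:
    # pandas silently mangles duplicate column names, so check the raw header
    seen: set[str] = set()
    for f in fields[1:]:
        if f in seen:
            raise ValidationError(f"{path}: duplicate signature id {f!r}")
        seen.add(f)


def _frame_to_matrix(df: pd.DataFrame, path: Path) -> SignatureMatrix:
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric value at gene {df.index[i]!r}, "
            f"signature {df.columns[j]!r}"
        )
    if numeric.isna().any().any():
        raise ValidationError(f"{path}: matrix contains missing values")
    try:
        return SignatureMatrix.from_frame(numeric)
    except ValidationError as e:
        raise ValidationError(f"{path}: {e}") from e


def _read_gct(path: Path) -> SignatureMatrix:
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.3":
            raise FormatError(f"{path}: expected '#1.3' header, got {version!r}")
        dims = fh.readline().split()
        if len(dims) not in (2, 4) or not all(d.lstrip("-").isdigit() for d in dims):
            raise FormatError(f"{path}: malformed GCT dimension line: {dims}")
        nrow, ncol = int(dims[0]), int(dims[1])
        nrmeta = int(dims[2]) if len(dims) == 4 else 0
        ncmeta = int(dims[3]) if len(dims) == 4 else 0
        header_pos = fh.tell()
        _check_header_unique(
            fh.readline().rstrip("\n").split("\t")[nrmeta:], path
        )
        fh.seek(header_pos)
        body = pd.read_csv(fh, sep="\t", header=0, index_col=0, dtype=str)
    # drop row-metadata columns and column-metadata rows
    data = body.iloc[ncmeta:, nrmeta:]
    if data.shape != (nrow, ncol):
        raise FormatError(
            f"{path}: data block shape {data.shape} does not match declared "
            f"({nrow}, {ncol})"
        )
    return _frame_to_matrix(data, path)


def write_signature_matrix(
    matrix: SignatureMatrix, path: str | Path, format: str | None = None
) -> None:
    """Write a matrix as GCT v1.3 text (no metadata block) or CSV."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        matrix.to_frame().to_csv(path)
    elif fmt == "gct":
        with open(path, "w") as fh:
            fh.write("#1.3\n")
            fh.write(f"{matrix.n_genes}\t{matrix.n_signatures}\t0\t0\n")
            matrix.to_frame().to_csv(fh, sep="\t", index_label="id", lineterminator="\n")
    else:
        raise FormatError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# Metadata and label-set IO


def read_metadata(path: str | Path) -> SignatureMeta:
    """Read a metadata table (TSV or CSV by extension, default TSV)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    return SignatureMeta(df)


def write_metadata(meta: SignatureMeta, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    meta.table.to_csv(path, sep=sep, index=False)


def read_label_set(path: str | Path, moa_name: str = "moa") -> CompoundLabelSet:
    """Read a two-column CSV (compound_id, label in {positive, negative})."""
    df = pd.read_csv(path, dtype=str)
    if not {"compound_id", "label"} <= set(df.columns):
        raise ValidationError(f"{path}: need columns compound_id, label")
    labels = set(df["label"].unique()) - {"positive", "negative"}
    if labels:
        raise ValidationError(f"{path}: unknown labels {sorted(labels)}")
    return CompoundLabelSet(
        positives=set(df.loc[df["label"] == "positive", "compound_id"]),
        negatives=set(df.loc[df["label"] == "negative", "compound_id"]),
        moa_name=moa_name,
    )


def write_label_set(labels: CompoundLabelSet, path: str | Path) -> None:
    rows = [(c, "positive") for c in sorted(labels.positives)]
    rows += [(c, "negative") for c in sorted(labels.negatives)]
    pd.DataFrame(rows, columns=["compound_id", "label"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------


def align(
    matrix: SignatureMatrix, meta: SignatureMeta
) -> tuple[SignatureMatrix, SignatureMeta]:
    """Intersect matrix columns with annotated signatures.

    Returns the matrix restricted to signatures that have metadata (in matrix
    column order) and the metadata restricted and reordered to match.
    Signatures lacking metadata are dropped with a warning.
    """
    meta_ids = set(meta.sig_ids)
    keep = [s for s in matrix.sig_ids if s in meta_ids]
    if not keep:
        raise ValidationError("no overlap between matrix signatures and metadata")
    dropped = len(matrix.sig_ids) - len(keep)
    if dropped:
        warnings.warn(f"align: dropped {dropped} signature(s) without metadata")
    return matrix.subset_signatures(keep), meta.subset(keep)
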