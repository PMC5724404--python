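"""Readers and writers for every external artifact.

In-memory containers are plain pandas objects:

* expression matrix — ``DataFrame`` of float fluorescence, probes in rows
  (index = probe ids), samples in columns, RMA-normalized log2 scale;
* sample metadata — ``Series`` mapping sample id to ``"male"``/``"female"``;
* probe annotation — ``DataFrame`` indexed by probe id with columns
  ``gene_symbol`` and ``chromosome``;
* gene-set collection — ``dict`` mapping set name to :class:`GeneSet`;
* qPCR table — long-format ``DataFrame`` with columns ``gene_symbol``,
  ``sample_id``, ``ct``.

All delimited text; matrices must already be post-RMA log2 values (CEL
parsing and RMA are deliberately out of scope). Missing values are rejected,
not imputed: RMA output is complete, so a hole indicates a broken file.
Writers emit a leading ``#`` comment header with the tool version and the
parameters used; readers skip such lines.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "GeneSet",
    "read_expression_matrix",
    "write_expression_matrix",
    "validate_expression_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_probe_annotation",
    "write_probe_annotation",
    "read_gmt",
    "write_gmt",
    "read_qpcr_table",
    "write_qpcr_table",
]

_SEX_TOKENS = {"male": "male", "m": "male", "female": "female", "f": "female"}


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


@dataclass(frozen=True)
class GeneSet:
    """One named gene set (GMT line): description plus member symbols."""

    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise FormatError("gene set has no members")


def _comment_header(params: Mapping[str, object] | None = None) -> str:
    from ygate import __version__

    lines = [f"# ygate {__version__}"]
    for key, value in (params or {}).items():
        lines.append(f"# {key}={value}")
    return "\n".join(lines) + "\n"


def _strip_comments(text: str) -> str:
    return "".join(
        line for line in text.splitlines(keepends=True) if not line.startswith("#")
    )


def validate_expression_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check the expression-matrix invariants, returning the matrix.

    Raises :class:`FormatError` on duplicate probe/sample ids or non-finite
    values.
    """
    dup_probes = matrix.index[matrix.index.duplicated()].unique()
    if len(dup_probes):
        raise FormatError(f"duplicate probe id(s): {', '.join(map(str, dup_probes))}")
    dup_samples = matrix.columns[matrix.columns.duplicated()].unique()
    if len(dup_samples):
        raise FormatError(f"duplicate sample id(s): {', '.join(map(str, dup_samples))}")
    values = matrix.to_numpy()
    if values.size and not np.isfinite(values).all():
        bad = np.argwhere(~np.isfinite(values))[0]
        raise FormatError(
            f"non-finite fluorescence at probe {matrix.index[bad[0]]!r}, "
            f"sample {matrix.columns[bad[1]]!r}"
        )
    return matrix


def _extract_series_matrix_table(text: str) -> str:
    lines = text.splitlines()
    begin = end = None
    for i, line in enumerate(lines):
        token = line.strip().lower()
        if token.startswith("!series_matrix_table_begin"):
            begin = i
        elif token.startswith("!series_matrix_table_end"):
            end = i
    if begin is not None:
        stop = end if end is not None else len(lines)
        body = lines[begin + 1 : stop]
    else:  # tolerate a bare table with "!" metadata sprinkled around it
        body = [line for line in lines if not line.startswith("!")]
    return "\n".join(body)


def read_expression_matrix(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    """Read a probes × samples fluorescence matrix.

    Parameters
    ----------
    path
        Delimited text file: first column probe ids, header row sample ids.
    dialect
        ``"tsv"``, ``"csv"``, or ``"series_matrix"`` (GEO series-matrix
        export: ``!``-prefixed metadata lines are skipped and the table
        between the table-begin/table-end markers is used; tab-separated,
        ids may be quoted).

    Returns the matrix with file row/column order preserved. Raises
    :class:`FormatError` for duplicate probe ids (naming the id), ragged
    rows (with line number), or non-numeric cells.
    """
    if dialect not in {"tsv", "csv", "series_matrix"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    text = Path(path).read_text()
    if dialect == "series_matrix":
        text = _extract_series_matrix_table(text)
    text = _strip_comments(text)
    sep = "," if dialect == "csv" else "\t"

    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty expression matrix")
    try:
        frame = pd.read_csv(
            _io.StringIO(text), sep=sep, index_col=0, dtype={0: str},
            na_filter=False,  # "NA" etc. must surface as format errors
        )
    except pd.errors.ParserError as exc:  # ragged rows land here
        raise FormatError(f"{path}: ragged table ({exc})") from exc
    n_fields = len(lines[0].split(sep))
    for lineno, line in enumerate(lines[1:], start=2):
        if len(line.split(sep)) not in (n_fields, n_fields + 1):
            raise FormatError(f"{path}: ragged row at line {lineno}")
    frame.index = frame.index.astype(str).str.strip('"')
    frame.columns = frame.columns.astype(str).str.strip('"')
    for col in frame.columns:
        if not pd.api.types.is_numeric_dtype(frame[col]):
            bad = frame[col][pd.to_numeric(frame[col], errors="coerce").isna()]
            raise FormatError(
                f"{path}: non-numeric cell in sample {col!r} "
                f"at probe {bad.index[0]!r}: {bad.iloc[0]!r}"
            )
    frame = frame.astype(float)
    frame.index.name = "probe_id"
    return validate_expression_matrix(frame)


def write_expression_matrix(
    matrix: pd.DataFrame,
    path: str | Path,
    dialect: str = "tsv",
    params: Mapping[str, object] | None = None,
) -> None:
    validate_expression_matrix(matrix)
    sep = "," if dialect == "csv" else "\t"
    with open(path, "w") as handle:
        handle.write(_comment_header(params))
        matrix.rename_axis("probe_id").to_csv(handle, sep=sep)


def read_sample_sheet(path: str | Path) -> pd.Series:
    """Read a two-column (sample_id, sex) sheet into a Series.

    Sex tokens are matched case-insensitively among male/m/female/f and
    normalized to "male"/"female".
    """
    text = _strip_comments(Path(path).read_text())
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = [f.strip() for f in line.replace(",", "\t").split("\t")]
        if len(fields) < 2:
            raise FormatError(f"{path}: line {lineno}: expected sample_id and sex")
        rows.append((lineno, fields[0], fields[1]))
    if rows and rows[0][2].lower() not in _SEX_TOKENS and rows[0][1].lower() in (
        "sample_id",
        "sample",
        "id",
    ):
        rows = rows[1:]  # header row
    if not rows:
        raise FormatError(f"{path}: empty sample sheet")
    ids, sexes = [], []
    for lineno, sample_id, sex in rows:
        token = sex.lower()
        if token not in _SEX_TOKENS:
            raise FormatError(
                f"{path}: line {lineno}: unknown sex token {sex!r} "
                f"(accepted: male, m, female, f; case-insensitive)"
            )
        if sample_id in ids:
            raise FormatError(f"{path}: duplicate sample id {sample_id!r}")
        ids.append(sample_id)
        sexes.append(_SEX_TOKENS[token])
    meta = pd.Series(sexes, index=pd.Index(ids, name="sample_id"), name="sex")
    return meta


def write_sample_sheet(
    meta: pd.Series, path: str | Path, params: Mapping[str, object] | None = None
) -> None:
    with open(path, "w") as handle:
        handle.write(_comment_header(params))
        handle.write("sample_id\tsex\n")
        for sample_id, sex in meta.items():
            handle.write(f"{sample_id}\t{sex}\n")


def read_probe_annotation(path: str | Path) -> pd.DataFrame:
    """Read a 3-column (probe_id, gene_symbol, chromosome) annotation.

    Gene symbols are uppercased on load so that GMT and annotation sources
    with differing case conventions match. Probe ids must be unique; one
    gene symbol may map to several probes.
    """
    text = _strip_comments(Path(path).read_text())
    frame = pd.read_csv(
        _io.StringIO(text),
        sep="\t",
        dtype=str,
        names=["probe_id", "gene_symbol", "chromosome"],
        header=None,
    )
    if len(frame) and frame.iloc[0, 0].lower() in ("probe_id", "probe"):
        frame = frame.iloc[1:]
    if frame.empty:
        raise FormatError(f"{path}: empty annotation")
    if frame.isna().any().any():
        lineno = int(frame.isna().any(axis=1).idxmax()) + 1
        raise FormatError(f"{path}: line {lineno}: expected 3 tab-separated fields")
    frame["gene_symbol"] = frame["gene_symbol"].str.upper()
    dup = frame["probe_id"][frame["probe_id"].duplicated()].unique()
    if len(dup):
        raise FormatError(f"{path}: duplicate probe id(s): {', '.join(dup)}")
    return frame.set_index("probe_id")


def write_probe_annotation(
    annot: pd.DataFrame, path: str | Path, params: Mapping[str, object] | None = None
) -> None:
    with open(path, "w") as handle:
        handle.write(_comment_header(params))
        annot.rename_axis("probe_id").to_csv(handle, sep="\t")


def read_gmt(path: str | Path) -> dict[str, GeneSet]:
    """Read a GMT gene-set file: one set per line, tab-separated
    name, description, members... Member symbols are uppercased on load.
    """
    collection: dict[str, GeneSet] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"{path}: line {lineno}: GMT line needs name, description "
                f"and at least one member (got {len(fields)} field(s))"
            )
        name, description, *members = fields
        members = tuple(m.strip().upper() for m in members if m.strip())
        if not members:
            raise FormatError(f"{path}: line {lineno}: gene set {name!r} is empty")
        collection[name] = GeneSet(description, members)
    return collection


def write_gmt(collection: Mapping[str, GeneSet], path: str | Path) -> None:
    with open(path, "w") as handle:
        for name, gene_set in collection.items():
            handle.write(
                "\t".join([name, gene_set.description, *gene_set.genes]) + "\n"
            )


def read_qpcr_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format qPCR table: gene_symbol, sample_id, ct (cycles).

    Ct/Cp values must be positive and finite (a qPCR machine never reports
    a non-positive crossing point).
    """
    text = _strip_comments(Path(path).read_text())
    frame = pd.read_csv(
        _io.StringIO(text),
        sep="\t",
        header=None,
        names=["gene_symbol", "sample_id", "ct"],
        dtype={0: str, 1: str},
    )
    if len(frame) and str(frame.iloc[0, 0]).lower() in ("gene_symbol", "gene"):
        frame = frame.iloc[1:].reset_index(drop=True)
    if frame.empty:
        raise FormatError(f"{path}: empty qPCR table")
    frame["ct"] = pd.to_numeric(frame["ct"], errors="coerce")
    if frame["ct"].isna().any() or not np.isfinite(frame["ct"]).all():
        lineno = int(frame.index[~np.isfinite(frame["ct"].fillna(np.inf))][0]) + 1
        raise FormatError(f"{path}: non-numeric or non-finite Ct near line {lineno}")
    if (frame["ct"] <= 0).any():
        bad = frame.loc[frame["ct"] <= 0].iloc[0]
        raise FormatError(
            f"{path}: non-positive Ct {bad['ct']} for gene {bad['gene_symbol']!r}"
        )
    frame["gene_symbol"] = frame["gene_symbol"].str.upper()
    return frame.reset_index(drop=True)


def write_qpcr_table(
    qpcr: pd.DataFrame, path: str | Path, params: Mapping[str, object] | None = None
) -> None:
    with open(path, "w") as handle:
        handle.write(_comment_header(params))
        handle.write("gene_symbol\tsample_id\tct\n")
        qpcr.to_csv(handle, sep="\t", header=False, index=False)
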