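"""Readers and writers for expression matrices, gene sets and clinical tables.

Containers are deliberately plain: an expression matrix is a pandas
DataFrame (genes x samples, log-scale values), a gene set collection is a
dict mapping set name to an ordered list of gene ids, and a clinical table
is a DataFrame indexed by sample id. Loading enforces the invariants the
downstream estimators assume (unique ids, numeric values, no missing
expression, valid response / survival encodings).
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RESPONSE_LEVELS = ("pCR", "RD")

#: canonical clinical column names
CLINICAL_COLUMNS = {
    "sample_id": "sample_id",
    "response": "response",
    "os_time": "os_time",
    "os_event": "os_event",
    "pfi_time": "pfi_time",
    "pfi_event": "pfi_event",
}


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene set file (name TAB description TAB gene...).

    Duplicate genes within a line are collapsed, keeping first occurrence;
    gene order is otherwise preserved. Duplicate set names or lines with
    fewer than three fields are errors.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            name = fields[0]
            if name in sets:
                raise ParseError(f"{path}: line {lineno}: duplicate gene set name {name!r}")
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            if not genes:
                raise ParseError(f"{path}: line {lineno}: gene set {name!r} is empty")
            sets[name] = genes
    if not sets:
        raise ParseError(f"{path}: no gene sets")
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, descriptions: dict | None = None) -> None:
    """Write gene sets to GMT; inverse of :func:`read_gmt` for membership."""
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def _collapse_duplicate_genes(df: pd.DataFrame) -> pd.DataFrame:
    """Keep, for each duplicated gene id, the row with the highest variance."""
    if df.index.is_unique:
        return df
    n_dup = df.index.duplicated().sum()
    logger.warning("collapsing %d duplicate gene ids by max variance", n_dup)
    variances = df.var(axis=1, ddof=1).to_numpy()
    order = np.argsort(-variances, kind="stable")
    # first occurrence after sorting by descending variance wins
    keep_sorted = df.iloc[order]
    keep = keep_sorted[~keep_sorted.index.duplicated(keep="first")]
    # restore first-appearance order of the retained gene ids
    first_pos = {g: i for i, g in reversed(list(enumerate(df.index)))}
    return keep.loc[sorted(keep.index, key=first_pos.__getitem__)]


def read_expression(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    """Read a genes x samples expression matrix (TSV, CSV or GCT).

    First column holds gene ids; the header row holds sample ids. GCT files
    carry a two-line header and ``Name``/``Description`` columns, of which
    ``Name`` supplies the gene id. Duplicate gene ids are collapsed by
    keeping the highest-variance row; genes with any missing value are
    dropped with a warning.
    """
    path = Path(path)
    if dialect == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if not version.startswith("#1."):
                raise ParseError(f"{path}: not a GCT file (header {version!r})")
            fh.readline()  # dims line
            df = pd.read_csv(fh, sep="\t")
        df = df.set_index(df.columns[0])
        if df.columns[0].lower() == "description":
            df = df.drop(columns=df.columns[0])
    elif dialect in ("tsv", "csv"):
        sep = "\t" if dialect == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    df.index = df.index.astype(str)
    if df.columns.duplicated().any():
        raise ParseError(f"{path}: duplicate sample ids in header")
    non_numeric = df.columns[[not np.issubdtype(dt, np.number) for dt in df.dtypes]]
    if len(non_numeric):
        col = non_numeric[0]
        bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
        where = f"gene {bad.index[0]!r}, sample {col!r}" if len(bad) else f"sample {col!r}"
        raise ParseError(f"{path}: non-numeric expression value at {where}")
    if df.shape[1] < 3:
        raise ParseError(f"{path}: fewer than 3 samples ({df.shape[1]})")

    df = _collapse_duplicate_genes(df)
    if df.isna().any().any():
        n_bad = int(df.isna().any(axis=1).sum())
        warnings.warn(f"dropping {n_bad} genes with missing values", stacklevel=2)
        df = df.dropna(axis=0)
    validate_expression(df)
    return df.astype(float)


def validate_expression(expr: pd.DataFrame) -> None:
    if not expr.index.is_unique:
        raise ValueError("duplicate gene ids")
    if not expr.columns.is_unique:
        raise ValueError("duplicate sample ids")
    if expr.shape[0] < 2 or expr.shape[1] < 3:
        raise ValueError(f"expression matrix too small: {expr.shape}")
    if expr.isna().any().any():
        raise ValueError("missing expression values")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical CSV into a sample-indexed DataFrame.

    Requires a ``sample_id`` column. Response labels are folded
    case-insensitively onto {pCR, RD}; unrecognized labels become missing
    with a warning. Event flags must be 0/1 and times non-negative. Any
    further columns are kept as covariates.
    """
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: missing required column 'sample_id'")
    if df["sample_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate sample ids")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)

    if "response" in df.columns:
        folded = df["response"].astype("string").str.strip().str.lower()
        mapping = {lvl.lower(): lvl for lvl in RESPONSE_LEVELS}
        mapped = folded.map(mapping)
        unknown = df["response"].notna() & mapped.isna()
        if unknown.any():
            warnings.warn(
                f"{int(unknown.sum())} unrecognized response labels set to missing",
                stacklevel=2,
            )
        df["response"] = mapped.astype(object)

    for time_col, event_col in (("os_time", "os_event"), ("pfi_time", "pfi_event")):
        if time_col in df.columns:
            times = pd.to_numeric(df[time_col], errors="raise")
            if (times.dropna() < 0).any():
                raise ParseError(f"{path}: negative value in {time_col}")
            df[time_col] = times
        if event_col in df.columns:
            events = pd.to_numeric(df[event_col], errors="raise").dropna()
            if not events.isin([0, 1]).all():
                raise ParseError(f"{path}: {event_col} values must be 0 or 1")
    return df


def align_samples(expr: pd.DataFrame, clinical: pd.DataFrame, min_overlap: int = 10):
    """Restrict both tables to their shared samples, in expression order."""
    shared = [s for s in expr.columns if s in clinical.index]
    if not shared:
        raise ValueError("expression and clinical tables share no samples")
    if len(shared) < min_overlap:
        raise ValueError(
            f"only {len(shared)} shared samples between expression and clinical "
            f"(minimum {min_overlap})"
        )
    return expr[shared], clinical.loc[shared]
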