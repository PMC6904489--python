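"""Readers/writers and validation for every table the pipeline touches.

Dialects: CSV (comma, UTF-8, header required) for phenotype and qPCR tables;
TSV for count matrices and DE tables (genes as rows, first column the gene
id, header row of sample ids).  Allelic-series grids live in a directory of
``cag<Q>_age<M>.tsv`` files.  Writers emit a sidecar ``<name>.schema.json``
with the column schema and package version.

Readers never silently coerce: duplicate keys, non-numeric cells and negative
counts are rejected with row-numbered messages.  Empty phenotype cells are
carried as NaN (behavioural batteries have dropouts); downstream operations
define their own missing-data policy.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__

log = logging.getLogger(__name__)

PHENOTYPE_COLUMNS = ["animal_id", "genotype", "litter", "trait", "timepoint", "value"]
QPCR_COLUMNS = ["animal_id", "tissue", "gene", "ct"]
GENOTYPES = {"wt", "mut"}
_SERIES_RE = re.compile(r"^cag(\d+)_age(\d+)\.tsv$")


class FormatError(ValueError):
    """A table violated its documented dialect."""


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        raise FormatError(f"{path}: empty table")


def _write_sidecar(path: Path, columns: dict[str, str]) -> None:
    sidecar = path.with_suffix(path.suffix + ".schema.json")
    sidecar.write_text(
        json.dumps({"columns": columns, "phenoscreen_version": __version__}, indent=2)
        + "\n"
    )


def read_phenotypes(path) -> pd.DataFrame:
    """Read and validate a long-form phenotype CSV."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"animal_id": str, "litter": str,
                                  "trait": str, "timepoint": str})
    _require_columns(df, PHENOTYPE_COLUMNS, path)
    bad_geno = df.loc[~df["genotype"].isin(GENOTYPES)]
    if len(bad_geno):
        rows = (bad_geno.index + 2).tolist()[:5]
        raise FormatError(f"{path}: genotype must be one of {sorted(GENOTYPES)} "
                          f"(rows {rows})")
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = df["value"].notna() & values.isna()
    if bad.any():
        rows = (df.index[bad] + 2).tolist()[:5]
        raise FormatError(f"{path}: non-numeric 'value' cells at rows {rows}")
    if np.isinf(values.dropna()).any():
        raise FormatError(f"{path}: non-finite 'value' cells")
    df["value"] = values
    dup = df.duplicated(subset=["animal_id", "trait", "timepoint"], keep=False)
    if dup.any():
        rows = (df.index[dup] + 2).tolist()[:5]
        raise FormatError(
            f"{path}: duplicate (animal, trait, timepoint) keys at rows {rows}")
    n_missing = int(df["value"].isna().sum())
    if n_missing:
        log.warning("%s: %d missing trait value(s) carried as NaN", path, n_missing)
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    path = Path(path)
    df.to_csv(path, index=False)
    _write_sidecar(path, {c: str(df[c].dtype) for c in df.columns})


def read_counts(path, meta_path=None) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Read a genes x samples count TSV (plus optional sample-metadata CSV)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty or df.shape[1] == 0:
        raise FormatError(f"{path}: empty count matrix")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise FormatError(f"{path}: duplicate gene ids {dupes}")
    if df.columns.has_duplicates:
        raise FormatError(f"{path}: duplicate sample ids")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(np.argmax(vals.isna().to_numpy())) + 2
            raise FormatError(f"{path}: non-numeric count at row {row}, column {col!r}")
        if (vals < 0).any():
            row = int(np.argmax((vals < 0).to_numpy())) + 2
            raise FormatError(f"{path}: negative count at row {row}, column {col!r}")
        if not np.allclose(vals, np.round(vals)):
            row = int(np.argmax(~np.isclose(vals, np.round(vals)))) + 2
            raise FormatError(f"{path}: non-integer count at row {row}, column {col!r}")
    counts = df.astype(np.int64)
    counts.index.name = "gene"

    meta = None
    if meta_path is not None:
        meta = pd.read_csv(Path(meta_path), dtype=str)
        _require_columns(meta, ["animal_id", "genotype"], meta_path)
        extra = set(counts.columns) - set(meta["animal_id"])
        if extra:
            raise FormatError(f"{meta_path}: samples without metadata: {sorted(extra)[:5]}")
        meta = meta.set_index("animal_id").loc[list(counts.columns)].reset_index()
    return counts, meta


def write_counts(counts: pd.DataFrame, path, meta: pd.DataFrame | None = None,
                 meta_path=None) -> None:
    path = Path(path)
    counts.to_csv(path, sep="\t")
    _write_sidecar(path, {"gene": "str", "samples": "int64"})
    if meta is not None and meta_path is not None:
        meta.to_csv(Path(meta_path), index=False)


def read_qpcr(path) -> pd.DataFrame:
    """Read a qPCR Ct CSV with columns animal_id, tissue, gene, ct."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"animal_id": str, "tissue": str, "gene": str})
    _require_columns(df, QPCR_COLUMNS, path)
    ct = pd.to_numeric(df["ct"], errors="coerce")
    bad = ct.isna() | ~np.isfinite(ct)
    if bad.any():
        rows = (df.index[bad] + 2).tolist()[:5]
        raise FormatError(f"{path}: missing/non-numeric Ct at rows {rows}")
    df["ct"] = ct
    dup = df.duplicated(subset=["animal_id", "tissue", "gene"], keep=False)
    if dup.any():
        rows = (df.index[dup] + 2).tolist()[:5]
        raise FormatError(f"{path}: duplicate (animal, tissue, gene) keys at rows {rows}")
    return df


def read_de_table(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["gene", "log2fc", "p"], path)
    p = pd.to_numeric(df["p"], errors="coerce")
    if p.isna().any() or (p <= 0).any() or (p > 1).any():
        raise FormatError(f"{path}: p-values must lie in (0, 1]")
    df["p"] = p
    df["log2fc"] = pd.to_numeric(df["log2fc"], errors="raise")
    return df


def read_series(directory) -> dict[tuple[int, int], pd.DataFrame]:
    """Read a directory of cag<Q>_age<M>.tsv ranked DE tables."""
    directory = Path(directory)
    cells: dict[tuple[int, int], pd.DataFrame] = {}
    for f in sorted(directory.glob("*.tsv")):
        m = _SERIES_RE.match(f.name)
        if not m:
            continue
        cells[(int(m.group(1)), int(m.group(2)))] = read_de_table(f)
    if not cells:
        raise FormatError(f"{directory}: no cag<Q>_age<M>.tsv tables found")
    universes = {cell: frozenset(t["gene"]) for cell, t in cells.items()}
    first = next(iter(universes.values()))
    mismatched = [c for c, u in universes.items() if u != first]
    if mismatched:
        raise FormatError(f"{directory}: gene universes differ across cells {mismatched}")
    return cells


def write_series(series: dict[tuple[int, int], pd.DataFrame], directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for (cag, age), table in series.items():
        table.to_csv(directory / f"cag{cag}_age{age}.tsv", sep="\t", index=False)


def read_gene_list(path) -> set[str]:
    """Read a plain-text gene list (one id per line); duplicates are logged."""
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines()]
    genes = [ln for ln in lines if ln and not ln.startswith("#")]
    if not genes:
        raise FormatError(f"{path}: empty gene list")
    unique = set(genes)
    if len(unique) < len(genes):
        log.warning("%s: %d duplicate gene id(s) removed", path, len(genes) - len(unique))
    return unique


def write_gene_list(genes, path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n")
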