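"""Readers and writers for the pipeline's tab-delimited formats.

Formats
-------
* expression matrix: tab-delimited text, first column gene ids, header row of
  sample ids, log2 values; leading ``#`` lines are comments
* sample annotation: tab-delimited, first column sample ids, one column per
  field (``batch``, ``condition``, traits)
* gene sets: GMT (``name<TAB>description<TAB>gene1<TAB>gene2...``)

Gene/sample identifier matching throughout the package is exact string match
after whitespace trimming; no alias resolution is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from adsubtypes.errors import FormatError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets with unique names and non-empty member lists."""

    sets: dict[str, GeneSet]

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets.values())

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]


def _read_table(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows
        raise FormatError(f"{path}: malformed table: {exc}") from exc
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    return df


def _check_unique(values: Iterable[str], what: str, path) -> None:
    seen: set[str] = set()
    for v in values:
        if v in seen:
            raise FormatError(f"{path}: duplicate {what} {v!r}")
        seen.add(v)


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples log2 expression matrix.

    Raises :class:`FormatError` on duplicate gene/sample ids, ragged rows,
    missing entries, or non-numeric cells (named by row and column).
    """
    df = _read_table(path)
    _check_unique(df.index, "gene id", path)
    _check_unique(df.columns, "sample id", path)
    numeric = df.apply(lambda col: pd.to_numeric(col.str.strip(), errors="coerce"))
    bad = numeric.isna()
    if bad.to_numpy().any():
        row, col = next(zip(*np.nonzero(bad.to_numpy())))
        raise FormatError(
            f"{path}: missing or non-numeric value at gene {df.index[row]!r}, "
            f"sample {df.columns[col]!r}"
        )
    numeric.index.name = "gene_id"
    return numeric


def write_expression(matrix: pd.DataFrame, path, comments: list[str] | None = None) -> None:
    """Write an expression matrix with optional ``#`` header comments.

    Values are formatted to 6 decimal places, so write-then-read round-trips
    to that precision.
    """
    with open(path, "w") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        matrix.to_csv(fh, sep="\t", index_label="gene_id", float_format="%.6f")


def read_annotation(path) -> pd.DataFrame:
    """Read a per-sample annotation table (first column sample ids).

    ``condition`` must be present for every sample and be AD or ND; trait
    values may be absent (pairwise-complete analysis downstream, matching
    real cohorts where per-trait n varies).
    """
    df = _read_table(path)
    _check_unique(df.index, "sample id", path)
    if "condition" not in df.columns:
        raise FormatError(f"{path}: annotation lacks a 'condition' column")
    cond = df["condition"].str.strip()
    bad = ~cond.isin(["AD", "ND"])
    if bad.any():
        sample = df.index[bad][0]
        raise FormatError(
            f"{path}: sample {sample!r} has condition {df.loc[sample, 'condition']!r}; "
            "expected 'AD' or 'ND'"
        )
    out = df.copy()
    out["condition"] = cond
    for col in out.columns:
        if col in ("batch", "condition", "subgroup", "sex"):
            continue
        out[col] = pd.to_numeric(out[col], errors="coerce")
    out.index.name = "sample_id"
    return out


def write_annotation(annot: pd.DataFrame, path, comments: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        annot.to_csv(fh, sep="\t", index_label="sample_id", float_format="%.6f")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file.

    One set per line; duplicate genes within a line are deduplicated with a
    logged warning; a line with fewer than 3 fields is a format error.
    """
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s); "
                    "expected name, description and at least one gene"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            deduped = list(dict.fromkeys(genes))
            if len(deduped) < len(genes):
                logger.warning(
                    "%s:%d: set %r contains duplicate genes; deduplicated",
                    path,
                    lineno,
                    name,
                )
            sets[name] = GeneSet(name, description, tuple(deduped))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


def intersect_matrices(matrices: list[pd.DataFrame]) -> list[pd.DataFrame]:
    """Restrict several matrices to their common genes (multi-cohort merge).

    Mirrors merging platforms on intersected gene identifiers before batch
    correction. Gene order follows the first matrix.
    """
    if not matrices:
        return []
    common = set(matrices[0].index)
    for m in matrices[1:]:
        common &= set(m.index)
    order = [g for g in matrices[0].index if g in common]
    if not order:
        raise FormatError("no genes common to all matrices")
    return [m.loc[order] for m in matrices]
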