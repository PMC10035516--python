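"""Reading, normalizing and harmonizing bulk expression data.

This module turns raw probe-level expression tables (plain TSV or the GEO
series-matrix dialect) into a canonical gene-by-sample
:class:`ExpressionMatrix`: probes are quantile normalized on the log2 scale
and collapsed to one row per gene symbol, keeping for each symbol the probe
with the highest mean expression. GMT-style gene-set files are read into
:class:`GeneSet` objects for downstream overlap and enrichment analyses.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "ProbeTable",
    "GeneSet",
    "ExpressionParseError",
    "read_expression_table",
    "collapse_probes_to_genes",
    "quantile_normalize_log2",
    "read_gene_sets",
    "write_expression_matrix",
    "read_expression_matrix",
]


class ExpressionParseError(ValueError):
    """Raised when an expression or gene-set file cannot be parsed."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ProbeTable:
    """Probe-level expression: probes x samples, with optional annotation.

    Parameters
    ----------
    values
        DataFrame indexed by probe id, one column per sample, float64.
    annotation
        Optional probe id -> gene symbol mapping. Many-to-one is allowed;
        probes absent from the mapping are treated as unmapped.
    """

    values: pd.DataFrame
    annotation: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()]
            raise ExpressionParseError(f"duplicate sample ids: {sorted(set(dupes))}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ExpressionMatrix:
    """Log2 gene-by-sample expression with per-sample patient ids/metadata.

    ``values`` is indexed by unique gene symbol with unique sample-id
    columns; ``patient_ids`` maps each sample to its patient (repeats mark
    multi-lesion patients); ``metadata`` holds optional per-sample clinical
    keys (sex, primary-tumor side, mutation flags, ...).
    """

    values: pd.DataFrame
    patient_ids: pd.Series | None = None
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("gene symbols must be unique")
        if self.values.columns.duplicated().any():
            raise ValueError("sample ids must be unique")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite with no missing entries")
        if self.patient_ids is None:
            # default: every sample is its own patient
            self.patient_ids = pd.Series(
                list(self.values.columns), index=self.values.columns, name="patient_id"
            )
        else:
            self.patient_ids = pd.Series(self.patient_ids).reindex(self.values.columns)
            if self.patient_ids.isna().any():
                missing = list(self.patient_ids.index[self.patient_ids.isna()])
                raise ValueError(f"samples without patient id: {missing}")

    @property
    def gene_symbols(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class GeneSet:
    """A named set of gene symbols (e.g. one line of a GMT file)."""

    name: str
    genes: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------


def _parse_numeric_body(
    rows: list[list[str]], header: list[str], path: str
) -> pd.DataFrame:
    """Parse string rows into a float frame, naming the first bad cell."""
    index = []
    data = np.empty((len(rows), len(header)), dtype=float)
    for i, row in enumerate(rows):
        if len(row) != len(header) + 1:
            raise ExpressionParseError(
                f"{path}: row {i + 2} has {len(row)} fields, expected {len(header) + 1}"
            )
        index.append(row[0])
        for j, cell in enumerate(row[1:]):
            try:
                data[i, j] = float(cell)
            except ValueError:
                raise ExpressionParseError(
                    f"{path}: non-numeric value {cell!r} at row {row[0]!r}, "
                    f"column {header[j]!r}"
                ) from None
    frame = pd.DataFrame(data, index=index, columns=header)
    if frame.columns.duplicated().any():
        dupes = sorted(set(frame.columns[frame.columns.duplicated()]))
        raise ExpressionParseError(f"{path}: duplicate sample ids {dupes}")
    return frame


def read_expression_table(
    path: str | Path,
    format: str = "tsv",
    annotation: Mapping[str, str] | None = None,
) -> ProbeTable:
    """Read a probes-x-samples expression table.

    ``format="tsv"`` expects one header row of sample ids followed by
    numeric rows keyed by probe id. ``format="series_matrix"`` reads the GEO
    series-matrix dialect: only rows between ``!series_matrix_table_begin``
    and ``!series_matrix_table_end`` are parsed, quotes are stripped.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if format == "series_matrix":
        try:
            start = next(
                i for i, ln in enumerate(lines) if ln.startswith("!series_matrix_table_begin")
            )
            stop = next(
                i for i, ln in enumerate(lines) if ln.startswith("!series_matrix_table_end")
            )
        except StopIteration:
            raise ExpressionParseError(
                f"{path}: missing !series_matrix_table_begin/end markers"
            ) from None
        lines = lines[start + 1 : stop]
    elif format != "tsv":
        raise ValueError(f"unknown format {format!r}")

    reader = csv.reader(lines, delimiter="\t")
    rows = [[cell.strip().strip('"') for cell in row] for row in reader if row]
    if len(rows) < 2:
        raise ExpressionParseError(f"{path}: no data rows")
    header = rows[0][1:]
    frame = _parse_numeric_body(rows[1:], header, str(path))
    logger.info(
        "read %s (%s): %d probes x %d samples", path.name, format, *frame.shape
    )
    return ProbeTable(values=frame, annotation=annotation)


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...``.

    Duplicate symbols within a line are deduplicated with a warning; a line
    with fewer than three fields raises, naming the line number.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ExpressionParseError(
                f"{path}: line {lineno} has {len(fields)} fields, expected >= 3 "
                "(name, description, genes...)"
            )
        name, source = fields[0], fields[1]
        genes = [g.strip() for g in fields[2:] if g.strip()]
        if len(genes) != len(set(genes)):
            logger.warning(
                "gene set %s (line %d): %d duplicate symbols removed",
                name, lineno, len(genes) - len(set(genes)),
            )
        sets.append(GeneSet(name=name, genes=frozenset(genes), source=source))
    return sets


# ---------------------------------------------------------------------------
# Normalization and probe collapse
# ---------------------------------------------------------------------------


def quantile_normalize_log2(probes: ProbeTable, already_log2: bool = True) -> ProbeTable:
    """Quantile normalize columns on the log2 scale.

    When ``already_log2`` is false the values are log2 transformed first
    (requiring strictly positive input). After normalization every sample
    column holds the identical sorted multiset: the rank-wise mean of the
    column-sorted values. Ties within a column receive the mean of the
    reference values at the tied ranks.
    """
    values = probes.values.to_numpy(dtype=float, copy=True)
    if not already_log2:
        if (values <= 0).any():
            i, j = np.argwhere(values <= 0)[0]
            raise ValueError(
                f"non-positive value at probe {probes.probe_ids[i]!r}, sample "
                f"{probes.sample_ids[j]!r}: cannot log2 transform"
            )
        values = np.log2(values)

    n_probes, n_samples = values.shape
    order = np.argsort(values, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(values, order, axis=0)
    reference = sorted_vals.mean(axis=1)

    out = np.empty_like(values)
    for j in range(n_samples):
        col = values[:, j]
        ranked = np.empty(n_probes)
        ranked[order[:, j]] = reference
        # tie rule: tied values share the mean reference value of their ranks
        tied = pd.Series(ranked).groupby(pd.Series(col), sort=False).transform("mean")
        out[:, j] = tied.to_numpy()

    frame = pd.DataFrame(out, index=probes.values.index, columns=probes.values.columns)
    return ProbeTable(values=frame, annotation=probes.annotation)


def collapse_probes_to_genes(
    probes: ProbeTable,
    patient_ids: pd.Series | Mapping[str, str] | None = None,
    metadata: pd.DataFrame | None = None,
) -> ExpressionMatrix:
    """Collapse probe rows to one row per gene symbol.

    For symbols measured by several probes the probe with the highest mean
    expression across samples is retained (ties broken by lexicographically
    smallest probe id). Unmapped probes and rows containing missing values
    are dropped, with counts logged.
    """
    if probes.annotation is None:
        raise ValueError("probe table has no probe->gene annotation")
    annotation = dict(probes.annotation)

    symbols = pd.Series(
        [annotation.get(p) or None for p in probes.probe_ids], index=probes.values.index
    )
    unmapped = int(symbols.isna().sum())
    if unmapped:
        logger.info("dropping %d unmapped probes", unmapped)
    mapped = probes.values.loc[symbols.notna()]
    mapped_symbols = symbols.dropna()
    if mapped.empty:
        raise ValueError("no probe maps to a gene symbol")

    missing_rows = mapped.isna().any(axis=1)
    if missing_rows.any():
        logger.info("dropping %d probe rows with missing values", int(missing_rows.sum()))
        mapped = mapped.loc[~missing_rows]
        mapped_symbols = mapped_symbols.loc[~missing_rows]
        if mapped.empty:
            raise ValueError("all mapped probes contain missing values")

    means = mapped.mean(axis=1)
    # sort so the winner (max mean, then smallest probe id) is first per symbol
    choice = (
        pd.DataFrame({"symbol": mapped_symbols, "mean": means, "probe": mapped.index})
        .sort_values(["symbol", "mean", "probe"], ascending=[True, False, True], kind="stable")
        .drop_duplicates("symbol", keep="first")
    )
    kept = mapped.loc[choice["probe"]]
    kept.index = pd.Index(choice["symbol"].to_numpy(), name="gene")
    n_multi = int((mapped_symbols.value_counts() > 1).sum())
    if n_multi:
        logger.info("collapsed %d symbols with multiple probes (max-mean rule)", n_multi)
    kept = kept.sort_index()
    return ExpressionMatrix(values=kept, patient_ids=patient_ids, metadata=metadata)


# ---------------------------------------------------------------------------
# Round-trip I/O for the canonical matrix
# ---------------------------------------------------------------------------


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write genes x samples TSV plus a ``<stem>.patients.tsv`` sidecar."""
    path = Path(path)
    matrix.values.to_csv(path, sep="\t", index_label="gene")
    side = pd.DataFrame({"sample_id": matrix.sample_ids,
                         "patient_id": matrix.patient_ids.to_numpy()})
    if matrix.metadata is not None:
        side = side.join(matrix.metadata.reset_index(drop=True))
    side.to_csv(path.with_suffix(path.suffix + ".patients.tsv"), sep="\t", index=False)


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a matrix written by :func:`write_expression_matrix`."""
    path = Path(path)
    values = pd.read_csv(path, sep="\t", index_col="gene")
    side_path = path.with_suffix(path.suffix + ".patients.tsv")
    patient_ids = None
    metadata = None
    if side_path.exists():
        side = pd.read_csv(side_path, sep="\t", dtype=str).set_index("sample_id")
        patient_ids = side["patient_id"]
        extra = side.drop(columns=["patient_id"])
        metadata = extra if not extra.empty else None
    return ExpressionMatrix(values=values, patient_ids=patient_ids, metadata=metadata)
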