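"""Expression-matrix data model and tab-delimited I/O.

The central container is :class:`ExpressionMatrix`: an ``n x m`` real matrix of
expression values for ``n`` genes measured at ``m`` uniformly spaced
timepoints, with an explicit missing-value mask.  Row and column order are
significant and preserved through every I/O round trip.  Timepoint labels are
carried as metadata only; all computation treats the time axis as the sample
index ``t = 1..m``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Cell contents treated as missing by default (Spellman-style files use
#: empty cells).
DEFAULT_NA_TOKENS = frozenset({"", "NA", "NaN", "null"})


@dataclasses.dataclass
class ExpressionMatrix:
    """Gene x timepoint expression matrix with a missing-value mask.

    Parameters
    ----------
    gene_ids : list of str
        Unique row identifiers, length ``n``.
    timepoints : list of str
        Column labels, length ``m`` (ordinal metadata; uniform sampling is
        assumed for all computation).
    values : ndarray of shape (n, m)
        Expression values; entries where :attr:`missing_mask` is true hold
        ``NaN``.
    """

    gene_ids: list[str]
    timepoints: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, m = self.values.shape
        if n < 1 or m < 2:
            raise ValueError(f"need n >= 1 genes and m >= 2 timepoints, got {n} x {m}")
        if len(self.gene_ids) != n:
            raise ValueError("gene_ids length does not match row count")
        if len(self.timepoints) != m:
            raise ValueError("timepoints length does not match column count")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.timepoints = [str(t) for t in self.timepoints]
        dup = _first_duplicate(self.gene_ids)
        if dup is not None:
            raise ValueError(f"duplicate gene ID: {dup!r}")
        observed = ~np.isnan(self.values)
        if not np.isfinite(self.values[observed]).all():
            raise ValueError("values must be finite wherever not missing")

    # -- basic geometry -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (n, m) array, true where the value is missing."""
        return np.isnan(self.values)

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            list(self.gene_ids), list(self.timepoints), self.values.copy()
        )

    def with_values(self, values: np.ndarray) -> "ExpressionMatrix":
        """Same gene/timepoint labels, new value array."""
        return ExpressionMatrix(list(self.gene_ids), list(self.timepoints), values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.gene_ids, name="gene_id"),
            columns=self.timepoints,
        )


def _first_duplicate(items: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


def read_expression_tsv(
    path: str | Path, na_tokens: Iterable[str] = DEFAULT_NA_TOKENS
) -> ExpressionMatrix:
    """Read a gene x timepoint tab-delimited file.

    First column holds gene IDs, the header row the timepoint labels.  Cells
    that are empty or in ``na_tokens`` become missing values.  Row and column
    order are preserved exactly.

    Raises
    ------
    ValueError
        On duplicate gene IDs (naming the ID), ragged rows (naming the line
        number), zero data columns, or unparseable numeric cells.
    """
    path = Path(path)
    na = {str(t) for t in na_tokens}
    with path.open("r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise ValueError(f"{path}: zero data columns")
    timepoints = header[1:]
    m = len(timepoints)
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if line == "":
            continue  # trailing blank line
        fields = line.split("\t")
        if len(fields) != m + 1:
            raise ValueError(
                f"{path}: line {lineno}: expected {m + 1} fields, got {len(fields)}"
            )
        gene_ids.append(fields[0])
        row = []
        for j, cell in enumerate(fields[1:]):
            if cell.strip() in na:
                row.append(np.nan)
            else:
                try:
                    row.append(float(cell))
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: line {lineno}, column {j + 2}: "
                        f"cannot parse {cell!r}"
                    ) from exc
        rows.append(row)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    dup = _first_duplicate(gene_ids)
    if dup is not None:
        raise ValueError(f"{path}: duplicate gene ID: {dup!r}")
    return ExpressionMatrix(gene_ids, timepoints, np.array(rows, dtype=float))


def write_expression_tsv(
    matrix: ExpressionMatrix, path: str | Path, float_format: str = "%.6g"
) -> None:
    """Write a matrix in the canonical tab-delimited form (``NA`` for missing)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(matrix.timepoints) + "\n")
        for g, row in zip(matrix.gene_ids, matrix.values):
            cells = ["NA" if np.isnan(v) else float_format % v for v in row]
            fh.write(g + "\t" + "\t".join(cells) + "\n")


def write_results_tsv(table, path: str | Path) -> None:
    """Write a :class:`~periodsig.significance.SignificanceTable` as TSV.

    Columns ``gene_id, score, p_value, q_value, significant`` sorted by
    ascending p-value with ties broken by gene ID, so the byte output is
    deterministic for a fixed table.
    """
    path = Path(path)
    df = table.to_frame()
    df = df.sort_values(["p_value", "gene_id"], kind="mergesort")
    out = df.copy()
    out["significant"] = out["significant"].astype(int)
    for col in ("score", "p_value", "q_value"):
        out[col] = out[col].map(lambda v: "%.6g" % v)
    out.to_csv(path, sep="\t", index=False)


def read_results_tsv(path: str | Path) -> pd.DataFrame:
    """Read back a results TSV written by :func:`write_results_tsv`."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    df["significant"] = df["significant"].astype(bool)
    return df


def read_gene_list(path: str | Path) -> set[str]:
    """Read a one-ID-per-line benchmark gene list (blank lines ignored)."""
    with Path(path).open("r", encoding="utf-8") as fh:
        return {line.strip() for line in fh if line.strip()}
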