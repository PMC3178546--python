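"""Reading, writing and harmonizing gene-by-sample expression matrices.

Two on-disk dialects are supported: a plain TSV (header row of sample ids,
first column ``gene_id``) and the GEO series-matrix dialect (``!``-prefixed
metadata lines, data table bounded by the table begin/end marker lines).
All downstream analysis assumes log2-scale values; :func:`ensure_log2`
harmonizes linear-scale (MAS5-like) inputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "SampleMetadata",
    "MatrixFormatError",
    "read_matrix",
    "write_matrix",
    "ensure_log2",
    "align_genes",
    "read_metadata",
    "write_metadata",
    "metadata_index",
]


class MatrixFormatError(ValueError):
    """Raised when an on-disk matrix or metadata file is malformed."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples numeric matrix on log2 scale.

    Parameters
    ----------
    gene_ids
        Unique, ordered gene identifiers (rows). Identifiers are opaque
        strings and matched case-sensitively.
    sample_ids
        Unique, ordered sample identifiers (columns).
    values
        Float array of shape ``(len(gene_ids), len(sample_ids))`` with no
        non-finite entries.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        genes = tuple(str(g) for g in self.gene_ids)
        samples = tuple(str(s) for s in self.sample_ids)
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise MatrixFormatError("values must be a 2-D array")
        if values.shape != (len(genes), len(samples)):
            raise MatrixFormatError(
                f"shape mismatch: values {values.shape} vs "
                f"{len(genes)} genes x {len(samples)} samples"
            )
        if len(set(genes)) != len(genes):
            dupes = _duplicates(genes)
            raise MatrixFormatError(f"duplicate gene ids: {sorted(dupes)[:5]}")
        if len(set(samples)) != len(samples):
            dupes = _duplicates(samples)
            raise MatrixFormatError(f"duplicate sample ids: {sorted(dupes)[:5]}")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise MatrixFormatError(
                f"non-finite value at gene {genes[bad[0]]!r}, "
                f"sample {samples[bad[1]]!r}"
            )
        object.__setattr__(self, "gene_ids", genes)
        object.__setattr__(self, "sample_ids", samples)
        object.__setattr__(self, "values", values)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not in matrix") from None

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Row-subset to ``genes`` in the given order; missing genes raise."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes absent from matrix: {sorted(missing)[:10]}")
        idx = [lookup[g] for g in genes]
        return ExpressionMatrix(tuple(genes), self.sample_ids, self.values[idx])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in lookup]
        if missing:
            raise KeyError(f"samples absent from matrix: {sorted(missing)[:10]}")
        idx = [lookup[s] for s in samples]
        return ExpressionMatrix(self.gene_ids, tuple(samples), self.values[:, idx])

    def sample_vector(self, sample_id: str) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        if sample_id not in lookup:
            raise KeyError(f"sample {sample_id!r} not in matrix")
        return self.values[:, lookup[sample_id]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            tuple(str(g) for g in frame.index),
            tuple(str(s) for s in frame.columns),
            frame.to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample annotations: tissue label, dataset of origin, optional
    time covariate (unit caller-declared) and condition tag."""

    sample_id: str
    tissue: str
    dataset_id: str
    time: float | None = None
    condition: str | None = None
    time_unit: str | None = None

    def __post_init__(self) -> None:
        if self.time is not None:
            t = float(self.time)
            if not math.isfinite(t) or t < 0:
                raise ValueError(
                    f"time for sample {self.sample_id!r} must be finite and "
                    f"nonnegative, got {self.time}"
                )
            object.__setattr__(self, "time", t)


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for item in items:
        if item in seen:
            dupes.add(item)
        seen.add(item)
    return dupes


# ---------------------------------------------------------------------------
# matrix I/O


_TABLE_BEGIN = "!series_matrix_table_begin"
_TABLE_END = "!series_matrix_table_end"


def read_matrix(
    path: str | Path,
    format: str = "tsv",
    collapse: str = "max-mean-row",
    missing: str = "error",
) -> ExpressionMatrix:
    """Read an expression matrix from disk.

    Parameters
    ----------
    format
        ``tsv`` or ``series_matrix`` (GEO dialect).
    collapse
        Policy for duplicate gene rows (multiple probes per gene):
        ``max-mean-row`` keeps the row with the highest mean (microarray
        convention), ``mean`` averages rows elementwise, ``error`` refuses.
    missing
        ``error`` rejects empty/NA cells; ``impute-mean`` fills each with
        its gene's row mean.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format not in ("tsv", "series_matrix"):
        raise ValueError(f"unknown format {format!r}")
    if collapse not in ("max-mean-row", "mean", "error"):
        raise ValueError(f"unknown collapse policy {collapse!r}")
    if missing not in ("error", "impute-mean"):
        raise ValueError(f"unknown missing policy {missing!r}")

    text = path.read_text(encoding="utf-8")
    if format == "series_matrix":
        table_text = _extract_series_matrix_table(text, path)
    else:
        table_text = text
    frame = _parse_table(table_text, path)
    frame = _handle_missing(frame, missing, path)
    frame = _collapse_duplicates(frame, collapse)
    return ExpressionMatrix.from_frame(frame)


def _extract_series_matrix_table(text: str, path: Path) -> str:
    lines = text.splitlines()
    begin = end = None
    for i, line in enumerate(lines):
        stripped = line.strip().strip('"')
        if stripped == _TABLE_BEGIN:
            begin = i
        elif stripped == _TABLE_END:
            end = i
    if begin is not None:
        stop = end if end is not None else len(lines)
        table = lines[begin + 1 : stop]
    else:
        # Marker-less fallback: everything that is not a '!' metadata line.
        table = [ln for ln in lines if not ln.startswith("!")]
    table = [ln for ln in table if ln.strip()]
    if not table:
        raise MatrixFormatError(f"{path}: no data table found")
    return "\n".join(table)


def _parse_table(table_text: str, path: Path) -> pd.DataFrame:
    lines = [ln for ln in table_text.splitlines() if ln.strip()]
    if not lines:
        raise MatrixFormatError(f"{path}: empty file")
    header = [c.strip().strip('"') for c in lines[0].split("\t")]
    if len(header) < 2:
        raise MatrixFormatError(
            f"{path}: line 1: header must contain a gene-id column and at "
            f"least one sample column"
        )
    sample_ids = header[1:]
    dupes = _duplicates(sample_ids)
    if dupes:
        raise MatrixFormatError(f"{path}: duplicate sample ids: {sorted(dupes)}")
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = [c.strip().strip('"') for c in line.split("\t")]
        if len(cells) != len(header):
            raise MatrixFormatError(
                f"{path}: line {lineno}: expected {len(header)} columns, "
                f"got {len(cells)}"
            )
        gene_ids.append(cells[0])
        row: list[float] = []
        for col, cell in enumerate(cells[1:]):
            if cell == "" or cell.upper() in ("NA", "NAN", "NULL"):
                row.append(np.nan)
                continue
            try:
                row.append(float(cell))
            except ValueError:
                raise MatrixFormatError(
                    f"{path}: line {lineno}: non-numeric value {cell!r} for "
                    f"gene {cells[0]!r}, sample {sample_ids[col]!r}"
                ) from None
        rows.append(row)
    if not rows:
        raise MatrixFormatError(f"{path}: no data rows")
    return pd.DataFrame(rows, index=gene_ids, columns=sample_ids, dtype=float)


def _handle_missing(frame: pd.DataFrame, missing: str, path: Path) -> pd.DataFrame:
    mask = frame.isna()
    if not mask.to_numpy().any():
        return frame
    if missing == "error":
        gene, sample = next(
            (g, s) for g in frame.index for s in frame.columns if mask.at[g, s]
        )
        raise MatrixFormatError(
            f"{path}: missing value at gene {gene!r}, sample {sample!r} "
            f"(pass missing='impute-mean' to impute)"
        )
    filled = frame.apply(lambda row: row.fillna(row.mean()), axis=1)
    if filled.isna().to_numpy().any():
        raise MatrixFormatError(f"{path}: gene with all values missing")
    n = int(mask.to_numpy().sum())
    logger.warning("imputed %d missing values with per-gene means", n)
    return filled


def _collapse_duplicates(frame: pd.DataFrame, collapse: str) -> pd.DataFrame:
    if frame.index.is_unique:
        return frame
    if collapse == "error":
        dupes = sorted(_duplicates(frame.index))
        raise MatrixFormatError(f"duplicate gene rows: {dupes[:10]}")
    if collapse == "mean":
        collapsed = frame.groupby(level=0, sort=False).mean()
    else:  # max-mean-row: keep the probe with the highest row mean
        order = frame.mean(axis=1).to_numpy()
        keep = (
            pd.Series(order, index=frame.index)
            .groupby(level=0, sort=False)
            .idxmax()
        )
        positions = {}
        for pos, gene in enumerate(frame.index):
            positions.setdefault(gene, []).append(pos)
        rows = []
        for gene in dict.fromkeys(frame.index):
            candidates = positions[gene]
            best = max(candidates, key=lambda p: (order[p], -p))
            rows.append(best)
        collapsed = frame.iloc[rows]
        collapsed.index = list(dict.fromkeys(frame.index))
    logger.info(
        "collapsed %d duplicate gene rows (policy=%s)",
        len(frame) - len(collapsed),
        collapse,
    )
    return collapsed


def write_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    """Write ``m`` as TSV with a ``gene_id`` header column."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(m.sample_ids) + "\n")
        for gene, row in zip(m.gene_ids, m.values):
            fh.write(gene + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# scale harmonization


def ensure_log2(
    m: ExpressionMatrix,
    mode: str = "auto",
    epsilon: float = 1.0,
    linear_threshold: float = 50.0,
) -> ExpressionMatrix:
    """Return ``m`` on log2 scale.

    ``mode='force'`` always applies ``log2(v + epsilon)``; ``mode='auto'``
    applies it only when the matrix maximum exceeds ``linear_threshold``
    (log2 microarray values essentially never exceed ~20 while linear MAS5
    intensities reach the thousands); ``mode='skip'`` returns the input.
    """
    if mode not in ("auto", "force", "skip"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "skip":
        logger.info("ensure_log2: mode=skip, matrix unchanged")
        return m
    if mode == "auto" and float(m.values.max(initial=-np.inf)) <= linear_threshold:
        logger.info(
            "ensure_log2: heuristic not fired (max %.3g <= %.3g), assuming log2",
            m.values.max(initial=-np.inf),
            linear_threshold,
        )
        return m
    if np.any(m.values < 0):
        bad = np.argwhere(m.values < 0)[0]
        raise ValueError(
            f"negative value at gene {m.gene_ids[bad[0]]!r}, sample "
            f"{m.sample_ids[bad[1]]!r}: data appears already log-scaled or corrupt"
        )
    logger.info("ensure_log2: applying log2(v + %g) (mode=%s)", epsilon, mode)
    return ExpressionMatrix(m.gene_ids, m.sample_ids, np.log2(m.values + epsilon))


def align_genes(matrices: Sequence[ExpressionMatrix]) -> list[ExpressionMatrix]:
    """Row-subset every matrix to the sorted intersection of their genes."""
    if len(matrices) < 2:
        raise ValueError("align_genes needs at least two matrices")
    shared = set(matrices[0].gene_ids)
    for m in matrices[1:]:
        shared &= set(m.gene_ids)
    if not shared:
        raise ValueError("gene intersection across matrices is empty")
    ordered = sorted(shared)
    return [m.subset_genes(ordered) for m in matrices]


# ---------------------------------------------------------------------------
# metadata I/O


_META_COLUMNS = ("sample_id", "tissue", "dataset_id", "time", "condition")


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read sample metadata TSV (columns: sample_id, tissue, dataset_id,
    optional time, condition)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "tissue", "dataset_id"}
    missing = required - set(frame.columns)
    if missing:
        raise MatrixFormatError(
            f"{path}: metadata missing required columns {sorted(missing)}"
        )
    records = []
    for _, row in frame.iterrows():
        time = None
        if "time" in frame.columns and pd.notna(row.get("time")) and row["time"] != "":
            time = float(row["time"])
        condition = None
        if "condition" in frame.columns and pd.notna(row.get("condition")):
            condition = str(row["condition"])
        records.append(
            SampleMetadata(
                sample_id=str(row["sample_id"]),
                tissue=str(row["tissue"]),
                dataset_id=str(row["dataset_id"]),
                time=time,
                condition=condition,
            )
        )
    return records


def write_metadata(metas: Sequence[SampleMetadata], path: str | Path) -> None:
    rows = []
    for meta in metas:
        rows.append(
            {
                "sample_id": meta.sample_id,
                "tissue": meta.tissue,
                "dataset_id": meta.dataset_id,
                "time": "" if meta.time is None else repr(meta.time),
                "condition": "" if meta.condition is None else meta.condition,
            }
        )
    pd.DataFrame(rows, columns=list(_META_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def metadata_index(metas: Sequence[SampleMetadata]) -> dict[str, SampleMetadata]:
    """Map sample_id -> metadata, rejecting duplicate sample ids."""
    index: dict[str, SampleMetadata] = {}
    for meta in metas:
        if meta.sample_id in index:
            raise ValueError(f"duplicate metadata for sample {meta.sample_id!r}")
        index[meta.sample_id] = meta
    return index
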