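"""Readers and writers for expression matrices, stage maps and call tables.

Two input layouts are supported: a plain TSV (header row of sample IDs,
first column of gene IDs) and the GEO series-matrix text format (metadata
lines prefixed with ``!``, the expression table delimited by
``!series_matrix_table_begin`` / ``!series_matrix_table_end``). Sample IDs
are matched against the stage map after stripping internal whitespace, so a
printed ID like "GSM 21215" and the file form "GSM21215" are the same
sample.
"""

from __future__ import annotations

import io as _io
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CandidateCall
from .matrix import (
    DISEASE_STAGES,
    STAGES,
    StagedExpressionMatrix,
    ValidationError,
    normalize_sample_id,
)

logger = logging.getLogger(__name__)

CANDIDATE_COLUMNS = [
    "gene_id",
    "direction",
    "criterion",
    "A_incip",
    "A_moder",
    "A_severe",
    "D_ctrl",
    "D_incip",
    "D_moder",
    "D_severe",
]

_AMP_KEYS = dict(zip(["A_incip", "A_moder", "A_severe"], DISEASE_STAGES))
_DEV_KEYS = dict(zip(["D_ctrl", "D_incip", "D_moder", "D_severe"], STAGES))


def read_stage_map(path) -> dict[str, str]:
    """Read a two-column TSV (sample_id, stage) into a normalized mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "stage"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"stage map {path} must have columns sample_id and stage; "
            f"found {list(df.columns)}"
        )
    mapping: dict[str, str] = {}
    for sample, stage in zip(df["sample_id"], df["stage"]):
        key = normalize_sample_id(sample)
        if key in mapping and mapping[key] != stage:
            raise ValidationError(
                f"sample {key!r} listed with conflicting stages"
            )
        mapping[key] = str(stage).strip()
    return mapping


def _build_matrix(
    values: pd.DataFrame,
    stage_map: dict[str, str],
    log2: bool,
    drop_missing: bool,
) -> StagedExpressionMatrix:
    values = values.copy()
    values.index = values.index.map(str)
    values.columns = [normalize_sample_id(c) for c in values.columns]

    # cell-wise float() parse: correctly rounded (bit-exact round trips,
    # which pandas' fast to_numeric path is not) and yields coordinates
    for j, col in enumerate(values.columns):
        raw = values[col].to_numpy(dtype=object)
        out = np.empty(len(raw), dtype=float)
        for i, cell in enumerate(raw):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                out[i] = np.nan
                continue
            try:
                out[i] = float(cell)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"non-numeric cell at gene {values.index[i]!r} "
                    f"(row {i + 1}), sample {col!r} (column {j + 1}): "
                    f"{cell!r}"
                ) from None
        values[col] = out

    if drop_missing:
        keep = values.notna().all(axis=1)
        dropped = int((~keep).sum())
        if dropped:
            logger.info("dropped %d gene(s) with missing entries", dropped)
        values = values[keep]
    elif values.isna().any().any():
        bad = values.index[values.isna().any(axis=1)][:5].tolist()
        raise ValidationError(
            f"missing values (first genes: {bad}); rerun with "
            "drop_missing=True to discard those genes"
        )

    if log2:
        if (values.to_numpy() < 0).any():
            raise ValidationError("negative intensities under --log2")
        values = np.log2(values + 1.0)

    absent = [c for c in values.columns if c not in stage_map]
    if absent:
        raise ValidationError(
            f"samples missing from stage map: {absent}"
        )
    stage_of = {c: stage_map[c] for c in values.columns}
    return StagedExpressionMatrix.from_dataframe(values, stage_of)


def read_matrix_tsv(
    path,
    stage_map_path,
    log2: bool = False,
    drop_missing: bool = False,
) -> StagedExpressionMatrix:
    """Read a plain TSV matrix plus stage map into a validated container.

    The TSV must have a header row of sample IDs and one row per gene with
    the gene ID in the first column. Row and column order are preserved.
    ``log2`` applies log2(x + 1) for raw-intensity inputs (values are
    otherwise assumed already log-transformed); ``drop_missing`` discards
    genes with any missing entry instead of erroring.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ValidationError(f"duplicate gene IDs in {path}: {dups}")
    stage_map = read_stage_map(stage_map_path)
    return _build_matrix(df, stage_map, log2=log2, drop_missing=drop_missing)


def read_series_matrix(
    path,
    stage_map_path,
    log2: bool = False,
    drop_missing: bool = False,
) -> StagedExpressionMatrix:
    """Read a GEO series-matrix text file plus stage map.

    Metadata lines (``!``-prefixed) are ignored; the expression table between
    ``!series_matrix_table_begin`` and ``!series_matrix_table_end`` is parsed
    with the same contract as :func:`read_matrix_tsv`. Values may be quoted.
    """
    text = Path(path).read_text()
    lines = text.splitlines()
    try:
        begin = next(
            i for i, ln in enumerate(lines)
            if ln.strip().lower().startswith("!series_matrix_table_begin")
        )
    except StopIteration:
        raise ValidationError(
            f"{path}: no !series_matrix_table_begin line; not a "
            "series-matrix file"
        ) from None
    end = next(
        (
            i for i, ln in enumerate(lines)
            if ln.strip().lower().startswith("!series_matrix_table_end")
        ),
        len(lines),
    )
    if end <= begin + 1:
        raise ValidationError(f"{path}: empty series-matrix table")
    table = "\n".join(lines[begin + 1 : end])
    df = pd.read_csv(
        _io.StringIO(table), sep="\t", index_col=0, dtype=str, quotechar='"'
    )
    df.index = df.index.map(lambda s: str(s).strip('"'))
    df.columns = [str(c).strip('"') for c in df.columns]
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ValidationError(f"duplicate gene IDs in {path}: {dups}")
    stage_map = read_stage_map(stage_map_path)
    return _build_matrix(df, stage_map, log2=log2, drop_missing=drop_missing)


def write_matrix_tsv(matrix: StagedExpressionMatrix, path) -> None:
    """Write the matrix in the plain TSV layout.

    Floats are written with the shortest representation that round-trips, so
    write -> read reproduces the matrix bit-exactly.
    """
    df = matrix.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def write_stage_map(matrix: StagedExpressionMatrix, path) -> None:
    rows = [(s, matrix.stage_of[s]) for s in matrix.sample_ids]
    pd.DataFrame(rows, columns=["sample_id", "stage"]).to_csv(
        path, sep="\t", index=False
    )


def candidates_to_frame(calls: list[CandidateCall]) -> pd.DataFrame:
    """Tidy DataFrame of calls, sorted by (criterion, direction, gene_id)."""
    rows = []
    for c in sorted(calls, key=CandidateCall.sort_key):
        row = {"gene_id": c.gene_id, "direction": c.direction,
               "criterion": c.criterion}
        for col, stage in _AMP_KEYS.items():
            row[col] = c.amplitudes.get(stage, float("nan"))
        for col, stage in _DEV_KEYS.items():
            row[col] = c.deviations.get(stage, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)


def write_candidates(calls: list[CandidateCall], path) -> None:
    """Write the candidate table as TSV in a deterministic row order."""
    candidates_to_frame(calls).to_csv(path, sep="\t", index=False)


def read_candidates(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
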