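"""Readers and writers: trait tables, dissimilarity matrices, reports, config.

All files are plain text — CSV for tables and matrices, JSON for structured
reports, YAML or JSON for configuration.  Reader/writer pairs are lossless
round trips at double precision.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any, Literal

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    DistanceMatrix,
    FormatError,
    IntegrityError,
    ParseError,
    PipelineConfig,
    TraitTable,
    ValidityError,
    ID_COLUMNS,
)

log = logging.getLogger(__name__)

Dialect = Literal["wide", "long"]
MatrixShape = Literal["square", "lower_triangle", "upper_triangle"]


def _read_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if df.empty:
        raise FormatError(f"{path}: no data rows")
    return df


def _to_float(df: pd.DataFrame, columns: list[str], path: Path) -> pd.DataFrame:
    out = df.copy()
    for col in columns:
        converted = pd.to_numeric(out[col], errors="coerce")
        bad = converted.isna() & out[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}: non-numeric value {out[col].iloc[row]!r} "
                f"in column {col!r} at data row {row}"
            )
        out[col] = converted.astype(float)
    return out


def read_trait_table(path: str | Path, dialect: Dialect = "wide") -> TraitTable:
    """Read a replicated trait table from CSV.

    The wide dialect has columns ``genotype``, ``replicate`` and one column
    per trait; the long dialect has ``genotype``, ``replicate``, ``trait``,
    ``value`` and is pivoted to wide form preserving trait order of first
    appearance.
    """
    path = Path(path)
    df = _read_csv(path)
    if dialect == "long":
        required = ["genotype", "replicate", "trait", "value"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: long dialect lacks columns {missing}")
        df = _to_float(df, ["value"], path)
        order = list(dict.fromkeys(df["trait"]))
        wide = df.pivot(index=["genotype", "replicate"], columns="trait", values="value")
        if wide.isna().any().any():
            raise IntegrityError(f"{path}: trait set differs across (genotype, replicate)")
        df = wide[order].reset_index()
        df.columns.name = None
    elif dialect == "wide":
        missing = [c for c in ID_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: wide dialect lacks columns {missing}")
        traits = [c for c in df.columns if c not in ID_COLUMNS]
        df = _to_float(df, traits, path)
    else:
        raise ValidityError(f"unknown dialect {dialect!r}")
    df["genotype"] = df["genotype"].astype(str)
    df["replicate"] = df["replicate"].astype(str)
    table = TraitTable(df)
    log.info(
        "read trait table %s: %d genotypes, %d rows, %d traits, balanced=%s",
        path, len(table.genotypes), len(df), len(table.traits), table.balanced,
    )
    return table


def write_trait_table(table: TraitTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


def read_distance_matrix(path: str | Path, shape: MatrixShape = "square") -> DistanceMatrix:
    """Read a labeled dissimilarity matrix from CSV.

    The square shape requires symmetry to 1e-9; triangle shapes carry blank
    cells (or zeros) on the unused side and are mirrored to full symmetry.
    """
    path = Path(path)
    df = _read_csv(path)
    labels = [str(x) for x in df.iloc[:, 0]]
    header = [str(c) for c in df.columns[1:]]
    if header != labels:
        raise FormatError(f"{path}: row labels and column header disagree")
    raw = df.iloc[:, 1:].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    n = len(labels)
    if raw.shape != (n, n):
        raise FormatError(f"{path}: matrix block is {raw.shape}, expected ({n}, {n})")
    if shape == "square":
        if np.isnan(raw).any():
            raise ParseError(f"{path}: blank or non-numeric cell in square matrix")
        if np.abs(raw - raw.T).max() > DistanceMatrix.ATOL:
            raise IntegrityError(f"{path}: square matrix asymmetric beyond 1e-9")
        d = raw
    elif shape in ("upper_triangle", "lower_triangle"):
        tri = np.triu(np.nan_to_num(raw), 1) if shape == "upper_triangle" else np.tril(
            np.nan_to_num(raw), -1
        )
        d = tri + tri.T
    else:
        raise ValidityError(f"unknown matrix shape {shape!r}")
    if d.min() < -DistanceMatrix.ATOL:
        raise IntegrityError(f"{path}: negative distance entry")
    m = DistanceMatrix(tuple(labels), d)
    log.info("read distance matrix %s: %d labels", path, m.n)
    return m


def write_distance_matrix(matrix: DistanceMatrix, path: str | Path) -> None:
    """Write the full square form (readers accept all three shapes)."""
    matrix.to_frame().to_csv(path, index_label="genotype")


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, DistanceMatrix):
        return {"labels": list(obj.labels), "d": obj.d.tolist()}
    if isinstance(obj, pd.DataFrame):
        return {
            "index": [str(i) for i in obj.index],
            "columns": [str(c) for c in obj.columns],
            "values": obj.to_numpy().tolist(),
        }
    if isinstance(obj, pd.Series):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(results: Any, path: str | Path) -> None:
    """Serialize any stage output (dataclasses, frames, matrices) to JSON."""
    path = Path(path)
    payload = _jsonable(results)
    path.write_text(json.dumps(payload, indent=2, allow_nan=True) + "\n")
    log.info("wrote report %s", path)


def read_report(path: str | Path) -> Any:
    return json.loads(Path(path).read_text())


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline configuration from YAML or JSON."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
    if "display_cutoffs" in raw:
        raw["display_cutoffs"] = tuple(raw["display_cutoffs"])
    return PipelineConfig(**raw)
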