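"""Readers and writers for the package's plain-text interchange formats.

Canonical formats (CSV, delimiter sniffed or declared):

- long-format Ct table: ``sample_id, group, gene, replicate, ct``
  (``group`` optional; ``ct`` may be empty or the token ``Undetermined``);
- dilution table: ``gene, log10_quantity, replicate, ct``;
- wide expression matrix: rows = genes, columns = samples, with group
  labels in a sidecar JSON;
- echo table: one row per animal with the measurement columns of
  :data:`refstab.stats.ECHO_COLUMNS`.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .quantify import ExpressionMatrix, StandardCurve

log = logging.getLogger(__name__)

UNDETERMINED_TOKENS = {"undetermined", "undet", "na", "nan", ""}


class SchemaError(ValueError):
    pass


def _sniff_sep(path: Path) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(4096)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",;\t").delimiter
    except csv.Error:
        return ","


def _read_table(path: str | Path, sep: str | None) -> pd.DataFrame:
    path = Path(path)
    sep = sep or _sniff_sep(path)
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_ct_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a long-format Ct table, parsing undetermined wells.

    Ct cells that are empty or read ``Undetermined`` (case-insensitive) are
    flagged ``undetermined=True`` with NaN Ct; any other non-numeric cell
    raises a row-level error naming the line.
    """
    raw = _read_table(path, sep)
    required = {"sample_id", "gene", "replicate", "ct"}
    missing = sorted(required - set(raw.columns))
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    cts = []
    undet = []
    for idx, token in raw["ct"].items():
        stripped = str(token).strip()
        if stripped.lower() in UNDETERMINED_TOKENS:
            cts.append(np.nan)
            undet.append(True)
            continue
        try:
            cts.append(float(stripped))
            undet.append(False)
        except ValueError as err:
            raise SchemaError(
                f"{path}: non-numeric ct {stripped!r} at data line {idx + 2}"
            ) from err
    out = raw.copy()
    out["ct"] = cts
    out["undetermined"] = undet
    out["replicate"] = out["replicate"].astype(int)
    n_undet = int(out["undetermined"].sum())
    if n_undet:
        log.warning("%s: %d undetermined Ct cell(s)", path, n_undet)
    cols = ["sample_id"] + (["group"] if "group" in out.columns else [])
    cols += ["gene", "replicate", "ct", "undetermined"]
    return out[cols]


def write_ct_table(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    out["ct"] = [
        "Undetermined" if u else format(c, ".6f")
        for c, u in zip(out["ct"], out.get("undetermined", out["ct"].isna()))
    ]
    out.drop(columns=[c for c in ("undetermined",) if c in out.columns]).to_csv(
        path, index=False
    )


def read_dilution_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    raw = _read_table(path, sep)
    required = {"gene", "log10_quantity", "replicate", "ct"}
    missing = sorted(required - set(raw.columns))
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    out = raw.copy()
    for col in ("log10_quantity", "ct"):
        out[col] = out[col].astype(float)
    out["replicate"] = out["replicate"].astype(int)
    return out[["gene", "log10_quantity", "replicate", "ct"]]


def write_dilution_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def write_curve_table(curves: dict[str, StandardCurve], path: str | Path) -> None:
    rows = [
        {
            "gene": c.gene,
            "slope": c.slope,
            "intercept": c.intercept,
            "r2": c.r_squared,
            "efficiency_percent": c.efficiency_percent,
            "n_points": c.n_points,
        }
        for c in curves.values()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the genes x samples matrix as CSV plus a ``.groups.json``
    sidecar carrying group labels and dropped samples."""
    path = Path(path)
    matrix.data.to_csv(path, index_label="gene")
    sidecar = {
        "groups": {k: (None if pd.isna(v) else v) for k, v in matrix.groups.items()},
        "dropped_samples": matrix.dropped_samples,
    }
    path.with_suffix(path.suffix + ".groups.json").write_text(
        json.dumps(sidecar, indent=2)
    )


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    path = Path(path)
    data = pd.read_csv(path, index_col="gene")
    sidecar_path = path.with_suffix(path.suffix + ".groups.json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        groups = pd.Series(sidecar.get("groups", {})).reindex(data.columns)
        dropped = list(sidecar.get("dropped_samples", []))
    else:
        groups = pd.Series(index=data.columns, dtype=object)
        dropped = []
    return ExpressionMatrix(data=data, groups=groups, dropped_samples=dropped)


def read_echo_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    raw = _read_table(path, sep)
    if "sample_id" not in raw.columns:
        raise SchemaError(f"{path}: missing required column(s) ['sample_id']")
    out = raw.set_index("sample_id")
    for col in out.columns:
        out[col] = pd.to_numeric(out[col], errors="coerce")
    return out


def write_echo_table(echo: pd.DataFrame, path: str | Path) -> None:
    echo.to_csv(path, index_label="sample_id")
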