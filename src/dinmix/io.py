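"""CSV / JSON / YAML input and output.

Matrices travel as plain CSV of 0/1 entries: Q-matrices with items as rows
and attributes as columns, response matrices with persons as rows and items
as columns.  A header row is optional and detected automatically.  Run
configurations are JSON or YAML mappings.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .models import AttributeMatrix, QMatrix

__all__ = [
    "read_matrix_csv",
    "write_matrix_csv",
    "read_config",
    "write_config",
]

_KINDS = ("q", "response", "attribute")


def _looks_like_header(first_row: list[str]) -> bool:
    for cell in first_row:
        cell = cell.strip()
        if cell not in ("0", "1"):
            return True
    return False


def read_matrix_csv(path, kind: str = "response"):
    """Read a binary matrix from CSV.

    ``kind`` selects the returned type: ``"q"`` -> :class:`QMatrix`,
    ``"attribute"`` -> :class:`AttributeMatrix`, ``"response"`` -> plain
    int8 ndarray.  Non-binary cells and ragged rows raise a ValueError
    naming the offending location.
    """
    if kind not in _KINDS:
        raise ValueError(f"kind must be one of {_KINDS}, got {kind!r}")
    path = Path(path)
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                rows.append([c.strip() for c in line.split(",")])
    if not rows:
        raise ValueError(f"{path}: empty file")
    if _looks_like_header(rows[0]):
        rows = rows[1:]
    if not rows:
        raise ValueError(f"{path}: no data rows")
    width = len(rows[0])
    data = np.empty((len(rows), width), dtype=np.int8)
    for r, row in enumerate(rows):
        if len(row) != width:
            raise ValueError(
                f"{path}: row {r + 1} has {len(row)} cells, expected {width}"
            )
        for c, cell in enumerate(row):
            if cell not in ("0", "1"):
                raise ValueError(
                    f"{path}: non-binary cell {cell!r} at row {r + 1}, "
                    f"column {c + 1}"
                )
            data[r, c] = int(cell)
    if kind == "q":
        return QMatrix(data)
    if kind == "attribute":
        return AttributeMatrix(data)
    return data


def write_matrix_csv(path, matrix, header=None) -> None:
    """Write a binary matrix as CSV (optionally with a header row)."""
    arr = np.asarray(matrix, dtype=np.int8)
    df = pd.DataFrame(arr, columns=header)
    df.to_csv(path, index=False, header=header is not None)


def read_config(path) -> dict:
    """Read a JSON or YAML run-configuration mapping."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg


def write_config(path, config: dict) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(config, indent=2, default=str) + "\n")
    else:
        path.write_text(yaml.safe_dump(config, sort_keys=False))
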