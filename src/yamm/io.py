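"""Reading point clouds from delimited text and writing estimates."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .medians import MedianEstimate

__all__ = ["read_points", "write_estimate", "read_estimate"]


def _sniff_delimiter(line: str, delimiter=None) -> str | None:
    if delimiter is not None:
        return delimiter
    if "," in line:
        return ","
    if "\t" in line:
        return "\t"
    return None  # whitespace split


def read_points(path, delimiter=None, header: bool | str = "auto") -> np.ndarray:
    """Read a ``(k, n)`` point cloud from a delimited text file.

    One row per observation; delimiter is sniffed (comma, tab, whitespace)
    unless given.  ``header="auto"`` skips a first row that fails numeric
    parsing; ``header=True`` always skips it; ``header=False`` never does.
    Ragged or non-numeric rows raise a ``ValueError`` naming the offending
    line (1-based) and column.
    """
    path = Path(path)
    raw = [
        (i + 1, line.strip())
        for i, line in enumerate(path.read_text().splitlines())
        if line.strip()
    ]
    if not raw:
        raise ValueError(f"{path}: file is empty")
    delim = _sniff_delimiter(raw[0][1], delimiter)

    def split(line: str) -> list[str]:
        return [c.strip() for c in (line.split(delim) if delim else line.split())]

    start = 0
    if header is True:
        start = 1
    elif header == "auto":
        try:
            [float(c) for c in split(raw[0][1])]
        except ValueError:
            start = 1
    if start >= len(raw):
        raise ValueError(f"{path}: no data rows after header")

    rows = []
    width = None
    for lineno, line in raw[start:]:
        cells = split(line)
        if width is None:
            width = len(cells)
        elif len(cells) != width:
            raise ValueError(
                f"{path}: line {lineno} has {len(cells)} columns, expected {width}"
            )
        vals = []
        for col, cell in enumerate(cells, start=1):
            try:
                vals.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} at line {lineno}, column {col}"
                ) from None
        rows.append(vals)
    return np.asarray(rows, dtype=float)


def _jsonable(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, dict):
        return {k: _jsonable(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    if value is None or isinstance(value, (bool, int, float, str)):
        return value
    return repr(value)


def write_estimate(est: MedianEstimate, path, format: str = "json") -> None:
    """Write an estimate to ``path`` as JSON (location, method,
    diagnostics) or as a single CSV row of coordinates."""
    path = Path(path)
    if format == "json":
        payload = {
            "location": [float(v) for v in est.location],
            "method": est.method,
            "diagnostics": _jsonable(est.diagnostics),
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
    elif format == "csv":
        path.write_text(",".join(repr(float(v)) for v in est.location) + "\n")
    else:
        raise ValueError(f"unknown output format {format!r} (use 'csv' or 'json')")


def read_estimate(path) -> MedianEstimate:
    """Read back a JSON estimate written by :func:`write_estimate`."""
    payload = json.loads(Path(path).read_text())
    return MedianEstimate(
        np.asarray(payload["location"], dtype=float),
        payload["method"],
        payload.get("diagnostics", {}),
    )
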