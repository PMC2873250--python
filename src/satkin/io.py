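"""CSV/JSON input and output for the toolkit.

The CSV dialect is deliberately plain: a header row naming ``x,y`` (and
optionally ``replicate``), ``#``-prefixed comment lines, decimal points
only.  Unit labels may be supplied in header comments::

    # x_unit: mmol/L
    # y_unit: umol/L/min
    x,y
    0.5,1.25
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from . import __version__
from .data import XYDataSet
from .exceptions import ParseError

__all__ = ["read_xy_csv", "write_xy_csv", "write_report"]

_UNIT_RE = re.compile(r"#\s*(x_unit|y_unit)\s*:\s*(.+?)\s*$")


def read_xy_csv(path: Union[str, Path]) -> XYDataSet:
    """Read a two-column (x, y[, replicate]) CSV into an XYDataSet."""
    path = Path(path)
    units = {"x_unit": "", "y_unit": ""}
    rows = []
    header = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = _UNIT_RE.match(line)
                if m:
                    units[m.group(1)] = m.group(2)
                continue
            cells = [c.strip() for c in line.split(",")]
            if header is None:
                header = [c.lower() for c in cells]
                for col in ("x", "y"):
                    if col not in header:
                        raise ParseError(
                            f"{path}:{lineno}: missing column {col!r} in header"
                        )
                continue
            if len(cells) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} cells, got {len(cells)}"
                )
            rows.append((lineno, cells))

    if header is None:
        raise ParseError(f"{path}: no header row found")

    ix, iy = header.index("x"), header.index("y")
    ir = header.index("replicate") if "replicate" in header else None
    xs, ys, reps = [], [], []
    for lineno, cells in rows:
        try:
            xs.append(float(cells[ix]))
            ys.append(float(cells[iy]))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
        if ir is not None:
            reps.append(cells[ir])

    return XYDataSet(
        x=np.array(xs), y=np.array(ys),
        x_unit=units["x_unit"], y_unit=units["y_unit"],
        replicate_ids=np.array(reps) if reps else None,
        source=str(path),
    )


def write_xy_csv(data: XYDataSet, path: Union[str, Path]) -> None:
    """Write an XYDataSet in the dialect read_xy_csv understands."""
    path = Path(path)
    with open(path, "w") as fh:
        if data.x_unit:
            fh.write(f"# x_unit: {data.x_unit}\n")
        if data.y_unit:
            fh.write(f"# y_unit: {data.y_unit}\n")
        if data.source:
            fh.write(f"# source: {data.source}\n")
        cols = ["x", "y"] + (["replicate"] if data.replicate_ids is not None else [])
        fh.write(",".join(cols) + "\n")
        for i in range(len(data)):
            row = [repr(float(data.x[i])), repr(float(data.y[i]))]
            if data.replicate_ids is not None:
                row.append(str(data.replicate_ids[i]))
            fh.write(",".join(row) + "\n")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(result, path: Union[str, Path], format: str = "json",
                 seed=None, extra: dict | None = None) -> None:
    """Serialize a result object to JSON (or CSV for tabular profiles).

    ``result`` may expose ``to_dict()`` (FitResult, domain reports,
    InhibitionVerdict), be a plain dict, or — for format="csv" — a pandas
    DataFrame.  Floats are written at 17 significant digits so a
    write/read round trip is lossless.
    """
    path = Path(path)
    if format == "csv":
        df = result if isinstance(result, pd.DataFrame) else pd.DataFrame(result)
        df.to_csv(path, index=False, float_format="%.17g")
        return
    if format != "json":
        raise ValueError(f"format must be 'json' or 'csv', got {format!r}")

    payload = result.to_dict() if hasattr(result, "to_dict") else dict(result)
    payload = _jsonable(payload)
    payload["tool_version"] = __version__
    if seed is not None:
        payload["seed"] = seed
    if extra:
        payload.update(_jsonable(extra))
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
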