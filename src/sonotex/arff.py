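"""Minimal ARFF (Attribute-Relation File Format) writer and reader for
numeric feature tables with a nominal ``class`` attribute.

Only the subset of the grammar this package emits is supported: a
``@relation`` line, ``@attribute <name> numeric`` declarations, one
``@attribute class {normal,abnormal}`` nominal attribute, and comma-
separated ``@data`` rows.  Parse errors report the offending line number.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["write_arff", "read_arff"]


def write_arff(table: pd.DataFrame, path: str | Path,
               relation: str = "liver_features", class_col: str = "class") -> None:
    """Serialize a feature table (numeric columns + nominal class).

    Non-feature bookkeeping columns (``case_id``) are omitted; the CSV
    mirror written by the pipeline keeps them.
    """
    if class_col not in table.columns:
        raise ValueError(f"table has no {class_col!r} column")
    feature_cols = [c for c in table.columns if c not in (class_col, "case_id")]
    classes = sorted(table[class_col].unique(), reverse=True)  # normal first
    lines = [f"@relation {relation}", ""]
    for name in feature_cols:
        lines.append(f"@attribute {name} numeric")
    lines.append(f"@attribute {class_col} {{{','.join(classes)}}}")
    lines.extend(["", "@data"])
    for _, row in table.iterrows():
        vals = [repr(float(row[c])) for c in feature_cols]
        vals.append(str(row[class_col]))
        lines.append(",".join(vals))
    Path(path).write_text("\n".join(lines) + "\n")


def read_arff(path: str | Path) -> pd.DataFrame:
    """Parse an ARFF file written by :func:`write_arff` (or any file using
    the same numeric + single-nominal subset)."""
    names: list[str] = []
    kinds: list[str] = []
    nominal: dict[str, list[str]] = {}
    rows: list[list] = []
    in_data = False
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("%"):
            continue
        low = line.lower()
        if low.startswith("@relation"):
            continue
        if low.startswith("@attribute"):
            if in_data:
                raise ValueError(f"{path}:{lineno}: @attribute after @data")
            parts = line.split(None, 2)
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: malformed @attribute line")
            _, name, kind = parts
            if kind.strip().startswith("{"):
                values = [v.strip() for v in kind.strip().strip("{}").split(",")]
                names.append(name)
                kinds.append("nominal")
                nominal[name] = values
            elif kind.strip().lower() in ("numeric", "real", "integer"):
                names.append(name)
                kinds.append("numeric")
            else:
                raise ValueError(f"{path}:{lineno}: unsupported type {kind!r}")
            continue
        if low.startswith("@data"):
            in_data = True
            continue
        if not in_data:
            raise ValueError(f"{path}:{lineno}: data row before @data section")
        fields = [f.strip() for f in line.split(",")]
        if len(fields) != len(names):
            raise ValueError(
                f"{path}:{lineno}: expected {len(names)} fields, got {len(fields)}"
            )
        row = []
        for value, name, kind in zip(fields, names, kinds):
            if kind == "numeric":
                try:
                    row.append(float(value))
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric value {value!r} "
                        f"for attribute {name!r}"
                    ) from exc
            else:
                if value not in nominal[name]:
                    raise ValueError(
                        f"{path}:{lineno}: {value!r} not in declared domain "
                        f"of {name!r}"
                    )
                row.append(value)
        rows.append(row)
    if not names:
        raise ValueError(f"{path}: no @attribute declarations found")
    return pd.DataFrame(rows, columns=names)
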