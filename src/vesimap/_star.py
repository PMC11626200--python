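"""Minimal reader/writer for RELION-style STAR particle tables.

Supports the subset this package needs: ``data_`` blocks containing a
``loop_`` with ``_rlnName #n`` column headers followed by whitespace-
separated rows. Values are converted to numeric dtypes where possible.
"""

from __future__ import annotations

import shlex
from pathlib import Path

import pandas as pd

from .errors import FormatError

__all__ = ["read_star", "write_star"]


def read_star(path: str | Path) -> dict[str, pd.DataFrame]:
    """Parse a STAR file into ``{block_name: DataFrame}``.

    Only loop blocks are returned; simple key-value blocks are ignored.
    """
    path = Path(path)
    blocks: dict[str, pd.DataFrame] = {}
    block_name = None
    columns: list[str] = []
    rows: list[list[str]] = []
    in_loop = False

    def flush() -> None:
        nonlocal columns, rows, in_loop
        if columns:
            df = pd.DataFrame(rows, columns=columns)
            for col in df.columns:
                try:
                    df[col] = pd.to_numeric(df[col])
                except (ValueError, TypeError):
                    pass
            blocks[block_name or "data"] = df
        columns, rows, in_loop = [], [], False

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("data_"):
                flush()
                block_name = line[len("data_"):] or "data"
            elif line == "loop_":
                flush()
                in_loop = True
            elif line.startswith("_"):
                if in_loop:
                    columns.append(line.split()[0].lstrip("_"))
                # key-value pairs outside loops are ignored
            elif in_loop and columns:
                fields = shlex.split(line)
                if len(fields) != len(columns):
                    raise FormatError(
                        f"{path}: row has {len(fields)} fields, "
                        f"expected {len(columns)}: {line!r}"
                    )
                rows.append(fields)
    flush()
    if not blocks:
        raise FormatError(f"{path}: no loop_ data blocks found")
    return blocks


def write_star(df: pd.DataFrame, path: str | Path, block: str = "particles") -> None:
    """Write a DataFrame as a single-block STAR loop.

    Floats are written with repr-roundtrip precision so read_star(write_star(x))
    reproduces the values bit-exactly.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"data_{block}\n\nloop_\n")
        for i, col in enumerate(df.columns, start=1):
            fh.write(f"_{col} #{i}\n")
        for _, row in df.iterrows():
            fields = []
            for v in row:
                if isinstance(v, float):
                    fields.append(format(v, ".17g"))
                else:
                    fields.append(str(v))
            fh.write(" ".join(fields) + "\n")
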