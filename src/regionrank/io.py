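"""Readers and writers for the plain-text formats used throughout the package.

Expression matrices, trait tables, and label tables travel as TSV (pandas);
gene sets travel as GMT (one set per line: name, description, members).
Every writer can prepend ``#``-commented header lines carrying run parameters
so outputs are self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_table_tsv",
    "write_table_tsv",
    "read_gmt",
    "write_gmt",
    "write_json",
]


def _header_lines(params: Mapping[str, object] | None) -> str:
    if not params:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in params.items())


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a probesets x samples expression TSV (row index = probeset IDs)."""
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def write_expression_tsv(
    df: pd.DataFrame, path: str | Path, params: Mapping[str, object] | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(params))
        df.to_csv(fh, sep="\t")


def read_table_tsv(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, comment="#")


def write_table_tsv(
    df: pd.DataFrame,
    path: str | Path,
    params: Mapping[str, object] | None = None,
    index: bool = True,
) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(params))
        df.to_csv(fh, sep="\t", index=index)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file into ``{set name: [genes]}`` (description column dropped)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(
    sets: Mapping[str, Iterable[str]], path: str | Path, description: str = "regionrank"
) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *map(str, genes)]) + "\n")


def write_json(obj: object, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
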