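"""File formats: JSON-lines grid records and CSV tables.

Grid record format (one diagram per line):

    {"n": 5, "x": [0, 1, 2, 3, 4], "o": [2, 3, 4, 0, 1]}

CSV writers emit UTF-8 with LF endings and a fixed column order; readers
tolerate metadata/comment lines prefixed with ``#``.  Write -> read is
bit-exact for every table in the package.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Iterator, Union

import pandas as pd

from .grid import GridDiagram, validate

PathLike = Union[str, Path]

CENSUS_COLUMNS = ["gn", "knot", "count"]
FLUX_COLUMNS = ["gn_scope", "policy", "max_area", "from_knot", "to_knot", "count"]


def write_grids_jsonl(path: PathLike, grids: Iterable[GridDiagram]) -> int:
    n = 0
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for g in grids:
            fh.write(json.dumps({"n": g.n, "x": list(g.xs), "o": list(g.os)}) + "\n")
            n += 1
    return n


def read_grids_jsonl(path: PathLike) -> Iterator[GridDiagram]:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rec = json.loads(line)
            g = validate(rec["x"], rec["o"])
            if g.n != rec.get("n", g.n):
                raise ValueError(f"inconsistent grid record: {rec}")
            yield g


def _write_table(path: PathLike, df: pd.DataFrame, columns: list[str], meta: dict) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"table is missing columns {missing}")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, columns=columns, index=False, lineterminator="\n")


def _read_table(path: PathLike, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if list(df.columns) != columns:
        raise ValueError(
            f"{path}: expected columns {columns}, found {list(df.columns)}"
        )
    return df


def write_census_csv(path: PathLike, df: pd.DataFrame, **meta) -> None:
    _write_table(path, df, CENSUS_COLUMNS, meta)


def read_census_csv(path: PathLike) -> pd.DataFrame:
    return _read_table(path, CENSUS_COLUMNS)


def write_flux_csv(path: PathLike, df: pd.DataFrame, **meta) -> None:
    _write_table(path, df, FLUX_COLUMNS, meta)


def read_flux_csv(path: PathLike) -> pd.DataFrame:
    return _read_table(path, FLUX_COLUMNS)
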