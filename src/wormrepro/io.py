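"""Table and configuration I/O.

Egg-count tables travel as plain CSV with a commented metadata header
(`# key: value` lines) so they stay readable by standard tools;
temperature laws and pipeline configurations are YAML.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .kinetics import TemperatureLaw
from .simulate import SAMPLING_MODES, TABLE_COLUMNS

__all__ = ["read_table", "write_table", "read_law", "write_law", "TableError"]


class TableError(ValueError):
    """Malformed egg-count table."""


def write_table(path: Union[str, Path], table: pd.DataFrame) -> None:
    """Write an egg-count table as CSV with a commented metadata header."""
    path = Path(path)
    _validate(table, where=str(path))
    with open(path, "w") as fh:
        for key, val in sorted(table.attrs.items()):
            fh.write(f"# {key}: {val}\n")
        table[TABLE_COLUMNS].to_csv(fh, index=False)


def read_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate an egg-count table written by :func:`write_table`."""
    path = Path(path)
    attrs = {}
    n_meta = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_meta += 1
            body = line[1:].strip()
            if ":" in body:
                key, _, val = body.partition(":")
                attrs[key.strip()] = val.strip()
    table = pd.read_csv(path, comment="#")
    # data rows start after the metadata block and the header line
    _validate(table, where=str(path), line_offset=n_meta + 2)
    table.attrs.update(attrs)
    return table


def _validate(table: pd.DataFrame, where: str = "table", line_offset: int = 2) -> None:
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise TableError(f"{where}: missing columns {missing}")
    problems = []

    def flag(mask: pd.Series, msg: str) -> None:
        for i in table.index[mask][:5]:
            problems.append(f"line {i + line_offset}: {msg}")

    eggs = pd.to_numeric(table["eggs_cum"], errors="coerce")
    flag(eggs.isna() | (eggs < 0) | (eggs != eggs.round()), "eggs_cum must be a non-negative integer")
    times = pd.to_numeric(table["time_h"], errors="coerce")
    flag(times.isna() | (times < 0), "time_h must be a non-negative number")
    flag(~table["mode"].isin(SAMPLING_MODES), f"mode must be one of {SAMPLING_MODES}")
    if not problems:
        long = table[table["mode"] == "longitudinal"]
        for ind, grp in long.groupby("individual_id", sort=False):
            grp = grp.sort_values("time_h")
            if np.any(np.diff(grp["eggs_cum"].to_numpy()) < 0):
                problems.append(f"individual {ind}: cumulative eggs decrease in time")
    if problems:
        raise TableError(f"{where}: " + "; ".join(problems))


def write_law(path: Union[str, Path], law: TemperatureLaw) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(law.to_dict(), fh, sort_keys=True)


def read_law(path: Union[str, Path]) -> TemperatureLaw:
    with open(path) as fh:
        return TemperatureLaw.from_dict(yaml.safe_load(fh))
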