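"""Reproduction of the comparison tables and deterministic export.

Each of the six comparison tables (ids 3-8) lists index values over the ten
(m, n) grid points (1,1) ... (5,6).  ``reproduce_table`` recomputes every
cell exactly from the partition, renders it under the table's printed
precision rule, and flags whether it matches the transcribed reported value.
Mismatches correspond one-to-one with the errata ledger
(:func:`tcnbtopo.closed_forms.errata_report`); there are no silent
disagreements.

Rendering rules (inferred from the printed data):

* tables 3, 5, 8 and the ReZG1/ReZG3 columns of table 7: exact integers,
  printed with one decimal;
* table 4: 5 significant digits (large entries like 4325300.0 are
  5-significant-digit roundings of exact values such as 4325308);
* table 6: 5 significant digits in scientific notation;
* ReZG2: the printed number of decimal places varies by row (2 then 1);
  matching rounds the exact value to each cell's own printed precision.

Exports are deterministic and byte-stable: fixed column order, sorted keys,
LF line endings.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from decimal import Decimal
from fractions import Fraction
from typing import Iterable

import pandas as pd

from . import reported
from .closed_forms import derive_closed_form, errata_cells, evaluate
from .indices import (
    IndexValue,
    edge_product_index,
    round_decimals,
    round_significant,
)
from .partition import PartitionSpec, tcnb_partition

ERRATUM_LEVEL = logging.WARNING + 5
logging.addLevelName(ERRATUM_LEVEL, "ERRATUM")
logger = logging.getLogger("tcnbtopo")

_RS_BY_COLUMN = {"M_{1,1}": (1, 1), "M_{1,2}": (1, 2), "M_{2,2}": (2, 2)}


@dataclass(frozen=True)
class TableSpec:
    """Layout of one comparison table: id, columns, per-column render rule."""

    table_id: int
    columns: tuple[str, ...]
    rules: dict[str, str]  # column -> "int" | "sig5" | "sig5-sci" | "printed-dp"


def table_spec(table_id: int) -> TableSpec:
    if table_id not in reported.TABLE_COLUMNS:
        raise KeyError(f"unknown table id {table_id}; expected 3..8")
    columns = tuple(reported.TABLE_COLUMNS[table_id])
    rules = {}
    for col in columns:
        if table_id == 4:
            rules[col] = "sig5"
        elif table_id == 6:
            rules[col] = "sig5-sci"
        elif col == "ReZG2":
            rules[col] = "printed-dp"
        else:
            rules[col] = "int"
    return TableSpec(table_id, columns, rules)


def _engine_value(
    column: str, size: tuple[int, int], spec: PartitionSpec
) -> Fraction | int:
    if column in ("PM1", "PM2"):
        return edge_product_index(spec, column, size).exact
    r_s = _RS_BY_COLUMN.get(column)
    poly_ = derive_closed_form(column, r_s=r_s, spec=spec)
    value = evaluate(poly_, size)
    return int(value) if value.denominator == 1 else value


def _render(value: Fraction | int, rule: str, printed: str) -> str:
    if rule == "int":
        return f"{int(value)}.0"
    if rule == "sig5":
        return format(round_significant(value, 5), "f")
    if rule == "sig5-sci":
        return format(round_significant(value, 5).normalize(), ".4e")
    if rule == "printed-dp":
        places = len(printed.split(".")[1]) if "." in printed else 0
        return str(round_decimals(value, places))
    raise ValueError(rule)


def _matches(value: Fraction | int, rule: str, printed: str) -> bool:
    target = Decimal(printed)
    if rule == "int":
        return Fraction(value).denominator == 1 and Decimal(int(value)) == target
    if rule in ("sig5", "sig5-sci"):
        return round_significant(value, 5) == target
    if rule == "printed-dp":
        places = len(printed.split(".")[1]) if "." in printed else 0
        return round_decimals(value, places) == target
    raise ValueError(rule)


def reproduce_table(
    table_id: int, spec: PartitionSpec | None = None
) -> pd.DataFrame:
    """Recompute one comparison table and flag agreement cell by cell.

    Returns a DataFrame with a ``(m,n)`` row column and, per index, three
    columns: the engine value rendered under the table's precision rule, the
    transcribed reported value, and a boolean match flag.  Every mismatch is
    logged at the ERRATUM level.
    """
    spec = spec or tcnb_partition()
    ts = table_spec(table_id)
    rows = []
    for size in reported.GRID:
        row: dict[str, object] = {"(m,n)": f"({size[0]},{size[1]})"}
        for col in ts.columns:
            printed = reported.REPORTED_TABLES[table_id][col][reported.GRID.index(size)]
            value = _engine_value(col, size, spec)
            match = _matches(value, ts.rules[col], printed)
            row[f"{col} engine"] = _render(value, ts.rules[col], printed)
            row[f"{col} reported"] = printed
            row[f"{col} match"] = match
            if not match:
                logger.log(
                    ERRATUM_LEVEL,
                    "table %d, %s at %s: derived %s, reported %s",
                    table_id, col, size, row[f"{col} engine"], printed,
                )
        rows.append(row)
    return pd.DataFrame(rows)


def mismatch_cells(
    table_id: int, spec: PartitionSpec | None = None
) -> set[tuple[int, str, tuple[int, int]]]:
    """Cells of one table where the engine value disagrees with the reported one."""
    frame = reproduce_table(table_id, spec)
    out = set()
    for col in reported.TABLE_COLUMNS[table_id]:
        for i, size in enumerate(reported.GRID):
            if not frame.loc[i, f"{col} match"]:
                out.add((table_id, col, size))
    return out


def verify_errata_coverage(spec: PartitionSpec | None = None) -> bool:
    """True iff table mismatches and errata-record cells coincide exactly."""
    found = set()
    for table_id in reported.TABLE_COLUMNS:
        found |= mismatch_cells(table_id, spec)
    return found == errata_cells(spec)


# -- export -------------------------------------------------------------


def export_table(frame: pd.DataFrame, destination: str, fmt: str = "csv") -> None:
    """Write a reproduced table as deterministic CSV or JSON (LF endings)."""
    if fmt == "csv":
        frame.to_csv(destination, index=False, lineterminator="\n")
    elif fmt == "json":
        payload = frame.to_dict(orient="records")
        with open(destination, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def export_catalog(values: Iterable[IndexValue], destination: str, fmt: str = "json") -> None:
    """Write an index catalog; exact values as strings, renderings alongside."""
    records = [
        {
            "name": v.name,
            "exact": str(v.exact),
            "decimal": v.decimal,
            "log10": v.log10,
        }
        for v in values
    ]
    if fmt == "json":
        with open(destination, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(records, fh, indent=2, sort_keys=True)
            fh.write("\n")
    elif fmt == "csv":
        pd.DataFrame(records).to_csv(destination, index=False, lineterminator="\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def plot_growth(table_id: int, destination: str, spec: PartitionSpec | None = None) -> None:
    """Optional: plot each index of a table over the (m,n) grid (log scale for PM)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    spec = spec or tcnb_partition()
    fig, ax = plt.subplots(figsize=(7, 4))
    labels = [f"({m},{n})" for m, n in reported.GRID]
    for col in reported.TABLE_COLUMNS[table_id]:
        values = [_engine_value(col, size, spec) for size in reported.GRID]
        if table_id == 6:
            from .indices import log10_exact

            ax.plot(labels, [log10_exact(v) for v in values], marker="o", label=f"log10 {col}")
        else:
            ax.plot(labels, [float(v) for v in values], marker="o", label=col)
    ax.set_xlabel("(m,n)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(destination, dpi=120)
    plt.close(fig)
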