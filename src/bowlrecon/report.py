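"""Relative-error arithmetic and the per-bowl error report."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from io import StringIO
from pathlib import Path

import pandas as pd

__all__ = ["relative_error", "round_half_away", "ErrorReport", "build_report"]

PARAMETERS = ("diameter", "depth", "capacity")


def relative_error(actual: float, calculated: float) -> float:
    """Signed relative error in percent: (calculated - actual) / actual * 100."""
    if actual == 0:
        raise ValueError("actual value must be nonzero")
    return (calculated - actual) / actual * 100.0


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention of the printed tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ErrorReport:
    """Per-bowl actual/calculated/relative-error table plus summaries."""

    table: pd.DataFrame
    max_abs_error: dict[str, float]
    median_error: dict[str, float]

    def to_csv(self, path: str | Path | None = None) -> str | None:
        if path is None:
            buf = StringIO()
            self.table.to_csv(buf, index=False)
            return buf.getvalue()
        self.table.to_csv(path, index=False)
        return None

    def to_markdown(self) -> str:
        return self.table.to_markdown(index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ErrorReport":
        df = pd.read_csv(path)
        return _report_from_table(df)


def build_report(rows: list[dict]) -> ErrorReport:
    """Build the error report from per-bowl measurement rows.

    Each row maps ``bowl`` to an identifier and, for each measured
    parameter, ``actual_<param>`` / ``calculated_<param>`` pairs (any of
    diameter, depth, capacity may be present).
    """
    records = []
    for row in rows:
        rec: dict = {"bowl": row["bowl"]}
        for param in PARAMETERS:
            a, c = row.get(f"actual_{param}"), row.get(f"calculated_{param}")
            if a is None or c is None:
                continue
            rec[f"actual_{param}"] = a
            rec[f"calculated_{param}"] = c
            rec[f"error_{param}_pct"] = round_half_away(relative_error(a, c))
        records.append(rec)
    df = pd.DataFrame(records)
    return _report_from_table(df)


def _report_from_table(df: pd.DataFrame) -> ErrorReport:
    max_abs: dict[str, float] = {}
    median: dict[str, float] = {}
    for param in PARAMETERS:
        col = f"error_{param}_pct"
        if col in df.columns and df[col].notna().any():
            max_abs[param] = float(df[col].abs().max())
            median[param] = float(df[col].median())
    return ErrorReport(table=df, max_abs_error=max_abs, median_error=median)
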