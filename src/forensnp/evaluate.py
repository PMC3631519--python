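"""Confusion tables and per-category accuracy summaries.

Predicted categories index the rows, observed (site-reported) categories the
columns.  Accuracies are reported both as exact fractions and as integer
percentages under round-half-up, the convention used in published
forensic-chip evaluation tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


def round_half_up(x: float, digits: int = 0) -> float:
    """Round with ties away from zero (0.5 -> 1), unlike banker's rounding."""
    scale = 10**digits
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class ConfusionTable:
    """Predicted-category rows × observed-category columns of counts."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if (t.to_numpy() < 0).any():
            raise ValueError("confusion counts must be non-negative")
        if not np.issubdtype(t.to_numpy().dtype, np.integer):
            object.__setattr__(self, "table", t.astype(int))

    @classmethod
    def from_counts(
        cls,
        counts: Mapping[str, Iterable[int]],
        columns: Iterable[str],
    ) -> "ConfusionTable":
        """Build from a mapping predicted-row -> per-column counts."""
        return cls(pd.DataFrame.from_dict(counts, orient="index", columns=list(columns)))

    @classmethod
    def from_labels(
        cls,
        predicted: Iterable[str],
        observed: Iterable[str],
        rows: Iterable[str] | None = None,
        columns: Iterable[str] | None = None,
    ) -> "ConfusionTable":
        ct = pd.crosstab(pd.Series(predicted, name="predicted"), pd.Series(observed, name="observed"))
        if rows is not None:
            ct = ct.reindex(list(rows), fill_value=0)
        if columns is not None:
            ct = ct.reindex(columns=list(columns), fill_value=0)
        return cls(ct)

    @property
    def total(self) -> int:
        return int(self.table.to_numpy().sum())

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t")


def confusion_stats(
    t: ConfusionTable,
    correct_map: Mapping[str, Iterable[str]],
    exclude_columns: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-row and overall accuracy of a confusion table.

    Parameters
    ----------
    correct_map
        For every predicted row, the set of observed columns counted as a
        correct prediction (a row may legitimately map to several columns,
        as broad shade categories do).
    exclude_columns
        Observed columns dropped before computing accuracies (e.g. an
        unreliable self-reported category).

    Returns a frame indexed by row (plus an ``overall`` row) with columns
    ``n_correct``, ``n_total``, ``fraction`` and ``percent`` (round-half-up
    integer).  A row left empty by the exclusions gets ``NaN`` fraction and
    ``defined=False`` rather than a misleading zero.
    """
    missing_rows = set(t.table.index) - set(correct_map)
    if missing_rows:
        raise ValueError(f"correct_map does not cover rows: {sorted(missing_rows)}")
    excl = set(exclude_columns or [])
    unknown = excl - set(t.table.columns)
    if unknown:
        raise ValueError(f"exclude_columns not in table: {sorted(unknown)}")
    cols = [c for c in t.table.columns if c not in excl]
    sub = t.table[cols]
    records = []
    for row in sub.index:
        correct_cols = [c for c in correct_map[row] if c in cols]
        n_correct = int(sub.loc[row, correct_cols].sum()) if correct_cols else 0
        n_total = int(sub.loc[row].sum())
        frac = n_correct / n_total if n_total else np.nan
        records.append((row, n_correct, n_total, frac, n_total > 0))
    n_corr_all = sum(r[1] for r in records)
    n_tot_all = sum(r[2] for r in records)
    records.append(
        (
            "overall",
            n_corr_all,
            n_tot_all,
            n_corr_all / n_tot_all if n_tot_all else np.nan,
            n_tot_all > 0,
        )
    )
    out = pd.DataFrame(
        records, columns=["row", "n_correct", "n_total", "fraction", "defined"]
    ).set_index("row")
    out["percent"] = [
        round_half_up(100 * f) if np.isfinite(f) else np.nan for f in out["fraction"]
    ]
    return out
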