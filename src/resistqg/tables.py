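"""Typed tabular containers and CSV round-trip for the two experiments.

Both tables are thin wrappers over :class:`pandas.DataFrame` with schema
validation on construction and on read, so invariant violations (deaths
exceeding nymph counts, non-monotone cumulative hatch counts) are caught
at the boundary and reported with the offending row index.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "FamilySurvivalTable",
    "LifeHistoryTable",
    "write_tables",
    "read_tables",
]

TREATMENTS = ("control", "exposed")


class SchemaError(ValueError):
    """A table failed schema validation; the message names the row."""


def _require_columns(df: pd.DataFrame, columns: tuple[str, ...], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}")


def _require_int(df: pd.DataFrame, col: str, what: str) -> pd.Series:
    s = df[col]
    if len(s) == 0:
        return s.astype(int)
    arr = pd.to_numeric(s, errors="coerce")
    if arr.isna().any():
        row = int(arr.index[arr.isna()][0])
        raise SchemaError(f"{what}: non-numeric {col!r} at row {row}")
    if not np.allclose(arr, np.round(arr)):
        row = int(arr.index[~np.isclose(arr, np.round(arr))][0])
        raise SchemaError(f"{what}: non-integer {col!r} at row {row}")
    return arr.astype(int)


@dataclass
class FamilySurvivalTable:
    """One row per family × treatment × replicate with nymph counts and
    deaths at day 10 post-exposure."""

    COLUMNS = (
        "family_id",
        "dam_id",
        "sire_id",
        "block_id",
        "plant_id",
        "replicate",
        "treatment",
        "n_nymphs",
        "n_dead_day10",
    )

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df = self.validate(self.df)

    @classmethod
    def validate(cls, df: pd.DataFrame) -> pd.DataFrame:
        what = "FamilySurvivalTable"
        _require_columns(df, cls.COLUMNS, what)
        df = df.loc[:, list(cls.COLUMNS)].reset_index(drop=True)
        for col in ("n_nymphs", "n_dead_day10"):
            df[col] = _require_int(df, col, what)
        if len(df) == 0:
            return df
        bad = df.index[(df["n_dead_day10"] < 0) | (df["n_nymphs"] < 0)]
        if len(bad):
            raise SchemaError(f"{what}: negative count at row {int(bad[0])}")
        bad = df.index[df["n_dead_day10"] > df["n_nymphs"]]
        if len(bad):
            raise SchemaError(
                f"{what}: n_dead_day10 > n_nymphs at row {int(bad[0])}"
            )
        bad = df.index[~df["treatment"].isin(TREATMENTS)]
        if len(bad):
            raise SchemaError(f"{what}: unknown treatment at row {int(bad[0])}")
        return df

    def subset(self, treatment: str) -> "FamilySurvivalTable":
        if treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {treatment!r}")
        return FamilySurvivalTable(
            self.df[self.df["treatment"] == treatment].reset_index(drop=True)
        )

    def proportion_dead(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return (
                self.df["n_dead_day10"].to_numpy(float)
                / self.df["n_nymphs"].to_numpy(float)
            )

    def __eq__(self, other: object) -> bool:
        return isinstance(other, FamilySurvivalTable) and self.df.equals(other.df)

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class LifeHistoryTable:
    """Per-pair per-disk egg counts with cumulative hatch counts.

    ``hatched_d{d}`` columns hold the cumulative number hatched by day
    ``d`` post-laying over the observation window.
    """

    BASE_COLUMNS = (
        "plant_id",
        "replicate_id",
        "treatment",
        "disk_day",
        "eggs_laid",
    )

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df = self.validate(self.df)

    @staticmethod
    def hatch_columns(df: pd.DataFrame) -> list[str]:
        cols = [c for c in df.columns if c.startswith("hatched_d")]
        return sorted(cols, key=lambda c: int(c.removeprefix("hatched_d")))

    @classmethod
    def validate(cls, df: pd.DataFrame) -> pd.DataFrame:
        what = "LifeHistoryTable"
        _require_columns(df, cls.BASE_COLUMNS, what)
        hcols = cls.hatch_columns(df)
        if not hcols:
            raise SchemaError(f"{what}: no hatched_d* columns")
        df = df.loc[:, list(cls.BASE_COLUMNS) + hcols].reset_index(drop=True)
        for col in ("disk_day", "eggs_laid", *hcols):
            df[col] = _require_int(df, col, what)
        if len(df) == 0:
            return df
        bad = df.index[~df["treatment"].isin(TREATMENTS)]
        if len(bad):
            raise SchemaError(f"{what}: unknown treatment at row {int(bad[0])}")
        if (df["eggs_laid"] < 0).any() or (df[hcols] < 0).any().any():
            raise SchemaError(f"{what}: negative count")
        hm = df[hcols].to_numpy()
        if (np.diff(hm, axis=1) < 0).any():
            row = int(np.where((np.diff(hm, axis=1) < 0).any(axis=1))[0][0])
            raise SchemaError(
                f"{what}: cumulative hatch counts decrease at row {row}"
            )
        bad = df.index[hm[:, -1] > df["eggs_laid"]]
        if len(bad):
            raise SchemaError(
                f"{what}: hatched exceeds eggs_laid at row {int(bad[0])}"
            )
        return df

    def final_hatched(self) -> np.ndarray:
        return self.df[self.hatch_columns(self.df)].to_numpy()[:, -1]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, LifeHistoryTable) and self.df.equals(other.df)

    def __len__(self) -> int:
        return len(self.df)


_FILENAMES = {
    FamilySurvivalTable: "survival.csv",
    LifeHistoryTable: "life_history.csv",
}


def write_tables(
    tables: dict[str, FamilySurvivalTable | LifeHistoryTable] |
        list[FamilySurvivalTable | LifeHistoryTable],
    path: str | pathlib.Path,
) -> dict[str, pathlib.Path]:
    """Write tables as UTF-8 CSV files under ``path``; returns name → file."""
    path = pathlib.Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if isinstance(tables, list):
        tables = {_FILENAMES[type(t)].removesuffix(".csv"): t for t in tables}
    written: dict[str, pathlib.Path] = {}
    for name, table in tables.items():
        out = path / f"{name}.csv"
        table.df.to_csv(out, index=False)
        written[name] = out
    return written


def read_tables(path: str | pathlib.Path) -> dict[str, object]:
    """Read every known CSV under ``path`` back into typed tables."""
    path = pathlib.Path(path)
    result: dict[str, object] = {}
    surv = path / "survival.csv"
    if surv.exists():
        result["survival"] = FamilySurvivalTable(pd.read_csv(surv))
    life = path / "life_history.csv"
    if life.exists():
        result["life_history"] = LifeHistoryTable(pd.read_csv(life))
    if not result:
        raise FileNotFoundError(f"no survival.csv or life_history.csv under {path}")
    return result
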