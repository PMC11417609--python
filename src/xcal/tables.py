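"""Outcome tables: the tidy subject x parameter x (scanner, method) container.

CSV schema: ``subject_id,parameter,scanner,method,value,units``.  The 14
recognised outcome parameters and their units are fixed; unknown names are
rejected so unit errors surface at the boundary rather than in statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["PARAMETER_UNITS", "PARAMETERS", "SCANNERS", "METHODS",
           "OutcomeTable", "read_outcome_table", "write_outcome_table"]

PARAMETER_UNITS: dict[str, str] = {
    "Tt.BMD": "mgHA/cm^3",
    "Tb.Ar": "mm^2",
    "Tb.BMD": "mgHA/cm^3",
    "BV/TV": "-",
    "Tb.N": "1/mm",
    "Tb.Th": "mm",
    "Tb.Sp": "mm",
    "Tb.1/N.SD": "mm",
    "Ct.Ar": "mm^2",
    "Ct.BMD": "mgHA/cm^3",
    "Ct.Pm": "mm",
    "Ct.Po": "-",
    "Ct.Th": "mm",
    "Ct.Po.Dm": "mm",
}
PARAMETERS = tuple(PARAMETER_UNITS)
SCANNERS = ("XCTI", "XCTII")
METHODS = ("standard", "LH")

_COLUMNS = ["subject_id", "parameter", "scanner", "method", "value", "units"]


@dataclass
class OutcomeTable:
    """Validated tidy table of outcome measurements."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"outcome table missing columns {missing}")
        df = df[_COLUMNS].copy()
        df["subject_id"] = df["subject_id"].astype(str)
        df["value"] = pd.to_numeric(df["value"], errors="coerce")
        bad = sorted(set(df["parameter"]) - set(PARAMETERS))
        if bad:
            raise ValueError(
                f"unknown parameter(s) {bad}; allowed: {list(PARAMETERS)}"
            )
        bad = sorted(set(df["scanner"]) - set(SCANNERS))
        if bad:
            raise ValueError(f"unknown scanner(s) {bad}; allowed: {list(SCANNERS)}")
        bad = sorted(set(df["method"]) - set(METHODS))
        if bad:
            raise ValueError(f"unknown method(s) {bad}; allowed: {list(METHODS)}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def subjects(self) -> list[str]:
        return sorted(self.df["subject_id"].unique())

    @property
    def parameters(self) -> list[str]:
        return sorted(self.df["parameter"].unique())

    def n_missing(self) -> int:
        return int(self.df["value"].isna().sum())

    def values_for(self, parameter: str, scanner: str | None = None,
                   method: str | None = None) -> pd.Series:
        """Per-subject values (indexed by subject_id) for one parameter."""
        sel = self.df["parameter"] == parameter
        if scanner is not None:
            sel &= self.df["scanner"] == scanner
        if method is not None:
            sel &= self.df["method"] == method
        sub = self.df[sel]
        if sub.duplicated("subject_id").any():
            raise ValueError(
                f"multiple rows per subject for {parameter!r}; "
                "specify scanner/method to disambiguate"
            )
        return sub.set_index("subject_id")["value"].sort_index()

    def subset(self, subject_ids) -> "OutcomeTable":
        ids = set(map(str, subject_ids))
        return OutcomeTable(self.df[self.df["subject_id"].isin(ids)].copy())

    @classmethod
    def from_records(cls, records: list[dict]) -> "OutcomeTable":
        df = pd.DataFrame.from_records(records)
        if "units" not in df.columns:
            df["units"] = df["parameter"].map(PARAMETER_UNITS)
        return cls(df)

    @classmethod
    def concat(cls, tables: list["OutcomeTable"]) -> "OutcomeTable":
        return cls(pd.concat([t.df for t in tables], ignore_index=True))


def write_outcome_table(table: OutcomeTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False, float_format="%.10g")


def read_outcome_table(path: str | Path) -> OutcomeTable:
    """Read a CSV outcome table, reporting malformed rows by line number.

    'NA' / empty values parse as missing (counted via ``n_missing``).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    values = pd.to_numeric(df["value"].replace({"": "NA"}), errors="coerce")
    malformed = values.isna() & ~df["value"].isin(["", "NA", "NaN", "nan"])
    if malformed.any():
        # +2: header line plus 1-based indexing
        lines = (np.flatnonzero(malformed) + 2).tolist()
        raise ValueError(f"{path}: malformed value(s) at line(s) {lines}")
    df = df.assign(value=values)
    return OutcomeTable(df)
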