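"""Compound-table readers/writers and panel validation.

The native table format is headered UTF-8 CSV (the Greek Ψ is welcome).
Mandatory columns are ``id`` and ``sequence``; recognized optional columns
are ``charge`` (MS charge state, default 1), ``formula_printed``,
``calc_mz_printed``, ``meas_mz_printed``, ``inh``, ``inh_sd``,
``log_ic50``, ``log_ic50_se``; anything else is carried through untouched.

A reference panel of 23 characterized triazolopeptides — sequences,
printed formulas and calculated/measured m/z, and percent inhibition at
10 µM — ships with the package (``load_reference_panel``).  The printed
calculated m/z of compound 23 is inconsistent with its own printed
formula, whose true monoisotopic [M+H]+ (507.3011) instead matches the
printed *measured* value; ``validate_panel`` therefore reports that row
as a calc-m/z failure on the shipped table.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .notation import parse_sequence
from .structure import (additive_formula, assemble_graph, formula_from_graph,
                        monoisotopic_mz)

__all__ = ["CompoundRecord", "read_compound_table", "write_report",
           "load_reference_panel", "validate_panel", "MZ_TOLERANCE"]

#: |computed − printed| tolerance for a 4-dp m/z comparison.
MZ_TOLERANCE = 0.00005

_MANDATORY = ("id", "sequence")
_NUMERIC = ("calc_mz_printed", "meas_mz_printed", "inh", "inh_sd",
            "log_ic50", "log_ic50_se")


@dataclass
class CompoundRecord:
    id: str
    sequence: str
    charge: int = 1
    formula_printed: Optional[str] = None
    calc_mz_printed: Optional[float] = None
    meas_mz_printed: Optional[float] = None
    inh: Optional[float] = None
    inh_sd: Optional[float] = None
    log_ic50: Optional[float] = None
    log_ic50_se: Optional[float] = None
    extra: Dict[str, object] = None  # passthrough metadata

    def parsed(self):
        return parse_sequence(self.sequence)


def _opt_float(value, column: str, line: int) -> Optional[float]:
    if value is None or (isinstance(value, float) and np.isnan(value)) \
            or value == "":
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValueError(
            f"line {line}: column {column!r} has malformed number {value!r}")


def read_compound_table(path) -> List[CompoundRecord]:
    """Read a compound table CSV into typed records.

    Duplicate ids, malformed numbers and missing mandatory columns all
    raise with line-numbered messages; an empty table is an error too.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: no records")
    known = set(_MANDATORY) | set(_NUMERIC) | {"charge", "formula_printed"}
    records: List[CompoundRecord] = []
    seen: Dict[str, int] = {}
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        cid = row["id"].strip()
        if not cid:
            raise ValueError(f"line {line}: empty id")
        if cid in seen:
            raise ValueError(
                f"line {line}: duplicate id {cid!r} (first on line {seen[cid]})")
        seen[cid] = line
        charge_raw = row.get("charge", "") or "1"
        try:
            charge = int(charge_raw)
        except ValueError:
            raise ValueError(
                f"line {line}: column 'charge' has malformed number "
                f"{charge_raw!r}")
        rec = CompoundRecord(
            id=cid, sequence=row["sequence"].strip(), charge=charge,
            formula_printed=(row.get("formula_printed") or None),
            extra={k: row[k] for k in df.columns if k not in known},
        )
        for col in _NUMERIC:
            if col in df.columns:
                setattr(rec, col, _opt_float(row[col], col, line))
        records.append(rec)
    return records


def write_report(df: pd.DataFrame, path, title: Optional[str] = None) -> None:
    """Write a result table as CSV plus a small aligned text summary
    alongside it (same stem, ``.txt``)."""
    path = Path(path)
    df.to_csv(path, index=False)
    txt = path.with_suffix(".txt")
    with open(txt, "w", encoding="utf-8") as fh:
        if title:
            fh.write(title + "\n")
        fh.write(df.to_string(index=False) + "\n")


def load_reference_panel() -> List[CompoundRecord]:
    """The 23-compound characterized panel shipped with the package."""
    ref = importlib.resources.files("triazopep") / "data" / "reference_panel.csv"
    with importlib.resources.as_file(ref) as p:
        return read_compound_table(p)


def validate_panel(records: List[CompoundRecord],
                   mz_tolerance: float = MZ_TOLERANCE) -> pd.DataFrame:
    """Check each record's printed formula and calc m/z against the values
    recomputed from its sequence.

    Returns one row per compound with computed values and PASS/FAIL
    columns (``formula_ok``, ``mz_ok``; NaN when no printed value exists).
    Failures are report rows, never exceptions.  Summary counts live in
    ``DataFrame.attrs``.
    """
    rows = []
    for rec in records:
        seq = rec.parsed()
        formula = additive_formula(seq)
        graph_formula = formula_from_graph(assemble_graph(seq))
        mz = monoisotopic_mz(formula, rec.charge)
        row = {
            "id": rec.id,
            "formula_computed": str(formula),
            "formula_printed": rec.formula_printed,
            "mz_computed": mz.mz_reported,
            "charge": rec.charge,
            "calc_mz_printed": rec.calc_mz_printed,
            "routes_agree": str(formula) == str(graph_formula),
            "formula_ok": (str(formula) == rec.formula_printed
                           if rec.formula_printed else np.nan),
            "mz_ok": (abs(mz.mz_reported - rec.calc_mz_printed) <= mz_tolerance
                      if rec.calc_mz_printed is not None else np.nan),
        }
        rows.append(row)
    df = pd.DataFrame(rows)
    for col in ("formula_ok", "mz_ok"):
        checked = df[col].notna()
        df.attrs[f"{col}_pass"] = int(df.loc[checked, col].sum())
        df.attrs[f"{col}_checked"] = int(checked.sum())
    return df
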