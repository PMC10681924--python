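"""Compound-table parsing, chromatographic peak filtering and ADMET screening.

A GC-MS analysis of an essential oil yields a table of candidate chemicals:
name, molecular formula, SMILES, retention time and relative peak area,
plus SwissADME-style pharmacokinetic predictions (gastrointestinal
absorption, blood-brain-barrier permeation, P-glycoprotein substrate
status, drug-likeness).  This module turns that table into records,
filters peaks by relative area, computes average molecular weight from
the formula, and applies rule-based ADMET screening.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

__all__ = [
    "CompoundRecord",
    "AdmetProfile",
    "ScreenRules",
    "STRICT_SWISSADME",
    "parse_compound_table",
    "packaged_component_table",
    "filter_peaks",
    "molecular_weight",
    "admet_filter",
    "write_compound_table",
]

# IUPAC 2021 standard (average) atomic weights, 4 decimals.  Average --
# not monoisotopic -- masses are what SwissADME/PubChem print as MW.
ATOMIC_MASS = {
    "H": 1.0080,
    "B": 10.8110,
    "C": 12.0110,
    "N": 14.0070,
    "O": 15.9990,
    "F": 18.9984,
    "Na": 22.9898,
    "Mg": 24.3050,
    "Si": 28.0850,
    "P": 30.9738,
    "S": 32.0600,
    "Cl": 35.4500,
    "K": 39.0983,
    "Ca": 40.0780,
    "Br": 79.9040,
    "I": 126.9045,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ValidationError(ValueError):
    """Raised when an input row or value violates a contract."""


def molecular_weight(formula: str) -> float:
    """Average molecular weight (u) of a Hill-style molecular formula.

    ``formula`` is a sequence of element symbols, each optionally followed
    by an integer count, e.g. ``"C10H16O"``.  Parenthesised groups are not
    supported (GC-MS tables do not use them).

    Raises
    ------
    ValidationError
        If the formula is empty, contains an unknown element symbol,
        an explicit zero count, or stray characters.
    """
    if not formula or not formula.strip():
        raise ValidationError("empty molecular formula")
    formula = formula.strip()
    pos = 0
    total = 0.0
    seen = False
    while pos < len(formula):
        m = _FORMULA_TOKEN.match(formula, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise ValidationError(f"cannot parse formula {formula!r} at position {pos}")
        sym, count_s = m.group(1), m.group(2)
        if sym not in ATOMIC_MASS:
            raise ValidationError(f"unknown element symbol {sym!r} in formula {formula!r}")
        count = int(count_s) if count_s else 1
        if count < 1:
            raise ValidationError(f"zero count for element {sym!r} in formula {formula!r}")
        total += ATOMIC_MASS[sym] * count
        seen = True
        pos = m.end()
    if not seen:
        raise ValidationError(f"formula {formula!r} contains no elements")
    return total


@dataclass
class CompoundRecord:
    """One GC-MS-identified chemical."""

    name: str
    formula: str
    smiles: str = ""
    cid: Optional[str] = None
    retention_time: Optional[float] = None
    peak_area_pct: Optional[float] = None
    mw: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mw is None:
            self.mw = molecular_weight(self.formula)
        if self.mw <= 0:
            raise ValidationError(f"{self.name}: molecular weight must be positive")
        if self.retention_time is not None and self.retention_time < 0:
            raise ValidationError(f"{self.name}: negative retention time")
        if self.peak_area_pct is not None and not (self.peak_area_pct >= 0):
            raise ValidationError(f"{self.name}: peak area % must be finite and >= 0")


_YESNO = {"yes": "Yes", "no": "No"}
_GI = {"high": "High", "low": "Low"}


@dataclass
class AdmetProfile:
    """SwissADME-style pharmacokinetic flags for one compound."""

    gi_absorption: str  # "High" | "Low"
    bbb: str  # "Yes" | "No"
    pgp_substrate: str  # "Yes" | "No"
    dl_pass: bool
    dl_violations: int = 0

    def __post_init__(self) -> None:
        gi = _GI.get(str(self.gi_absorption).strip().lower())
        if gi is None:
            raise ValidationError(f"gi_absorption must be High or Low, got {self.gi_absorption!r}")
        self.gi_absorption = gi
        for attr in ("bbb", "pgp_substrate"):
            val = _YESNO.get(str(getattr(self, attr)).strip().lower())
            if val is None:
                raise ValidationError(f"{attr} must be Yes or No, got {getattr(self, attr)!r}")
            setattr(self, attr, val)
        if self.dl_violations < 0:
            raise ValidationError("dl_violations must be >= 0")


@dataclass
class ScreenRules:
    """Thresholds for the peak-area and pharmacokinetic screens.

    Defaults keep the blood-brain-barrier flag unconstrained and tolerate
    one drug-likeness violation, mirroring what the published component
    table actually retains; ``STRICT_SWISSADME`` is the stated rule set
    (GI High, BBB Yes, not a P-gp substrate, drug-likeness pass).
    """

    min_peak_area_pct: float = 0.12
    require_gi: str = "High"
    require_bbb: str = "any"
    require_pgp: str = "No"
    require_dl_pass: bool = True
    max_dl_violations: Union[int, str] = 1  # int or "unbounded"

    def __post_init__(self) -> None:
        if self.min_peak_area_pct < 0:
            raise ValidationError("min_peak_area_pct must be >= 0")


#: The screening conditions as stated: GI absorption High, BBB permeant,
#: not a P-gp substrate, drug-likeness pass.
STRICT_SWISSADME = ScreenRules(require_bbb="Yes", max_dl_violations="unbounded")

#: Default column mapping for the packaged component table.
DEFAULT_DIALECT = {
    "name": "Name",
    "formula": "Formula",
    "smiles": "Canonical SMILES",
    "cid": "CID No",
    "retention_time": "Time",
    "peak_area_pct": "Peak area %",  # absent from the packaged table
    "mw": "MW",
    "gi_absorption": "GI absorption (OB)",
    "bbb": "BBB",
    "pgp_substrate": "P-gp substrate",
    "drug_likeness": "Drug likeness (DL)",
}

_DL_RE = re.compile(r"(yes|no)\s*;?\s*(\d+)?", re.IGNORECASE)


def _parse_dl(cell: str) -> tuple[bool, int]:
    """Parse a 'Yes; 1 violation'-style drug-likeness cell."""
    m = _DL_RE.match(str(cell).strip())
    if not m:
        raise ValidationError(f"cannot parse drug-likeness cell {cell!r}")
    return m.group(1).lower() == "yes", int(m.group(2) or 0)


def parse_compound_table(
    path: Union[str, Path],
    dialect: Optional[dict] = None,
    sep: str = "\t",
) -> list[tuple[CompoundRecord, AdmetProfile]]:
    """Read a compound table into (record, ADMET profile) pairs, in file order.

    ``dialect`` maps field names to column headers (``None`` meaning the
    column is absent); it defaults to the packaged table's headers.
    Missing optional cells become ``None``, never zero.  A malformed
    formula or enum token raises :class:`ValidationError` naming the row
    and column.
    """
    dia = dict(DEFAULT_DIALECT)
    if dialect:
        dia.update(dialect)
    df = pd.read_csv(path, sep=sep, dtype=str)

    def cell(row, key):
        col = dia.get(key)
        if col is None or col not in df.columns:
            return None
        v = row[col]
        if v is None or (isinstance(v, float)) or str(v).strip() == "" or str(v) == "nan":
            return None
        return str(v).strip()

    out: list[tuple[CompoundRecord, AdmetProfile]] = []
    for i, (_, row) in enumerate(df.iterrows()):
        try:
            rt = cell(row, "retention_time")
            area = cell(row, "peak_area_pct")
            rec = CompoundRecord(
                name=cell(row, "name") or "",
                formula=cell(row, "formula") or "",
                smiles=cell(row, "smiles") or "",
                cid=cell(row, "cid"),
                retention_time=float(rt) if rt is not None else None,
                peak_area_pct=float(area) if area is not None else None,
            )
            dl_cell = cell(row, "drug_likeness")
            if dl_cell is None:
                raise ValidationError("missing drug-likeness cell")
            dl_pass, dl_viol = _parse_dl(dl_cell)
            prof = AdmetProfile(
                gi_absorption=cell(row, "gi_absorption") or "",
                bbb=cell(row, "bbb") or "",
                pgp_substrate=cell(row, "pgp_substrate") or "",
                dl_pass=dl_pass,
                dl_violations=dl_viol,
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i + 1}: {exc}") from exc
        out.append((rec, prof))
    return out


def packaged_component_table() -> Path:
    """Path to the packaged lavender-essential-oil component table."""
    return Path(str(resources.files("netpharm").joinpath("data/leo_active_components.tsv")))


def filter_peaks(records: Sequence[CompoundRecord], rules: ScreenRules = None) -> list[CompoundRecord]:
    """Keep records whose relative peak area strictly exceeds the threshold.

    The cut is strict (area > ``min_peak_area_pct``), matching "more than"
    phrasing of chromatographic selection; order is preserved.  A record
    lacking ``peak_area_pct`` raises :class:`ValidationError`.
    """
    rules = rules or ScreenRules()
    for r in records:
        if r.peak_area_pct is None:
            raise ValidationError(f"{r.name}: peak_area_pct is required for peak filtering")
    return [r for r in records if r.peak_area_pct > rules.min_peak_area_pct]


def admet_filter(
    records: Iterable[tuple[CompoundRecord, AdmetProfile]],
    rules: ScreenRules = None,
    rejection_log: Optional[list] = None,
) -> list[CompoundRecord]:
    """Apply the pharmacokinetic screen, preserving order.

    Each rejected compound is appended to ``rejection_log`` (if given) as
    ``(name, first_failed_rule)``.
    """
    rules = rules or ScreenRules()
    kept: list[CompoundRecord] = []
    for rec, prof in records:
        reason = _first_failed_rule(prof, rules)
        if reason is None:
            kept.append(rec)
        elif rejection_log is not None:
            rejection_log.append((rec.name, reason))
    return kept


def _first_failed_rule(prof: AdmetProfile, rules: ScreenRules) -> Optional[str]:
    if rules.require_gi != "any" and prof.gi_absorption != rules.require_gi:
        return "gi_absorption"
    if rules.require_bbb != "any" and prof.bbb != rules.require_bbb:
        return "bbb"
    if rules.require_pgp != "any" and prof.pgp_substrate != rules.require_pgp:
        return "pgp_substrate"
    if rules.require_dl_pass and not prof.dl_pass:
        return "dl_pass"
    if rules.max_dl_violations != "unbounded" and prof.dl_violations > int(rules.max_dl_violations):
        return "dl_violations"
    return None


def write_compound_table(records: Sequence[CompoundRecord], path: Union[str, Path]) -> None:
    """Write records as TSV (name, formula, smiles, cid, rt, area, mw)."""
    pd.DataFrame(
        [
            {
                "Name": r.name,
                "Formula": r.formula,
                "Canonical SMILES": r.smiles,
                "CID No": r.cid,
                "Time": r.retention_time,
                "Peak area %": r.peak_area_pct,
                "MW": r.mw,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)
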