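"""Reading and normalizing FAERS quarterly ASCII extracts.

FAERS ships each quarter as a set of '$'-delimited text files (DEMO, DRUG,
REAC, THER, OUTC, INDI) keyed by PRIMARYID/CASEID.  This module loads those
files into canonical pandas tables, parses the YYYY[MM[DD]] date dialect,
removes duplicate case versions by the FDA rule (same CASEID -> keep the
latest FDA_DT, ties broken by the larger PRIMARYID), converts age and weight
unit codes, and restricts drug mentions to primary-suspect (PS) rows matching
a user-supplied synonym map.
"""

from __future__ import annotations

import calendar
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PartialDate",
    "FaersDataset",
    "FaersLoadError",
    "FaersSchemaError",
    "read_quarter",
    "parse_partial_date",
    "deduplicate",
    "deduplicate_dataset",
    "normalize_age",
    "normalize_weight",
    "normalize_sex",
    "filter_primary_suspect",
    "load_synonym_map",
    "load_term_map",
]

# canonical lower-case column names per table; legacy (ISR-era, pre-2012Q4)
# variants are mapped onto the same schema
_COLUMN_ALIASES = {
    "isr": "primaryid",
    "case": "caseid",
    "gndr_cod": "sex",
    "dsg_drug_seq": "drug_seq",
    "indi_drug_seq": "drug_seq",
}

#: tables that must be present for any analysis
MANDATORY_TABLES = ("DEMO", "DRUG", "REAC")
#: all tables the reader recognizes
KNOWN_TABLES = ("DEMO", "DRUG", "REAC", "THER", "OUTC", "INDI")

_KEY_COLUMNS = {
    "DEMO": {"primaryid", "caseid"},
    "DRUG": {"primaryid", "role_cod", "drugname"},
    "REAC": {"primaryid", "pt"},
    "THER": {"primaryid", "start_dt"},
    "OUTC": {"primaryid", "outc_cod"},
    "INDI": {"primaryid"},
}


class FaersLoadError(RuntimeError):
    """A mandatory table is missing or a file cannot be read."""


class FaersSchemaError(RuntimeError):
    """A table's columns do not match any known FAERS schema."""


@dataclass(frozen=True)
class PartialDate:
    """A FAERS date with explicit precision (day, month, or year).

    FAERS date fields are strings ``YYYYMMDD``, ``YYYYMM`` or ``YYYY``;
    anything else (including impossible calendar dates) is invalid and
    represented as ``None`` by :func:`parse_partial_date`.
    """

    year: int
    month: int | None = None
    day: int | None = None

    @property
    def precision(self) -> str:
        if self.day is not None:
            return "day"
        if self.month is not None:
            return "month"
        return "year"

    def to_timestamp(self) -> pd.Timestamp:
        """Timestamp at full precision; raises if precision < day."""
        if self.precision != "day":
            raise ValueError(f"date {self} has {self.precision} precision")
        return pd.Timestamp(self.year, self.month, self.day)


def parse_partial_date(raw: object) -> PartialDate | None:
    """Parse a FAERS date string; returns ``None`` for anything invalid.

    Total over inputs: never raises.  "20230115" -> day precision,
    "202301" -> month precision, "2023" -> year precision.
    """
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    s = str(raw).strip()
    if s.endswith(".0"):  # numeric round-trip artifact
        s = s[:-2]
    if not s.isdigit() or len(s) not in (4, 6, 8):
        return None
    year = int(s[:4])
    if not 1900 <= year <= 2100:
        return None
    if len(s) == 4:
        return PartialDate(year)
    month = int(s[4:6])
    if not 1 <= month <= 12:
        return None
    if len(s) == 6:
        return PartialDate(year, month)
    day = int(s[6:8])
    if not 1 <= day <= calendar.monthrange(year, month)[1]:
        return None
    return PartialDate(year, month, day)


@dataclass
class FaersDataset:
    """One or more FAERS quarters loaded into canonical tables.

    ``tables`` maps table names ("DEMO", "DRUG", ...) to DataFrames with
    lower-case canonical columns; ``rejected_rows`` counts malformed rows
    per table (logged, never silently dropped).
    """

    tables: dict[str, pd.DataFrame]
    rejected_rows: dict[str, int] = field(default_factory=dict)

    def __getitem__(self, name: str) -> pd.DataFrame:
        return self.tables[name]

    def __contains__(self, name: str) -> bool:
        return name in self.tables

    def row_counts(self) -> dict[str, int]:
        return {name: len(df) for name, df in self.tables.items()}


def _read_dollar_file(path: Path) -> tuple[pd.DataFrame, int]:
    """Read one '$'-delimited file; returns (frame, n_rejected_rows).

    Rows whose field count disagrees with the header are counted and
    skipped.  All values are kept as strings; empty string means missing.
    """
    rejected = 0

    def _on_bad(line: list[str]) -> None:
        nonlocal rejected
        rejected += 1
        return None

    try:
        df = pd.read_csv(
            path,
            sep="$",
            dtype=str,
            keep_default_na=False,
            engine="python",
            on_bad_lines=_on_bad,
        )
    except OSError as exc:  # pragma: no cover - filesystem failure
        raise FaersLoadError(f"cannot read {path}: {exc}") from exc
    df.columns = [c.strip().lower() for c in df.columns]
    df = df.rename(columns=_COLUMN_ALIASES)
    return df, rejected


def _find_table_file(directory: Path, table: str) -> Path | None:
    hits = sorted(
        p
        for p in directory.iterdir()
        if p.is_file() and p.name.upper().startswith(table) and p.suffix.lower() in (".txt", ".tsv")
    )
    return hits[0] if hits else None


def read_quarter(directory: str | Path) -> FaersDataset:
    """Load one FAERS ASCII quarter from ``directory``.

    Each recognized table (DEMO/DRUG/REAC/THER/OUTC/INDI) is read from the
    first file whose name starts with the table name.  Column-name variants
    across FAERS eras (ISR vs PRIMARYID) are mapped onto one canonical
    schema; a table whose columns match no era raises
    :class:`FaersSchemaError`.  Missing mandatory tables raise
    :class:`FaersLoadError`.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FaersLoadError(f"not a directory: {directory}")
    tables: dict[str, pd.DataFrame] = {}
    rejected: dict[str, int] = {}
    for table in KNOWN_TABLES:
        path = _find_table_file(directory, table)
        if path is None:
            if table in MANDATORY_TABLES:
                raise FaersLoadError(f"mandatory table {table} not found in {directory}")
            continue
        df, n_bad = _read_dollar_file(path)
        missing = _KEY_COLUMNS[table] - set(df.columns)
        if missing:
            raise FaersSchemaError(
                f"table {table} in {path.name}: unmatched columns {sorted(missing)}; "
                f"found {list(df.columns)}"
            )
        for col in ("primaryid", "caseid", "drug_seq"):
            if col in df.columns:
                df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
        bad_key = df["primaryid"].isna()
        if bad_key.any():
            n_bad += int(bad_key.sum())
            df = df.loc[~bad_key].reset_index(drop=True)
        tables[table] = df
        rejected[table] = n_bad
    return FaersDataset(tables=tables, rejected_rows=rejected)


# ---------------------------------------------------------------------------
# deduplication


def _fda_dt_sort_key(raw: pd.Series) -> pd.Series:
    """Lexicographic sort key for FDA_DT; missing/invalid dates sort oldest.

    Partial dates are zero-padded to 8 digits so a month-precision date
    sorts before any day within that month — a record missing its FDA_DT is
    always superseded by a dated version of the same case.
    """
    s = raw.astype(str).str.strip().str.replace(r"\.0$", "", regex=True)
    valid = s.str.fullmatch(r"\d{4}(\d{2}(\d{2})?)?").fillna(False)
    return s.where(valid, "0").str.pad(8, side="right", fillchar="0")


def deduplicate(demo: pd.DataFrame) -> pd.DataFrame:
    """Keep one DEMO row per CASEID: latest FDA_DT, then largest PRIMARYID.

    Idempotent and order-independent: the survivor is the maximum of
    ``(fda_dt, primaryid)`` in lexicographic order within each CASEID group.
    """
    if demo.empty:
        return demo.copy()
    key = demo.assign(
        _dtkey=_fda_dt_sort_key(demo.get("fda_dt", pd.Series("", index=demo.index))),
        _pid=demo["primaryid"].astype("int64"),
    )
    key = key.sort_values(["caseid", "_dtkey", "_pid"], kind="mergesort")
    survivors = key.drop_duplicates("caseid", keep="last")
    out = survivors.drop(columns=["_dtkey", "_pid"]).sort_values("primaryid", kind="mergesort")
    return out.reset_index(drop=True)


def deduplicate_dataset(dataset: FaersDataset) -> FaersDataset:
    """Deduplicate DEMO and drop child-table rows of non-surviving versions."""
    demo = deduplicate(dataset["DEMO"])
    keep = set(demo["primaryid"].astype("int64"))
    tables = {"DEMO": demo}
    for name, df in dataset.tables.items():
        if name == "DEMO":
            continue
        mask = df["primaryid"].astype("int64").isin(keep)
        tables[name] = df.loc[mask].reset_index(drop=True)
    return FaersDataset(tables=tables, rejected_rows=dict(dataset.rejected_rows))


# ---------------------------------------------------------------------------
# unit normalization

#: AGE_COD -> multiplier converting the coded value to years
_AGE_FACTORS = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.1775,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

_WEIGHT_FACTORS = {"KG": 1.0, "KGS": 1.0, "LBS": 0.453592, "GMS": 1e-3}


def normalize_age(value: object, unit_code: object = "YR") -> float:
    """Convert a FAERS (AGE, AGE_COD) pair to years; NaN when implausible.

    A missing or unrecognized unit code with a value present is treated as
    years.  Nonpositive results and results >= 150 years are implausible and
    returned as NaN.
    """
    try:
        v = float(value)
    except (TypeError, ValueError):
        return float("nan")
    if np.isnan(v):
        return float("nan")
    unit = str(unit_code).strip().upper() if unit_code is not None else ""
    factor = _AGE_FACTORS.get(unit, 1.0)
    years = v * factor
    if years <= 0 or years >= 150:
        return float("nan")
    return years


def normalize_weight(value: object, unit_code: object = "KG") -> float:
    """Convert a FAERS (WT, WT_COD) pair to kilograms; NaN when implausible."""
    try:
        v = float(value)
    except (TypeError, ValueError):
        return float("nan")
    if np.isnan(v):
        return float("nan")
    unit = str(unit_code).strip().upper() if unit_code is not None else ""
    kg = v * _WEIGHT_FACTORS.get(unit, 1.0)
    if kg <= 0 or kg >= 700:
        return float("nan")
    return kg


def normalize_sex(value: object) -> str:
    v = str(value).strip().upper() if value is not None else ""
    if v in ("F", "FEMALE"):
        return "female"
    if v in ("M", "MALE"):
        return "male"
    return "unknown"


# ---------------------------------------------------------------------------
# drug-name matching

_PUNCT_RE = re.compile(r"[^\w\s]")
_DOSAGE_RE = re.compile(
    r"^(\d+(\.\d+)?(mg|mcg|ug|g|ml|ml\b|%)?|mg|mcg|ug|g|ml|tablets?|capsules?|"
    r"cap|tab|hcl|hydrochloride|xr|er|sr|cr|dr|od)$"
)


def _clean_drug_name(name: str) -> str:
    """Case-fold, strip punctuation, drop dosage/formulation tokens."""
    s = _PUNCT_RE.sub(" ", str(name).casefold())
    tokens = [t for t in s.split() if not _DOSAGE_RE.match(t)]
    return " ".join(tokens)


def load_synonym_map(path: str | Path) -> dict[str, str]:
    """Load a two-column (synonym, generic) text table; '#' starts a comment.

    Columns may be separated by tab or comma.  Keys are cleaned the same way
    verbatim drug names are, so matching is deterministic and auditable.
    """
    mapping: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = re.split(r"[\t,]", line)
        if len(parts) < 2:
            continue
        synonym, generic = parts[0].strip(), parts[1].strip()
        mapping[_clean_drug_name(synonym)] = generic.casefold()
    return mapping


def load_term_map(path: str | Path) -> dict[str, str]:
    """Load a two-column (term, value) map, e.g. PT -> SOC, keyed case-insensitively."""
    mapping: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = re.split(r"[\t]", line) if "\t" in line else re.split(r",", line)
        if len(parts) < 2:
            continue
        mapping[parts[0].strip().casefold()] = parts[1].strip()
    return mapping


def filter_primary_suspect(
    drug: pd.DataFrame, synonym_map: dict[str, str]
) -> pd.DataFrame:
    """Restrict DRUG rows to PS mentions of mapped target drugs.

    A mention is retained when its role code is ``PS`` and its verbatim name
    (case-folded, punctuation- and dosage-token-stripped) exactly matches a
    synonym; the returned frame carries a ``normalized_name`` column with the
    generic name.  Matching is exact after cleaning — no fuzzy logic.
    """
    if not synonym_map:
        raise ValueError("empty drug synonym map")
    cleaned_map = { _clean_drug_name(k): v for k, v in synonym_map.items() }
    ps = drug.loc[drug["role_cod"].astype(str).str.strip().str.upper() == "PS"].copy()
    if ps.empty:
        ps["normalized_name"] = pd.Series(dtype=str)
        return ps
    cleaned = ps["drugname"].map(_clean_drug_name)
    ps["normalized_name"] = cleaned.map(cleaned_map)
    out = ps.loc[ps["normalized_name"].notna()].reset_index(drop=True)
    return out
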