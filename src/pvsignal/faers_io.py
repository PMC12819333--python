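"""Readers and writers for FAERS-style quarterly ASCII tables.

The FDA Adverse Event Reporting System distributes each quarter as a set of
"$"-delimited ASCII files with a single header row: demographics (DEMO),
drugs (DRUG), reactions (REAC), therapy dates (THER), outcomes (OUTC) and
indications (INDI).  One patient case (CASEID) may appear as several report
versions (PRIMARYID); analyses must keep exactly one version per case.  This
module reads such quarters tolerantly (modern and legacy header sets, either
"$" or "|" delimiters), applies the FDA deduplication rule, and normalizes
the result into a single report-level store that the rest of the package
consumes.

The deduplication rule retains, within each CASEID, the record with the
latest FDA receipt date (FDA_DT); ties on FDA_DT are broken by the highest
PRIMARYID.
"""

from __future__ import annotations

import csv
import datetime as _dt
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PartialDate",
    "RawTableSet",
    "parse_partial_date",
    "read_quarter",
    "deduplicate",
    "build_report_store",
    "write_store",
    "read_store",
]

#: canonical lower-case table names in reading order
TABLE_NAMES = ("demo", "drug", "reac", "ther", "outc", "indi")

#: columns that must be present per table (after header normalization)
REQUIRED_COLUMNS: dict[str, tuple[str, ...]] = {
    "demo": ("PRIMARYID", "CASEID", "FDA_DT", "EVENT_DT", "AGE", "AGE_COD",
             "OCCR_COUNTRY", "OCCP_COD"),
    "drug": ("PRIMARYID", "DRUGNAME", "ROLE_COD"),
    "reac": ("PRIMARYID", "PT"),
    "ther": ("PRIMARYID", "START_DT"),
    "outc": ("PRIMARYID", "OUTC_COD"),
    "indi": ("PRIMARYID", "INDI_PT"),
}

#: legacy (pre-2012 AERS) header aliases mapped onto the modern names
LEGACY_ALIASES = {"ISR": "PRIMARYID", "CASE": "CASEID", "GNDR_COD": "SEX"}

#: AGE_COD unit conversion to years; unknown codes yield a missing age
AGE_UNIT_TO_YEARS = {
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.14,
    "DY": 1.0 / 365.25,
    "DEC": 10.0,
    "HR": 1.0 / 8766.0,
}

#: OUTC_COD -> outcome category used in cohort summaries
OUTCOME_CODES = {
    "HO": "hospitalization",
    "LT": "life-threatening",
    "DS": "disability",
    "DE": "death",
    "CA": "other",
    "RI": "other",
    "OT": "other",
}

#: OCCP_COD -> reporter category
_HCP_CODES = {"MD", "PH", "HP", "OT", "RN"}
_NON_HCP_CODES = {"CN", "LW"}

#: fixed column order of the serialized report store
STORE_COLUMNS = (
    "primaryid", "caseid", "fda_dt", "event_dt", "sex", "age_years",
    "country", "reporter", "outcomes",
)


@dataclass(frozen=True)
class PartialDate:
    """A FAERS date string decoded at whatever precision it carries.

    FAERS encodes dates as 4 (year), 6 (year+month) or 8 (full day) digit
    strings; time-to-onset computations require day precision on both ends.
    """

    year: int
    month: int | None = None
    day: int | None = None

    def __post_init__(self) -> None:
        if self.day is not None and self.month is None:
            raise ValueError("day precision requires a month")

    @property
    def precision(self) -> str:
        if self.day is not None:
            return "day"
        if self.month is not None:
            return "month"
        return "year"

    def to_date(self) -> _dt.date:
        if self.precision != "day":
            raise ValueError(f"date has {self.precision} precision, not day")
        return _dt.date(self.year, self.month, self.day)


def parse_partial_date(raw: str | None) -> PartialDate | None:
    """Decode a raw FAERS date string; return None for anything malformed.

    Accepts 4-, 6- or 8-digit strings.  Out-of-range months/days and
    impossible calendar dates (e.g. February 30) also yield None, so that
    erroneous entries drop out of date-based analyses.
    """
    if raw is None:
        return None
    s = str(raw).strip()
    if not s.isdigit() or len(s) not in (4, 6, 8):
        return None
    year = int(s[:4])
    if year < 1900 or year > 2100:
        return None
    if len(s) == 4:
        return PartialDate(year)
    month = int(s[4:6])
    if not 1 <= month <= 12:
        return None
    if len(s) == 6:
        return PartialDate(year, month)
    day = int(s[6:8])
    try:
        _dt.date(year, month, day)
    except ValueError:
        return None
    return PartialDate(year, month, day)


@dataclass
class RawTableSet:
    """The six FAERS tables of one quarter, as raw-string DataFrames."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    outc: pd.DataFrame
    indi: pd.DataFrame
    source_quarter: str = ""
    read_report: dict = field(default_factory=dict)

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)


def _read_table(path: Path, delimiter: str) -> tuple[pd.DataFrame, int]:
    """Read one "$"-delimited file; skip (and count) rows whose field count
    does not match the header."""
    with open(path, newline="", encoding="utf-8", errors="replace") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file, no header row")
        header = [LEGACY_ALIASES.get(h.strip().upper(), h.strip().upper())
                  for h in header]
        ncol = len(header)
        rows: list[list[str]] = []
        skipped = 0
        for row in reader:
            if not row:
                continue
            if len(row) != ncol:
                skipped += 1
                continue
            rows.append(row)
    frame = pd.DataFrame(rows, columns=header, dtype=str)
    return frame, skipped


def _locate(directory: Path, name: str) -> Path:
    candidates = sorted(
        p for p in directory.iterdir()
        if p.is_file() and p.name.lower().startswith(name)
    )
    if not candidates:
        raise FileNotFoundError(
            f"required FAERS table '{name.upper()}' not found in {directory}"
        )
    return candidates[0]


def read_quarter(directory_path: str | Path, delimiter: str = "$",
                 quarter_label: str | None = None) -> RawTableSet:
    """Read one FAERS-style quarter from a directory of ASCII tables.

    Column-name matching is case-insensitive; legacy headers (ISR, CASE,
    GNDR_COD) are mapped onto the modern names.  Rows whose field count
    disagrees with the header are skipped and counted in ``read_report``.
    Non-DEMO rows whose PRIMARYID does not join to DEMO are counted as
    orphans (they cannot contribute a report) but left in the raw tables.
    """
    directory = Path(directory_path)
    if not directory.is_dir():
        raise FileNotFoundError(f"not a directory: {directory}")
    frames: dict[str, pd.DataFrame] = {}
    report = {"rows_read": {}, "rows_skipped": {}, "orphan_rows": {}}
    for name in TABLE_NAMES:
        path = _locate(directory, name)
        frame, skipped = _read_table(path, delimiter)
        for col in REQUIRED_COLUMNS[name]:
            if col not in frame.columns:
                raise ValueError(
                    f"table '{name.upper()}' ({path.name}) lacks required "
                    f"column '{col}'"
                )
        if name == "demo" and "SEX" not in frame.columns:
            raise ValueError(
                f"table 'DEMO' ({path.name}) lacks a sex column "
                "(SEX or GNDR_COD)"
            )
        frames[name] = frame
        report["rows_read"][name] = int(len(frame))
        report["rows_skipped"][name] = int(skipped)

    demo_ids = set(frames["demo"]["PRIMARYID"])
    for name in TABLE_NAMES[1:]:
        ids = frames[name]["PRIMARYID"]
        report["orphan_rows"][name] = int((~ids.isin(demo_ids)).sum())

    return RawTableSet(
        **frames,
        source_quarter=quarter_label or directory.name,
        read_report=report,
    )


def _fda_sort_key(raw: str) -> int:
    """Total order on FDA_DT strings: valid 8-digit dates by value, anything
    unparseable sorts before every dated record."""
    d = parse_partial_date(raw)
    if d is None or d.precision != "day":
        return -1
    return d.year * 10000 + d.month * 100 + d.day


def deduplicate(demo: pd.DataFrame) -> tuple[set[int], pd.DataFrame]:
    """Apply the FDA duplicate rule to DEMO rows.

    Within each CASEID the record with the latest FDA_DT is kept; FDA_DT
    ties are broken by the highest PRIMARYID.  Returns the kept PRIMARYID
    set and a drop log with one row per removed record.
    """
    if demo.empty:
        return set(), pd.DataFrame(columns=["dropped_primaryid", "caseid", "reason"])
    work = demo[["PRIMARYID", "CASEID", "FDA_DT"]].copy()
    work["pid"] = pd.to_numeric(work["PRIMARYID"], errors="coerce")
    if work["pid"].isna().any():
        raise ValueError("DEMO contains rows with unparseable PRIMARYID")
    work["pid"] = work["pid"].astype("int64")
    parsed = pd.to_datetime(work["FDA_DT"].str.strip(), format="%Y%m%d",
                            errors="coerce")
    days = parsed.to_numpy().astype("int64") // 86_400_000_000_000
    work["fda_key"] = np.where(parsed.isna().to_numpy(), -1, days)
    n_bad = int((work["fda_key"] == -1).sum())
    if n_bad:
        warnings.warn(
            f"{n_bad} DEMO rows have unparseable FDA_DT; they sort before "
            "any dated record when resolving duplicates",
            stacklevel=2,
        )
    work = work.sort_values(["CASEID", "fda_key", "pid"], kind="mergesort")
    keep_mask = ~work.duplicated("CASEID", keep="last")
    kept = set(work.loc[keep_mask, "pid"].tolist())

    dropped = work.loc[~keep_mask]
    if dropped.empty:
        log = pd.DataFrame(columns=["dropped_primaryid", "caseid", "reason"])
    else:
        winners = work.loc[keep_mask, ["CASEID", "fda_key"]].set_index("CASEID")["fda_key"]
        reasons = [
            "fda_dt_tie_lower_primaryid"
            if row.fda_key == winners[row.CASEID] else "superseded_by_later_fda_dt"
            for row in dropped.itertuples()
        ]
        log = pd.DataFrame({
            "dropped_primaryid": dropped["pid"].to_numpy(),
            "caseid": dropped["CASEID"].to_numpy(),
            "reason": reasons,
        })
    return kept, log


def build_report_store(tables: RawTableSet) -> tuple[pd.DataFrame, dict]:
    """Deduplicate a quarter and normalize DEMO/OUTC into report records.

    Returns the report store (one row per kept report, columns in
    ``STORE_COLUMNS`` order) and a JSON-serializable processing report
    ``{rows_read, rows_skipped, duplicates_dropped, ...}``.
    """
    kept, drop_log = deduplicate(tables.demo)
    demo = tables.demo.copy()
    demo["primaryid"] = pd.to_numeric(demo["PRIMARYID"], errors="coerce").astype("int64")
    demo = demo[demo["primaryid"].isin(kept)]

    country_col = demo["OCCR_COUNTRY"].str.strip()
    if "REPORTER_COUNTRY" in demo.columns:
        fallback = demo["REPORTER_COUNTRY"].str.strip()
        country_col = country_col.where(country_col != "", fallback)

    age_num = pd.to_numeric(demo["AGE"], errors="coerce")
    factor = demo["AGE_COD"].str.strip().str.upper().map(AGE_UNIT_TO_YEARS)
    age_years = age_num * factor
    age_years = age_years.where((age_years >= 0) & (age_years <= 120))

    sex = (demo["SEX"].str.strip().str.upper()
           .map({"M": "male", "F": "female"}).fillna("unspecified"))
    occp = demo["OCCP_COD"].str.strip().str.upper()
    reporter = pd.Series(
        np.select(
            [occp.isin(_HCP_CODES), occp.isin(_NON_HCP_CODES)],
            ["healthcare professional", "non-healthcare professional"],
            default="missing",
        ),
        index=demo.index,
    )

    store = pd.DataFrame({
        "primaryid": demo["primaryid"].to_numpy(),
        "caseid": demo["CASEID"].str.strip().to_numpy(),
        "fda_dt": demo["FDA_DT"].str.strip().to_numpy(),
        "event_dt": demo["EVENT_DT"].str.strip().to_numpy(),
        "sex": sex.to_numpy(),
        "age_years": age_years.to_numpy(),
        "country": country_col.where(country_col != "", None).to_numpy(),
        "reporter": reporter.to_numpy(),
    })

    outc = tables.outc.copy()
    outc["primaryid"] = pd.to_numeric(outc["PRIMARYID"], errors="coerce")
    outc = outc.dropna(subset=["primaryid"])
    outc["primaryid"] = outc["primaryid"].astype("int64")
    outc["category"] = outc["OUTC_COD"].str.strip().str.upper().map(OUTCOME_CODES)
    outc = outc.dropna(subset=["category"])
    flags = (outc.assign(v=True)
             .pivot_table(index="primaryid", columns="category", values="v",
                          aggfunc="any", fill_value=False))
    joined = np.full(len(flags), "", dtype=object)
    for cat in sorted(flags.columns):
        piece = np.where(flags[cat].to_numpy(), cat, "")
        joined = np.where(joined == "", piece,
                          np.where(piece == "", joined, joined + "," + piece))
    per_report = pd.Series(joined, index=flags.index)
    store["outcomes"] = store["primaryid"].map(per_report).fillna("missing")

    store = store.loc[:, list(STORE_COLUMNS)].reset_index(drop=True)
    processing = {
        "rows_read": tables.read_report.get("rows_read", {}),
        "rows_skipped": tables.read_report.get("rows_skipped", {}),
        "orphan_rows": tables.read_report.get("orphan_rows", {}),
        "duplicates_dropped": int(len(drop_log)),
        "reports_kept": int(len(store)),
    }
    return store, processing


def write_store(store: pd.DataFrame, directory: str | Path,
                processing: dict | None = None) -> Path:
    """Serialize a report store as TSV (fixed column order) plus a JSON
    processing report; returns the store path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / "report_store.tsv"
    store.loc[:, list(STORE_COLUMNS)].to_csv(path, sep="\t", index=False)
    if processing is not None:
        (directory / "processing_report.json").write_text(
            json.dumps(processing, indent=2, sort_keys=True)
        )
    return path


def read_store(directory: str | Path) -> pd.DataFrame:
    path = Path(directory) / "report_store.tsv"
    store = pd.read_csv(path, sep="\t", dtype={"caseid": str, "fda_dt": str,
                                               "event_dt": str})
    return store
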