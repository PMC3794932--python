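"""EHR record types and delimited-text cohort I/O.

Four flat tables describe an inpatient cohort: prescriptions (one row per
drug administration of one drug on one day), laboratory results, admissions,
and diagnoses.  The analysis bins prescriptions by calendar day, so all
dates are handled at day resolution; intra-day times are truncated on load.

Tables are UTF-8 delimited text with a header row (comma-separated,
ISO-8601 dates by default; both configurable through :class:`CsvDialect`).
Every input row is either loaded or rejected with a per-row reason — rows
are never silently dropped.  Laboratory values are either numeric
(quantitative analytes, e.g. serum potassium in mmol/L) or one of the
nominal tokens ``positive``/``negative`` (e.g. a C. difficile toxin test).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "PrescriptionRecord",
    "LabRecord",
    "AdmissionRecord",
    "DiagnosisRecord",
    "CohortData",
    "CsvDialect",
    "LoadReport",
    "RowIssue",
    "SchemaError",
    "read_cohort",
    "write_cohort",
    "cohort_paths",
    "TABLE_COLUMNS",
]

NOMINAL_TOKENS = ("positive", "negative")

#: lexical shape of an ICD-10 code: letter, two digits, optional subcode
ICD10_RE = re.compile(r"^[A-Za-z]\d{2}(\.[0-9A-Za-z]{1,4})?$")

TABLE_COLUMNS: dict[str, list[str]] = {
    "prescriptions": ["patient_id", "admission_id", "drug_code", "prescriber_id", "admin_date"],
    "labs": ["patient_id", "admission_id", "analyte", "value", "order_date", "result_date"],
    "admissions": ["patient_id", "admission_id", "admit_date", "discharge_date"],
    "diagnoses": ["patient_id", "icd10_code"],
}

DEFAULT_FILENAMES = {name: f"{name}.csv" for name in TABLE_COLUMNS}


class SchemaError(ValueError):
    """A table is missing a required column (or cannot be parsed at all)."""


@dataclass(frozen=True)
class RowIssue:
    """One rejected input row: which table, which line (1-based, header = 1), why."""

    table: str
    line: int
    reason: str


@dataclass
class LoadReport:
    """Tally of loaded vs. rejected rows per table, with per-row reasons."""

    issues: list[RowIssue] = field(default_factory=list)
    n_loaded: dict[str, int] = field(default_factory=dict)
    n_rejected: dict[str, int] = field(default_factory=dict)

    def summary(self) -> str:
        lines = []
        for table in TABLE_COLUMNS:
            lines.append(
                f"{table}: {self.n_loaded.get(table, 0)} loaded, "
                f"{self.n_rejected.get(table, 0)} rejected"
            )
        for issue in self.issues:
            lines.append(f"  {issue.table}:{issue.line}: {issue.reason}")
        return "\n".join(lines)


@dataclass(frozen=True)
class PrescriptionRecord:
    """One administration of one drug to one patient on one calendar day."""

    patient_id: str
    admission_id: str
    drug_code: str  # ATC-style code
    prescriber_id: str  # may be "" when the prescriber is unknown
    admin_date: dt.date


@dataclass(frozen=True)
class LabRecord:
    """One laboratory result; ``value`` is a float for quantitative analytes
    (e.g. serum potassium, mmol/L) or a ``positive``/``negative`` token for
    nominal tests."""

    patient_id: str
    admission_id: str
    analyte: str
    value: Union[float, str]
    result_date: dt.date
    order_date: dt.date | None = None

    @property
    def is_quantitative(self) -> bool:
        return not isinstance(self.value, str)


@dataclass(frozen=True)
class AdmissionRecord:
    patient_id: str
    admission_id: str
    admit_date: dt.date
    discharge_date: dt.date


@dataclass(frozen=True)
class DiagnosisRecord:
    patient_id: str
    icd10_code: str


@dataclass(frozen=True)
class CsvDialect:
    """Delimiter and date format of the input tables.

    ``date_format=None`` accepts anything :func:`pandas.to_datetime` can
    parse and truncates to the day.
    """

    delimiter: str = ","
    date_format: str | None = "%Y-%m-%d"


@dataclass
class CohortData:
    """A validated cohort: four pandas DataFrames with canonical dtypes.

    Canonical columns
    -----------------
    prescriptions : patient_id, admission_id, drug_code, prescriber_id, admin_date
    labs          : patient_id, admission_id, analyte, value_num (float, NaN for
                    nominal results), value_str ("" for numeric results),
                    order_date (may be NaT), result_date
    admissions    : patient_id, admission_id, admit_date, discharge_date
    diagnoses     : patient_id, icd10_code

    All date columns are ``datetime64[ns]`` normalized to midnight.
    """

    prescriptions: pd.DataFrame
    labs: pd.DataFrame
    admissions: pd.DataFrame
    diagnoses: pd.DataFrame
    load_report: LoadReport | None = dataclasses.field(default=None, compare=False)

    # ------------------------------------------------------------------ build
    @classmethod
    def empty(cls) -> "CohortData":
        return cls.from_records([], [], [], [])

    @classmethod
    def from_records(
        cls,
        prescriptions: Iterable[PrescriptionRecord] = (),
        labs: Iterable[LabRecord] = (),
        admissions: Iterable[AdmissionRecord] = (),
        diagnoses: Iterable[DiagnosisRecord] = (),
    ) -> "CohortData":
        rx = pd.DataFrame(
            [
                (r.patient_id, r.admission_id, r.drug_code, r.prescriber_id, pd.Timestamp(r.admin_date))
                for r in prescriptions
            ],
            columns=TABLE_COLUMNS["prescriptions"],
        )
        lab_rows = []
        for r in labs:
            num = np.nan if isinstance(r.value, str) else float(r.value)
            tok = r.value.lower() if isinstance(r.value, str) else ""
            lab_rows.append(
                (
                    r.patient_id,
                    r.admission_id,
                    r.analyte,
                    num,
                    tok,
                    pd.Timestamp(r.order_date) if r.order_date is not None else pd.NaT,
                    pd.Timestamp(r.result_date),
                )
            )
        lb = pd.DataFrame(
            lab_rows,
            columns=["patient_id", "admission_id", "analyte", "value_num", "value_str", "order_date", "result_date"],
        )
        ad = pd.DataFrame(
            [
                (r.patient_id, r.admission_id, pd.Timestamp(r.admit_date), pd.Timestamp(r.discharge_date))
                for r in admissions
            ],
            columns=TABLE_COLUMNS["admissions"],
        )
        dx = pd.DataFrame(
            [(r.patient_id, r.icd10_code) for r in diagnoses],
            columns=TABLE_COLUMNS["diagnoses"],
        )
        return cls(*(_canonicalize(name, df) for name, df in
                     zip(("prescriptions", "labs", "admissions", "diagnoses"), (rx, lb, ad, dx))))

    # -------------------------------------------------------------- inspect
    @property
    def n_records(self) -> dict[str, int]:
        return {
            "prescriptions": len(self.prescriptions),
            "labs": len(self.labs),
            "admissions": len(self.admissions),
            "diagnoses": len(self.diagnoses),
        }

    def validate(self) -> list[str]:
        """Re-check the cohort invariants; returns a list of violations."""
        problems: list[str] = []
        adm = self.admissions
        if adm["admission_id"].duplicated().any():
            problems.append("duplicate admission_id in admissions")
        if (adm["admit_date"] > adm["discharge_date"]).any():
            problems.append("admission with admit_date after discharge_date")
        known = set(adm["admission_id"])
        for table, df in (("prescriptions", self.prescriptions), ("labs", self.labs)):
            missing = set(df["admission_id"]) - known
            if missing:
                problems.append(f"{table} reference unknown admissions: {sorted(missing)[:5]}")
        rx = self.prescriptions.merge(adm, on="admission_id", suffixes=("", "_adm"))
        out = (rx["admin_date"] < rx["admit_date"]) | (rx["admin_date"] > rx["discharge_date"])
        if out.any():
            problems.append(f"{int(out.sum())} prescriptions dated outside their admission span")
        if (self.prescriptions["drug_code"] == "").any():
            problems.append("prescription with empty drug_code")
        both = self.labs.dropna(subset=["order_date"])
        if (both["order_date"] > both["result_date"]).any():
            problems.append("lab with order_date after result_date")
        bad_tok = ~self.labs["value_str"].isin(("",) + NOMINAL_TOKENS)
        if bad_tok.any():
            problems.append("lab with nominal value outside {positive, negative}")
        bad_code = ~self.diagnoses["icd10_code"].map(lambda c: bool(ICD10_RE.match(c)))
        if bad_code.any():
            problems.append("diagnosis code not ICD-10 shaped")
        return problems


def _canonicalize(name: str, df: pd.DataFrame) -> pd.DataFrame:
    date_cols = {
        "prescriptions": ["admin_date"],
        "labs": ["order_date", "result_date"],
        "admissions": ["admit_date", "discharge_date"],
        "diagnoses": [],
    }[name]
    df = df.copy()
    for col in df.columns:
        if col in date_cols:
            df[col] = pd.to_datetime(df[col]).dt.normalize() if len(df) else pd.to_datetime(df[col])
        elif col == "value_num":
            df[col] = df[col].astype(float)
        else:
            df[col] = df[col].astype(object) if len(df) else df[col]
    return df.reset_index(drop=True)


def cohort_paths(directory: Union[str, Path]) -> dict[str, Path]:
    """Default per-table file paths inside ``directory``."""
    d = Path(directory)
    return {name: d / fname for name, fname in DEFAULT_FILENAMES.items()}


def _resolve_paths(paths: Union[str, Path, Mapping[str, Union[str, Path]]]) -> dict[str, Path]:
    if isinstance(paths, (str, Path)):
        return cohort_paths(paths)
    resolved = {}
    for name in TABLE_COLUMNS:
        if name not in paths:
            raise SchemaError(f"no path given for table '{name}'")
        resolved[name] = Path(paths[name])
    return resolved


def _parse_dates(series: pd.Series, dialect: CsvDialect) -> pd.Series:
    if dialect.date_format is None:
        parsed = pd.to_datetime(series, errors="coerce")
    else:
        parsed = pd.to_datetime(series, format=dialect.date_format, errors="coerce")
    return parsed.dt.normalize()


def read_cohort(
    paths: Union[str, Path, Mapping[str, Union[str, Path]]],
    dialect: CsvDialect = CsvDialect(),
) -> CohortData:
    """Load and validate the four cohort tables.

    Parameters
    ----------
    paths
        Either a directory containing the default filenames
        (``prescriptions.csv`` etc.) or a mapping from table name to path.
    dialect
        Delimiter and date format.

    Returns
    -------
    CohortData
        Validated cohort; ``cohort.load_report`` lists every rejected row
        with its table, line number and reason.

    Raises
    ------
    SchemaError
        If a required column is missing from a table.
    FileNotFoundError
        If an input file does not exist.
    """
    resolved = _resolve_paths(paths)
    raw: dict[str, pd.DataFrame] = {}
    for name, path in resolved.items():
        if not Path(path).exists():
            raise FileNotFoundError(f"input table '{name}' not found: {path}")
        df = pd.read_csv(path, sep=dialect.delimiter, dtype=str, keep_default_na=False)
        for col in TABLE_COLUMNS[name]:
            if col not in df.columns:
                raise SchemaError(f"{name}: missing column '{col}'")
        raw[name] = df

    report = LoadReport()

    def reject(table: str, idx: int, reason: str) -> None:
        report.issues.append(RowIssue(table, int(idx) + 2, reason))  # +2: header + 1-based

    # admissions first: they anchor referential integrity
    adm = raw["admissions"]
    admit = _parse_dates(adm["admit_date"], dialect)
    disch = _parse_dates(adm["discharge_date"], dialect)
    keep = np.ones(len(adm), dtype=bool)
    for i in adm.index:
        if pd.isna(admit[i]) or pd.isna(disch[i]):
            reject("admissions", i, "unparseable date")
            keep[i] = False
        elif admit[i] > disch[i]:
            reject("admissions", i, "admit_date after discharge_date")
            keep[i] = False
    adm_ok = pd.DataFrame(
        {
            "patient_id": adm["patient_id"],
            "admission_id": adm["admission_id"],
            "admit_date": admit,
            "discharge_date": disch,
        }
    )[keep]
    dup = adm_ok["admission_id"].duplicated()
    for i in adm_ok.index[dup]:
        reject("admissions", i, f"duplicate admission_id '{adm_ok.at[i, 'admission_id']}'")
    adm_ok = adm_ok[~dup]
    span = adm_ok.set_index("admission_id")[["admit_date", "discharge_date"]]

    # prescriptions
    rx = raw["prescriptions"]
    rx_date = _parse_dates(rx["admin_date"], dialect)
    rx_rows = []
    for i in rx.index:
        aid = rx.at[i, "admission_id"]
        if rx.at[i, "drug_code"] == "":
            reject("prescriptions", i, "empty drug_code")
            continue
        if pd.isna(rx_date[i]):
            reject("prescriptions", i, "unparseable admin_date")
            continue
        if aid not in span.index:
            reject("prescriptions", i, f"unknown admission_id '{aid}'")
            continue
        lo, hi = span.at[aid, "admit_date"], span.at[aid, "discharge_date"]
        if not (lo <= rx_date[i] <= hi):
            reject("prescriptions", i, "admin_date outside admission span")
            continue
        rx_rows.append(
            (rx.at[i, "patient_id"], aid, rx.at[i, "drug_code"], rx.at[i, "prescriber_id"], rx_date[i])
        )
    rx_ok = pd.DataFrame(rx_rows, columns=TABLE_COLUMNS["prescriptions"])

    # labs
    lb = raw["labs"]
    lb_res = _parse_dates(lb["result_date"], dialect)
    lb_ord = _parse_dates(lb["order_date"], dialect) if len(lb) else lb_res
    lab_rows = []
    for i in lb.index:
        aid = lb.at[i, "admission_id"]
        if aid not in span.index:
            reject("labs", i, f"unknown admission_id '{aid}'")
            continue
        if pd.isna(lb_res[i]):
            reject("labs", i, "unparseable result_date")
            continue
        has_order = str(lb.at[i, "order_date"]) != ""
        if has_order and pd.isna(lb_ord[i]):
            reject("labs", i, "unparseable order_date")
            continue
        odate = lb_ord[i] if has_order else pd.NaT
        if has_order and odate > lb_res[i]:
            reject("labs", i, "order_date after result_date")
            continue
        rawval = str(lb.at[i, "value"]).strip()
        try:
            num, tok = float(rawval), ""
        except ValueError:
            num, tok = np.nan, rawval.lower()
            if tok not in NOMINAL_TOKENS:
                reject("labs", i, f"nominal value '{rawval}' not in {{positive, negative}}")
                continue
        lab_rows.append((lb.at[i, "patient_id"], aid, lb.at[i, "analyte"], num, tok, odate, lb_res[i]))
    lb_ok = pd.DataFrame(
        lab_rows,
        columns=["patient_id", "admission_id", "analyte", "value_num", "value_str", "order_date", "result_date"],
    )

    # diagnoses
    dx = raw["diagnoses"]
    dx_rows = []
    for i in dx.index:
        code = dx.at[i, "icd10_code"]
        if not ICD10_RE.match(code):
            reject("diagnoses", i, f"icd10_code '{code}' not ICD-10 shaped")
            continue
        dx_rows.append((dx.at[i, "patient_id"], code))
    dx_ok = pd.DataFrame(dx_rows, columns=TABLE_COLUMNS["diagnoses"])

    tables = {"prescriptions": rx_ok, "labs": lb_ok, "admissions": adm_ok.reset_index(drop=True), "diagnoses": dx_ok}
    for name in TABLE_COLUMNS:
        report.n_loaded[name] = len(tables[name])
        report.n_rejected[name] = len(raw[name]) - len(tables[name])

    cohort = CohortData(
        *(_canonicalize(name, tables[name]) for name in ("prescriptions", "labs", "admissions", "diagnoses"))
    )
    cohort.load_report = report
    return cohort


def _fmt_date(ts) -> str:
    if pd.isna(ts):
        return ""
    return pd.Timestamp(ts).strftime("%Y-%m-%d")


def write_cohort(
    cohort: CohortData,
    paths: Union[str, Path, Mapping[str, Union[str, Path]]],
    dialect: CsvDialect = CsvDialect(),
) -> dict[str, Path]:
    """Write the four cohort tables as delimited text.

    Writing is deterministic: the same cohort produces byte-identical files
    on repeated writes, and ``read_cohort(write_cohort(x))`` reproduces the
    record multisets of ``x``.
    """
    resolved = _resolve_paths(paths)
    for path in resolved.values():
        path.parent.mkdir(parents=True, exist_ok=True)
    fmt = dialect.date_format or "%Y-%m-%d"

    rx = cohort.prescriptions.copy()
    rx["admin_date"] = rx["admin_date"].map(lambda t: pd.Timestamp(t).strftime(fmt))
    rx.to_csv(resolved["prescriptions"], index=False, sep=dialect.delimiter)

    lb = cohort.labs.copy()
    value = [
        row.value_str if row.value_str != "" else repr(float(row.value_num))
        for row in lb.itertuples()
    ]
    out = pd.DataFrame(
        {
            "patient_id": lb["patient_id"],
            "admission_id": lb["admission_id"],
            "analyte": lb["analyte"],
            "value": value,
            "order_date": lb["order_date"].map(lambda t: "" if pd.isna(t) else pd.Timestamp(t).strftime(fmt)),
            "result_date": lb["result_date"].map(lambda t: pd.Timestamp(t).strftime(fmt)),
        }
    )
    out.to_csv(resolved["labs"], index=False, sep=dialect.delimiter)

    ad = cohort.admissions.copy()
    for col in ("admit_date", "discharge_date"):
        ad[col] = ad[col].map(lambda t: pd.Timestamp(t).strftime(fmt))
    ad.to_csv(resolved["admissions"], index=False, sep=dialect.delimiter)

    cohort.diagnoses.to_csv(resolved["diagnoses"], index=False, sep=dialect.delimiter)
    return resolved
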