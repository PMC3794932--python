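"""Hand-built cohort fixtures and independent brute-force oracles."""

from __future__ import annotations

import datetime as dt

import pandas as pd

import pacekit as pk

BASE = dt.date(2022, 1, 1)


def day(n: int) -> dt.date:
    return BASE + dt.timedelta(days=int(n))


def admission(pid, aid, start, end):
    return pk.AdmissionRecord(pid, aid, day(start), day(end))


def rx(pid, aid, drug, d, prescriber="DR1"):
    return pk.PrescriptionRecord(pid, aid, drug, prescriber, day(d))


def lab(pid, aid, analyte, value, d, order=None):
    return pk.LabRecord(
        pid, aid, analyte, value, day(d), day(order) if order is not None else None
    )


def dx(pid, code):
    return pk.DiagnosisRecord(pid, code)


def cohort(prescriptions=(), labs=(), admissions=(), diagnoses=()):
    return pk.CohortData.from_records(prescriptions, labs, admissions, diagnoses)


def single_window_cohort(
    event_day=10, admit=0, discharge=20, rx_days=(), drug="D1", analyte="potassium"
):
    """One admission with a normal baseline and one threshold crossing."""
    labs = [
        lab("P1", "A1", analyte, 4.0, admit + 1),
        lab("P1", "A1", analyte, 5.6, event_day),
    ]
    return cohort(
        prescriptions=[rx("P1", "A1", drug, d) for d in rx_days],
        labs=labs,
        admissions=[admission("P1", "A1", admit, discharge)],
    )


def brute_force_counts(cohort_data: pk.CohortData, windows, drug: str):
    """Quadratic per-(prescription, window) scan; independent of tabulate."""
    counts = {k: 0 for k in range(-4, 2)}
    for w in windows:
        for row in cohort_data.prescriptions.itertuples():
            if row.drug_code != drug or row.admission_id != w.event.admission_id:
                continue
            off = (row.admin_date - w.event.index_date).days
            if -4 <= off <= 1:
                counts[off] += 1
    return tuple(counts[k] for k in range(-4, 2))


def relabel(cohort_data: pk.CohortData, suffix: str) -> pk.CohortData:
    """Suffix all patient/admission ids, producing a disjoint copy."""

    def fix(df, cols):
        df = df.copy()
        for c in cols:
            df[c] = df[c].astype(str) + suffix
        return df

    return pk.CohortData(
        fix(cohort_data.prescriptions, ["patient_id", "admission_id"]),
        fix(cohort_data.labs, ["patient_id", "admission_id"]),
        fix(cohort_data.admissions, ["patient_id", "admission_id"]),
        fix(cohort_data.diagnoses, ["patient_id"]),
    )


def concat_cohorts(a: pk.CohortData, b: pk.CohortData) -> pk.CohortData:
    return pk.CohortData(
        pd.concat([a.prescriptions, b.prescriptions], ignore_index=True),
        pd.concat([a.labs, b.labs], ignore_index=True),
        pd.concat([a.admissions, b.admissions], ignore_index=True),
        pd.concat([a.diagnoses, b.diagnoses], ignore_index=True),
    )


def sorted_table(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(list(df.columns), kind="mergesort").reset_index(drop=True)


def assert_cohorts_equal(a: pk.CohortData, b: pk.CohortData):
    for name in ("prescriptions", "labs", "admissions", "diagnoses"):
        pd.testing.assert_frame_equal(
            sorted_table(getattr(a, name)), sorted_table(getattr(b, name)), check_dtype=False
        )
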