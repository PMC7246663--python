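"""Patient-level ICD-10 diagnosis records: reading, validation, and stratification.

A cohort is a collection of patients who all carry one *index disease*
(here, by default, hepatocellular carcinoma — ICD-10 C22.0).  Each patient
record carries demographics (age in years, binary sex) and a de-duplicated
set of ICD-10 diagnosis codes originating from one primary and up to 15
secondary diagnosis slots of a hospital discharge record.

Codes are normalized to uppercase with dots removed ("C22.0" -> "C220") and
compared as exact strings; the only hierarchy operation supported is
truncation to the 3-character ICD-10 category ("C220" -> "C22").
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace

import pandas as pd

#: Age bins used for stratified analyses, as (label, lower, upper) with
#: inclusive bounds.  A patient's age falls in exactly one bin.
AGE_BINS: tuple[tuple[str, int, int], ...] = (
    ("<=39", 0, 39),
    ("40-49", 40, 49),
    ("50-59", 50, 59),
    ("60-69", 60, 69),
    (">=70", 70, 10**9),
)

AGE_BIN_LABELS: tuple[str, ...] = tuple(b[0] for b in AGE_BINS)

SEXES = ("male", "female")

#: One primary + 15 secondary diagnosis slots per raw record.
MAX_DX_SLOTS = 16

_SEX_ALIASES = {
    "male": "male", "m": "male", "1": "male",
    "female": "female", "f": "female", "2": "female",
}


class RecordFormatError(ValueError):
    """Malformed input file: missing columns, duplicate slots, bad layout."""


class RecordValueError(ValueError):
    """Record-level invalid values (age, sex, conflicting demographics)."""


def normalize_code(code: str) -> str:
    """Normalize one ICD-10 code: strip whitespace, uppercase, drop dots."""
    return str(code).strip().upper().replace(".", "")


def age_bin(age: int) -> str:
    """Return the label of the age bin containing ``age``."""
    if age < 0:
        raise RecordValueError(f"age must be >= 0, got {age}")
    for label, lo, hi in AGE_BINS:
        if lo <= age <= hi:
            return label
    raise AssertionError("unreachable: AGE_BINS cover [0, inf)")


@dataclass(frozen=True)
class PatientRecord:
    """One patient's demographics and de-duplicated diagnosis codes.

    ``diagnoses`` preserves first-seen order (primary diagnosis first) and
    contains no duplicates after normalization.
    """

    patient_id: str
    age: int
    sex: str
    diagnoses: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise RecordValueError(
                f"patient {self.patient_id!r}: sex must be one of {SEXES}, got {self.sex!r}"
            )
        if self.age < 0:
            raise RecordValueError(f"patient {self.patient_id!r}: age must be >= 0")
        if not self.diagnoses:
            raise RecordValueError(f"patient {self.patient_id!r}: no diagnoses")
        if len(set(self.diagnoses)) != len(self.diagnoses):
            raise RecordValueError(f"patient {self.patient_id!r}: duplicate diagnoses")

    @property
    def age_bin(self) -> str:
        return age_bin(self.age)

    def comorbidities(self, index_codes: frozenset[str]) -> tuple[str, ...]:
        """Diagnoses excluding the index-disease codes."""
        return tuple(d for d in self.diagnoses if d not in index_codes)


@dataclass(frozen=True)
class Cohort:
    """An ordered collection of unique patients sharing an index disease."""

    records: tuple[PatientRecord, ...]
    index_codes: frozenset[str] = frozenset({"C220"})
    label: str = "all"

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise RecordValueError(f"duplicate patient_id values: {dupes}")
        if not self.index_codes:
            raise RecordValueError("index_codes must be non-empty")

    @property
    def n(self) -> int:
        return len(self.records)

    # Backwards-friendly alias matching the epidemiological "N".
    N = n

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def _merge_rows(pid: str, rows: pd.DataFrame, codes: list[str]) -> PatientRecord:
    ages = rows["age"].unique()
    sexes = rows["sex"].unique()
    if len(ages) > 1 or len(sexes) > 1:
        raise RecordValueError(
            f"patient {pid!r}: conflicting demographics across rows "
            f"(ages {sorted(ages)}, sexes {sorted(sexes)})"
        )
    seen: dict[str, None] = {}
    for c in codes:
        seen.setdefault(c, None)
    return PatientRecord(pid, int(ages[0]), str(sexes[0]), tuple(seen))


def _parse_demographics(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    bad_age = []
    ages = []
    for pid, raw in zip(df["patient_id"], df["age"]):
        try:
            a = int(raw)
            if a < 0:
                raise ValueError
        except (TypeError, ValueError):
            bad_age.append(str(pid))
            a = -1
        ages.append(a)
    sexes = []
    bad_sex = []
    for pid, raw in zip(df["patient_id"], df["sex"]):
        s = _SEX_ALIASES.get(str(raw).strip().lower())
        if s is None:
            bad_sex.append(str(pid))
        sexes.append(s)
    problems = []
    if bad_age:
        problems.append(f"unparseable age for patient_ids {sorted(set(bad_age))}")
    if bad_sex:
        problems.append(f"unparseable sex for patient_ids {sorted(set(bad_sex))}")
    if problems:
        raise RecordValueError("; ".join(problems))
    df["age"] = ages
    df["sex"] = sexes
    return df


def _read_delimited(path) -> pd.DataFrame:
    # Header sniff: tab wins if present in the first line, else comma.
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise RecordFormatError(
            f"{path}: missing mandatory column(s) {missing}; found {list(df.columns)}"
        )


def read_records(path, layout: str = "long", index_codes=("C220",)) -> Cohort:
    """Read patient diagnosis records from a delimited text file.

    Parameters
    ----------
    path
        CSV (or TSV) file with a header row, UTF-8.
    layout
        ``"long"``: columns (patient_id, age, sex, dx_rank, icd10), one row
        per diagnosis; rows for one patient are merged into one record.
        ``"wide"``: columns (patient_id, age, sex, dx_primary,
        dx_sec_1..dx_sec_15), one row per patient, empty slots allowed.
    index_codes
        Codes defining the index disease; stored on the returned cohort
        (no filtering is applied here — see :func:`filter_index_cohort`).
    """
    if layout not in ("long", "wide"):
        raise RecordFormatError(f"unknown layout {layout!r}; expected 'long' or 'wide'")
    df = _read_delimited(path)
    if layout == "long":
        _require_columns(df, ["patient_id", "age", "sex", "dx_rank", "icd10"], path)
        df = _parse_demographics(df)
        dup = df.duplicated(subset=["patient_id", "dx_rank"], keep=False)
        if dup.any():
            offending = df.loc[dup, ["patient_id", "dx_rank"]].drop_duplicates()
            raise RecordFormatError(
                f"{path}: duplicate (patient_id, dx_rank) rows: "
                f"{offending.to_records(index=False).tolist()}"
            )
        records = []
        for pid, rows in df.groupby("patient_id", sort=False):
            rows = rows.copy()
            rows["_rank"] = rows["dx_rank"].astype(int)
            if len(rows) > MAX_DX_SLOTS:
                raise RecordFormatError(
                    f"{path}: patient {pid!r} has {len(rows)} diagnosis rows; "
                    f"at most {MAX_DX_SLOTS} slots (1 primary + 15 secondary) allowed"
                )
            rows = rows.sort_values("_rank", kind="stable")
            codes = [normalize_code(c) for c in rows["icd10"] if str(c).strip()]
            records.append(_merge_rows(str(pid), rows, codes))
    else:
        slot_cols = ["dx_primary"] + [f"dx_sec_{i}" for i in range(1, MAX_DX_SLOTS)]
        _require_columns(df, ["patient_id", "age", "sex", "dx_primary"], path)
        df = _parse_demographics(df)
        dup = df.duplicated(subset=["patient_id"], keep=False)
        if dup.any():
            raise RecordFormatError(
                f"{path}: duplicate patient_id rows in wide layout: "
                f"{sorted(df.loc[dup, 'patient_id'].unique())}"
            )
        records = []
        for _, row in df.iterrows():
            codes = []
            for col in slot_cols:
                if col in df.columns and str(row[col]).strip():
                    codes.append(normalize_code(row[col]))
            rec = _merge_rows(str(row["patient_id"]), row.to_frame().T, codes)
            records.append(rec)
    idx = frozenset(normalize_code(c) for c in index_codes)
    return Cohort(tuple(records), index_codes=idx)


def write_records(cohort: Cohort, path, layout: str = "long") -> None:
    """Write a cohort back to delimited text, inverse of :func:`read_records`."""
    buf = io.StringIO()
    if layout == "long":
        buf.write("patient_id,age,sex,dx_rank,icd10\n")
        for rec in cohort:
            for rank, code in enumerate(rec.diagnoses, start=1):
                buf.write(f"{rec.patient_id},{rec.age},{rec.sex},{rank},{code}\n")
    elif layout == "wide":
        cols = ["dx_primary"] + [f"dx_sec_{i}" for i in range(1, MAX_DX_SLOTS)]
        buf.write("patient_id,age,sex," + ",".join(cols) + "\n")
        for rec in cohort:
            slots = list(rec.diagnoses) + [""] * (MAX_DX_SLOTS - len(rec.diagnoses))
            buf.write(f"{rec.patient_id},{rec.age},{rec.sex}," + ",".join(slots) + "\n")
    else:
        raise RecordFormatError(f"unknown layout {layout!r}")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(buf.getvalue())


def filter_index_cohort(cohort: Cohort, index_codes=None) -> Cohort:
    """Retain exactly the records whose diagnoses intersect the index codes.

    An empty result is legal (downstream statistics return empty tables).
    """
    idx = cohort.index_codes if index_codes is None else frozenset(
        normalize_code(c) for c in index_codes
    )
    if not idx:
        raise RecordValueError("index_codes must be non-empty")
    kept = tuple(r for r in cohort.records if idx.intersection(r.diagnoses))
    return Cohort(kept, index_codes=idx, label=cohort.label)


def normalize_codes(cohort: Cohort, level: str = "full") -> Cohort:
    """Re-express every diagnosis code at the requested ICD-10 granularity.

    ``full`` is the identity; ``category3`` truncates to the 3-character
    category and re-de-duplicates (idempotent).
    """
    if level == "full":
        return cohort
    if level != "category3":
        raise ValueError(f"unknown code level {level!r}; expected 'full' or 'category3'")

    def trunc(codes):
        seen: dict[str, None] = {}
        for c in codes:
            seen.setdefault(c[:3], None)
        return tuple(seen)

    records = tuple(replace(r, diagnoses=trunc(r.diagnoses)) for r in cohort.records)
    idx = frozenset(c[:3] for c in cohort.index_codes)
    return Cohort(records, index_codes=idx, label=cohort.label)


def stratify(cohort: Cohort, by: str = "age_bin") -> dict[str, Cohort]:
    """Partition a cohort into disjoint sub-cohorts by sex, age bin, or both.

    Returns a label -> Cohort mapping; labels appear in canonical order
    (sexes male/female; age bins ascending).  Empty strata are omitted.
    Record order within each stratum follows the parent cohort.
    """
    if by == "sex":
        keys = list(SEXES)
        keyfun = lambda r: r.sex  # noqa: E731
    elif by == "age_bin":
        keys = list(AGE_BIN_LABELS)
        keyfun = lambda r: r.age_bin  # noqa: E731
    elif by == "sex_x_age_bin":
        keys = [f"{s}:{a}" for s in SEXES for a in AGE_BIN_LABELS]
        keyfun = lambda r: f"{r.sex}:{r.age_bin}"  # noqa: E731
    else:
        raise ValueError(f"unknown stratification {by!r}")
    buckets: dict[str, list[PatientRecord]] = {k: [] for k in keys}
    for rec in cohort:
        buckets[keyfun(rec)].append(rec)
    return {
        k: Cohort(tuple(v), index_codes=cohort.index_codes, label=k)
        for k, v in buckets.items()
        if v
    }


def demographics_table(cohort: Cohort) -> pd.DataFrame:
    """Counts and percentages by sex and age bin (discharge-summary style)."""
    rows = []
    n = cohort.n
    for by, keys in (("age", AGE_BIN_LABELS), ("sex", SEXES)):
        strata = stratify(cohort, "age_bin" if by == "age" else "sex")
        for k in keys:
            cnt = strata[k].n if k in strata else 0
            pct = round_half_up(100.0 * cnt / n, 2) if n else 0.0
            rows.append({"variable": by, "level": k, "count": cnt, "percent": pct})
    return pd.DataFrame(rows)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (table convention)."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
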