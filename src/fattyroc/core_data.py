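"""Domain types, derived-ratio computation, and CSV input/output.

Concentrations are *relative*: each measured fatty acid is expressed as a
percentage of total fatty acids in the erythrocyte sample, so the eleven
measured analytes of one subject sum to at most 100 (unmeasured species
make up the remainder).  Four derived measures — DHA/AA, EPA/AA, the
n-3/n-6 ratio and total PUFA — are computed from the measured panel.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: The 11 measured fatty acids, in canonical reporting order.
MEASURED_ANALYTES: tuple[str, ...] = (
    "AA",
    "DGLA",
    "DHA",
    "EPA",
    "elaidic",
    "LA",
    "oleic",
    "palmitelaidic",
    "palmitic",
    "palmitoleic",
    "stearic",
)

#: The 4 derived measures, appended after the measured panel.
DERIVED_ANALYTES: tuple[str, ...] = ("DHA/AA", "EPA/AA", "n-3/n-6", "total_PUFA")

#: All 15 analytes, in canonical reporting order.
ANALYTES: tuple[str, ...] = MEASURED_ANALYTES + DERIVED_ANALYTES

#: Human-readable names (used for CSV headers and report tables).
DISPLAY_NAMES: dict[str, str] = {
    "AA": "AA (20:4n-6)",
    "DGLA": "DGLA (20:3n-6)",
    "DHA": "DHA (22:6n-3)",
    "EPA": "EPA (20:5n-3)",
    "elaidic": "Elaidic acid (18:1n-9 trans)",
    "LA": "Linoleic acid (18:2n-6)",
    "oleic": "Oleic acid (18:1n-9)",
    "palmitelaidic": "Palmitelaidic acid (16:1n-9 trans)",
    "palmitic": "Palmitic acid (16:0)",
    "palmitoleic": "Palmitoleic acid (17:1n-7)",
    "stearic": "Stearic acid (18:0)",
    "DHA/AA": "DHA/AA",
    "EPA/AA": "EPA/AA",
    "n-3/n-6": "n-3/n-6",
    "total_PUFA": "Total PUFA",
}

#: PUFA composition of the derived measures.  Among the measured panel
#: the n-3 PUFAs are DHA and EPA; the n-6 PUFAs are AA, DGLA and LA.
#: The "total PUFA" reported alongside the ratios is the long-chain
#: total AA + DGLA + DHA + EPA: the dietary precursor LA enters the
#: n-6 denominator of the n-3/n-6 ratio but not the panel total (LA at
#: ~14% of total fatty acids would otherwise dominate the sum).
N3_ANALYTES: tuple[str, ...] = ("DHA", "EPA")
N6_ANALYTES: tuple[str, ...] = ("AA", "DGLA", "LA")
TOTAL_PUFA_ANALYTES: tuple[str, ...] = ("AA", "DGLA", "DHA", "EPA")

COHORTS = ("ASD", "NEU")
SUBTYPES = ("autism", "Aspergers", "PDD_NOS", "none")


@dataclass
class SubjectRecord:
    """One study participant: cohort label, metadata, and analyte panel.

    ``concentrations`` maps analyte name (see :data:`ANALYTES`) to value;
    the eleven measured analytes are in percent of total fatty acids, the
    four derived measures are dimensionless.  Missing values are ``NaN``.
    """

    subject_id: str
    cohort: str
    concentrations: dict[str, float] = field(default_factory=dict)
    diagnosis_subtype: str | None = None
    seafood_meals_per_month: float | None = None
    severity_scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValueError(f"cohort must be one of {COHORTS}, got {self.cohort!r}")
        if self.diagnosis_subtype is not None and self.diagnosis_subtype not in SUBTYPES:
            raise ValueError(
                f"diagnosis_subtype must be one of {SUBTYPES}, got {self.diagnosis_subtype!r}"
            )
        bad = set(self.concentrations) - set(ANALYTES)
        if bad:
            raise ValueError(f"unknown analyte name(s): {sorted(bad)}")
        for name in MEASURED_ANALYTES:
            v = self.concentrations.get(name, math.nan)
            if not math.isnan(v) and v < 0:
                raise ValueError(f"{name} concentration must be nonnegative, got {v}")

    def get(self, analyte: str) -> float:
        """Value for one analyte; NaN if absent."""
        return self.concentrations.get(analyte, math.nan)


@dataclass
class CohortTable:
    """Ordered collection of :class:`SubjectRecord` with unique ids."""

    records: list[SubjectRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate subject_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def cohort_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in COHORTS}
        for r in self.records:
            counts[r.cohort] += 1
        return counts

    def analyte_values(self, analyte: str, cohort: str | None = None) -> np.ndarray:
        """Finite values of one analyte, optionally restricted to a cohort.

        Missing values are dropped (pairwise-complete per analyte), so the
        effective n may differ between analytes.
        """
        vals = [
            r.get(analyte)
            for r in self.records
            if cohort is None or r.cohort == cohort
        ]
        arr = np.asarray(vals, dtype=float)
        return arr[np.isfinite(arr)]

    def subset(self, predicate) -> "CohortTable":
        return CohortTable(
            records=[r for r in self.records if predicate(r)],
            provenance=self.provenance,
        )

    def to_frame(self) -> pd.DataFrame:
        """Tabular view (one row per subject, analytes as columns)."""
        rows = []
        severity_keys = sorted({k for r in self.records for k in r.severity_scores})
        for r in self.records:
            row: dict[str, object] = {
                "subject_id": r.subject_id,
                "cohort": r.cohort,
                "diagnosis_subtype": r.diagnosis_subtype,
                "seafood_meals_per_month": (
                    math.nan
                    if r.seafood_meals_per_month is None
                    else r.seafood_meals_per_month
                ),
            }
            for a in ANALYTES:
                row[a] = r.get(a)
            for k in severity_keys:
                row[f"severity:{k}"] = r.severity_scores.get(k, math.nan)
            rows.append(row)
        base_cols = ["subject_id", "cohort", "diagnosis_subtype",
                     "seafood_meals_per_month", *ANALYTES]
        if not rows:
            return pd.DataFrame(columns=base_cols).astype(
                {c: float for c in base_cols[3:]} | {"seafood_meals_per_month": float}
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------


@dataclass
class CsvDialect:
    """Mapping from CSV column headers to record fields and analytes.

    The exact headers of an external individual-level file are not fixed,
    so the reader is driven by this mapping; the default is a best guess
    that the synthetic writer also uses, giving lossless round trips.
    """

    subject_id_col: str = "subject_id"
    cohort_col: str = "cohort"
    subtype_col: str = "diagnosis_subtype"
    seafood_col: str = "seafood_meals_per_month"
    severity_prefix: str = "severity:"
    #: header -> canonical analyte name
    analyte_cols: dict[str, str] = field(
        default_factory=lambda: {a: a for a in ANALYTES}
    )
    #: raw cohort label -> {"ASD", "NEU"}
    cohort_labels: dict[str, str] = field(
        default_factory=lambda: {"ASD": "ASD", "NEU": "NEU"}
    )

    @classmethod
    def from_file(cls, path) -> "CsvDialect":
        """Read a flat ``key = value`` mapping file.

        Keys ``subject_id``, ``cohort``, ``subtype``, ``seafood`` rename
        the metadata columns; ``analyte.<name> = <header>`` maps a CSV
        header onto canonical analyte ``<name>``; ``cohort_label.<raw> =
        ASD|NEU`` maps raw cohort labels.
        """
        d = cls(analyte_cols={}, cohort_labels={})
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key == "subject_id":
                    d.subject_id_col = value
                elif key == "cohort":
                    d.cohort_col = value
                elif key == "subtype":
                    d.subtype_col = value
                elif key == "seafood":
                    d.seafood_col = value
                elif key.startswith("analyte."):
                    name = key.split(".", 1)[1]
                    if name not in ANALYTES:
                        raise ValueError(f"unknown analyte in dialect: {name!r}")
                    d.analyte_cols[value] = name
                elif key.startswith("cohort_label."):
                    d.cohort_labels[key.split(".", 1)[1]] = value
                else:
                    raise ValueError(f"unknown dialect key: {key!r}")
        if not d.analyte_cols:
            d.analyte_cols = {a: a for a in ANALYTES}
        if not d.cohort_labels:
            d.cohort_labels = {"ASD": "ASD", "NEU": "NEU"}
        return d


def _parse_cell(value) -> float:
    """Numeric cell -> float; blank or unparseable -> NaN (never zero)."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return math.nan
    s = str(value).strip()
    if not s:
        return math.nan
    try:
        return float(s)
    except ValueError:
        return math.nan


def read_cohort_csv(path, dialect: CsvDialect | None = None) -> CohortTable:
    """Read an individual-level CSV into a :class:`CohortTable`.

    Unparseable numeric cells become missing values (NaN), never silent
    zeros.  Unknown analyte-like columns are ignored with a warning; a
    missing cohort column or duplicated subject ids are hard errors.
    """
    dialect = dialect or CsvDialect()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if dialect.cohort_col not in df.columns:
        raise ValueError(
            f"cohort column {dialect.cohort_col!r} not found in {path}"
        )
    known = (
        {dialect.subject_id_col, dialect.cohort_col, dialect.subtype_col, dialect.seafood_col}
        | set(dialect.analyte_cols)
    )
    unknown = [
        c
        for c in df.columns
        if c not in known and not c.startswith(dialect.severity_prefix)
    ]
    if unknown:
        warnings.warn(f"ignoring unrecognized column(s): {unknown}", stacklevel=2)

    records = []
    for i, row in df.iterrows():
        raw_cohort = row[dialect.cohort_col].strip()
        if raw_cohort not in dialect.cohort_labels:
            raise ValueError(
                f"row {i}: cohort label {raw_cohort!r} not in dialect mapping"
            )
        conc = {
            analyte: _parse_cell(row[header])
            for header, analyte in dialect.analyte_cols.items()
            if header in df.columns
        }
        subtype = None
        if dialect.subtype_col in df.columns:
            s = row[dialect.subtype_col].strip()
            subtype = s if s else None
        seafood = None
        if dialect.seafood_col in df.columns:
            v = _parse_cell(row[dialect.seafood_col])
            seafood = None if math.isnan(v) else v
        severity = {}
        for c in df.columns:
            if c.startswith(dialect.severity_prefix):
                v = _parse_cell(row[c])
                if not math.isnan(v):
                    severity[c[len(dialect.severity_prefix):]] = v
        sid = (
            str(row[dialect.subject_id_col]).strip()
            if dialect.subject_id_col in df.columns
            else f"row{i}"
        )
        records.append(
            SubjectRecord(
                subject_id=sid,
                cohort=dialect.cohort_labels[raw_cohort],
                concentrations=conc,
                diagnosis_subtype=subtype,
                seafood_meals_per_month=seafood,
                severity_scores=severity,
            )
        )
    table = CohortTable(records=records, provenance=str(path))
    counts = table.cohort_counts()
    log.info("read %d records (%s)", len(table), counts)
    return table


def write_cohort_csv(table: CohortTable, path) -> None:
    """Write a table in the default dialect; re-reading restores all
    numeric fields to 1e-12 and reproduces the missingness pattern."""
    df = table.to_frame()
    if len(df):
        # drop all-empty optional columns so absent metadata stays absent
        for col in ("diagnosis_subtype", "seafood_meals_per_month"):
            if df[col].isna().all():
                df = df.drop(columns=[col])
        df = df.dropna(axis=1, how="all")
    float_cols = df.select_dtypes(include=[float]).columns
    df[float_cols] = df[float_cols].map(lambda v: f"{v:.17g}" if np.isfinite(v) else "")
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Derived measures
# ---------------------------------------------------------------------------


def compute_derived(record: SubjectRecord) -> SubjectRecord:
    """Fill the four derived measures from the measured panel.

    DHA/AA and EPA/AA are direct quotients; n-3/n-6 divides the n-3 sum
    (DHA+EPA) by the n-6 sum (AA+DGLA+LA); total PUFA is the long-chain
    sum AA+DGLA+DHA+EPA (see :data:`TOTAL_PUFA_ANALYTES`).  A zero
    denominator yields a missing ratio with a warning.  Idempotent:
    derived values are recomputed from the measured panel.
    """
    c = record.concentrations
    missing = [a for a in MEASURED_ANALYTES if math.isnan(c.get(a, math.nan))]
    aa, dha, epa = c.get("AA", math.nan), c.get("DHA", math.nan), c.get("EPA", math.nan)
    n3 = sum(c.get(a, math.nan) for a in N3_ANALYTES)
    n6 = sum(c.get(a, math.nan) for a in N6_ANALYTES)
    new = dict(c)
    if aa == 0:
        warnings.warn(
            f"{record.subject_id}: AA is zero; DHA/AA and EPA/AA set missing",
            stacklevel=2,
        )
        new["DHA/AA"] = math.nan
        new["EPA/AA"] = math.nan
    else:
        new["DHA/AA"] = dha / aa
        new["EPA/AA"] = epa / aa
    if n6 == 0:
        warnings.warn(
            f"{record.subject_id}: n-6 sum is zero; n-3/n-6 set missing",
            stacklevel=2,
        )
        new["n-3/n-6"] = math.nan
    else:
        new["n-3/n-6"] = n3 / n6
    new["total_PUFA"] = sum(c.get(a, math.nan) for a in TOTAL_PUFA_ANALYTES)
    if missing:
        log.debug("%s: measured analytes missing %s", record.subject_id, missing)
    return replace(record, concentrations=new)


def compute_derived_table(table: CohortTable) -> CohortTable:
    """Apply :func:`compute_derived` to every record."""
    return CohortTable(
        records=[compute_derived(r) for r in table.records],
        provenance=table.provenance,
    )


def exclude_subtypes(table: CohortTable, subtypes) -> CohortTable:
    """Drop ASD records whose diagnosis subtype is in ``subtypes``.

    Control (NEU) records are never removed.  Raises if the requested
    exclusion cannot be applied because subtype metadata is absent from
    every ASD record.
    """
    subtypes = set(subtypes)
    if not subtypes:
        return CohortTable(records=list(table.records), provenance=table.provenance)
    bad = subtypes - set(SUBTYPES)
    if bad:
        raise ValueError(f"unknown subtype(s): {sorted(bad)}")
    asd = [r for r in table.records if r.cohort == "ASD"]
    if asd and all(r.diagnosis_subtype is None for r in asd):
        raise ValueError(
            "cannot exclude subtypes: no ASD record carries the "
            "'diagnosis_subtype' column"
        )
    kept = [
        r
        for r in table.records
        if r.cohort != "ASD" or r.diagnosis_subtype not in subtypes
    ]
    removed = len(table.records) - len(kept)
    log.info("exclude_subtypes: removed %d ASD record(s)", removed)
    return CohortTable(records=kept, provenance=table.provenance)
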