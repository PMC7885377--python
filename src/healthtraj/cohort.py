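"""Patient cohort handling: reading, validation, binarisation, stratification.

The analysis operates on a register-style table with one row per patient
(sex, age, BMI, smoking status, UCLA activity category, sports-activity
level, long-distance-walking ability) and a binary early-reoperation
outcome.  This module turns such a table into validated records, maps each
record to its binary positive-factor set (the object row of the formal
context) and produces register-style summary tables stratified by sex and
age.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import HealthTrajError, percent

logger = logging.getLogger(__name__)

# The positive-factor universe.  Factor names follow the convention used in
# lattice visualisations of this method: protective = present.
FACTORS: tuple[str, ...] = ("NoSmoking", "lowBMI", "Activity", "Sport", "LongDistWalk")

SEXES = ("female", "male")
SMOKING_LEVELS = ("never", "ex", "current")
SPORT_LEVELS = ("none", "recreational", "competitive", "professional", "NA")
WALK_LEVELS = ("yes", "no", "NA")

#: Age cut-offs splitting each sex into a younger (<= cutoff) and an older
#: (> cutoff) stratum; register medians of the reoperated patients.
DEFAULT_AGE_CUTOFFS: dict[str, int] = {"female": 71, "male": 66}

STRATUM_LABELS = ("younger_female", "older_female", "younger_male", "older_male")

REQUIRED_COLUMNS = (
    "patient_id",
    "sex",
    "age",
    "bmi",
    "smoking",
    "ucla",
    "sport",
    "long_walk",
    "reoperated",
)

#: Accepted header synonyms (lower-cased); extendable via ``read_cohort``.
DEFAULT_SYNONYMS: dict[str, str] = {
    "id": "patient_id",
    "patient": "patient_id",
    "gender": "sex",
    "age_years": "age",
    "ucla_activity": "ucla",
    "sport_activity": "sport",
    "sports": "sport",
    "long_distance_walk": "long_walk",
    "longdistwalk": "long_walk",
    "walk": "long_walk",
    "reoperation": "reoperated",
}


class SchemaError(HealthTrajError):
    """The input table is missing a required column."""


class RecordError(HealthTrajError):
    """A cell could not be parsed or violates a record invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BinarisationRules:
    """Pure configuration mapping raw fields to binary positive factors.

    Parameters
    ----------
    bmi_cutoff:
        Obesity threshold in kg/m²; ``lowBMI`` is credited iff bmi < cutoff.
    ucla_active_min:
        Minimal UCLA category counted as physically active (default 5, i.e.
        inactive = categories 1–4, active = categories 5–10).
    na_policy:
        Handling of ``NA`` sport / long-walk values: ``factor_absent`` keeps
        the record and does not credit the factor (conservative);
        ``drop_record`` excludes the record from binarised output.
    """

    bmi_cutoff: float = 30.0
    ucla_active_min: int = 5
    na_policy: str = "factor_absent"

    def __post_init__(self) -> None:
        if self.na_policy not in ("factor_absent", "drop_record"):
            raise ValueError(f"unknown na_policy: {self.na_policy!r}")
        if not 1 <= self.ucla_active_min <= 10:
            raise ValueError("ucla_active_min must be in [1, 10]")
        if self.bmi_cutoff <= 0:
            raise ValueError("bmi_cutoff must be positive")


@dataclass(frozen=True)
class PatientRecord:
    """One validated register row."""

    patient_id: str
    sex: str
    age: int
    bmi: float
    smoking: str
    ucla: int
    sport: str
    long_walk: str
    reoperated: bool

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise RecordError(f"unknown sex {self.sex!r} for {self.patient_id}")
        if self.age < 18:
            raise RecordError(f"age must be >= 18 (got {self.age}) for {self.patient_id}")
        if not self.bmi > 0:
            raise RecordError(f"bmi must be positive (got {self.bmi}) for {self.patient_id}")
        if self.smoking not in SMOKING_LEVELS:
            raise RecordError(f"unknown smoking level {self.smoking!r} for {self.patient_id}")
        if not 1 <= self.ucla <= 10:
            raise RecordError(f"ucla must be in [1, 10] (got {self.ucla}) for {self.patient_id}")
        if self.sport not in SPORT_LEVELS:
            raise RecordError(f"unknown sport level {self.sport!r} for {self.patient_id}")
        if self.long_walk not in WALK_LEVELS:
            raise RecordError(f"unknown long_walk value {self.long_walk!r} for {self.patient_id}")


@dataclass(frozen=True)
class FactorVector:
    """A patient's binary positive-factor set plus outcome label.

    Factor names must belong to the attribute universe of the context the
    vector enters; ``build_context`` enforces this.
    """

    patient_id: str
    factors: frozenset[str]
    reoperated: bool


@dataclass(frozen=True)
class Stratum:
    """A sex × age cohort stratum; boundary ages belong to 'younger'."""

    label: str
    sex: str
    age_cutoff: int


@dataclass
class LoadReport:
    """Counts emitted when reading a cohort file."""

    n_read: int = 0
    n_rejected_missing_outcome: int = 0
    rejected_rows: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

_NA_STRINGS = {"", "na", "n/a", "nan", "none", "null"}

_YES = {"yes", "y", "1", "true"}
_NO = {"no", "n", "0", "false"}

_SMOKING_ALIASES = {
    "never": "never",
    "no": "never",
    "non-smoker": "never",
    "nonsmoker": "never",
    "ex": "ex",
    "stop": "ex",
    "former": "ex",
    "ex-smoker": "ex",
    "current": "current",
    "yes": "current",
    "smoker": "current",
}


def _parse_bool(value: str, column: str, row: int) -> bool:
    v = value.strip().lower()
    if v in _YES:
        return True
    if v in _NO:
        return False
    raise RecordError(f"row {row}: cannot parse {column}={value!r} as yes/no")


def _parse_row(row: Mapping[str, str], row_number: int) -> PatientRecord:
    def cell(column: str) -> str:
        return (row.get(column) or "").strip()

    def numeric(column: str, caster, kind: str):
        raw = cell(column)
        if raw.lower() in _NA_STRINGS:
            raise RecordError(f"row {row_number}: missing {column}")
        try:
            return caster(raw)
        except ValueError as exc:
            raise RecordError(
                f"row {row_number}: cannot parse {column}={raw!r} as {kind}"
            ) from exc

    sex = cell("sex").lower()
    if sex in ("f", "woman"):
        sex = "female"
    elif sex in ("m", "man"):
        sex = "male"

    smoking_raw = cell("smoking").lower()
    smoking = _SMOKING_ALIASES.get(smoking_raw)
    if smoking is None:
        raise RecordError(f"row {row_number}: cannot parse smoking={cell('smoking')!r}")

    sport = cell("sport").lower()
    sport = "NA" if sport in _NA_STRINGS else sport
    walk = cell("long_walk").lower()
    if walk in _NA_STRINGS:
        walk = "NA"
    elif walk in _YES:
        walk = "yes"
    elif walk in _NO:
        walk = "no"

    try:
        return PatientRecord(
            patient_id=cell("patient_id") or f"row{row_number}",
            sex=sex,
            age=numeric("age", lambda s: int(float(s)), "integer"),
            bmi=numeric("bmi", float, "number"),
            smoking=smoking,
            ucla=numeric("ucla", lambda s: int(float(s)), "integer"),
            sport=sport,
            long_walk=walk,
            reoperated=_parse_bool(cell("reoperated"), "reoperated", row_number),
        )
    except RecordError:
        raise
    except ValueError as exc:  # invariant violations surfaced by the dataclass
        raise RecordError(f"row {row_number}: {exc}") from exc


def load_cohort(
    path: str | Path,
    synonyms: Mapping[str, str] | None = None,
) -> tuple[list[PatientRecord], LoadReport]:
    """Read a cohort CSV/TSV and return validated records plus a load report.

    Header matching is case-insensitive and accepts the documented synonyms.
    Rows with a missing outcome are rejected (and counted); any other
    unparseable cell raises :class:`RecordError` naming the row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","

    name_map = dict(DEFAULT_SYNONYMS)
    if synonyms:
        name_map.update({k.lower(): v for k, v in synonyms.items()})

    records: list[PatientRecord] = []
    report = LoadReport()
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file") from None
        canonical = [name_map.get(h.strip().lower(), h.strip().lower()) for h in header]
        missing = [c for c in REQUIRED_COLUMNS if c not in canonical]
        if missing:
            raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
        for row_number, raw in enumerate(reader, start=2):
            if not any(v.strip() for v in raw):
                continue
            row = dict(zip(canonical, raw))
            if (row.get("reoperated") or "").strip().lower() in _NA_STRINGS:
                report.n_rejected_missing_outcome += 1
                report.rejected_rows.append(row_number)
                continue
            records.append(_parse_row(row, row_number))
            report.n_read += 1
    logger.info(
        "loaded %s: %d records read, %d rejected (missing outcome)",
        path,
        report.n_read,
        report.n_rejected_missing_outcome,
    )
    return records, report


def read_cohort(path: str | Path, synonyms: Mapping[str, str] | None = None) -> list[PatientRecord]:
    """Read a cohort file, returning the validated records (see ``load_cohort``)."""
    return load_cohort(path, synonyms=synonyms)[0]


def write_cohort_csv(records: Iterable[PatientRecord], path: str | Path) -> None:
    """Write records in the standard cohort CSV schema."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(REQUIRED_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.patient_id,
                    r.sex,
                    r.age,
                    f"{r.bmi:g}",
                    r.smoking,
                    r.ucla,
                    r.sport,
                    r.long_walk,
                    "yes" if r.reoperated else "no",
                ]
            )


# ---------------------------------------------------------------------------
# Binarisation and stratification
# ---------------------------------------------------------------------------


def binarize_record(record: PatientRecord, rules: BinarisationRules | None = None) -> FactorVector | None:
    """Map one record to its positive-factor set.

    Returns ``None`` when ``rules.na_policy == "drop_record"`` and the record
    has an NA sport or long-walk value.
    """
    rules = rules or BinarisationRules()
    has_na = record.sport == "NA" or record.long_walk == "NA"
    if has_na and rules.na_policy == "drop_record":
        return None
    factors = set()
    if record.smoking in ("never", "ex"):
        factors.add("NoSmoking")
    if record.bmi < rules.bmi_cutoff:
        factors.add("lowBMI")
    if record.ucla >= rules.ucla_active_min:
        factors.add("Activity")
    if record.sport in ("recreational", "competitive", "professional"):
        factors.add("Sport")
    if record.long_walk == "yes":
        factors.add("LongDistWalk")
    return FactorVector(record.patient_id, frozenset(factors), record.reoperated)


def binarize_cohort(
    records: Iterable[PatientRecord], rules: BinarisationRules | None = None
) -> list[FactorVector]:
    """Binarise a cohort, applying the NA policy."""
    rules = rules or BinarisationRules()
    out = []
    for record in records:
        vector = binarize_record(record, rules)
        if vector is not None:
            out.append(vector)
    return out


def stratify(
    record: PatientRecord, age_cutoffs: Mapping[str, int] | None = None
) -> Stratum:
    """Assign a record to its sex × age stratum (boundary age -> younger)."""
    cutoffs = age_cutoffs or DEFAULT_AGE_CUTOFFS
    if record.sex not in cutoffs:
        raise RecordError(f"no age cutoff configured for sex {record.sex!r}")
    cutoff = cutoffs[record.sex]
    side = "younger" if record.age <= cutoff else "older"
    return Stratum(label=f"{side}_{record.sex}", sex=record.sex, age_cutoff=cutoff)


def split_by_stratum(
    records: Sequence[PatientRecord], age_cutoffs: Mapping[str, int] | None = None
) -> dict[str, list[PatientRecord]]:
    """Partition a cohort into the four strata (empty strata included)."""
    groups: dict[str, list[PatientRecord]] = {label: [] for label in STRATUM_LABELS}
    for record in records:
        groups[stratify(record, age_cutoffs).label].append(record)
    return groups


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def _category_blocks(rules: BinarisationRules) -> list[tuple[str, list[str], callable]]:
    cutoff = rules.bmi_cutoff
    active = rules.ucla_active_min

    def bmi_band(r: PatientRecord) -> str:
        if r.bmi < cutoff:
            return f"<{cutoff:g}"
        if r.bmi <= 35:
            return f"{cutoff:g}-35"
        return ">35"

    return [
        ("bmi", [f"<{cutoff:g}", f"{cutoff:g}-35", ">35"], bmi_band),
        ("smoking", list(SMOKING_LEVELS), lambda r: r.smoking),
        (
            "ucla",
            [f"inactive (<{active})", f"active (>={active})"],
            lambda r: f"inactive (<{active})" if r.ucla < active else f"active (>={active})",
        ),
        (
            "sport",
            ["none", "active", "NA"],
            lambda r: "NA" if r.sport == "NA" else ("none" if r.sport == "none" else "active"),
        ),
        ("long_walk", ["yes", "no", "NA"], lambda r: r.long_walk),
        ("reoperated", ["no", "yes"], lambda r: "yes" if r.reoperated else "no"),
    ]


def summarize_cohort(
    records: Sequence[PatientRecord],
    rules: BinarisationRules | None = None,
    age_cutoffs: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Register-style summary: per-stratum N, category counts and percentages.

    Percentages are rounded half-away-from-zero to one decimal and, within a
    category block of one stratum, sum to 100 up to rounding.  Empty strata
    get N = 0 and no percentages.
    """
    if not records:
        raise ValueError("cannot summarise an empty cohort")
    rules = rules or BinarisationRules()
    groups = split_by_stratum(records, age_cutoffs)
    blocks = _category_blocks(rules)

    index = [("cohort", "N")] + [
        (block, category) for block, categories, _ in blocks for category in categories
    ]
    columns = pd.MultiIndex.from_product([STRATUM_LABELS, ["n", "pct"]])
    table = pd.DataFrame(index=pd.MultiIndex.from_tuples(index), columns=columns, dtype=float)

    for label in STRATUM_LABELS:
        members = groups[label]
        n_total = len(members)
        table.loc[("cohort", "N"), (label, "n")] = n_total
        for block, categories, key in blocks:
            counts = {c: 0 for c in categories}
            for record in members:
                counts[key(record)] += 1
            for category in categories:
                table.loc[(block, category), (label, "n")] = counts[category]
                if n_total > 0:
                    table.loc[(block, category), (label, "pct")] = percent(
                        counts[category], n_total
                    )
    return table


def reoperation_rates(
    records: Sequence[PatientRecord], age_cutoffs: Mapping[str, int] | None = None
) -> dict[str, float]:
    """Per-stratum reoperation rate in percent, one decimal."""
    rates = {}
    for label, members in split_by_stratum(records, age_cutoffs).items():
        if members:
            k = sum(r.reoperated for r in members)
            rates[label] = percent(k, len(members))
    return rates


# ---------------------------------------------------------------------------
# Binarised-cohort serialisation (round-trippable)
# ---------------------------------------------------------------------------


def write_factor_vectors_csv(vectors: Iterable[FactorVector], path: str | Path) -> None:
    """Write binarised cohort: one 0/1 column per factor plus the outcome."""
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["patient_id", *FACTORS, "reoperated"])
        for v in vectors:
            writer.writerow(
                [v.patient_id]
                + [int(f in v.factors) for f in FACTORS]
                + ["yes" if v.reoperated else "no"]
            )


def read_factor_vectors_csv(path: str | Path) -> list[FactorVector]:
    """Read a binarised cohort written by :func:`write_factor_vectors_csv`."""
    vectors = []
    with Path(path).open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        for row in reader:
            factors = frozenset(f for f in FACTORS if row[f].strip() == "1")
            vectors.append(
                FactorVector(row["patient_id"], factors, row["reoperated"].strip() == "yes")
            )
    return vectors
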