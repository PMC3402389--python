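"""Data model, file I/O and validation for per-study genotype count records.

A *study record* is one case-control study of a biallelic SNP (here written
with alleles G and T): genotype counts (GG, GT, TT) for the case arm and the
control arm, plus the metadata typically extracted for a meta-analysis
(first author, year, ethnicity, control source, genotyping method and any
further categorical strata).

The on-disk format is delimited text (CSV by default, TSV accepted) with a
fixed header vocabulary::

    study_id, first_author, year, ethnicity, control_source, method,
    case_gg, case_gt, case_tt, ctrl_gg, ctrl_gt, ctrl_tt

Any additional columns are carried along as categorical strata. Case and
control totals are always derived from the genotype triples, never from a
separate totals column, because the triples are what every downstream
contrast uses.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

__all__ = [
    "GenotypeCounts",
    "StudyRecord",
    "Dataset",
    "Finding",
    "DataError",
    "SchemaError",
    "ValidationError",
    "read_studies",
    "write_studies",
    "validate_dataset",
    "load_mdm2_studies",
    "REQUIRED_COLUMNS",
    "KNOWN_ETHNICITIES",
    "KNOWN_CONTROL_SOURCES",
]

REQUIRED_COLUMNS = (
    "study_id",
    "first_author",
    "year",
    "ethnicity",
    "control_source",
    "method",
    "case_gg",
    "case_gt",
    "case_tt",
    "ctrl_gg",
    "ctrl_gt",
    "ctrl_tt",
)

COUNT_COLUMNS = REQUIRED_COLUMNS[6:]

#: Vocabulary used for validation; unknown labels are flagged, not rejected.
KNOWN_ETHNICITIES = frozenset({"Asian", "Caucasian", "African"})
KNOWN_CONTROL_SOURCES = frozenset({"HB", "PB"})


class DataError(Exception):
    """Base class for study-data I/O and validation failures."""


class SchemaError(DataError):
    """The input file does not carry the required column schema."""


class ValidationError(DataError):
    """The parsed records violate a dataset-level invariant."""


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts (GG, GT, TT) for one arm of one study."""

    gg: int
    gt: int
    tt: int

    def __post_init__(self) -> None:
        for name in ("gg", "gt", "tt"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise TypeError(f"genotype count {name!r} must be an integer, got {v!r}")
            if v < 0:
                raise ValueError(f"genotype count {name!r} must be non-negative, got {v}")

    @property
    def total(self) -> int:
        return self.gg + self.gt + self.tt

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.gg, self.gt, self.tt)


@dataclass(frozen=True)
class StudyRecord:
    """One study: metadata plus case and control genotype count triples."""

    study_id: str
    first_author: str
    year: int
    ethnicity: str
    control_source: str
    method: str
    cases: GenotypeCounts
    controls: GenotypeCounts
    extra_strata: Mapping[str, str] = field(default_factory=dict)

    def stratum(self, column: str) -> str:
        """Look up a categorical annotation by column name.

        Core metadata columns (ethnicity, control_source, ...) and extra
        strata columns are addressed uniformly.
        """
        if column in ("ethnicity", "control_source", "first_author", "method"):
            return getattr(self, column)
        if column == "year":
            return str(self.year)
        try:
            return self.extra_strata[column]
        except KeyError:
            raise KeyError(
                f"unknown stratum column {column!r}; available: "
                f"{sorted(self.available_strata())}"
            ) from None

    def available_strata(self) -> set[str]:
        return {"ethnicity", "control_source", "first_author", "method", "year"} | set(
            self.extra_strata
        )


@dataclass(frozen=True)
class Dataset:
    """An ordered collection of study records with free-text provenance."""

    records: tuple[StudyRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[StudyRecord]:
        return iter(self.records)

    def __getitem__(self, key: int) -> StudyRecord:
        return self.records[key]

    @property
    def total_cases(self) -> int:
        return sum(r.cases.total for r in self.records)

    @property
    def total_controls(self) -> int:
        return sum(r.controls.total for r in self.records)

    def subset(self, study_ids: Iterable[str]) -> "Dataset":
        wanted = set(study_ids)
        return Dataset(
            tuple(r for r in self.records if r.study_id in wanted),
            provenance=self.provenance,
        )

    def drop(self, study_id: str) -> "Dataset":
        return Dataset(
            tuple(r for r in self.records if r.study_id != study_id),
            provenance=self.provenance,
        )

    def partition(self, column: str) -> dict[str, "Dataset"]:
        """Split records by the levels of a categorical column (order-stable)."""
        levels: dict[str, list[StudyRecord]] = {}
        for r in self.records:
            levels.setdefault(r.stratum(column), []).append(r)
        return {
            lvl: Dataset(tuple(recs), provenance=self.provenance)
            for lvl, recs in levels.items()
        }

    def to_dataframe(self) -> pd.DataFrame:
        extra_cols: list[str] = []
        for r in self.records:
            for c in r.extra_strata:
                if c not in extra_cols:
                    extra_cols.append(c)
        rows = []
        for r in self.records:
            row = {
                "study_id": r.study_id,
                "first_author": r.first_author,
                "year": r.year,
                "ethnicity": r.ethnicity,
                "control_source": r.control_source,
                "method": r.method,
                "case_gg": r.cases.gg,
                "case_gt": r.cases.gt,
                "case_tt": r.cases.tt,
                "ctrl_gg": r.controls.gg,
                "ctrl_gt": r.controls.gt,
                "ctrl_tt": r.controls.tt,
            }
            for c in extra_cols:
                row[c] = r.extra_strata.get(c, "")
            rows.append(row)
        return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS) + extra_cols)


@dataclass(frozen=True)
class Finding:
    """One validation finding (problem description, not an exception)."""

    severity: str  # "error" | "warning"
    study_id: str | None
    message: str


def _sniff_delimiter(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        return {"csv": ",", "tsv": "\t", ",": ",", "\t": "\t"}.get(dialect, dialect)
    head = path.read_text().splitlines()
    first = head[0] if head else ""
    return "\t" if first.count("\t") > first.count(",") else ","


def read_studies(path: str | Path, dialect: str | None = None) -> Dataset:
    """Read a delimited study table into a :class:`Dataset`.

    Parameters
    ----------
    path
        CSV or TSV file with the required header (see module docstring).
    dialect
        ``"csv"``, ``"tsv"``, an explicit delimiter character, or ``None``
        to sniff from the header line.

    Raises
    ------
    SchemaError
        A required column is missing from the header.
    ValidationError
        Non-integer or negative counts (reported with row numbers),
        duplicate study ids, or a file with no data rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sniff_delimiter(path, dialect)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise ValidationError("no records: file contains a header but no data rows")

    extra_cols = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    records: list[StudyRecord] = []
    problems: list[str] = []
    for i, row in df.iterrows():
        rowno = int(i) + 2  # 1-based, counting the header line
        counts: dict[str, int] = {}
        bad = False
        for col in COUNT_COLUMNS:
            raw = str(row[col]).strip()
            try:
                v = int(raw)
            except ValueError:
                problems.append(f"row {rowno}: non-integer count {col}={raw!r}")
                bad = True
                continue
            if v < 0:
                problems.append(f"row {rowno}: negative count {col}={v}")
                bad = True
                continue
            counts[col] = v
        try:
            year = int(str(row["year"]).strip())
        except ValueError:
            problems.append(f"row {rowno}: non-integer year {row['year']!r}")
            bad = True
        if bad:
            continue
        records.append(
            StudyRecord(
                study_id=str(row["study_id"]).strip(),
                first_author=str(row["first_author"]).strip(),
                year=year,
                ethnicity=str(row["ethnicity"]).strip(),
                control_source=str(row["control_source"]).strip(),
                method=str(row["method"]).strip(),
                cases=GenotypeCounts(counts["case_gg"], counts["case_gt"], counts["case_tt"]),
                controls=GenotypeCounts(counts["ctrl_gg"], counts["ctrl_gt"], counts["ctrl_tt"]),
                extra_strata={c: str(row[c]).strip() for c in extra_cols},
            )
        )
    if problems:
        raise ValidationError("; ".join(problems))

    ids = [r.study_id for r in records]
    dupes = sorted({s for s in ids if ids.count(s) > 1})
    if dupes:
        raise ValidationError(f"duplicate study_id(s): {', '.join(dupes)}")

    return Dataset(tuple(records), provenance=str(path))


def write_studies(ds: Dataset, path: str | Path, dialect: str = "csv") -> None:
    """Write a dataset back to delimited text (inverse of :func:`read_studies`)."""
    sep = {"csv": ",", "tsv": "\t"}.get(dialect, dialect)
    ds.to_dataframe().to_csv(path, sep=sep, index=False)


def validate_dataset(ds: Dataset) -> list[Finding]:
    """Check dataset-level invariants; returns findings rather than raising.

    A clean dataset yields an empty list. Checks: positive arm totals,
    duplicate ids, and metadata labels outside the declared vocabulary
    (flagged as warnings — unknown levels form their own subgroup rather
    than being dropped).
    """
    findings: list[Finding] = []
    seen: set[str] = set()
    for r in ds.records:
        if r.study_id in seen:
            findings.append(Finding("error", r.study_id, "duplicate id"))
        seen.add(r.study_id)
        if r.cases.total == 0:
            findings.append(Finding("error", r.study_id, "empty case arm"))
        if r.controls.total == 0:
            findings.append(Finding("error", r.study_id, "empty control arm"))
        if r.ethnicity not in KNOWN_ETHNICITIES:
            findings.append(
                Finding("warning", r.study_id, f"unknown ethnicity label {r.ethnicity!r}")
            )
        if r.control_source not in KNOWN_CONTROL_SOURCES:
            findings.append(
                Finding(
                    "warning", r.study_id, f"unknown control_source label {r.control_source!r}"
                )
            )
    if len(ds) == 0:
        findings.append(Finding("error", None, "dataset has no records"))
    return findings


def load_mdm2_studies() -> Dataset:
    """Load the packaged 11-study MDM2 SNP309 (rs2279744) lung-cancer dataset.

    The fixture is a transcription of the published genotype distributions:
    eleven case-control studies, 7196 cases and 8456 controls in total, with
    the multi-ethnic study split into its African and Caucasian strata. It
    is the worked example used throughout the documentation and tests.
    """
    ref = resources.files("genemeta").joinpath("data/mdm2_t309g_studies.csv")
    with resources.as_file(ref) as p:
        ds = read_studies(p)
    return Dataset(ds.records, provenance="packaged MDM2 T309G lung-cancer study table")
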