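"""Study data model and table I/O.

The unit of input is a case-control study summarised by genotype counts at
one biallelic SNP: CC / CT / TT in cases and in controls, where C is the
reference allele and T the risk (effect) allele.  Studies carry two
categorical moderators — ethnicity and source of controls (hospital-based
vs population-based) — plus optional Newcastle-Ottawa quality stars, which
are metadata only and never enter any computation.

Tables are plain CSV (or TSV) with a fixed header; a curated 13-study
prostate-cancer dataset for the MSMB promoter variant rs10993994 ships with
the package and is returned by :func:`load_fixture`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .errors import SchemaError, ValidationError

__all__ = [
    "GenotypeCounts",
    "Ethnicity",
    "SourceOfControls",
    "Study",
    "StudySet",
    "read_studies",
    "write_studies",
    "totals",
    "load_fixture",
    "REQUIRED_COLUMNS",
]

REQUIRED_COLUMNS = (
    "study_id",
    "year",
    "ethnicity",
    "soc",
    "case_cc",
    "case_ct",
    "case_tt",
    "control_cc",
    "control_ct",
    "control_tt",
)

_FIXTURE_NAME = "msmb_rs10993994.csv"


class Ethnicity(Enum):
    """Closed ethnicity vocabulary, in canonical reporting order."""

    CAUCASIAN = "Caucasian"
    ASIAN = "Asian"
    AFRICAN_AMERICAN = "African-American"
    MIXED = "Mixed"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class SourceOfControls(Enum):
    """Control recruitment: hospital-based or population-based."""

    HB = "HB"
    PB = "PB"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def _parse_ethnicity(label: str) -> Ethnicity:
    # unify unicode dash variants ("African–American" etc.)
    norm = label.strip()
    for dash in ("‐", "‑", "‒", "–", "—"):
        norm = norm.replace(dash, "-")
    for member in Ethnicity:
        if member.value.lower() == norm.lower():
            return member
    raise ValidationError(f"unknown ethnicity label {label!r}")


def _parse_soc(label: str) -> SourceOfControls:
    norm = label.strip().upper()
    try:
        return SourceOfControls[norm]
    except KeyError:
        raise ValidationError(f"unknown source-of-controls label {label!r}") from None


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts for one group (cases or controls) of one study.

    ``cc``, ``ct``, ``tt`` are counts of reference homozygotes,
    heterozygotes and risk-allele homozygotes; all must be non-negative
    integers.
    """

    cc: int
    ct: int
    tt: int

    def __post_init__(self) -> None:
        for name in ("cc", "ct", "tt"):
            value = getattr(self, name)
            if not isinstance(value, int) or isinstance(value, bool):
                raise ValidationError(f"genotype count {name} must be an integer, got {value!r}")
            if value < 0:
                raise ValidationError(f"genotype count {name} must be non-negative, got {value}")

    @property
    def n(self) -> int:
        """Number of genotyped individuals in the group."""
        return self.cc + self.ct + self.tt

    @property
    def c_alleles(self) -> int:
        """Count of reference (C) alleles, 2*cc + ct."""
        return 2 * self.cc + self.ct

    @property
    def t_alleles(self) -> int:
        """Count of risk (T) alleles, ct + 2*tt."""
        return self.ct + 2 * self.tt


@dataclass(frozen=True)
class Study:
    """One case-control study: genotype counts plus study-level moderators.

    ``nos`` (Newcastle-Ottawa stars, 0-9) and ``hwe_flag`` are descriptive
    metadata and are never used in computation.
    """

    study_id: str
    year: int
    ethnicity: Ethnicity
    soc: SourceOfControls
    cases: GenotypeCounts
    controls: GenotypeCounts
    nos: int | None = None
    hwe_flag: bool | None = None

    def __post_init__(self) -> None:
        if not self.study_id:
            raise ValidationError("study_id must be non-empty")
        if self.cases.n == 0:
            raise ValidationError(f"study {self.study_id!r}: case group is empty")
        if self.controls.n == 0:
            raise ValidationError(f"study {self.study_id!r}: control group is empty")
        if self.nos is not None and not 0 <= self.nos <= 9:
            raise ValidationError(f"study {self.study_id!r}: nos must be in 0..9, got {self.nos}")


@dataclass(frozen=True)
class StudySet:
    """An ordered collection of studies with unique ids.

    Input order is preserved; it drives forest-plot ordering and
    leave-one-out labelling.
    """

    studies: tuple[Study, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "studies", tuple(self.studies))
        seen: set[str] = set()
        for s in self.studies:
            if s.study_id in seen:
                raise ValidationError(f"duplicate study_id {s.study_id!r}")
            seen.add(s.study_id)

    def __len__(self) -> int:
        return len(self.studies)

    def __iter__(self) -> Iterator[Study]:
        return iter(self.studies)

    def __getitem__(self, index: int) -> Study:
        return self.studies[index]

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(s.study_id for s in self.studies)

    def subset(self, ids: Iterable[str]) -> "StudySet":
        """Restrict to the given ids, preserving the set's own order."""
        wanted = set(ids)
        missing = wanted - set(self.ids)
        if missing:
            raise ValidationError(f"unknown study ids: {sorted(missing)}")
        return StudySet(tuple(s for s in self.studies if s.study_id in wanted))

    def drop(self, study_id: str) -> "StudySet":
        """Return the set without one study (used by leave-one-out)."""
        if study_id not in self.ids:
            raise ValidationError(f"unknown study id {study_id!r}")
        return StudySet(tuple(s for s in self.studies if s.study_id != study_id))


def _parse_count(raw: str, study_id: str, column: str) -> int:
    text = raw.strip()
    try:
        value = int(text)
    except ValueError:
        raise ValidationError(
            f"study {study_id!r}, column {column!r}: {raw!r} is not an integer"
        ) from None
    if value < 0:
        raise ValidationError(f"study {study_id!r}, column {column!r}: negative count {value}")
    return value


def read_studies(path: str | Path, dialect: str = "csv") -> StudySet:
    """Read a study table from ``path``.

    ``dialect`` is ``"csv"`` (comma, RFC-4180 quoting) or ``"tsv"``.  The
    header must name all required columns; an ``nos`` column is optional.
    Counts are parsed as exact integers with surrounding whitespace
    stripped.
    """
    if dialect not in ("csv", "tsv"):
        raise SchemaError(f"unknown table dialect {dialect!r}")
    delim = "," if dialect == "csv" else "\t"
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter=delim)
        header = [h.strip() for h in (reader.fieldnames or [])]
        missing = [c for c in REQUIRED_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        studies = []
        for row in reader:
            row = {(k or "").strip(): (v or "") for k, v in row.items()}
            sid = row["study_id"].strip()
            counts = {
                c: _parse_count(row[c], sid, c)
                for c in REQUIRED_COLUMNS
                if c.startswith(("case_", "control_"))
            }
            nos_raw = row.get("nos", "").strip()
            studies.append(
                Study(
                    study_id=sid,
                    year=_parse_count(row["year"], sid, "year"),
                    ethnicity=_parse_ethnicity(row["ethnicity"]),
                    soc=_parse_soc(row["soc"]),
                    cases=GenotypeCounts(counts["case_cc"], counts["case_ct"], counts["case_tt"]),
                    controls=GenotypeCounts(
                        counts["control_cc"], counts["control_ct"], counts["control_tt"]
                    ),
                    nos=int(nos_raw) if nos_raw else None,
                )
            )
    return StudySet(tuple(studies))


def write_studies(studies: StudySet, path: str | Path, dialect: str = "csv") -> None:
    """Write a study table; inverse of :func:`read_studies`."""
    if dialect not in ("csv", "tsv"):
        raise SchemaError(f"unknown table dialect {dialect!r}")
    delim = "," if dialect == "csv" else "\t"
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter=delim)
        writer.writerow(list(REQUIRED_COLUMNS) + ["nos"])
        for s in studies:
            writer.writerow(
                [
                    s.study_id,
                    s.year,
                    s.ethnicity.value,
                    s.soc.value,
                    s.cases.cc,
                    s.cases.ct,
                    s.cases.tt,
                    s.controls.cc,
                    s.controls.ct,
                    s.controls.tt,
                    "" if s.nos is None else s.nos,
                ]
            )


def totals(studies: StudySet) -> tuple[int, int, int]:
    """Return (total cases, total controls, number of studies)."""
    return (
        sum(s.cases.n for s in studies),
        sum(s.controls.n for s in studies),
        len(studies),
    )


def load_fixture() -> StudySet:
    """Load the bundled 13-study rs10993994 prostate-cancer dataset.

    31,584 cases and 30,251 controls in the published order; 9 Caucasian,
    2 Asian, 1 African-American and 1 Mixed study; 5 hospital-based and 8
    population-based control series.
    """
    with resources.as_file(resources.files("snpmeta.data") / _FIXTURE_NAME) as p:
        return read_studies(p)
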