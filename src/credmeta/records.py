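"""Study-level genotype records, association grouping, and delimited-table I/O.

The canonical input is one row per independent case-control study: six
genotype counts (hom-major / het / hom-minor for cases and controls) plus
the metadata needed for subgrouping and sensitivity analyses.  Every
downstream quantity -- allele tables, control MAF, Hardy-Weinberg tests --
derives from these counts, so genotype counts (not allele counts) are the
unit of exchange.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import RecordValidationError, SchemaError

ETHNICITIES = ("Asian", "Caucasian", "African", "Other")
OVERALL = "Overall"
#: minimum independent datasets for an association to be meta-analyzable
MIN_STUDIES = 3

GROUPING_RULES = ("overall", "by_ethnicity", "by_subtype")

_COUNT_FIELDS = (
    "case_hom_major",
    "case_het",
    "case_hom_minor",
    "ctrl_hom_major",
    "ctrl_het",
    "ctrl_hom_minor",
)

#: column order of the study-table format (header names are exact)
COLUMNS = (
    "study_id",
    "first_author",
    "year",
    "ethnicity",
    "disease",
    "subtype",
    "variant_id",
    "gene",
    "major_allele",
    "minor_allele",
) + _COUNT_FIELDS


@dataclass
class StudyRecord:
    """One study's genotype counts for cases and controls plus metadata."""

    study_id: str
    first_author: str
    year: int
    ethnicity: str
    disease: str
    variant_id: str
    gene: str
    major_allele: str
    minor_allele: str
    case_hom_major: int
    case_het: int
    case_hom_minor: int
    ctrl_hom_major: int
    ctrl_het: int
    ctrl_hom_minor: int
    subtype: str | None = None

    def __post_init__(self) -> None:
        for name in _COUNT_FIELDS:
            value = getattr(self, name)
            if not isinstance(value, (int,)) or isinstance(value, bool):
                raise RecordValidationError(
                    f"study {self.study_id!r}: field {name!r} must be an integer, "
                    f"got {value!r}"
                )
            if value < 0:
                raise RecordValidationError(
                    f"study {self.study_id!r}: field {name!r} must be >= 0, got {value}"
                )
        if not isinstance(self.year, int) or not 1000 <= self.year <= 9999:
            raise RecordValidationError(
                f"study {self.study_id!r}: year must be a 4-digit integer, "
                f"got {self.year!r}"
            )
        if self.ethnicity not in ETHNICITIES:
            raise RecordValidationError(
                f"study {self.study_id!r}: ethnicity {self.ethnicity!r} not in "
                f"{ETHNICITIES}"
            )
        if self.n_cases < 1 or self.n_controls < 1:
            raise RecordValidationError(
                f"study {self.study_id!r}: needs at least one case and one control"
            )

    @property
    def n_cases(self) -> int:
        return self.case_hom_major + self.case_het + self.case_hom_minor

    @property
    def n_controls(self) -> int:
        return self.ctrl_hom_major + self.ctrl_het + self.ctrl_hom_minor

    @property
    def case_counts(self) -> tuple[int, int, int]:
        """(hom-major, het, hom-minor) among cases."""
        return (self.case_hom_major, self.case_het, self.case_hom_minor)

    @property
    def ctrl_counts(self) -> tuple[int, int, int]:
        """(hom-major, het, hom-minor) among controls."""
        return (self.ctrl_hom_major, self.ctrl_het, self.ctrl_hom_minor)

    @property
    def minor_allele_count(self) -> int:
        """Combined minor-allele count over cases and controls."""
        return (
            2 * (self.case_hom_minor + self.ctrl_hom_minor)
            + self.case_het
            + self.ctrl_het
        )


@dataclass(frozen=True)
class AssociationKey:
    """Identifies one (variant, disease, group) meta-analysis."""

    variant_id: str
    disease: str
    group: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.variant_id}/{self.disease}/{self.group}"


@dataclass
class Dataset:
    """Ordered collection of study records with free-text provenance."""

    records: list[StudyRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, str]] = set()
        for rec in self.records:
            triple = (rec.study_id, rec.variant_id, rec.disease)
            if triple in seen:
                raise RecordValidationError(
                    f"duplicate (study_id, variant_id, disease) triple: {triple}"
                )
            seen.add(triple)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class StudyGroup:
    """Records contributing to one association, with meta-analysis eligibility."""

    key: AssociationKey
    records: list[StudyRecord]
    eligible: bool


def _infer_delimiter(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        return dialect
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_study_table(path: str | Path, dialect: str | None = None) -> Dataset:
    """Read a delimited study table into a validated :class:`Dataset`.

    ``dialect`` is the field delimiter; when omitted it is inferred from the
    file suffix (tab for ``.tsv``/``.tab``, comma otherwise).  Raises
    :class:`SchemaError` when a required column is missing and
    :class:`RecordValidationError` (naming row and field) for bad values.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=_infer_delimiter(path, dialect), dtype=str)
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"study table {path} is missing columns: {missing}")

    records: list[StudyRecord] = []
    for idx, row in frame.iterrows():
        kwargs: dict = {}
        for name in COLUMNS:
            raw = row[name]
            if name in _COUNT_FIELDS or name == "year":
                try:
                    kwargs[name] = int(raw)
                except (TypeError, ValueError):
                    raise RecordValidationError(
                        f"row {idx}: field {name!r} must be an integer, got {raw!r}"
                    ) from None
            elif name == "subtype":
                kwargs[name] = None if pd.isna(raw) or raw == "" else str(raw)
            else:
                kwargs[name] = "" if pd.isna(raw) else str(raw)
        records.append(StudyRecord(**kwargs))
    return Dataset(records=records, provenance=str(path))


def write_study_table(
    dataset: Dataset, path: str | Path, dialect: str | None = None
) -> None:
    """Write a dataset in the study-table format read by :func:`read_study_table`."""
    path = Path(path)
    rows = []
    for rec in dataset:
        d = dataclasses.asdict(rec)
        d["subtype"] = "" if rec.subtype is None else rec.subtype
        rows.append([d[name] for name in COLUMNS])
    frame = pd.DataFrame(rows, columns=list(COLUMNS))
    frame.to_csv(path, sep=_infer_delimiter(path, dialect), index=False)


def group_by_association(
    dataset: Dataset, grouping: str = "overall"
) -> Mapping[AssociationKey, StudyGroup]:
    """Partition records into per-association groups.

    Rules:

    ``overall``
        one group per (variant, disease) labelled "Overall".
    ``by_ethnicity``
        one group per contributing ethnicity, plus an "Overall" group whenever
        two or more ethnicities contribute to the same (variant, disease).
    ``by_subtype``
        one group per disease subtype label; records without a subtype are
        not assigned under this rule.

    Groups with fewer than :data:`MIN_STUDIES` records are returned with
    ``eligible=False`` rather than dropped.
    """
    if grouping not in GROUPING_RULES:
        raise ValueError(f"grouping must be one of {GROUPING_RULES}, got {grouping!r}")

    buckets: dict[AssociationKey, list[StudyRecord]] = {}

    def add(key: AssociationKey, rec: StudyRecord) -> None:
        buckets.setdefault(key, []).append(rec)

    for rec in dataset:
        if grouping == "overall":
            add(AssociationKey(rec.variant_id, rec.disease, OVERALL), rec)
        elif grouping == "by_ethnicity":
            add(AssociationKey(rec.variant_id, rec.disease, rec.ethnicity), rec)
        else:  # by_subtype
            if rec.subtype is not None:
                add(AssociationKey(rec.variant_id, rec.disease, rec.subtype), rec)

    if grouping == "by_ethnicity":
        # the pooled group exists only when >= 2 ethnicities contribute
        by_vd: dict[tuple[str, str], set[str]] = {}
        for key in buckets:
            by_vd.setdefault((key.variant_id, key.disease), set()).add(key.group)
        for rec in dataset:
            if len(by_vd.get((rec.variant_id, rec.disease), set())) >= 2:
                add(AssociationKey(rec.variant_id, rec.disease, OVERALL), rec)

    return {
        key: StudyGroup(key=key, records=recs, eligible=len(recs) >= MIN_STUDIES)
        for key, recs in buckets.items()
    }
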