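"""Data model and I/O for informant use-report surveys.

The atomic datum of quantitative ethnobotany is the *use report*: one
informant citing one plant species for one use category.  Every index
downstream (use value, relative frequency of citation, cultural
importance, ...) is a function of the multiset of such reports, of the
number of informants ``N`` and of the number of use categories ``NC``.

A :class:`Survey` holds a *deduplicated* set of reports — repeated
mentions of the same (informant, species, category) triple collapse to a
single report, which is the reading under which the classical indices
are defined.

The module also ships a packaged reference dataset: digitized citation
counts (distinct citing informants per species) for the 51 medicinal
species recorded in a published ethnobotanical field survey of 145
informants in a Bangladesh wildlife sanctuary, together with the index
values and rank columns as printed in that source.  Three rows of the
printed table are internally inconsistent and were reconciled during
digitization; see ``data/reference_citations.csv`` and the package
methods note.
"""

from __future__ import annotations

import csv
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import FormatError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "PLANT_PARTS",
    "UseReport",
    "Survey",
    "SpeciesCitationRecord",
    "ReferenceCitations",
    "read_use_reports",
    "write_use_reports",
    "fc_counts",
    "nu_counts",
    "part_usage_shares",
    "load_reference_citations",
    "reference_index_frame",
]

#: Closed vocabulary of plant parts used in preparations.
PLANT_PARTS = frozenset(
    {
        "leaf",
        "root",
        "bark",
        "stem",
        "flower",
        "seed",
        "fruit",
        "latex",
        "whole-aerial",
        "unknown",
    }
)

#: Default mapping from logical field to file column name.
DEFAULT_COLUMNS: Mapping[str, str] = {
    "informant": "informant",
    "species": "species",
    "category": "category",
    "part": "part",
    "preparation": "preparation",
    "administration": "administration",
}

_MANDATORY_FIELDS = ("informant", "species", "category")


def _normalize_name(name: str) -> str:
    """Collapse internal whitespace; species identity is the name string."""
    return " ".join(str(name).split())


@dataclass(frozen=True)
class UseReport:
    """One informant's citation of one species for one use category."""

    informant_id: str
    species_id: str
    use_category: str
    plant_part: str = "unknown"
    preparation: str = ""
    administration: str = ""

    def __post_init__(self) -> None:
        for attr in ("informant_id", "species_id", "use_category"):
            value = getattr(self, attr)
            if not str(value).strip():
                raise ValidationError(f"{attr} must be non-empty")
        object.__setattr__(self, "species_id", _normalize_name(self.species_id))
        part = str(self.plant_part).strip().lower() or "unknown"
        if part not in PLANT_PARTS:
            raise ValidationError(
                f"plant_part {part!r} not in closed vocabulary {sorted(PLANT_PARTS)}"
            )
        object.__setattr__(self, "plant_part", part)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.informant_id, self.species_id, self.use_category)


@dataclass(frozen=True)
class Survey:
    """The informant universe, the use-category universe, and all reports.

    ``informants`` and ``use_categories`` may be larger than what the
    reports mention (an informant who cited nothing still counts in
    ``N``; a category fixed by protocol still counts in ``NC``).
    """

    informants: tuple[str, ...]
    use_categories: tuple[str, ...]
    reports: tuple[UseReport, ...]

    def __post_init__(self) -> None:
        if len(self.informants) < 1:
            raise ValidationError("a survey needs at least one informant (N >= 1)")
        if len(self.use_categories) < 1:
            raise ValidationError("a survey needs at least one use category (NC >= 1)")
        informant_set = set(self.informants)
        category_set = set(self.use_categories)
        seen: set[tuple[str, str, str]] = set()
        for report in self.reports:
            if report.informant_id not in informant_set:
                raise ValidationError(
                    f"report references unknown informant {report.informant_id!r}"
                )
            if report.use_category not in category_set:
                raise ValidationError(
                    f"report references unknown use category {report.use_category!r}"
                )
            if report.key in seen:
                raise ValidationError(
                    f"duplicate (informant, species, category) triple {report.key!r}; "
                    "use Survey.from_reports to deduplicate"
                )
            seen.add(report.key)

    @classmethod
    def from_reports(
        cls,
        reports: Iterable[UseReport],
        informants: Sequence[str] | None = None,
        use_categories: Sequence[str] | None = None,
    ) -> "Survey":
        """Build a survey, collapsing duplicate triples with a warning.

        ``N`` and ``NC`` are inferred from the data unless the informant
        or category universe is passed explicitly (e.g. to fix ``NC`` at
        a protocol-defined number of categories).
        """
        unique: dict[tuple[str, str, str], UseReport] = {}
        n_dupes = 0
        for report in reports:
            if report.key in unique:
                n_dupes += 1
            else:
                unique[report.key] = report
        if n_dupes:
            logger.warning("collapsed %d duplicate use-report triple(s)", n_dupes)
        deduped = tuple(unique.values())
        if informants is None:
            informants = sorted({r.informant_id for r in deduped})
        if use_categories is None:
            use_categories = sorted({r.use_category for r in deduped})
        return cls(tuple(informants), tuple(use_categories), deduped)

    @property
    def n_informants(self) -> int:
        """Total number of informants, ``N``."""
        return len(self.informants)

    @property
    def n_categories(self) -> int:
        """Total number of use categories, ``NC``."""
        return len(self.use_categories)

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(sorted({r.species_id for r in self.reports}))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "informant": [r.informant_id for r in self.reports],
                "species": [r.species_id for r in self.reports],
                "category": [r.use_category for r in self.reports],
                "part": [r.plant_part for r in self.reports],
                "preparation": [r.preparation for r in self.reports],
                "administration": [r.administration for r in self.reports],
            }
        )


def read_use_reports(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    *,
    delimiter: str = ",",
    informants: Sequence[str] | None = None,
    use_categories: Sequence[str] | None = None,
) -> Survey:
    """Read a long-format delimited text file of use reports.

    One row is one (informant, species, category) report.  Mandatory
    columns: informant, species, category (names configurable through
    ``column_map``); optional: part, preparation, administration.
    Duplicate triples collapse to one report with a logged warning.
    """
    columns = dict(DEFAULT_COLUMNS)
    if column_map:
        columns.update(column_map)
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"use-report file {path} is empty") from exc
    if frame.empty:
        raise FormatError(f"use-report file {path} contains no data rows")
    for logical in _MANDATORY_FIELDS:
        if columns[logical] not in frame.columns:
            raise FormatError(
                f"mandatory column {columns[logical]!r} (field {logical!r}) "
                f"missing from {path}"
            )
    reports = []
    for _, row in frame.iterrows():
        reports.append(
            UseReport(
                informant_id=row[columns["informant"]],
                species_id=row[columns["species"]],
                use_category=row[columns["category"]],
                plant_part=row.get(columns["part"], "unknown") or "unknown",
                preparation=row.get(columns["preparation"], ""),
                administration=row.get(columns["administration"], ""),
            )
        )
    return Survey.from_reports(reports, informants=informants, use_categories=use_categories)


def write_use_reports(survey: Survey, path: str | Path, *, delimiter: str = ",") -> None:
    """Write a survey back to the long-format dialect `read_use_reports` reads."""
    survey.to_frame().to_csv(path, sep=delimiter, index=False)


def fc_counts(survey: Survey) -> dict[str, int]:
    """Frequency of citation per species: distinct citing informants.

    An informant citing a species in several categories counts once.
    Species never cited are absent from the map (FC = 0).
    """
    informants_by_species: dict[str, set[str]] = defaultdict(set)
    for report in survey.reports:
        informants_by_species[report.species_id].add(report.informant_id)
    return {species: len(cited) for species, cited in sorted(informants_by_species.items())}


def nu_counts(survey: Survey) -> dict[str, int]:
    """Number of distinct use categories cited per species (``NU_s``)."""
    categories_by_species: dict[str, set[str]] = defaultdict(set)
    for report in survey.reports:
        categories_by_species[report.species_id].add(report.use_category)
    return {species: len(cats) for species, cats in sorted(categories_by_species.items())}


def part_usage_shares(survey: Survey) -> dict[str, float]:
    """Fraction of reports using each plant part; sums to 1 over reports."""
    if not survey.reports:
        return {}
    counts: dict[str, int] = defaultdict(int)
    for report in survey.reports:
        counts[report.plant_part] += 1
    if set(counts) == {"unknown"}:
        logger.warning("all reports have unknown plant part")
        return {"unknown": 1.0}
    total = len(survey.reports)
    return {part: count / total for part, count in sorted(counts.items())}


# ---------------------------------------------------------------------------
# Packaged reference citation dataset
# ---------------------------------------------------------------------------

#: Number of informants behind the packaged reference citation counts.
REFERENCE_N_INFORMANTS = 145


@dataclass(frozen=True)
class SpeciesCitationRecord:
    """Per-species citation count with its taxonomic identifiers.

    ``wfo_id`` is carried as an opaque string (no online resolution).
    The reference dataset contains one known erratum kept verbatim: two
    distinct species share the id ``wfo-0001296467``.
    """

    species_name: str
    wfo_id: str
    fc: int


class ReferenceCitations:
    """The packaged 51-species reference citation dataset."""

    def __init__(self, records: Sequence[SpeciesCitationRecord], n_informants: int):
        self.records = tuple(records)
        self.n_informants = n_informants
        self._by_name = {r.species_name: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def lookup(self, species_name: str) -> SpeciesCitationRecord:
        """Record for a species binomial; raises ``KeyError`` if unknown."""
        return self._by_name[_normalize_name(species_name)]


def _reference_path():
    return resources.files("ethnosurvey.data").joinpath("reference_citations.csv")


def load_reference_citations() -> ReferenceCitations:
    """Load the packaged per-species citation counts (51 records, N = 145)."""
    records = []
    with _reference_path().open(encoding="utf-8") as handle:
        for row in csv.DictReader(handle):
            records.append(
                SpeciesCitationRecord(
                    species_name=row["species"],
                    wfo_id=row["wfo_id"],
                    fc=int(row["citation"]),
                )
            )
    return ReferenceCitations(records, REFERENCE_N_INFORMANTS)


def reference_index_frame() -> pd.DataFrame:
    """Full reference table including the published index and rank columns.

    The RFC column can be recomputed from the citation counts; the RI,
    CII and CVI columns (and all ranks) depend on per-informant data that
    was never deposited and are therefore carried as reported values only.
    """
    with _reference_path().open(encoding="utf-8") as handle:
        return pd.read_csv(handle)
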