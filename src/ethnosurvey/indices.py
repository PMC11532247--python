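"""The five classical ethnobotanical indices and species ranking.

Given a deduplicated survey with ``N`` informants, ``NC`` use categories
and per-species citation structure, the indices are

* ``UV_s``  — use value: total use reports for species *s* divided by N;
* ``RFC_s`` — relative frequency of citation: distinct citing
  informants ``FC_s`` divided by N;
* ``RI_s``  — relative importance: mean of an RFC term and the species'
  category share ``RNU_s = NU_s / NU_max``;
* ``CII_s`` — cultural importance: sum over use categories of
  per-category report counts, divided by N (range ``[0, NC]``);
* ``CVI_s`` — cultural value: ``(NU_s / NC) * (FC_s / N) * CII_s``.

Under the deduplicated use-report data model UV and CII coincide — both
equal (total reports for the species) / N; they are computed through
independent summation orders and both emitted, because the two names
have distinct lineages in the ethnobotany literature and readers expect
both columns.

Two conventions exist in the literature for the RFC term of RI:

* ``"normalized"`` — ``RFC_s / RFC_max``, so the top-cited species with
  top versatility scores exactly 1;
* ``"raw_rfc"`` — ``RFC_s`` unscaled (the default here), under which RI
  lives in ``(0, 1]`` but the top-cited species need not rank first.

Published tables are not always explicit about which was used, so the
convention is a visible parameter of every computation, never a silent
constant.

Reported values in field tables are typically *truncated*, not rounded,
at three decimals; :func:`truncate_decimal` reproduces this and
:class:`RoundingPolicy` lets a report choose either policy.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal
from typing import Literal

import pandas as pd

from .exceptions import DomainError
from .use_reports import Survey, fc_counts, nu_counts

__all__ = [
    "RoundingPolicy",
    "SpeciesIndexRow",
    "use_value",
    "rfc",
    "relative_importance",
    "cii",
    "cvi",
    "compute_index_table",
    "index_table_to_frame",
    "truncate_decimal",
]

RIConvention = Literal["normalized", "raw_rfc"]


def truncate_decimal(x: float, places: int) -> float:
    """Truncate ``x`` toward zero at the given decimal place (no rounding).

    >>> truncate_decimal(0.46896, 3)
    0.468
    """
    if places < 0:
        raise DomainError("places must be >= 0")
    quantum = Decimal(1).scaleb(-places)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_DOWN))


def round_decimal(x: float, places: int) -> float:
    """Round half up at the given decimal place (reporting convention)."""
    if places < 0:
        raise DomainError("places must be >= 0")
    quantum = Decimal(1).scaleb(-places)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RoundingPolicy:
    """How a report formats index values: truncate or round, at ``places``."""

    mode: Literal["truncate", "round"] = "truncate"
    places: int = 3

    def apply(self, x: float) -> float:
        if self.mode == "truncate":
            return truncate_decimal(x, self.places)
        return round_decimal(x, self.places)


@dataclass(frozen=True)
class SpeciesIndexRow:
    """One species' citation structure, index values and rank positions.

    Index values are kept unformatted; formatting is a reporting concern
    (see :func:`index_table_to_frame`).  Ranks are competition ranks
    (ties share the minimum rank) computed on the unformatted values.
    """

    species_id: str
    fc: int
    nu: int
    uv: float
    rfc: float
    rnu: float
    ri: float
    cii: float
    cvi: float
    rank_rfc: int
    rank_ri: int
    rank_cii: int
    rank_cvi: int


def use_value(survey: Survey, species_id: str) -> float:
    """Use value: sum over informants of their report count for the species, / N.

    Returns 0 for a species absent from the survey.
    """
    per_informant: dict[str, int] = {}
    for report in survey.reports:
        if report.species_id == species_id:
            per_informant[report.informant_id] = per_informant.get(report.informant_id, 0) + 1
    return sum(per_informant.values()) / survey.n_informants


def rfc(fc: int, n: int) -> float:
    """Relative frequency of citation, ``FC_s / N``."""
    if n < 1:
        raise DomainError("n must be >= 1")
    if not (0 <= fc <= n):
        raise DomainError(f"fc must lie in [0, n]; got fc={fc}, n={n}")
    return fc / n


def relative_importance(
    rfc_s: float,
    nu_s: int,
    rfc_max: float,
    nu_max: int,
    convention: RIConvention = "raw_rfc",
) -> float:
    """Relative importance: mean of an RFC term and the NU share.

    ``convention="normalized"`` divides the species' RFC by the maximum
    RFC; ``"raw_rfc"`` uses it unscaled.  The NU term is always
    ``nu_s / nu_max``.
    """
    if nu_max < 1 or rfc_max <= 0:
        raise DomainError("rfc_max and nu_max must be positive")
    if rfc_s > rfc_max + 1e-12 or nu_s > nu_max:
        raise DomainError("species values cannot exceed the maxima")
    rnu = nu_s / nu_max
    if convention == "normalized":
        return (rfc_s / rfc_max + rnu) / 2.0
    if convention == "raw_rfc":
        return (rfc_s + rnu) / 2.0
    raise DomainError(f"unknown RI convention {convention!r}")


def cii(survey: Survey, species_id: str) -> float:
    """Cultural importance: per-category report counts summed over categories, / N."""
    per_category: dict[str, int] = {}
    for report in survey.reports:
        if report.species_id == species_id:
            per_category[report.use_category] = per_category.get(report.use_category, 0) + 1
    return sum(per_category.values()) / survey.n_informants


def cvi(nu_s: int, nc: int, fc: int, n: int, cii_s: float) -> float:
    """Cultural value: ``(NU_s/NC) * (FC_s/N) * CII_s``; always <= CII_s."""
    if nc < 1 or n < 1:
        raise DomainError("nc and n must be >= 1")
    if not (0 <= nu_s <= nc):
        raise DomainError(f"nu_s must lie in [0, nc]; got {nu_s}")
    if not (0 <= fc <= n):
        raise DomainError(f"fc must lie in [0, n]; got {fc}")
    return (nu_s / nc) * (fc / n) * cii_s


def _competition_ranks(values: list[float]) -> list[int]:
    """Descending competition ranks: ties share the minimum rank."""
    series = pd.Series(values)
    return series.rank(method="min", ascending=False).astype(int).tolist()


def compute_index_table(
    survey: Survey,
    convention: RIConvention = "raw_rfc",
) -> list[SpeciesIndexRow]:
    """One row per cited species with all five indices and four rank columns.

    Ranks are computed on unformatted values (descending, competition
    ranking).  Rows are ordered by descending RI with ties broken by
    species name, mirroring the conventional presentation of such tables.
    """
    fcs = fc_counts(survey)
    nus = nu_counts(survey)
    if not fcs:
        return []
    n = survey.n_informants
    nc = survey.n_categories
    species = sorted(fcs)
    rfc_by_species = {s: rfc(fcs[s], n) for s in species}
    rfc_max = max(rfc_by_species.values())
    nu_max = max(nus.values())
    uv_by_species = {s: use_value(survey, s) for s in species}
    cii_by_species = {s: cii(survey, s) for s in species}
    ri_by_species = {
        s: relative_importance(rfc_by_species[s], nus[s], rfc_max, nu_max, convention)
        for s in species
    }
    cvi_by_species = {
        s: cvi(nus[s], nc, fcs[s], n, cii_by_species[s]) for s in species
    }
    rank_rfc = dict(zip(species, _competition_ranks([rfc_by_species[s] for s in species])))
    rank_ri = dict(zip(species, _competition_ranks([ri_by_species[s] for s in species])))
    rank_cii = dict(zip(species, _competition_ranks([cii_by_species[s] for s in species])))
    rank_cvi = dict(zip(species, _competition_ranks([cvi_by_species[s] for s in species])))

    rows = [
        SpeciesIndexRow(
            species_id=s,
            fc=fcs[s],
            nu=nus[s],
            uv=uv_by_species[s],
            rfc=rfc_by_species[s],
            rnu=nus[s] / nu_max,
            ri=ri_by_species[s],
            cii=cii_by_species[s],
            cvi=cvi_by_species[s],
            rank_rfc=rank_rfc[s],
            rank_ri=rank_ri[s],
            rank_cii=rank_cii[s],
            rank_cvi=rank_cvi[s],
        )
        for s in species
    ]
    rows.sort(key=lambda row: (-row.ri, row.species_id))
    return rows


def index_table_to_frame(
    rows: list[SpeciesIndexRow],
    rounding: RoundingPolicy | None = None,
) -> pd.DataFrame:
    """Tabulate index rows; optionally add formatted columns per a policy.

    The unformatted columns are always present; when ``rounding`` is
    given, ``rfc_fmt``/``ri_fmt``/``cii_fmt``/``cvi_fmt`` columns carry
    the display values.
    """
    frame = pd.DataFrame([row.__dict__ for row in rows])
    if rounding is not None and not frame.empty:
        for col in ("rfc", "ri", "cii", "cvi"):
            frame[f"{col}_fmt"] = frame[col].map(rounding.apply)
    return frame
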