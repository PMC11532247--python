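"""Capability-approach perception tallies.

Interview statements about a medicine system (herbal or allopathic) are
coded upstream into units of the form *(respondent group, medicine
evaluated, central capability, valence)*, where valence records whether
the statement casts the medicine as an **enabler** of or a **barrier**
to that capability.  This module tallies such statements into
capability x valence count matrices, overall and per
(user group, medicine evaluated) cell.

The capability label set follows Nussbaum's central-capabilities
framework.  Field studies typically select a subset of the ten central
capabilities and add a residual "practical reasons" bucket for
statements about cost, speed of recovery and ease of use.  The default
set below is an editorial reconstruction along those lines — projects
should pass their own label set where the coding frame differs.

Statements, not respondents, are the tally unit: one respondent may
contribute several instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import FormatError, ValidationError

__all__ = [
    "DEFAULT_CAPABILITIES",
    "USER_GROUPS",
    "MEDICINES",
    "VALENCES",
    "PerceptionStatement",
    "CapabilityTally",
    "tally_capabilities",
    "compare_groups",
    "read_perception_statements",
    "write_perception_statements",
    "plot_capability_tally",
]

#: Editorial default: seven central capabilities plus a practical-reasons
#: bucket.  Not authoritative for any particular study's coding frame.
DEFAULT_CAPABILITIES: tuple[str, ...] = (
    "affiliation",
    "bodily health",
    "bodily integrity",
    "emotions",
    "life",
    "senses, imagination and thought",
    "control over one's environment",
    "practical reasons",
)

USER_GROUPS = ("allopathy_user", "herbal_user")
MEDICINES = ("allopathy", "herbal")
VALENCES = ("enabler", "barrier")


@dataclass(frozen=True)
class PerceptionStatement:
    """One coded statement: a group member judging one medicine on one capability."""

    respondent_id: str
    user_group: str
    medicine_evaluated: str
    capability: str
    valence: str

    def __post_init__(self) -> None:
        if self.user_group not in USER_GROUPS:
            raise ValidationError(
                f"user_group must be one of {USER_GROUPS}, got {self.user_group!r}"
            )
        if self.medicine_evaluated not in MEDICINES:
            raise ValidationError(
                f"medicine_evaluated must be one of {MEDICINES}, got {self.medicine_evaluated!r}"
            )
        if self.valence not in VALENCES:
            raise ValidationError(
                f"valence must be one of {VALENCES}, got {self.valence!r}"
            )


@dataclass
class CapabilityTally:
    """Per-capability enabler/barrier counts for one (group, medicine) cell."""

    capabilities: tuple[str, ...]
    counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for capability in self.capabilities:
            self.counts.setdefault(capability, {"enabler": 0, "barrier": 0})

    def add(self, capability: str, valence: str) -> None:
        self.counts[capability][valence] += 1

    def enablers(self, capability: str) -> int:
        return self.counts[capability]["enabler"]

    def barriers(self, capability: str) -> int:
        return self.counts[capability]["barrier"]

    def total(self, capability: str) -> int:
        cell = self.counts[capability]
        return cell["enabler"] + cell["barrier"]

    @property
    def grand_total(self) -> int:
        return sum(self.total(c) for c in self.capabilities)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "capability": list(self.capabilities),
                "enabler": [self.enablers(c) for c in self.capabilities],
                "barrier": [self.barriers(c) for c in self.capabilities],
                "total": [self.total(c) for c in self.capabilities],
            }
        )


def _validate_capability(capability: str, capability_set: Sequence[str]) -> None:
    if capability not in capability_set:
        raise ValidationError(
            f"unknown capability {capability!r}; allowed labels: {list(capability_set)}"
        )


def tally_capabilities(
    statements: Iterable[PerceptionStatement],
    user_group: str,
    medicine_evaluated: str,
    capability_set: Sequence[str] = DEFAULT_CAPABILITIES,
) -> CapabilityTally:
    """Counts per capability x valence for one (group, medicine) filter."""
    tally = CapabilityTally(tuple(capability_set))
    for statement in statements:
        _validate_capability(statement.capability, capability_set)
        if (
            statement.user_group == user_group
            and statement.medicine_evaluated == medicine_evaluated
        ):
            tally.add(statement.capability, statement.valence)
    return tally


def compare_groups(
    statements: Iterable[PerceptionStatement],
    capability_set: Sequence[str] = DEFAULT_CAPABILITIES,
) -> dict[tuple[str, str], CapabilityTally]:
    """All four (user group, medicine evaluated) tallies at once.

    The cell totals partition the input: summing every cell over the
    matrix recovers the number of statements.
    """
    matrix = {
        (group, medicine): CapabilityTally(tuple(capability_set))
        for group in USER_GROUPS
        for medicine in MEDICINES
    }
    for statement in statements:
        _validate_capability(statement.capability, capability_set)
        matrix[(statement.user_group, statement.medicine_evaluated)].add(
            statement.capability, statement.valence
        )
    return matrix


def read_perception_statements(path: str | Path) -> list[PerceptionStatement]:
    """Read coded statements from a CSV with columns
    respondent,user_group,medicine,capability,valence."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"statement file {path} is empty") from exc
    required = {"respondent", "user_group", "medicine", "capability", "valence"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"statement file {path} missing column(s) {sorted(missing)}")
    return [
        PerceptionStatement(
            respondent_id=row["respondent"],
            user_group=row["user_group"],
            medicine_evaluated=row["medicine"],
            capability=row["capability"],
            valence=row["valence"],
        )
        for _, row in frame.iterrows()
    ]


def write_perception_statements(
    statements: Sequence[PerceptionStatement], path: str | Path
) -> None:
    pd.DataFrame(
        {
            "respondent": [s.respondent_id for s in statements],
            "user_group": [s.user_group for s in statements],
            "medicine": [s.medicine_evaluated for s in statements],
            "capability": [s.capability for s in statements],
            "valence": [s.valence for s in statements],
        }
    ).to_csv(path, index=False)


def plot_capability_tally(tally: CapabilityTally, path: str | Path, title: str = "") -> None:
    """Grouped-bar export of one tally (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    frame = tally.to_frame()
    x = np.arange(len(frame))
    width = 0.38
    fig, ax = plt.subplots(figsize=(9, 4.5))
    ax.bar(x - width / 2, frame["enabler"], width, label="enabler")
    ax.bar(x + width / 2, frame["barrier"], width, label="barrier")
    ax.set_xticks(x)
    ax.set_xticklabels(frame["capability"], rotation=35, ha="right")
    ax.set_ylabel("statement count")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
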