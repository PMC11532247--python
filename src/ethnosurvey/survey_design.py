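"""Sample-size determination for household surveys of finite populations.

A field survey of a small settlement cannot assume an infinite sampling
frame: with only a few hundred households in the study villages, the
required number of interviews is governed by the finite-population
formula

    n = N_T / (1 + N_T * e_p**2)

where ``N_T`` is the total number of households and ``e_p`` the desired
precision (margin of error) expressed as a fraction.  As ``e_p`` tends to
zero the formula degenerates to a full census (``n = N_T``); as ``N_T``
grows it approaches the familiar infinite-population ceiling
``1 / e_p**2``.

The non-integer result is rounded *up*: interviewing one household fewer
than the formula demands would undershoot the nominal precision, so the
conservative sampling convention is to take the ceiling.

Note that the formula carries no explicit z quantile; the conventional
"95 % confidence" attached to it in field protocols is narrative.  The
implementation evaluates exactly the expression above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .exceptions import DomainError

__all__ = ["SamplingFrame", "required_sample_size"]


@dataclass(frozen=True)
class SamplingFrame:
    """A finite household sampling frame.

    Parameters
    ----------
    total_households:
        Number of households in the frame (``N_T``); must be >= 1.
    precision:
        Margin of error ``e_p`` as a fraction in ``[0, 1)``.  The value 0
        is allowed only as a limit flag meaning "census": the formula then
        returns ``total_households``.
    confidence_note:
        Free-text record of the nominal confidence level.  Informational
        only — the formula has no z term.
    """

    total_households: int
    precision: float
    confidence_note: str = field(default="95 % nominal confidence (narrative)")

    def __post_init__(self) -> None:
        if int(self.total_households) != self.total_households or self.total_households < 1:
            raise DomainError(
                f"total_households must be a positive integer, got {self.total_households!r}"
            )
        if not (0 <= self.precision < 1):
            raise DomainError(
                f"precision must lie in [0, 1), got {self.precision!r}"
            )


def required_sample_size(frame: SamplingFrame) -> int:
    """Number of households to interview under the finite-population formula.

    Returns ``ceil(N_T / (1 + N_T * e_p**2))``.  The result is always in
    ``[1, N_T]`` and is nondecreasing in ``N_T`` and nonincreasing in
    ``e_p``.

    Examples
    --------
    >>> required_sample_size(SamplingFrame(227, 0.05))
    145
    >>> required_sample_size(SamplingFrame(1000, 0.05))
    286
    """
    n_t = int(frame.total_households)
    e_p = float(frame.precision)
    if e_p == 0.0:  # census limit
        return n_t
    n = math.ceil(n_t / (1.0 + n_t * e_p * e_p))
    # Guard against floating-point dust pushing the ceiling above N_T.
    return max(1, min(n, n_t))
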