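"""Spinal-cord domain assignment and serial-section aggregation.

Transverse (or lateral) views of the spinal cord are divided into four
equal sections along the dorsoventral axis: cells in the top two
sections are dorsal, cells in the third section belong to the pMN
domain, and cells in the bottom quarter are ventral.  Bins are
half-open toward dorsal — normalized depth u in [0, 0.5) is dorsal,
[0.5, 0.75) is pMN, [0.75, 1] is ventral — so every in-cord position
falls in exactly one domain.

Counts from serial cryosections (by convention 10 sequential 20-um
sections) are summed and reported as a total per 200-um span.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence


from .errors import ConfigurationError, OutOfCordError


class Domain(str, Enum):
    DORSAL = "dorsal"
    PMN = "pmn"
    VENTRAL = "ventral"


@dataclass
class SpinalCordFrame:
    """Dorsoventral reference frame from manual boundary annotation.

    ``dorsal_boundary`` and ``ventral_boundary`` are coordinates along
    the dorsoventral axis, in any consistent unit; the direction of
    increasing dorsality is implied by their order.
    """

    dorsal_boundary: float
    ventral_boundary: float

    def __post_init__(self):
        if self.dorsal_boundary == self.ventral_boundary:
            raise ConfigurationError("spinal-cord boundaries must be distinct")

    def normalized_depth(self, position: float) -> float:
        """0 at the dorsal boundary, 1 at the ventral boundary."""
        return (position - self.dorsal_boundary) / (self.ventral_boundary - self.dorsal_boundary)


@dataclass
class DomainCounts:
    """Cell counts per dorsoventral domain."""

    dorsal: int = 0
    pmn: int = 0
    ventral: int = 0
    span_um: float | None = None

    @property
    def total(self) -> int:
        return self.dorsal + self.pmn + self.ventral

    def __add__(self, other: "DomainCounts") -> "DomainCounts":
        return DomainCounts(
            self.dorsal + other.dorsal, self.pmn + other.pmn, self.ventral + other.ventral
        )


def assign_domain(position: float, frame: SpinalCordFrame) -> Domain:
    """Assign a dorsoventral position to dorsal / pMN / ventral.

    Raises :class:`OutOfCordError` when the position lies outside the
    annotated boundaries.
    """
    u = frame.normalized_depth(position)
    if not 0.0 <= u <= 1.0:
        raise OutOfCordError(
            f"position {position} maps to normalized depth {u:.3f}, outside [0, 1]"
        )
    if u < 0.5:
        return Domain.DORSAL
    if u < 0.75:
        return Domain.PMN
    return Domain.VENTRAL


def count_domains(positions: Iterable[float], frame: SpinalCordFrame) -> DomainCounts:
    """Count cells per domain for one image/section."""
    counts = DomainCounts()
    for pos in positions:
        dom = assign_domain(pos, frame)
        if dom is Domain.DORSAL:
            counts.dorsal += 1
        elif dom is Domain.PMN:
            counts.pmn += 1
        else:
            counts.ventral += 1
    return counts


def aggregate_sections(
    sections: Sequence[DomainCounts], n_sections: int = 10, thickness_um: float = 20.0
) -> DomainCounts:
    """Sum per-section counts into a total per ``n_sections * thickness_um`` span."""
    if n_sections < 1:
        raise ConfigurationError("n_sections must be >= 1")
    if len(sections) != n_sections:
        raise ConfigurationError(
            f"got {len(sections)} section counts but n_sections={n_sections}"
        )
    total = DomainCounts()
    for sec in sections:
        total = total + sec
    total.span_um = n_sections * thickness_um
    return total
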