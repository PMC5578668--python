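"""Containers for per-sample D-loop sequences mapped to reference coordinates."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .reference import (
    D_LOOP_END,
    D_LOOP_LENGTH,
    D_LOOP_START,
    GAP_REGION,
    HVR1_AMPLICON,
    HVR2_AMPLICON,
    MISSING,
)

#: An insertion event: bases inserted immediately after a reference position.
Insertion = tuple[int, str]


@dataclass(frozen=True)
class AmpliconSegment:
    """Raw (unaligned) bases of one sequenced amplicon for one sample."""

    sample_id: str
    region: str  # "HVR1" | "HVR2"
    bases: str

    def __post_init__(self) -> None:
        if self.region not in ("HVR1", "HVR2"):
            raise ValueError(f"unknown region {self.region!r}")
        if not self.bases:
            raise ValueError(f"{self.sample_id}/{self.region}: empty segment")

    @property
    def nominal_window(self) -> tuple[int, int]:
        return HVR1_AMPLICON if self.region == "HVR1" else HVR2_AMPLICON


@dataclass(frozen=True)
class DloopSequence:
    """One sample's D-loop, one column per reference position 15440-16642.

    ``aligned`` has exactly 1203 characters; '-' marks a missing or deleted
    column.  Insertions relative to the reference are kept off-matrix as
    (after-position, bases) events so that all sample-by-position matrices
    stay rectangular.
    """

    sample_id: str
    aligned: str
    insertions: tuple[Insertion, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.aligned) != D_LOOP_LENGTH:
            raise ValueError(
                f"{self.sample_id}: {len(self.aligned)} columns, "
                f"expected {D_LOOP_LENGTH}"
            )
        for after, bases in self.insertions:
            if not D_LOOP_START <= after <= D_LOOP_END:
                raise ValueError(
                    f"{self.sample_id}: insertion after {after} outside window"
                )
            if not bases:
                raise ValueError(f"{self.sample_id}: empty insertion at {after}")

    def base_at(self, position: int) -> str:
        if not D_LOOP_START <= position <= D_LOOP_END:
            raise IndexError(f"position {position} outside D-loop window")
        return self.aligned[position - D_LOOP_START]

    def slice(self, start: int, end: int) -> str:
        """Columns of the inclusive interval [start, end]."""
        if start < D_LOOP_START or end > D_LOOP_END:
            raise IndexError(f"interval [{start}, {end}] outside D-loop window")
        return self.aligned[start - D_LOOP_START : end - D_LOOP_START + 1]

    def is_missing(self, position: int) -> bool:
        return self.base_at(position) in MISSING

    def mask(self, positions: Iterable[int]) -> "DloopSequence":
        """Return a copy with the given columns set to missing."""
        cols = list(self.aligned)
        for pos in positions:
            if not D_LOOP_START <= pos <= D_LOOP_END:
                raise ValueError(f"mask position {pos} outside D-loop window")
            cols[pos - D_LOOP_START] = "-"
        return replace(self, aligned="".join(cols))

    def non_missing_positions(self) -> list[int]:
        return [
            D_LOOP_START + i for i, c in enumerate(self.aligned) if c not in MISSING
        ]


def from_alleles(
    sample_id: str,
    reference_bases: str,
    alleles: Mapping[int, str],
    insertions: Sequence[Insertion] = (),
    gap_region: tuple[int, int] = GAP_REGION,
) -> DloopSequence:
    """Build a DloopSequence as reference plus substitutions plus a gap block.

    The gap block is applied first, so an explicitly supplied allele inside
    it survives: a site observed in the study (e.g. 16371) keeps its base
    even though it falls in the nominally unsequenced stretch.
    """
    cols = list(reference_bases)
    if gap_region is not None:
        lo, hi = gap_region
        cols[lo - D_LOOP_START : hi - D_LOOP_START + 1] = "-" * (hi - lo + 1)
    for pos, allele in alleles.items():
        cols[pos - D_LOOP_START] = allele
    return DloopSequence(sample_id, "".join(cols), tuple(insertions))
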