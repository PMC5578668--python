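"""Reference coordinate system for the horse mtDNA D-loop window.

All coordinates in this package are 1-based, inclusive, in the numbering of
the GenBank record X79547 (complete horse mitochondrial genome).  The analysis
window runs from 15440 to 16642 and is represented as a fixed 1203-column
matrix; the non-hypervariable stretch 16109-16376 that lies between the two
sequenced amplicons is carried as missing ('-') columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from Bio import SeqIO

D_LOOP_START = 15440
D_LOOP_END = 16642
D_LOOP_LENGTH = D_LOOP_END - D_LOOP_START + 1  # 1203 columns

HVR1_AMPLICON = (15440, 16108)
HVR2_AMPLICON = (16377, 16642)
GAP_REGION = (16109, 16376)  # unsequenced, '-' filled

#: Mutational hotspots excluded from haplotype definition.
DEFAULT_HOTSPOTS = (15585, 15597, 15604, 15650)

#: Characters treated as missing data in every downstream computation.
MISSING = frozenset("-N?")

REFERENCE_ACCESSION = "X79547"


@dataclass(frozen=True)
class ReferenceSequence:
    """A reference sequence anchored at an absolute 1-based coordinate.

    ``bases[i]`` is the base at position ``coordinate_offset + i``.
    """

    accession: str
    bases: str
    coordinate_offset: int

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError("reference bases must be non-empty")
        bad = set(self.bases) - set("ACGTN")
        if bad:
            raise ValueError(f"invalid reference characters: {sorted(bad)}")

    @property
    def start(self) -> int:
        return self.coordinate_offset

    @property
    def end(self) -> int:
        return self.coordinate_offset + len(self.bases) - 1

    def base_at(self, position: int) -> str:
        if not self.start <= position <= self.end:
            raise IndexError(f"position {position} outside [{self.start}, {self.end}]")
        return self.bases[position - self.coordinate_offset]

    def window(self, start: int, end: int) -> str:
        """Bases covering the inclusive coordinate interval [start, end]."""
        if start > end:
            raise ValueError("empty window")
        if start < self.start or end > self.end:
            raise IndexError(f"window [{start}, {end}] outside reference span")
        i = start - self.coordinate_offset
        return self.bases[i : i + (end - start + 1)]


def load_reference() -> ReferenceSequence:
    """Load the bundled D-loop reference window.

    The bundled FASTA is a synthetic stand-in for X79547: the alleles at the
    42 variable positions of the study are the true reference alleles, while
    the remaining (invariant) positions carry an arbitrary fixed sequence.
    Every analysis result in this package depends only on the variable
    columns, which are faithful.
    """
    path = resources.files("matriloop.data") / "x79547_dloop_synthetic.fasta"
    with path.open() as handle:
        record = next(SeqIO.parse(handle, "fasta"))
    bases = str(record.seq).upper()
    if len(bases) != D_LOOP_LENGTH:
        raise ValueError(
            f"bundled reference has {len(bases)} bases, expected {D_LOOP_LENGTH}"
        )
    return ReferenceSequence(
        accession=REFERENCE_ACCESSION, bases=bases, coordinate_offset=D_LOOP_START
    )
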