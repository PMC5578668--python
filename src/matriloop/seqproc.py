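"""Assembly of the 1203-column whole-loop representation and sequence QC."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .align import AlignedSegment
from .reference import (
    D_LOOP_START,
    GAP_REGION,
    HVR1_AMPLICON,
    HVR2_AMPLICON,
    MISSING,
)
from .sequences import DloopSequence, Insertion

GAP_BLOCK_LENGTH = GAP_REGION[1] - GAP_REGION[0] + 1  # 268 columns


def concatenate_dloop(
    hvr1: AlignedSegment, hvr2: AlignedSegment, sample_id: str | None = None
) -> DloopSequence:
    """Join the two aligned amplicons into one whole-loop record.

    The unsequenced stretch 16109-16376 between the amplicons is filled with
    268 missing columns; insertion events of both segments are merged.
    """
    sample_id = sample_id or hvr1.sample_id
    for seg, region, window in (
        (hvr1, "HVR1", HVR1_AMPLICON),
        (hvr2, "HVR2", HVR2_AMPLICON),
    ):
        if seg is None:
            raise ValueError(f"{sample_id}: missing {region} segment")
        if seg.region != region or seg.window != window:
            raise ValueError(
                f"{sample_id}: segment for {region} covers window {seg.window}, "
                f"expected {window}"
            )
    if hvr1.sample_id != hvr2.sample_id:
        raise ValueError(
            f"segment sample ids differ: {hvr1.sample_id!r} vs {hvr2.sample_id!r}"
        )
    aligned = hvr1.columns + "-" * GAP_BLOCK_LENGTH + hvr2.columns
    insertions = tuple(sorted(hvr1.insertions + hvr2.insertions))
    return DloopSequence(sample_id, aligned, insertions)


def split_dloop(seq: DloopSequence) -> tuple[str, str]:
    """Inverse of :func:`concatenate_dloop`: the two amplicon column blocks."""
    return (
        seq.slice(*HVR1_AMPLICON),
        seq.slice(*HVR2_AMPLICON),
    )


@dataclass(frozen=True)
class QCReport:
    sample_id: str
    n_ambiguous: int
    coverage: dict  # region -> fraction of non-missing columns
    passed: bool
    reasons: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "n_ambiguous": self.n_ambiguous,
            "coverage": dict(self.coverage),
            "passed": self.passed,
            "reasons": list(self.reasons),
        }


def validate_sequence(
    seq: DloopSequence,
    max_ambiguities: int = 10,
    min_region_coverage: float = 0.8,
) -> QCReport:
    """Report-only QC: ambiguity count and per-amplicon coverage."""
    n_amb = seq.aligned.count("N") + seq.aligned.count("?")
    coverage = {}
    reasons: list[str] = []
    for region, (start, end) in (("HVR1", HVR1_AMPLICON), ("HVR2", HVR2_AMPLICON)):
        block = seq.slice(start, end)
        non_missing = sum(c not in MISSING for c in block)
        frac = non_missing / len(block)
        coverage[region] = frac
        if non_missing == 0:
            reasons.append(f"missing region: {region}")
        elif frac < min_region_coverage:
            reasons.append(
                f"low coverage in {region}: {frac:.2f} < {min_region_coverage:.2f}"
            )
    if n_amb > max_ambiguities:
        reasons.append(f"{n_amb} ambiguous bases exceed limit {max_ambiguities}")
    return QCReport(
        sample_id=seq.sample_id,
        n_ambiguous=n_amb,
        coverage=coverage,
        passed=not reasons,
        reasons=tuple(reasons),
    )
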