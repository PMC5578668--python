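"""FASTA and table I/O for aligned whole-loop records."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .sequences import DloopSequence, Insertion


def _encode_insertions(insertions: Sequence[Insertion]) -> str:
    if not insertions:
        return ""
    return "insertions=" + ",".join(f"{pos}:{bases}" for pos, bases in insertions)


def _decode_insertions(description: str) -> tuple[Insertion, ...]:
    for token in description.split():
        if token.startswith("insertions="):
            events = []
            for item in token[len("insertions=") :].split(","):
                pos, bases = item.split(":")
                events.append((int(pos), bases))
            return tuple(events)
    return ()


def write_fasta(sequences: Sequence[DloopSequence], path: str | Path) -> None:
    """One aligned 1203-column record per sample; insertion events are kept
    in the description so the format round-trips losslessly."""
    records = [
        SeqRecord(
            Seq(seq.aligned),
            id=seq.sample_id,
            description=_encode_insertions(seq.insertions),
        )
        for seq in sequences
    ]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")


def read_fasta(path: str | Path) -> list[DloopSequence]:
    sequences = []
    seen = set()
    with open(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in seen:
                raise ValueError(f"duplicate sample id {record.id!r} in {path}")
            seen.add(record.id)
            sequences.append(
                DloopSequence(
                    sample_id=record.id,
                    aligned=str(record.seq).upper(),
                    insertions=_decode_insertions(record.description),
                )
            )
    if not sequences:
        raise ValueError(f"no records in {path}")
    return sequences
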