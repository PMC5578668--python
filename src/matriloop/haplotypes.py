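"""Hotspot masking, variable-site detection and haplotype collapsing.

The central object is the variable-site table: the ordered polymorphic
positions of the alignment, the reference allele at each, and one allele
string per haplotype — the classic reference-anchored haplotype table of
mtDNA control-region studies.  Insertions are carried as auxiliary events
per haplotype: they distinguish haplotypes during collapsing but are not
counted among the substitution sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .reference import D_LOOP_END, D_LOOP_START, MISSING, ReferenceSequence
from .sequences import DloopSequence, Insertion


def mask_hotspots(
    sequences: Sequence[DloopSequence], hotspot_positions: Iterable[int]
) -> list[DloopSequence]:
    """Set the listed columns to missing in every sequence (idempotent)."""
    positions = sorted(set(hotspot_positions))
    for pos in positions:
        if not D_LOOP_START <= pos <= D_LOOP_END:
            raise ValueError(f"hotspot position {pos} outside D-loop window")
    if not positions:
        return list(sequences)
    return [seq.mask(positions) for seq in sequences]


@dataclass(frozen=True)
class SiteMatrix:
    """Per-sample alleles at the detected variable positions."""

    positions: tuple[int, ...]
    reference_alleles: tuple[str, ...]
    alleles: pd.DataFrame  # index = sample_id, columns = positions
    insertions: dict[str, tuple[Insertion, ...]] = field(default_factory=dict)

    def restrict(self, interval: tuple[int, int]) -> "SiteMatrix":
        lo, hi = interval
        keep = [i for i, p in enumerate(self.positions) if lo <= p <= hi]
        pos = tuple(self.positions[i] for i in keep)
        return SiteMatrix(
            positions=pos,
            reference_alleles=tuple(self.reference_alleles[i] for i in keep),
            alleles=self.alleles.loc[:, list(pos)],
            insertions={
                s: tuple(ev for ev in evs if lo <= ev[0] <= hi)
                for s, evs in self.insertions.items()
            },
        )


def variable_sites(
    sequences: Sequence[DloopSequence],
    region: tuple[int, int] | None = None,
    reference: ReferenceSequence | None = None,
) -> SiteMatrix:
    """Detect substitution-polymorphic columns.

    A column is variable when at least two distinct non-missing states occur
    among the samples — plus the reference allele when ``reference`` is given,
    which makes the scan reference-anchored as in outgroup-rooted analyses
    (a column where every sample differs identically from the reference still
    counts).  Missing characters never count as a state; insertions are
    collected separately per sample.
    """
    if len(sequences) < 2:
        raise ValueError("need at least two sequences")
    lo, hi = region if region is not None else (D_LOOP_START, D_LOOP_END)
    if lo < D_LOOP_START or hi > D_LOOP_END:
        raise ValueError(f"region [{lo}, {hi}] outside D-loop window")
    positions: list[int] = []
    ref_alleles: list[str] = []
    rows: dict[str, list[str]] = {seq.sample_id: [] for seq in sequences}
    if len(rows) != len(sequences):
        raise ValueError("duplicate sample ids in sequence set")
    for pos in range(lo, hi + 1):
        states = {}
        for seq in sequences:
            c = seq.base_at(pos)
            if c not in MISSING:
                states[c] = True
        observed = set(states)
        ref_base = reference.base_at(pos) if reference is not None else None
        pool = observed | ({ref_base} if ref_base not in (None, "N") else set())
        if len(pool) >= 2 and observed:
            positions.append(pos)
            ref_alleles.append(ref_base if ref_base is not None else "?")
            for seq in sequences:
                rows[seq.sample_id].append(seq.base_at(pos))
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=positions)
    frame = frame.reindex([seq.sample_id for seq in sequences])
    return SiteMatrix(
        positions=tuple(positions),
        reference_alleles=tuple(ref_alleles),
        alleles=frame,
        insertions={
            seq.sample_id: tuple(ev for ev in seq.insertions if lo <= ev[0] <= hi)
            for seq in sequences
            if seq.insertions
        },
    )


@dataclass(frozen=True)
class VariableSiteTable:
    """Ordered variable positions x haplotypes (the published table shape)."""

    positions: tuple[int, ...]
    reference_alleles: tuple[str, ...]
    haplotypes: dict[str, str]  # label -> allele string, one char per position
    insertions: dict[str, tuple[Insertion, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.positions) != sorted(set(self.positions)):
            raise ValueError("positions must be strictly increasing")
        for label, alleles in self.haplotypes.items():
            if len(alleles) != len(self.positions):
                raise ValueError(
                    f"haplotype {label}: {len(alleles)} alleles for "
                    f"{len(self.positions)} positions"
                )

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def allele(self, label: str, position: int) -> str:
        return self.haplotypes[label][self.positions.index(position)]

    def allele_map(self, label: str) -> dict[int, str]:
        return dict(zip(self.positions, self.haplotypes[label]))

    def restrict(self, interval: tuple[int, int]) -> "VariableSiteTable":
        """Sub-table of positions inside the inclusive interval."""
        lo, hi = interval
        keep = [i for i, p in enumerate(self.positions) if lo <= p <= hi]
        return VariableSiteTable(
            positions=tuple(self.positions[i] for i in keep),
            reference_alleles=tuple(self.reference_alleles[i] for i in keep),
            haplotypes={
                lab: "".join(s[i] for i in keep) for lab, s in self.haplotypes.items()
            },
            insertions={
                lab: tuple(ev for ev in evs if lo <= ev[0] <= hi)
                for lab, evs in self.insertions.items()
            },
        )


@dataclass(frozen=True)
class HaplotypeAssignment:
    sample_to_haplotype: dict[str, str]
    counts: dict[str, int]  # label -> member count
    discordant: frozenset[str] = frozenset()
    unassignable: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != len(self.sample_to_haplotype):
            raise ValueError("haplotype counts do not sum to assigned samples")

    @property
    def n_haplotypes(self) -> int:
        return len(self.counts)

    @property
    def n_samples(self) -> int:
        return len(self.sample_to_haplotype)


def collapse_haplotypes(
    matrix: SiteMatrix, label_prefix: str = "M"
) -> tuple[HaplotypeAssignment, VariableSiteTable]:
    """Group samples with identical allele vectors (and insertion events).

    Labels are assigned in order of first appearance in the sample order of
    the matrix.  A sample with a missing call at any variable site is never
    merged into a haplotype (missing matches nothing) and is reported in
    ``unassignable`` instead.
    """
    keys: dict[tuple, str] = {}
    assignment: dict[str, str] = {}
    counts: dict[str, int] = {}
    unassignable: list[str] = []
    definitions: dict[str, str] = {}
    ins_defs: dict[str, tuple[Insertion, ...]] = {}
    for sample_id in matrix.alleles.index:
        alleles = "".join(matrix.alleles.loc[sample_id])
        if any(c in MISSING for c in alleles):
            unassignable.append(sample_id)
            continue
        key = (alleles, tuple(sorted(matrix.insertions.get(sample_id, ()))))
        if key not in keys:
            label = f"{label_prefix}{len(keys) + 1}"
            keys[key] = label
            definitions[label] = alleles
            if key[1]:
                ins_defs[label] = key[1]
            counts[label] = 0
        label = keys[key]
        assignment[sample_id] = label
        counts[label] += 1
    table = VariableSiteTable(
        positions=matrix.positions,
        reference_alleles=matrix.reference_alleles,
        haplotypes=definitions,
        insertions=ins_defs,
    )
    hap = HaplotypeAssignment(
        sample_to_haplotype=assignment,
        counts=counts,
        unassignable=tuple(unassignable),
    )
    return hap, table


def _differ_at_comparable_site(a: str, b: str, ins_a, ins_b) -> bool:
    subst = any(
        x != y and x not in MISSING and y not in MISSING for x, y in zip(a, b)
    )
    return subst or tuple(sorted(ins_a)) != tuple(sorted(ins_b))


def detect_discordant(
    assignment: HaplotypeAssignment, table: VariableSiteTable
) -> list[str]:
    """Samples whose haplotype occurs once and is unlike every other.

    A discordant haplotype signals a sample swap or a pedigree error: in a
    verified matriline every haplotype should recur.
    """
    flagged: list[str] = []
    for sample_id, label in assignment.sample_to_haplotype.items():
        if assignment.counts[label] != 1:
            continue
        mine = table.haplotypes[label]
        my_ins = table.insertions.get(label, ())
        unique = all(
            _differ_at_comparable_site(
                mine, table.haplotypes[other], my_ins, table.insertions.get(other, ())
            )
            for other in table.haplotypes
            if other != label
        )
        if unique:
            flagged.append(sample_id)
    return sorted(flagged)


def with_discordant(
    assignment: HaplotypeAssignment, table: VariableSiteTable
) -> HaplotypeAssignment:
    return HaplotypeAssignment(
        sample_to_haplotype=assignment.sample_to_haplotype,
        counts=assignment.counts,
        discordant=frozenset(detect_discordant(assignment, table)),
        unassignable=assignment.unassignable,
    )


def private_substitutions(table: VariableSiteTable) -> dict[str, int]:
    """Per haplotype: positions where its allele is unlike reference and all
    other haplotypes."""
    result: dict[str, int] = {}
    labels = list(table.haplotypes)
    for label in labels:
        mine = table.haplotypes[label]
        count = 0
        for i, ref in enumerate(table.reference_alleles):
            a = mine[i]
            if a in MISSING or a == ref:
                continue
            if all(
                table.haplotypes[other][i] != a for other in labels if other != label
            ):
                count += 1
        result[label] = count
    return result


def restrict_region(
    table: VariableSiteTable, interval: tuple[int, int]
) -> VariableSiteTable:
    lo, hi = interval
    if lo < D_LOOP_START or hi > D_LOOP_END:
        raise ValueError(f"interval [{lo}, {hi}] outside D-loop window")
    return table.restrict(interval)


# ---------------------------------------------------------------------------
# serialization: the published blank-cell dialect and a dense machine dialect


def table_to_tsv(table: VariableSiteTable, dense: bool = False) -> str:
    """TSV rendering: blank cell = concordance with reference (default), or
    every allele written explicitly (``dense=True``)."""
    lines = ["Haplotype\t" + "\t".join(str(p) for p in table.positions)]
    lines.append("Ref\t" + "\t".join(table.reference_alleles))
    for label, alleles in table.haplotypes.items():
        if dense:
            cells = list(alleles)
        else:
            cells = [
                a if a != r else ""
                for a, r in zip(alleles, table.reference_alleles)
            ]
        lines.append(label + "\t" + "\t".join(cells))
    if table.insertions:
        for label, events in sorted(table.insertions.items()):
            for after, bases in events:
                lines.append(f"#insertion\t{label}\t{after}\t{bases}")
    return "\n".join(lines) + "\n"


def table_from_tsv(text: str) -> VariableSiteTable:
    """Parse either TSV dialect produced by :func:`table_to_tsv`."""
    rows = [ln.split("\t") for ln in text.splitlines() if ln.strip()]
    header = rows[0]
    if header[0] != "Haplotype":
        raise ValueError("variable-site table must start with a 'Haplotype' header")
    positions = tuple(int(p) for p in header[1:])
    ref_row = rows[1]
    if ref_row[0] != "Ref":
        raise ValueError("second row must be the 'Ref' allele row")
    ref = tuple(ref_row[1:])
    haplotypes: dict[str, str] = {}
    insertions: dict[str, list[Insertion]] = {}
    for row in rows[2:]:
        if row[0] == "#insertion":
            insertions.setdefault(row[1], []).append((int(row[2]), row[3]))
            continue
        cells = row[1:] + [""] * (len(positions) - len(row) + 1)
        haplotypes[row[0]] = "".join(
            c if c else r for c, r in zip(cells, ref)
        )
    return VariableSiteTable(
        positions=positions,
        reference_alleles=ref,
        haplotypes=haplotypes,
        insertions={k: tuple(v) for k, v in insertions.items()},
    )


def assignments_to_tsv(assignment: HaplotypeAssignment) -> str:
    lines = ["sample\thaplotype\tdiscordant"]
    for sample_id, label in assignment.sample_to_haplotype.items():
        flag = "yes" if sample_id in assignment.discordant else "no"
        lines.append(f"{sample_id}\t{label}\t{flag}")
    for sample_id in assignment.unassignable:
        lines.append(f"{sample_id}\tunassignable\tno")
    return "\n".join(lines) + "\n"
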