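"""Matrilineal pedigrees: individuals, dam links and historical families."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator


@dataclass(frozen=True)
class Individual:
    id: str
    dam: str | None  # None for founders / unknown dams
    family: str  # recorded historical family (strain)
    is_founder: bool = False
    sampled: bool = True  # carries a sequence in the study


class PedigreeError(ValueError):
    pass


@dataclass
class PedigreeSet:
    """A set of individuals with dam links, supporting matriline traversal."""

    individuals: dict[str, Individual] = field(default_factory=dict)

    def add(self, ind: Individual) -> None:
        if ind.id in self.individuals:
            raise PedigreeError(f"duplicate individual id {ind.id!r}")
        if ind.dam is not None and ind.dam == ind.id:
            raise PedigreeError(f"{ind.id!r} is its own dam")
        self.individuals[ind.id] = ind

    def __len__(self) -> int:
        return len(self.individuals)

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self.individuals

    def __getitem__(self, individual_id: str) -> Individual:
        return self.individuals[individual_id]

    def __iter__(self) -> Iterator[Individual]:
        return iter(self.individuals.values())

    def families(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self.individuals.values():
            seen.setdefault(ind.family, None)
        return list(seen)

    def members(self, family: str) -> list[Individual]:
        return [i for i in self.individuals.values() if i.family == family]

    def daughters(self, individual_id: str) -> list[Individual]:
        return [i for i in self.individuals.values() if i.dam == individual_id]

    def dam_of(self, individual_id: str) -> Individual | None:
        dam = self.individuals[individual_id].dam
        return self.individuals.get(dam) if dam else None

    def matriline(self, individual_id: str) -> list[Individual]:
        """The dam chain from the individual back to its founder."""
        chain = []
        seen = set()
        current: Individual | None = self.individuals[individual_id]
        while current is not None:
            if current.id in seen:
                raise PedigreeError(f"pedigree cycle through {current.id!r}")
            seen.add(current.id)
            chain.append(current)
            current = self.dam_of(current.id)
        return chain

    def validate(self) -> None:
        """Check dam references and absence of cycles."""
        for ind in self.individuals.values():
            if ind.dam is not None and ind.dam not in self.individuals:
                raise PedigreeError(
                    f"{ind.id!r} references unknown dam {ind.dam!r}"
                )
        for ind in self.individuals.values():
            self.matriline(ind.id)  # raises on cycles

    def reassign_family(self, individual_id: str, family: str) -> "PedigreeSet":
        """Copy with one individual's recorded family label changed."""
        new = PedigreeSet(dict(self.individuals))
        new.individuals[individual_id] = replace(
            self.individuals[individual_id], family=family
        )
        return new

    def sampled_ids(self) -> list[str]:
        return [i.id for i in self.individuals.values() if i.sampled]


PEDIGREE_HEADER = "individual\tdam\tfamily\tfounder"


def pedigree_to_tsv(pedigree: PedigreeSet) -> str:
    lines = [PEDIGREE_HEADER]
    for ind in pedigree:
        dam = ind.dam if ind.dam is not None else "0"
        lines.append(f"{ind.id}\t{dam}\t{ind.family}\t{int(ind.is_founder)}")
    return "\n".join(lines) + "\n"


def pedigree_from_tsv(text: str, sampled: Iterable[str] | None = None) -> PedigreeSet:
    """Strict parser; malformed lines are reported with their line number.

    When ``sampled`` is given only those ids are flagged as carrying a
    sequence; otherwise every non-founder is considered sampled.
    """
    sampled_set = set(sampled) if sampled is not None else None
    pedigree = PedigreeSet()
    lines = text.splitlines()
    if not lines:
        raise PedigreeError("empty pedigree file")
    if lines[0].rstrip("\r") != PEDIGREE_HEADER.replace("\t", "\t"):
        if lines[0].rstrip("\r").split("\t") != PEDIGREE_HEADER.split("\t"):
            raise PedigreeError(
                f"line 1: expected header {PEDIGREE_HEADER!r}"
            )
    for lineno, raw in enumerate(lines[1:], start=2):
        line = raw.rstrip("\r")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise PedigreeError(
                f"line {lineno}: expected 4 tab-separated fields, got {len(parts)}"
            )
        ind_id, dam, family, founder = parts
        if not ind_id:
            raise PedigreeError(f"line {lineno}: empty individual id")
        if founder not in ("0", "1"):
            raise PedigreeError(f"line {lineno}: founder flag must be 0 or 1")
        is_founder = founder == "1"
        try:
            pedigree.add(
                Individual(
                    id=ind_id,
                    dam=None if dam in ("0", "") else dam,
                    family=family,
                    is_founder=is_founder,
                    sampled=(
                        ind_id in sampled_set
                        if sampled_set is not None
                        else not is_founder
                    ),
                )
            )
        except PedigreeError as exc:
            raise PedigreeError(f"line {lineno}: {exc}") from exc
    pedigree.validate()
    return pedigree
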