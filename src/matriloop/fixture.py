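"""Reconstruction of the 126-horse study dataset from the published tables.

The packaged fixture transcribes the study's per-family summary (sample
counts, haplotype and haplogroup labels, inference-eligible counts) and its
variable-site table (10 haplotypes x 42 positions, plus the M9 cytosine
insertion after 16371).  From these, the full set of 126 aligned whole-loop
sequences and a matrilineal pedigree consistent with the printed
inference-eligible counts are rebuilt; the deposited GenBank records are not
required.

Pedigree construction: each family is rooted at an unsampled founder mare.
Table rows give "studied/available" counts; the difference d is realised as
one dam-to-daughter chain of d+1 sampled individuals (the proximal-deletion
rule keeps exactly the terminal member of such a chain), with the remaining
members attached directly to the founder.  Eligibility filtering therefore
reproduces the printed available counts from the pedigree structure itself.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .haplotypes import VariableSiteTable, table_from_tsv
from .pedigree import Individual, PedigreeSet
from .reference import ReferenceSequence, load_reference
from .sequences import DloopSequence, from_alleles


@dataclass(frozen=True)
class PaperFixture:
    sequences: list[DloopSequence]
    pedigree: PedigreeSet
    family_haplotype: dict[str, str]  # family -> expected haplotype label
    family_haplogroup: dict[str, str]  # family -> haplogroup label
    table: VariableSiteTable  # expected whole-loop variable-site table
    family_info: pd.DataFrame  # the per-family summary rows
    reference: ReferenceSequence

    @property
    def sample_family(self) -> dict[str, str]:
        return {
            ind.id: ind.family for ind in self.pedigree if ind.sampled
        }


def _read_data(name: str) -> str:
    path = resources.files("matriloop.data") / name
    try:
        return path.read_text()
    except FileNotFoundError as exc:
        raise FileNotFoundError(
            f"packaged fixture file {name!r} is missing or unreadable"
        ) from exc


def _slug(family: str) -> str:
    return "".join(part.capitalize() for part in family.split())


def load_paper_fixture() -> PaperFixture:
    """Rebuild the 126-sequence, 14-family study dataset."""
    try:
        info = pd.read_csv(io.StringIO(_read_data("table1.tsv")), sep="\t")
    except Exception as exc:  # malformed transcription is a hard error
        raise ValueError(f"malformed fixture file table1.tsv: {exc}") from exc
    required = {"family", "n_studied", "n_available", "haplotype", "haplogroup"}
    if not required.issubset(info.columns):
        raise ValueError(
            f"fixture file table1.tsv lacks columns {sorted(required - set(info.columns))}"
        )
    try:
        table = table_from_tsv(_read_data("table2.tsv"))
    except Exception as exc:
        raise ValueError(f"malformed fixture file table2.tsv: {exc}") from exc
    reference = load_reference()

    sequences: list[DloopSequence] = []
    pedigree = PedigreeSet()
    family_haplotype: dict[str, str] = {}
    family_haplogroup: dict[str, str] = {}
    for row in info.itertuples(index=False):
        family = row.family
        label = row.haplotype
        if label not in table.haplotypes:
            raise ValueError(
                f"fixture family {family!r} references unknown haplotype {label!r}"
            )
        family_haplotype[family] = label
        family_haplogroup[family] = row.haplogroup
        slug = _slug(family)
        founder_id = f"{slug}_F"
        pedigree.add(
            Individual(founder_id, None, family, is_founder=True, sampled=False)
        )
        n_studied = int(row.n_studied)
        n_available = int(row.n_available)
        chain = n_studied - n_available  # proximal individuals to realise
        alleles = table.allele_map(label)
        ins = table.insertions.get(label, ())
        prev = founder_id
        for i in range(1, n_studied + 1):
            ind_id = f"{slug}_{i:02d}"
            dam = prev if i <= chain + 1 and chain > 0 else founder_id
            if chain > 0 and i <= chain + 1:
                prev = ind_id
            pedigree.add(Individual(ind_id, dam, family))
            sequences.append(from_alleles(ind_id, reference.bases, alleles, ins))
    pedigree.validate()
    return PaperFixture(
        sequences=sequences,
        pedigree=pedigree,
        family_haplotype=family_haplotype,
        family_haplogroup=family_haplogroup,
        table=table,
        family_info=info,
        reference=reference,
    )
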