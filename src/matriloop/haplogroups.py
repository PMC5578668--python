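"""Haplogroup assignment from a user-configurable diagnostic-motif panel.

A panel maps haplogroup labels (Cieslak-style equine nomenclature, A-K and
X1-X8, at whatever granularity the panel author chooses) to one or more
diagnostic motifs; a motif is a set of (position, required allele) pairs.  A
haplotype receives a label when it fully matches at least one motif of that
label and no motif of any other label; missing alleles fail a motif
conservatively rather than wildcard-matching.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .haplotypes import HaplotypeAssignment, VariableSiteTable
from .reference import D_LOOP_END, D_LOOP_START, MISSING, ReferenceSequence

NO_DESIGNATION = "No designation"

Motif = dict[int, str]  # position -> required allele


class PanelError(ValueError):
    pass


@dataclass(frozen=True)
class HaplogroupPanel:
    entries: dict[str, tuple[Motif, ...]]  # label -> motifs (any may match)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, motifs in self.entries.items():
            if not motifs:
                raise PanelError(f"haplogroup {label!r}: no motifs")
            for i, motif in enumerate(motifs):
                if not motif:
                    raise PanelError(f"haplogroup {label!r} motif {i}: empty")
                for pos, allele in motif.items():
                    if not D_LOOP_START <= pos <= D_LOOP_END:
                        raise PanelError(
                            f"haplogroup {label!r} motif {i}: position {pos} "
                            f"outside [{D_LOOP_START}, {D_LOOP_END}]"
                        )
                    if allele not in "ACGT":
                        raise PanelError(
                            f"haplogroup {label!r} motif {i}: allele {allele!r} "
                            "is not a nucleotide"
                        )

    @property
    def labels(self) -> list[str]:
        return list(self.entries)


def load_panel(path: str | Path) -> HaplogroupPanel:
    """Load a panel from JSON ({label: [[{position, allele}, ...], ...]}) or
    TSV (label <tab> position <tab> allele; one motif per label)."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        warnings.warn(f"empty haplogroup panel file {path.name}", stacklevel=2)
        return HaplogroupPanel(entries={})
    if path.suffix.lower() == ".json":
        return _panel_from_json(text, str(path))
    return _panel_from_tsv(text, str(path))


def _panel_from_json(text: str, source: str) -> HaplogroupPanel:
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise PanelError(f"{source}: not valid JSON: {exc}") from exc
    groups = raw.get("haplogroups", raw)
    entries: dict[str, tuple[Motif, ...]] = {}
    for label, motifs in groups.items():
        if label in entries:
            raise PanelError(f"{source}: duplicate haplogroup label {label!r}")
        parsed = []
        for motif in motifs:
            parsed.append(
                {int(e["position"]): str(e["allele"]).upper() for e in motif}
            )
        entries[label] = tuple(parsed)
    metadata = raw.get("metadata", {}) if isinstance(raw, dict) else {}
    return HaplogroupPanel(entries=entries, metadata=metadata)


def _panel_from_tsv(text: str, source: str) -> HaplogroupPanel:
    motifs: dict[str, Motif] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\r")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise PanelError(f"{source} line {lineno}: expected 3 fields")
        label, pos, allele = parts
        motifs.setdefault(label, {})
        if int(pos) in motifs[label]:
            raise PanelError(
                f"{source} line {lineno}: duplicate position {pos} for {label!r}"
            )
        motifs[label][int(pos)] = allele.upper()
    return HaplogroupPanel(entries={k: (v,) for k, v in motifs.items()})


def bundled_panel() -> HaplogroupPanel:
    """The packaged demonstration panel reconstructed from the study's
    haplotype-to-haplogroup pairs."""
    from importlib import resources

    path = resources.files("matriloop.data") / "haplogroup_panel.json"
    return _panel_from_json(path.read_text(), "bundled panel")


@dataclass(frozen=True)
class HaplogroupCall:
    label: str  # assigned label, or "No designation"
    ambiguous: tuple[str, ...] = ()  # all matching labels when >= 2 matched

    @property
    def is_ambiguous(self) -> bool:
        return len(self.ambiguous) >= 2


def assign(alleles: Mapping[int, str], panel: HaplogroupPanel) -> HaplogroupCall:
    """Assign one haplotype (position -> allele, reference-filled) to a label.

    Positions absent from ``alleles`` and missing alleles fail a motif.
    Ambiguity (motifs of two or more labels matched) is reported explicitly,
    never silently resolved.
    """
    matched = []
    for label, motifs in panel.entries.items():
        for motif in motifs:
            if all(
                alleles.get(pos) == want and alleles.get(pos) not in MISSING
                for pos, want in motif.items()
            ):
                matched.append(label)
                break
    if not matched:
        return HaplogroupCall(NO_DESIGNATION)
    if len(matched) > 1:
        return HaplogroupCall(NO_DESIGNATION, ambiguous=tuple(matched))
    return HaplogroupCall(matched[0])


def assign_table(
    table: VariableSiteTable,
    panel: HaplogroupPanel,
    reference: "ReferenceSequence | None" = None,
) -> dict[str, HaplogroupCall]:
    """Assign every haplotype of a variable-site table.

    A motif position outside the table was invariant among the samples, so
    the haplotype carries the reference allele there; with no ``reference``
    supplied such positions cannot match (conservative).
    """
    calls = {}
    for label in table.haplotypes:
        alleles = dict(table.allele_map(label))
        if reference is not None:
            for motifs in panel.entries.values():
                for motif in motifs:
                    for pos in motif:
                        if pos not in alleles and reference.start <= pos <= reference.end:
                            alleles[pos] = reference.base_at(pos)
        calls[label] = assign(alleles, panel)
    return calls


def cross_tabulate(
    assignment: HaplotypeAssignment,
    sample_family: Mapping[str, str],
    haplogroups: Mapping[str, str],
) -> pd.DataFrame:
    """Per-family summary: member count, haplotype, haplogroup, sharing flag."""
    rows = []
    for sample_id in assignment.sample_to_haplotype:
        if sample_id not in sample_family:
            raise ValueError(f"sample {sample_id!r} has no recorded family")
    families: dict[str, list[str]] = {}
    for sample_id, label in assignment.sample_to_haplotype.items():
        families.setdefault(sample_family[sample_id], []).append(label)
    hap_to_families: dict[str, set[str]] = {}
    for family, labels in families.items():
        for label in set(labels):
            hap_to_families.setdefault(label, set()).add(family)
    for family, labels in families.items():
        unique = sorted(set(labels))
        hap = unique[0] if len(unique) == 1 else ",".join(unique)
        shared = any(len(hap_to_families[lab]) > 1 for lab in unique)
        rows.append(
            {
                "family": family,
                "n_members": len(labels),
                "haplotype": hap,
                "haplogroup": (
                    haplogroups.get(unique[0], NO_DESIGNATION)
                    if len(unique) == 1
                    else ";".join(
                        haplogroups.get(lab, NO_DESIGNATION) for lab in unique
                    )
                ),
                "haplotype_shared_with_other_family": shared,
            }
        )
    return pd.DataFrame(rows)
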