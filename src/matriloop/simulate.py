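"""Simulation of matrilineal pedigrees and D-loop sequence transmission.

The generator emulates the statistical structure the analysis assumes: each
historical family is a matrilineal tree rooted at one founder mare whose
haplotype is transmitted unchanged apart from rare per-meiosis substitutions
(a configurable set of hotspot positions mutates faster), rare single-base
indels, and optional recording errors that assign an individual to the wrong
historical family.  Every injected event is written to a truth log so tests
can recover the configured rates from simulated data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .pedigree import Individual, PedigreeSet
from .reference import D_LOOP_END, D_LOOP_START, DEFAULT_HOTSPOTS, MISSING
from .sequences import DloopSequence


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the simulator.

    Defaults mirror the study: 14 matrilines averaging nine sampled
    descendants each (126 expected), documented pedigree depth of up to
    fifteen generations, four fast-mutating hotspot positions.  The
    substitution rate is per site per transmission; equine control-region
    germline estimates put it around 1e-6, with hotspots roughly an order
    of magnitude faster.
    """

    n_families: int = 14
    mean_family_size: float = 9.0
    generations: int = 15
    per_site_substitution_rate: float = 1e-6
    hotspot_positions: tuple[int, ...] = DEFAULT_HOTSPOTS
    hotspot_rate_multiplier: float = 10.0
    indel_rate: float = 1e-7
    pedigree_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("need at least one family")
        if self.generations < 1:
            raise ValueError("need at least one generation")
        if self.mean_family_size <= 0:
            raise ValueError("mean family size must be positive")
        for name in (
            "per_site_substitution_rate",
            "indel_rate",
            "pedigree_error_rate",
        ):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        eff = self.per_site_substitution_rate * self.hotspot_rate_multiplier
        if self.hotspot_rate_multiplier < 1 or eff > 1.0:
            raise ValueError("hotspot multiplier must be >= 1 and keep rate <= 1")
        for pos in self.hotspot_positions:
            if not D_LOOP_START <= pos <= D_LOOP_END:
                raise ValueError(f"hotspot {pos} outside D-loop window")


@dataclass
class TruthLog:
    """Ground truth of one simulation run."""

    founder_haplotypes: dict[str, str] = field(default_factory=dict)
    mutations: list[tuple[str, int, str, str]] = field(default_factory=list)
    indels: list[tuple[str, str, int, str]] = field(default_factory=list)
    pedigree_errors: list[tuple[str, str, str]] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "founder_haplotypes": self.founder_haplotypes,
                "mutations": [list(m) for m in self.mutations],
                "indels": [list(i) for i in self.indels],
                "pedigree_errors": [list(e) for e in self.pedigree_errors],
            },
            indent=2,
            sort_keys=True,
        )


def generate_pedigree(config: SimulationConfig) -> PedigreeSet:
    """Matrilineal trees, one per family, rooted at unsampled founder mares.

    Family size (sampled descendants) is 1 + Poisson(mean - 1); each new
    individual picks its dam uniformly among family members shallower than
    the generation cap, so pedigrees mix chains and stars.
    """
    rng = np.random.default_rng(config.seed)
    pedigree = PedigreeSet()
    for f in range(config.n_families):
        family = f"Fam{f + 1:02d}"
        founder_id = f"{family}_F"
        pedigree.add(
            Individual(founder_id, None, family, is_founder=True, sampled=False)
        )
        size = 1 + rng.poisson(config.mean_family_size - 1.0)
        depth = {founder_id: 0}
        members = [founder_id]
        for i in range(size):
            candidates = [
                m for m in members if depth[m] < config.generations
            ]
            dam = candidates[rng.integers(len(candidates))] if candidates else members[0]
            ind_id = f"{family}_{i + 1:03d}"
            pedigree.add(Individual(ind_id, dam, family))
            depth[ind_id] = depth[dam] + 1
            members.append(ind_id)
    return pedigree


def _mutate_transmission(
    child_id: str,
    bases: np.ndarray,
    is_hotspot: np.ndarray,
    config: SimulationConfig,
    rng,
    log: TruthLog,
) -> np.ndarray:
    """One meiosis: independent per-site substitutions plus rare indels."""
    rate = config.per_site_substitution_rate
    rates = np.where(is_hotspot, rate * config.hotspot_rate_multiplier, rate)
    present = ~np.isin(bases, list(MISSING))
    hits = np.nonzero(present & (rng.random(len(bases)) < rates))[0]
    out = bases.copy()
    alphabet = np.array(list("ACGT"))
    for i in hits:
        old = out[i]
        choices = [b for b in alphabet if b != old]
        new = choices[rng.integers(3)]
        out[i] = new
        log.mutations.append((child_id, D_LOOP_START + int(i), str(old), str(new)))
    if rng.random() < config.indel_rate:
        candidates = np.nonzero(present)[0]
        if len(candidates):
            i = int(candidates[rng.integers(len(candidates))])
            if rng.random() < 0.5:
                out[i] = "-"
                log.indels.append((child_id, "del", D_LOOP_START + i, str(bases[i])))
            else:
                inserted = str(alphabet[rng.integers(4)])
                log.indels.append((child_id, "ins", D_LOOP_START + i, inserted))
    return out


def evolve_sequences(
    pedigree: PedigreeSet,
    founders: dict[str, DloopSequence],
    config: SimulationConfig,
) -> tuple[dict[str, DloopSequence], TruthLog]:
    """Drop sequences down the pedigree from the founder haplotypes.

    Each individual's sequence is its dam's sequence plus independent
    per-site substitutions (hotspots at rate x multiplier) and rare
    single-base indel events; deletions blank a column, insertions are
    recorded as off-matrix events.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    log = TruthLog()
    for family in pedigree.families():
        if family not in founders:
            raise ValueError(f"no founder haplotype supplied for family {family!r}")
        log.founder_haplotypes[family] = founders[family].aligned
    n = D_LOOP_END - D_LOOP_START + 1
    is_hotspot = np.zeros(n, dtype=bool)
    for pos in config.hotspot_positions:
        is_hotspot[pos - D_LOOP_START] = True
    sequences: dict[str, DloopSequence] = {}
    arr_cache: dict[str, np.ndarray] = {}
    ins_cache: dict[str, tuple] = {}

    def sequence_of(ind: Individual) -> np.ndarray:
        if ind.id in arr_cache:
            return arr_cache[ind.id]
        if ind.is_founder or ind.dam is None:
            arr = np.array(list(founders[ind.family].aligned))
            ins_cache[ind.id] = tuple(founders[ind.family].insertions)
        else:
            dam = pedigree[ind.dam]
            parent = sequence_of(dam)
            before = len(log.indels)
            arr = _mutate_transmission(
                ind.id, parent, is_hotspot, config, rng, log
            )
            ins = list(ins_cache[dam.id])
            for rec in log.indels[before:]:
                if rec[0] == ind.id and rec[1] == "ins":
                    ins.append((rec[2], rec[3]))
            ins_cache[ind.id] = tuple(sorted(ins))
        arr_cache[ind.id] = arr
        return arr

    for ind in pedigree:
        arr = sequence_of(ind)
        if ind.sampled:
            sequences[ind.id] = DloopSequence(
                ind.id, "".join(arr), ins_cache[ind.id]
            )
    return sequences, log


def inject_pedigree_errors(
    pedigree: PedigreeSet, config: SimulationConfig
) -> tuple[PedigreeSet, TruthLog]:
    """Reassign each sampled individual's recorded family with the configured
    probability (label swap only; the sequence stays with the horse)."""
    log = TruthLog()
    if config.pedigree_error_rate == 0.0:
        return pedigree, log
    families = pedigree.families()
    if len(families) < 2:
        raise ValueError("pedigree errors need at least two families")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    out = pedigree
    for ind in list(pedigree):
        if not ind.sampled:
            continue
        if rng.random() < config.pedigree_error_rate:
            others = [f for f in families if f != ind.family]
            target = others[rng.integers(len(others))]
            out = out.reassign_family(ind.id, target)
            log.pedigree_errors.append((ind.id, ind.family, target))
    return out, log


def simulate_dataset(
    config: SimulationConfig,
    founders: dict[str, DloopSequence] | None = None,
) -> tuple[dict[str, DloopSequence], PedigreeSet, TruthLog]:
    """Pedigree + sequences + merged truth log in one call.

    Without explicit founder haplotypes every family founder receives the
    reference sequence with the inter-amplicon gap block, i.e. families are
    initially identical and differ only by simulated mutation.
    """
    from .reference import GAP_REGION, load_reference
    from .sequences import from_alleles

    pedigree = generate_pedigree(config)
    if founders is None:
        reference = load_reference()
        founders = {
            family: from_alleles(f"{family}_founder", reference.bases, {})
            for family in pedigree.families()
        }
    sequences, log = evolve_sequences(pedigree, founders, config)
    pedigree, error_log = inject_pedigree_errors(pedigree, config)
    log.pedigree_errors = error_log.pedigree_errors
    return sequences, pedigree, log
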