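"""End-to-end analysis: QC, haplotyping, diversity, haplogroups, founders."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from . import diversity as div
from . import founders as fnd
from . import haplogroups as hg
from . import haplotypes as hap
from .config import RunConfig
from .pedigree import PedigreeSet, pedigree_from_tsv
from .reference import HVR1_AMPLICON, HVR2_AMPLICON, load_reference
from .seqproc import validate_sequence
from .sequences import DloopSequence
from .io import read_fasta


@dataclass
class ReportBundle:
    qc: list
    assignment: hap.HaplotypeAssignment
    table: hap.VariableSiteTable
    hvr1_assignment: hap.HaplotypeAssignment
    hvr1_table: hap.VariableSiteTable
    whole_indices: div.DiversityIndices
    hvr1_indices: div.DiversityIndices
    haplogroup_calls: dict
    family_summary: object  # DataFrame
    founder_results: list
    founder_excluded: dict
    trees: list
    config: RunConfig
    seed: int
    convergence_warning: bool


def run_pipeline(
    sequences: Sequence[DloopSequence],
    pedigree: PedigreeSet,
    config: RunConfig | None = None,
    seed: int | None = None,
    run_founders: bool = True,
) -> ReportBundle:
    config = config or RunConfig()
    seed = config.seed if seed is None else seed
    if not sequences:
        raise ValueError("empty sequence set")
    missing = [s.sample_id for s in sequences if s.sample_id not in pedigree]
    if missing:
        raise ValueError(
            f"samples absent from pedigree: {', '.join(sorted(missing)[:5])}"
        )
    reference = load_reference()
    qc = [validate_sequence(s, config.max_ambiguities) for s in sequences]

    masked = hap.mask_hotspots(sequences, config.hotspots)
    matrix = hap.variable_sites(masked, reference=reference)
    assignment, table = hap.collapse_haplotypes(matrix)
    assignment = hap.with_discordant(assignment, table)

    hvr1_matrix = matrix.restrict(config.hvr1_interval)
    hvr1_assignment, hvr1_table = hap.collapse_haplotypes(hvr1_matrix)
    hvr1_assignment = hap.with_discordant(hvr1_assignment, hvr1_table)

    whole_idx = div.compute_indices(assignment, table, masked, "Whole-loop")
    hvr1_idx = div.compute_indices(
        hvr1_assignment, hvr1_table, masked, "HVR1", region=config.hvr1_interval
    )

    panel = (
        hg.load_panel(config.panel_path)
        if config.panel_path
        else hg.bundled_panel()
    )
    calls = hg.assign_table(table, panel, reference=reference)
    sample_family = {
        ind.id: ind.family for ind in pedigree if ind.id in
        {s.sample_id for s in sequences}
    }
    summary = hg.cross_tabulate(
        assignment, sample_family, {lab: c.label for lab, c in calls.items()}
    )

    founder_results: list = []
    excluded: dict = {}
    trees: list = []
    convergence_warning = False
    if run_founders:
        founder_results, excluded, trees = fnd.run_founder_inference(
            masked,
            pedigree,
            assignment,
            table,
            reference,
            config=config.mcmc,
            seed=seed,
        )
        convergence_warning = any(not r.converged for r in founder_results)

    return ReportBundle(
        qc=qc,
        assignment=assignment,
        table=table,
        hvr1_assignment=hvr1_assignment,
        hvr1_table=hvr1_table,
        whole_indices=whole_idx,
        hvr1_indices=hvr1_idx,
        haplogroup_calls=calls,
        family_summary=summary,
        founder_results=founder_results,
        founder_excluded=excluded,
        trees=trees,
        config=config,
        seed=seed,
        convergence_warning=convergence_warning,
    )


def run_pipeline_paths(
    fasta_path: str | Path,
    pedigree_path: str | Path,
    config: RunConfig | None = None,
    seed: int | None = None,
    run_founders: bool = True,
) -> ReportBundle:
    sequences = read_fasta(fasta_path)
    pedigree = pedigree_from_tsv(
        Path(pedigree_path).read_text(),
        sampled=[s.sample_id for s in sequences],
    )
    return run_pipeline(sequences, pedigree, config, seed, run_founders)


def write_bundle(bundle: ReportBundle, out_dir: str | Path) -> None:
    """Write every artifact, stamped with the config hash and seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": bundle.config.config_hash(), "seed": bundle.seed}

    (out / "qc.json").write_text(
        json.dumps(
            {"stamp": stamp, "samples": [q.to_dict() for q in bundle.qc]},
            indent=2,
            sort_keys=True,
        )
    )
    (out / "variable_sites.tsv").write_text(hap.table_to_tsv(bundle.table))
    (out / "variable_sites_dense.tsv").write_text(
        hap.table_to_tsv(bundle.table, dense=True)
    )
    (out / "assignments.tsv").write_text(
        hap.assignments_to_tsv(bundle.assignment)
    )
    (out / "diversity.tsv").write_text(
        div.diversity_report(bundle.whole_indices, bundle.hvr1_indices).to_csv(
            sep="\t", index=False
        )
    )
    (out / "diversity.json").write_text(
        div.report_to_json(bundle.whole_indices, bundle.hvr1_indices)
    )
    summary = bundle.family_summary.copy()
    (out / "families.tsv").write_text(summary.to_csv(sep="\t", index=False))
    if bundle.founder_results:
        (out / "founder_posteriors.tsv").write_text(
            fnd.posteriors_to_tsv(bundle.founder_results)
        )
        (out / "founder_posteriors.json").write_text(
            fnd.posteriors_to_json(bundle.founder_results, bundle.founder_excluded)
        )
        (out / "trees.nwk").write_text(
            "".join(t.to_newick() + "\n" for t in bundle.trees)
        )
    (out / "run.json").write_text(
        json.dumps(
            {"stamp": stamp, "config": bundle.config.to_dict()},
            indent=2,
            sort_keys=True,
        )
    )
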