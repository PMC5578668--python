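# matriloop

Whole-loop mitochondrial D-loop analysis for matrilineal pedigree
verification — haplotype calling from paired hypervariable-region
amplicons, Nei diversity indices, haplogroup assignment, and Bayesian
inference of founder-mare haplotypes.

## The problem

Closed horse-breeding programmes organise stock into historical families
(matrilines, *rasans*), each supposedly an unbroken female line from a
single founder mare. Mitochondrial DNA is maternally inherited without
recombination, so every member of a true matriline should carry the same
D-loop haplotype, barring rare new mutation. Sequencing the *whole* D-loop
control region (reference window 15440–16642 of X79547, covered by an HVR1
amplicon at 15440–16108 and an HVR2 amplicon at 16377–16642) rather than
HVR1 alone resolves haplotypes that HVR1 cannot separate, and lets studbook
records be tested against genetics: do families carry private haplotypes,
do separate strains share ancestry, and how probable is it that each
founder mare carried the haplotype seen in her living descendants?

`matriloop` is for researchers and breed registries doing exactly this kind
of mtDNA lineage verification: it takes per-sample amplicon FASTA plus a
pedigree table and produces the variable-site table, haplotype assignments
with discordance flags, HVR1-versus-whole-loop diversity comparison,
haplogroup calls from a motif panel, and per-family founder posteriors.

## Methods in brief

- **Haplotyping** — sequences are anchored to reference coordinates by
  affine-gap pairwise alignment (insertions kept off-matrix, 3'-normalised),
  mutational hotspots are masked, polymorphic columns are detected
  reference-anchored, and samples are collapsed into haplotypes by exact
  allele-vector identity. A haplotype occurring once and unlike all others
  is flagged *discordant* (sample or pedigree error).
- **Diversity** — Nei's unbiased haplotype diversity
  h = n(1 − Σp_i²)/(n − 1) with its analytic SE, mean pairwise differences
  k (pairwise deletion of missing sites), and nucleotide diversity π = k/L
  with the comparable-site count L reported alongside.
- **Founder inference** — per family, terminal-line individuals (proximal
  dam/grand-dam of another sample dropped; minimum four) are placed on a
  star tree under the family MRCA with X79547 as outgroup. A
  Metropolis–Hastings sampler under the GTR model (exact pruning
  likelihood; exponential branch-length priors, flat Dirichlet priors on
  rates and frequencies; 2 chains × 100,000 iterations) draws the MRCA
  state vector each retained iteration, and the founder posterior is the
  fraction of draws matching the descendants' shared haplotype at every
  variable site. ESS and split-R̂ diagnostics accompany every estimate.

Details, defaults and limitations: [docs/methods.md](docs/methods.md).

## Worked example

The package ships a fixture reconstructing a published 126-horse,
14-matriline study panel from its printed tables (the reference FASTA is a
synthetic stand-in carrying the true alleles at the 42 variable sites).

```python
import matriloop as ml
from matriloop.diversity import compute_indices, diversity_report
from matriloop.haplotypes import collapse_haplotypes, mask_hotspots, variable_sites

fx = ml.load_paper_fixture()
masked = mask_hotspots(fx.sequences, ml.RunConfig().hotspots)
matrix = variable_sites(masked, reference=fx.reference)
assignment, table = collapse_haplotypes(matrix)

print(assignment.n_haplotypes, "haplotypes over", table.n_sites, "sites")

hvr1_assignment, hvr1_table = collapse_haplotypes(
    matrix.restrict(ml.RunConfig().hvr1_interval)
)
whole = compute_indices(assignment, table, masked, "Whole-loop")
hvr1 = compute_indices(hvr1_assignment, hvr1_table, masked, "HVR1",
                       region=ml.RunConfig().hvr1_interval)
print(diversity_report(whole, hvr1).to_string(index=False))
```

prints

```
10 haplotypes over 42 sites
    region  n_haplotypes haplotype_diversity nucleotide_diversity mean_pairwise_differences     L
      HVR1             9        0.85 (0.015)      0.0128 (0.0073)                       3.4 268.0
Whole-loop            10        0.86 (0.014)      0.0106 (0.0054)                       9.9 932.0
```

Reading: the whole loop resolves 10 haplotypes from 42 polymorphic sites
where HVR1 alone resolves 9 from 16 (two haplotypes are HVR1-identical);
haplotype diversity h barely moves (0.86 vs 0.85) while per-site diversity
π drops, because the added non-HVR1 sequence is less variable per site.
`L` is the comparable-site denominator of π — always check it before
comparing π across studies.

Founder inference (a few minutes for all 12 eligible families):

```python
results, excluded, trees = ml.run_founder_inference(
    masked, fx.pedigree, assignment, table, fx.reference, seed=1)
print(excluded)
for r in results[:2]:
    print(f"{r.family}: n={r.n_leaves} p={r.posterior_match:.4f} "
          f"ESS={r.ess:.0f} R-hat={r.rhat:.3f}")
```

```
{'Bint Karima': 'too few horses (2 < 4)', 'Nafaa': 'too few horses (3 < 4)'}
El Dahma: n=19 p=1.0000 ESS=591 R-hat=1.007
Bint El Bahreyn: n=8 p=1.0000 ESS=439 R-hat=1.003
```

Every eligible family's founder mare is inferred to carry her descendants'
shared haplotype with posterior probability ≥ 0.998 — the genetic signature
of reliable studbook records.

The same analyses are available from the shell:

```sh
matriloop all --fixture --out-dir results/fixture_run --seed 1
matriloop simulate --seed 3 --out-dir results/sim    # synthetic data + truth log
```

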