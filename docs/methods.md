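# Methods

`matriloop` analyses mitochondrial D-loop sequence data from closed,
strain-organised horse breeding programmes, where every historical family
(matriline, *rasan*) should descend from a single founder mare and therefore
carry a single maternally inherited haplotype. The pipeline has five stages:
sequence assembly onto a fixed reference coordinate system, haplotype
calling, diversity estimation, haplogroup assignment, and Bayesian inference
of the founder mare's haplotype for each family. This note records the
models, the defaults and their rationale, the numerical choices, and the
limits of what the packaged tests demonstrate.

## Coordinate system and sequence assembly

All coordinates are 1-based positions of the GenBank horse mitochondrial
genome X79547. The analysis window spans 15440–16642 and is represented as
a fixed 1203-column matrix. Two amplicons cover it: HVR1 (15440–16108) and
HVR2 (16377–16642); the intervening non-hypervariable stretch 16109–16376
is carried as 268 missing ('-') columns and treated as *missing*, never as
deletion, in every distance and likelihood computation. One exception is
deliberate: position 16371 was observed in the study panel (all ten
haplotypes carry C against reference T, and one haplotype additionally
carries a single inserted C after it), so the packaged fixture reconstructs
that column as sequence even though it falls inside the nominal gap; the
de novo amplicon-assembly path keeps the full gap block.

Each amplicon is aligned to its reference window with an affine-gap
Needleman–Wunsch pass (match +1, mismatch −1; a gap of length L costs
−4 − (L−1)). Terminal reference gaps are free, so a slightly short read
sits inside the window without penalty. Because study sequences are >98%
identical to the reference, per-sample pairwise anchoring is sufficient and
fully deterministic; no multiple alignment is needed. Insertion events are
stored off-matrix as (after-position, bases) pairs so every downstream
matrix stays rectangular, and are normalised to their 3'-most (rightmost)
equivalent placement — the HGVS convention — so an extra base in a
homopolymer or adjacent to an equal substituted base is always reported at
the highest reference position it can follow. Alignments below a
configurable identity floor (default 0.90) raise an error naming the sample;
this is the only guard against NUMT co-amplification.

The bundled reference FASTA is a synthetic stand-in for X79547: the alleles
at the 42 variable positions are the true reference alleles, the remaining
(invariant) positions carry an arbitrary fixed sequence. Every quantity the
package reports depends only on the variable columns.

## Haplotype calling

Four mutational hotspots (15585, 15597, 15604, 15650) are masked to missing
before haplotyping; masking is idempotent and configurable. A column is
polymorphic when at least two distinct non-missing states occur among the
samples plus, when a reference is supplied, the reference allele — the scan
is reference-anchored, as in outgroup-rooted variable-site tables, so a
column where every sample carries the same non-reference base still counts.
Missing characters never count as a state.

Samples are collapsed into haplotypes by exact identity of their allele
vectors over the polymorphic columns together with their insertion events;
insertions distinguish haplotypes but are excluded from the
substitution-site count. Labels (M1, M2, …) follow first appearance in
input order; the fixture's sample order follows the study's family table, so
the published labels are reproduced. A sample with a missing call at any
polymorphic site is reported as unassignable rather than wildcard-merged —
wildcard matching silently fuses haplotypes that differ only where one
sample has no data. A haplotype that occurs exactly once and differs from
every other haplotype at some mutually observed site is flagged
*discordant*: in a verified matriline every haplotype should recur, so a
unique singleton indicates a sample swap or a pedigree error.

The HVR1-restricted analysis re-runs collapsing on the sub-table inside the
configured interval `hvr1_interval` (default [15469, 15740]). The default
carries the 16 HVR1-polymorphic sites of the study panel (sites
15494–15720) and merges exactly the two whole-loop haplotypes that are
HVR1-identical; the typeset shading that fixed the original bound is not
recoverable from text, so the interval is configuration, not code.

## Diversity indices

Unbiased haplotype diversity follows Nei (1987):

    h = n (1 − Σ p_i²) / (n − 1)

with sampling variance

    V(h) = 2/(n(n−1)) · [ 2(n−2)(Σp_i³ − (Σp_i²)²) + Σp_i² − (Σp_i²)² ].

Mean pairwise differences k are computed either directly over all C(n,2)
sample pairs or in closed form Σ n_a n_b d_ab / C(n,2) from haplotype counts
and the haplotype distance matrix; the two routes are tested for equality.
Distances use pairwise deletion: a site contributes to d and to the
comparable-site count L only when both sequences carry non-missing bases.
Nucleotide diversity is π = k/L with the Nei/Tajima variance approximation;
L is reported with every π because the comparable-site denominator is a
convention (here: the mean over sample pairs of mutually non-missing
columns — 932 for the whole-loop fixture run), and π values are only
comparable across studies when L conventions match. Display rounding (h to
2 dp, π to 4 dp, k to 1 dp) is applied in reports only; objects keep full
precision.

## Haplogroup assignment

A haplogroup panel maps labels (Cieslak-style equine nomenclature) to lists
of diagnostic motifs, each motif a set of (position, required allele) pairs;
a motif may require reference alleles, which is how nested lineages (X3
versus X3c1) are kept distinct. A haplotype receives a label when it fully
matches at least one motif of exactly one label; missing alleles fail a
motif conservatively; matches under two or more labels are reported as
ambiguous, never silently resolved. The bundled panel is a *demonstration*
panel reconstructed from the study's haplotype-to-haplogroup pairs — one
motif per member haplotype, its variant alleles plus the minimal
reference-allele requirements that exclude all other study haplotypes. It
is not an authoritative motif catalogue; users analysing new data should
supply one (JSON or TSV).

## Founder-haplotype inference

**Eligibility.** Only terminal pedigree-line individuals enter the
analysis: every sampled individual that is the dam or grand-dam of another
sampled individual is dropped (the proximal member of a direct pair), and
families with fewer than four remaining individuals are excluded with the
reason recorded.

**Model.** Within each family the retained leaves carry one identical
haplotype, so the topology below the family's most recent common ancestor
is unidentifiable and is fixed to a star: each leaf attaches directly to
the MRCA (the founder proxy), the MRCA attaches to the root, and the
reference sequence X79547 hangs off the root as the outgroup, over the same
1203-column window. Substitution follows the general time-reversible (GTR)
model with the rate matrix scaled to one expected substitution per site per
unit branch length; missing data (the gap block and masked hotspots)
integrate to one over the alphabet. The likelihood is the exact Felsenstein
pruning likelihood over pattern-compressed sites; the production evaluator
exploits the star shape (per-leaf factor caching, reversibility-based
re-rooting at the MRCA) and is tested for equality against the general
pruning implementation, which in turn is tested against exhaustive
enumeration over internal-node states on all trees with up to six leaves.

**Priors and sampling.** Branch lengths have independent exponential
priors with mean 0.1 substitutions/site (diffuse relative to the observed
divergence, proper, and recoverable by a prior-only run); exchangeabilities
and stationary frequencies have flat Dirichlet priors. A random-scan
Metropolis–Hastings sampler runs 2 independent chains of 100,000 iterations
(25% burn-in, thinning 10, ~15,000 retained draws): 80% of moves rescale
one branch multiplicatively (log-uniform multiplier, window set for ~50%
acceptance), 10% propose exchangeabilities and 10% frequencies from a
Dirichlet centred on the current value (concentration 30) with the exact
Hastings correction. Chains are seeded from a single spawned seed sequence,
so runs are bit-reproducible.

**Founder states.** Following the Bayesian ancestral-state approach of
Huelsenbeck and Bollback, each retained draw also samples the MRCA state at
every analysed variable site from its exact conditional distribution given
the leaves, the outgroup and the drawn parameters — by reversibility this
is proportional to π_s · Π_i P(s→x_i; t_i) · P(s→x_og; t_MRCA + t_og). The
reported posterior probability is the fraction of drawn founder state
vectors equal to the descendants' shared haplotype at *all* analysed
variable sites (a joint match, stricter than any per-site summary), with
Monte-Carlo standard error sqrt(p(1−p)/ESS). If a family's leaves are not
monomorphic the majority haplotype is used and the output carries a
warning.

**Convergence.** Every run reports effective sample size and split-chain
R-hat (computed with ArviZ) on the log-likelihood and total tree length;
a family is flagged unless R-hat < 1.01 and ESS > 200. Flags are warnings
on the output and set CLI exit code 2; they never silently alter results.
With the default settings the smallest fixture families occasionally sit
near these thresholds while their posterior probabilities are numerically
stable at 1.0.

## Synthetic data generator

The simulator emulates the assumed data-generating process, with defaults
mirroring the study design: 14 matrilines with family sizes
1 + Poisson(mean−1), mean 9 (126 expected sampled descendants), pedigree
depth capped at 15 generations (the documented studbook depth); each new
individual picks its dam uniformly among family members above the depth
cap, producing a mixture of chains and stars. Transmission applies
independent per-site substitutions at 10⁻⁶ per meiosis (the order of equine
control-region germline estimates), a ×10 multiplier at the four hotspot
positions, and single-base indels at 10⁻⁷; heteroplasmy, paternal leakage
and recombination are not modelled, and there is no coalescent history
above the founders. Pedigree errors are recorded-family label swaps only —
the two error modes the analysis can detect (wrong horse sampled, wrong
pedigree) are observationally identical at the haplotype level. Every
injected event is written to a truth log, from which tests recover the
configured rates (chi-square goodness of fit on hotspot versus background
mutation counts, binomial check on the error rate).

What the generator does *not* emulate bounds what passing tests show:
real chromatogram noise, primer artefacts, NUMT co-amplification beyond the
identity floor, heteroplasmic positions, and realistic site-specific rate
variation beyond the four-hotspot dichotomy are all absent. Tests passing
on synthetic data demonstrate correctness of the estimators and samplers
under the stated model, not robustness to those artefacts.

## Numerical choices and degenerate inputs

- P(t) = exp(Qt) is computed from the symmetrised eigendecomposition of Q
  (exact for reversible models); rows are clipped to non-negative and
  renormalised against rounding error, and row sums are tested to 1e−10.
- Pattern compression drops all-missing columns (their likelihood factor is
  exactly 1).
- The pruning-versus-enumeration tolerance is 1e−10 in log space; alignment
  scores are compared exactly against an independent memoized DP.
- Alignment traceback prefers substitution over gap states on ties; indel
  events are then 3'-normalised, so tie placement cannot leak through.
- Degenerate inputs fail loudly: empty sequence sets, samples missing from
  the pedigree, pedigree cycles, founderless families, single-family error
  injection, n < 2 for diversity, L = 0 for π, chains that retain fewer
  than 1000 draws.

## Known limitations

- The founder posterior conditions on the star topology; it does not
  average over within-family tree shapes (immaterial for monomorphic
  families, which is the designed use case).
- The comparable-site denominator L, and hence π, depends on the missing-
  data convention; cross-study π comparisons need care.
- The demonstration haplogroup panel can only reproduce the study's own
  assignments; it has no power for haplotypes outside that panel.
- The identity floor is the only NUMT defence; heavily diverged nuclear
  copies below it are excluded, chimeric reads are not detected.
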