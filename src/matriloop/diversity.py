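"""Nei (1987) diversity indices for haplotype data.

Implements the unbiased haplotype diversity

    h = n (1 - sum_i p_i^2) / (n - 1)

with its sampling variance (Nei 1987, eq. 8.12), the mean number of pairwise
nucleotide differences

    k = sum_{i<j} d_ij / C(n, 2)

computed either directly over sample pairs or in closed form from haplotype
counts (k = sum_{a<b} n_a n_b d_ab / C(n,2)), and nucleotide diversity
pi = k / L with L the number of comparable (mutually non-missing) sites.
Missing data are handled by pairwise deletion: a site contributes to d and L
only when both sequences carry a non-missing base there.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from math import sqrt
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .haplotypes import HaplotypeAssignment, VariableSiteTable
from .reference import MISSING
from .sequences import DloopSequence


def haplotype_diversity(counts: Mapping[str, int] | Sequence[int]) -> tuple[float, float]:
    """Unbiased haplotype diversity and its standard error.

    ``counts`` maps haplotype label to member count (or is a bare count
    sequence).  Requires n >= 2.
    """
    values = list(counts.values()) if isinstance(counts, Mapping) else list(counts)
    if not values or any(c < 1 for c in values):
        raise ValueError("haplotype counts must be non-empty and positive")
    n = sum(values)
    if n < 2:
        raise ValueError("haplotype diversity undefined for n < 2")
    p = np.asarray(values, dtype=float) / n
    sum2 = float(np.sum(p**2))
    sum3 = float(np.sum(p**3))
    h = n * (1.0 - sum2) / (n - 1)
    var = (
        2.0
        / (n * (n - 1))
        * (2.0 * (n - 2) * (sum3 - sum2**2) + sum2 - sum2**2)
    )
    return h, sqrt(max(var, 0.0))


def hamming(a: str, b: str) -> int:
    """Differences over mutually non-missing characters (pairwise deletion)."""
    return sum(
        x != y for x, y in zip(a, b) if x not in MISSING and y not in MISSING
    )


def haplotype_distance_matrix(table: VariableSiteTable) -> pd.DataFrame:
    labels = list(table.haplotypes)
    d = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for a, b in itertools.combinations(labels, 2):
        dist = hamming(table.haplotypes[a], table.haplotypes[b])
        d.loc[a, b] = d.loc[b, a] = dist
    return d


def mean_pairwise_differences(
    assignment: HaplotypeAssignment, table: VariableSiteTable
) -> float:
    """k from haplotype counts and definitions (closed form over classes)."""
    n = assignment.n_samples
    if n < 2:
        raise ValueError("need at least two samples")
    d = haplotype_distance_matrix(table)
    total = 0.0
    for a, b in itertools.combinations(assignment.counts, 2):
        total += assignment.counts[a] * assignment.counts[b] * d.loc[a, b]
    return total / (n * (n - 1) / 2)


def mean_pairwise_differences_sequences(
    sequences: Sequence[DloopSequence],
) -> float:
    """k over all sample pairs with per-pair pairwise deletion of missing."""
    n = len(sequences)
    if n < 2:
        raise ValueError("need at least two sequences")
    total = sum(
        hamming(a.aligned, b.aligned)
        for a, b in itertools.combinations(sequences, 2)
    )
    return total / (n * (n - 1) / 2)


def comparable_sites(
    sequences: Sequence[DloopSequence], region: tuple[int, int] | None = None
) -> float:
    """Mean over sample pairs of the number of mutually non-missing columns."""
    if len(sequences) < 2:
        raise ValueError("need at least two sequences")
    blocks = [
        s.slice(*region) if region is not None else s.aligned for s in sequences
    ]
    arr = np.frombuffer("".join(blocks).encode(), dtype=np.uint8).reshape(
        len(blocks), -1
    )
    present = ~np.isin(arr, np.frombuffer(b"-N?", dtype=np.uint8))
    total = 0
    pairs = 0
    for i, j in itertools.combinations(range(len(blocks)), 2):
        total += int(np.sum(present[i] & present[j]))
        pairs += 1
    return total / pairs


def nucleotide_diversity(k: float, L: float, n: int) -> tuple[float, float]:
    """pi = k / L with Nei/Tajima sampling variance approximation."""
    if L <= 0:
        raise ValueError("L must be positive")
    if n < 2:
        raise ValueError("need n >= 2")
    pi = k / L
    var = (n + 1) / (3.0 * (n - 1) * L) * pi + (
        2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    ) * pi * pi
    return pi, sqrt(max(var, 0.0))


@dataclass(frozen=True)
class DiversityIndices:
    region: str
    n_samples: int
    n_haplotypes: int
    haplotype_diversity: float
    haplotype_diversity_se: float
    nucleotide_diversity: float
    nucleotide_diversity_se: float
    mean_pairwise_differences: float
    n_sites: float  # comparable-site denominator L actually used

    def __post_init__(self) -> None:
        if not 0.0 <= self.haplotype_diversity <= 1.0 + 1e-12:
            raise ValueError("haplotype diversity outside [0, 1]")
        if self.mean_pairwise_differences < 0:
            raise ValueError("k must be non-negative")
        if self.n_haplotypes > self.n_samples:
            raise ValueError("more haplotypes than samples")

    def to_dict(self) -> dict:
        return {
            "region": self.region,
            "n_samples": self.n_samples,
            "n_haplotypes": self.n_haplotypes,
            "h": self.haplotype_diversity,
            "h_se": self.haplotype_diversity_se,
            "pi": self.nucleotide_diversity,
            "pi_se": self.nucleotide_diversity_se,
            "k": self.mean_pairwise_differences,
            "L": self.n_sites,
        }


def compute_indices(
    assignment: HaplotypeAssignment,
    table: VariableSiteTable,
    sequences: Sequence[DloopSequence],
    region_label: str,
    region: tuple[int, int] | None = None,
) -> DiversityIndices:
    """All indices for one analysis region.

    ``table`` must already be restricted to the region; ``region`` bounds are
    used only for the comparable-site denominator L.
    """
    h, h_se = haplotype_diversity(assignment.counts)
    k = mean_pairwise_differences(assignment, table)
    L = comparable_sites(sequences, region)
    pi, pi_se = nucleotide_diversity(k, L, assignment.n_samples)
    return DiversityIndices(
        region=region_label,
        n_samples=assignment.n_samples,
        n_haplotypes=assignment.n_haplotypes,
        haplotype_diversity=h,
        haplotype_diversity_se=h_se,
        nucleotide_diversity=pi,
        nucleotide_diversity_se=pi_se,
        mean_pairwise_differences=k,
        n_sites=L,
    )


def diversity_report(
    whole: DiversityIndices, hvr1: DiversityIndices
) -> pd.DataFrame:
    """Two-row comparison table at the display precision of the field
    (h to 2 dp, pi to 4 dp, k to 1 dp); full precision stays on the objects."""
    rows = []
    for idx in (hvr1, whole):
        rows.append(
            {
                "region": idx.region,
                "n_haplotypes": idx.n_haplotypes,
                "haplotype_diversity": f"{idx.haplotype_diversity:.2f} "
                f"({idx.haplotype_diversity_se:.3f})",
                "nucleotide_diversity": f"{idx.nucleotide_diversity:.4f} "
                f"({idx.nucleotide_diversity_se:.4f})",
                "mean_pairwise_differences": f"{idx.mean_pairwise_differences:.1f}",
                "L": f"{idx.n_sites:.1f}",
            }
        )
    return pd.DataFrame(rows)


def report_to_json(whole: DiversityIndices, hvr1: DiversityIndices) -> str:
    return json.dumps(
        {"whole_loop": whole.to_dict(), "hvr1": hvr1.to_dict()},
        indent=2,
        sort_keys=True,
    )
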