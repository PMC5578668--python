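"""Bayesian inference of founder-mare haplotypes on matrilineal pedigrees.

For each historical family the studied descendants are filtered to the
terminal pedigree lines (dropping the proximal member of any sampled
dam-daughter or grand-dam-granddaughter pair, then requiring at least four
remaining individuals).  The retained leaves are attached to the family's
most recent common ancestor node — the founder proxy — and the reference
sequence is attached at the root as the outgroup.  Within a family the
retained leaves carry one identical haplotype, so topology is
unidentifiable below the MRCA and is fixed to a star; the question the
analysis answers is purely the state at the MRCA.

A Metropolis-Hastings sampler explores branch lengths (exponential prior)
and GTR exchangeabilities and stationary frequencies (flat Dirichlet
priors) under the exact pruning likelihood.  Each retained draw also samples
the founder node's state vector from its conditional distribution given the
leaves and the drawn parameters, integrating ancestral-state uncertainty
over parameter uncertainty.  The reported posterior probability is the
fraction of drawn founder vectors that equal the descendants' shared
haplotype at every analysed variable site.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln

from .gtr import GTRParams, TransitionCalculator, encode_bases
from .haplotypes import HaplotypeAssignment, VariableSiteTable
from .pedigree import PedigreeSet
from .reference import D_LOOP_START, ReferenceSequence
from .sequences import DloopSequence

OUTGROUP_ID = "X79547"


# ---------------------------------------------------------------------------
# eligibility filtering


def select_inference_set(
    pedigree: PedigreeSet,
    sampled_ids: Sequence[str] | None = None,
    min_family: int = 4,
) -> tuple[dict[str, list[str]], dict[str, str]]:
    """Per family, the leaves eligible for founder inference.

    Drops every sampled individual that is the dam or grand-dam of another
    sampled individual (the proximal member of a direct pair), then excludes
    families with fewer than ``min_family`` remaining leaves.  Returns
    (eligible leaves per family, exclusion reasons per family).
    """
    pedigree.validate()  # raises on cycles and dangling dams
    sampled = set(
        sampled_ids if sampled_ids is not None else pedigree.sampled_ids()
    )
    proximal: set[str] = set()
    for ind_id in sampled:
        dam = pedigree.dam_of(ind_id)
        if dam is not None and dam.id in sampled:
            proximal.add(dam.id)
        granddam = pedigree.dam_of(dam.id) if dam is not None else None
        if granddam is not None and granddam.id in sampled:
            proximal.add(granddam.id)
    eligible: dict[str, list[str]] = {}
    excluded: dict[str, str] = {}
    for family in pedigree.families():
        leaves = [
            ind.id
            for ind in pedigree.members(family)
            if ind.id in sampled and ind.id not in proximal
        ]
        if len(leaves) < min_family:
            excluded[family] = f"too few horses ({len(leaves)} < {min_family})"
        else:
            eligible[family] = leaves
    return eligible, excluded


# ---------------------------------------------------------------------------
# trees


@dataclass
class TreeNode:
    """A rooted tree node; ``length`` is the branch above (0 at the root)."""

    name: str | None = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def to_newick(self) -> str:
        return f"{self._newick()};"

    def _newick(self) -> str:
        label = self.name or ""
        if self.is_leaf:
            return f"{label}:{self.length:.8g}"
        inner = ",".join(c._newick() for c in self.children)
        return f"({inner}){label}:{self.length:.8g}"


@dataclass
class MatrilineTree:
    family: str
    root: TreeNode
    mrca: TreeNode  # founder proxy
    leaf_ids: tuple[str, ...]
    outgroup_id: str

    def to_newick(self) -> str:
        return self.root.to_newick()


def build_family_tree(
    family: str,
    leaf_ids: Sequence[str],
    outgroup_id: str = OUTGROUP_ID,
    leaf_branch: float = 0.005,
    mrca_branch: float = 0.01,
    outgroup_branch: float = 0.02,
    min_leaves: int = 4,
) -> MatrilineTree:
    """Star tree of family leaves under the MRCA, outgroup at the root."""
    if len(leaf_ids) < min_leaves:
        raise ValueError(
            f"family {family!r}: {len(leaf_ids)} leaves < minimum {min_leaves}"
        )
    if len(set(leaf_ids)) != len(leaf_ids):
        raise ValueError(f"family {family!r}: duplicate leaf ids")
    mrca = TreeNode(
        name=f"{family}_founder",
        length=mrca_branch,
        children=[TreeNode(name=lid, length=leaf_branch) for lid in leaf_ids],
    )
    root = TreeNode(
        name="root",
        children=[mrca, TreeNode(name=outgroup_id, length=outgroup_branch)],
    )
    return MatrilineTree(
        family=family,
        root=root,
        mrca=mrca,
        leaf_ids=tuple(leaf_ids),
        outgroup_id=outgroup_id,
    )


# ---------------------------------------------------------------------------
# likelihood


def pruning_likelihood(
    root: TreeNode,
    patterns: Mapping[str, np.ndarray] | np.ndarray,
    params: GTRParams,
    weights: np.ndarray | None = None,
    leaf_order: Sequence[str] | None = None,
) -> float:
    """Exact GTR log-likelihood of site patterns on a rooted tree.

    ``patterns`` is either a mapping leaf name -> state index array (length
    S, -1 for missing) or an (S, n_leaves) array with ``leaf_order`` giving
    the column order.  Sites are independent; missing states integrate to
    one over the alphabet.
    """
    if isinstance(patterns, np.ndarray):
        if leaf_order is None:
            raise ValueError("leaf_order required with an array of patterns")
        patterns = {
            name: patterns[:, i] for i, name in enumerate(leaf_order)
        }
    calc = TransitionCalculator(params)
    n_sites = len(next(iter(patterns.values())))
    w = np.ones(n_sites) if weights is None else np.asarray(weights, float)

    def conditional(node: TreeNode) -> np.ndarray:
        if node.is_leaf:
            states = np.asarray(patterns[node.name], dtype=int)
            L = np.zeros((n_sites, 4))
            missing = states < 0
            L[missing, :] = 1.0
            L[np.arange(n_sites)[~missing], states[~missing]] = 1.0
            return L
        L = np.ones((n_sites, 4))
        for child in node.children:
            P = calc.probability_matrix(child.length)
            L *= conditional(child) @ P.T
        return L

    root_cond = conditional(root)
    site_lik = root_cond @ np.asarray(params.freqs)
    if np.any(site_lik <= 0):
        return float("-inf")
    return float(np.dot(w, np.log(site_lik)))


# ---------------------------------------------------------------------------
# site patterns for the star model


@dataclass(frozen=True)
class StarModelData:
    """Pattern-compressed alignment of family leaves plus outgroup."""

    leaf_ids: tuple[str, ...]
    leaf_states: np.ndarray  # (S, k) int8, -1 = missing
    outgroup_states: np.ndarray  # (S,) int8
    weights: np.ndarray  # (S,) pattern multiplicities
    analysis_pattern_index: np.ndarray  # (V,) pattern index per analysed site
    analysis_positions: tuple[int, ...]
    target_states: np.ndarray  # (V,) int8 shared-haplotype state per site

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def n_patterns(self) -> int:
        return len(self.weights)


def build_star_data(
    leaf_sequences: Sequence[DloopSequence],
    outgroup: ReferenceSequence,
    analysis_positions: Sequence[int],
    target_alleles: str,
) -> StarModelData:
    """Compress the leaf+outgroup alignment into unique site patterns."""
    rows = [encode_bases(seq.aligned) for seq in leaf_sequences]
    rows.append(encode_bases(outgroup.bases))
    matrix = np.stack(rows)  # (k+1, n_cols)
    keep = ~np.all(matrix < 0, axis=0)  # drop all-missing columns
    col_to_pattern = np.full(matrix.shape[1], -1, dtype=int)
    uniq, inverse, counts = np.unique(
        matrix[:, keep].T, axis=0, return_inverse=True, return_counts=True
    )
    col_to_pattern[keep] = inverse
    idx = []
    for pos in analysis_positions:
        p = col_to_pattern[pos - D_LOOP_START]
        idx.append(p)
    return StarModelData(
        leaf_ids=tuple(s.sample_id for s in leaf_sequences),
        leaf_states=uniq[:, :-1].astype(np.int8),
        outgroup_states=uniq[:, -1].astype(np.int8),
        weights=counts.astype(float),
        analysis_pattern_index=np.asarray(idx, dtype=int),
        analysis_positions=tuple(analysis_positions),
        target_states=encode_bases(target_alleles),
    )


# ---------------------------------------------------------------------------
# MCMC


@dataclass(frozen=True)
class ChainConfig:
    n_iterations: int = 100_000
    burn_in: float = 0.25
    thin: int = 10
    n_chains: int = 2
    branch_prior_mean: float = 0.1
    branch_proposal_scale: float = 5.0
    dirichlet_concentration: float = 30.0
    ess_threshold: float = 200.0
    rhat_threshold: float = 1.01

    def __post_init__(self) -> None:
        if self.n_iterations <= 0:
            raise ValueError("chain length must be positive")
        if not 0 <= self.burn_in < 1:
            raise ValueError("burn-in fraction must be in [0, 1)")
        if self.thin < 1 or self.n_chains < 1:
            raise ValueError("thin and n_chains must be >= 1")


@dataclass
class PosteriorSamples:
    """Retained draws from all chains of one family's sampler."""

    family: str
    leaf_ids: tuple[str, ...]
    analysis_positions: tuple[int, ...]
    target_states: np.ndarray
    founder_states: np.ndarray  # (n_chains, n_retained, V) int8
    log_likelihood: np.ndarray  # (n_chains, n_retained)
    tree_length: np.ndarray  # (n_chains, n_retained)
    branch_lengths: np.ndarray  # (n_chains, n_retained, k + 2)
    acceptance_rate: float
    monomorphic: bool = True

    @property
    def n_retained(self) -> int:
        return self.founder_states.shape[1]


class _StarSampler:
    """One MH chain over branch lengths and GTR parameters on the star tree.

    State layout: branches[0:k] = leaf branches, branches[k] = MRCA-to-root,
    branches[k+1] = root-to-outgroup.  Under reversibility the likelihood
    depends on the outgroup path only through branches[k] + branches[k+1];
    both are kept so their prior mass is honest.
    """

    def __init__(self, data: StarModelData, config: ChainConfig, rng):
        self.data = data
        self.cfg = config
        self.rng = rng
        k = data.n_leaves
        self.k = k
        # row i of the states matrix: leaf i (i < k) or the outgroup (i = k)
        self.states = np.concatenate(
            [data.leaf_states.T, data.outgroup_states[None, :]], axis=0
        ).astype(int)
        self.missing = self.states < 0
        self.states_clipped = np.clip(self.states, 0, 3)
        self.branches = rng.exponential(config.branch_prior_mean, size=k + 2)
        self.params = GTRParams(
            rates=tuple(rng.dirichlet(np.full(6, 10.0))),
            freqs=tuple(rng.dirichlet(np.full(4, 10.0))),
        )
        self._rebuild_all()

    # -- likelihood bookkeeping ------------------------------------------

    def _effective_lengths(self) -> np.ndarray:
        """Per-row branch lengths; the outgroup row spans MRCA-root-outgroup."""
        return np.append(
            self.branches[: self.k], self.branches[self.k] + self.branches[self.k + 1]
        )

    def _rebuild_all(self) -> None:
        self.calc = TransitionCalculator(self.params)
        P_stack = self.calc.probability_matrices(self._effective_lengths())
        # fact[i, p, s] = P_i(s -> observed state of row i in pattern p)
        self.fact = P_stack[
            np.arange(self.k + 1)[:, None], :, self.states_clipped
        ]
        self.fact[self.missing] = 1.0
        self._refresh_product()

    def _set_factor(self, i: int) -> None:
        """Refresh one row after its effective branch length changed."""
        t = self._effective_lengths()[i]
        P = self.calc.probability_matrix(t)
        F = P[:, self.states_clipped[i]].T.copy()
        F[self.missing[i]] = 1.0
        self.fact[i] = F

    def _refresh_product(self) -> None:
        self.prod = self.fact.prod(axis=0)  # (S, 4)
        pi = np.asarray(self.params.freqs)
        site_lik = self.prod @ pi
        if self.data.n_patterns and np.any(site_lik <= 0):
            self.loglik = float("-inf")
        else:
            self.loglik = (
                float(self.data.weights @ np.log(site_lik))
                if self.data.n_patterns
                else 0.0
            )

    def log_prior_branches(self, branches: np.ndarray) -> float:
        return -float(branches.sum()) / self.cfg.branch_prior_mean

    # -- moves -------------------------------------------------------------

    def step(self) -> bool:
        # random scan: mostly branch updates, a fixed share of GTR updates
        u = self.rng.random()
        if u < 0.8:
            return self._branch_move(int(self.rng.integers(self.k + 2)))
        if u < 0.9:
            return self._simplex_move("rates")
        return self._simplex_move("freqs")

    def _branch_move(self, i: int) -> bool:
        old = self.branches[i]
        factor = np.exp(
            self.cfg.branch_proposal_scale * (self.rng.random() - 0.5)
        )
        new = old * factor
        delta_prior = -(new - old) / self.cfg.branch_prior_mean
        old_fact = self.fact[min(i, self.k)].copy()
        old_loglik = self.loglik
        self.branches[i] = new
        self._set_factor(min(i, self.k))
        self._refresh_product()
        log_accept = (self.loglik - old_loglik) + delta_prior + np.log(factor)
        if np.log(self.rng.random()) < log_accept:
            return True
        self.branches[i] = old
        self.fact[min(i, self.k)] = old_fact
        self._refresh_product()
        return False

    def _simplex_move(self, which: str) -> bool:
        current = np.asarray(
            self.params.rates if which == "rates" else self.params.freqs
        )
        conc = self.cfg.dirichlet_concentration
        proposal = self.rng.dirichlet(conc * current)
        if np.any(proposal < 1e-8):
            return False
        # flat prior on the simplex: only the Hastings ratio enters
        log_hastings = _dirichlet_logpdf(
            current, conc * proposal
        ) - _dirichlet_logpdf(proposal, conc * current)
        old_params = self.params
        old_loglik = self.loglik
        old_fact = self.fact.copy()
        old_calc = self.calc
        try:
            self.params = (
                GTRParams(rates=tuple(proposal), freqs=old_params.freqs)
                if which == "rates"
                else GTRParams(rates=old_params.rates, freqs=tuple(proposal))
            )
        except ValueError:
            self.params = old_params
            return False
        self._rebuild_all()
        log_accept = (self.loglik - old_loglik) + log_hastings
        if np.log(self.rng.random()) < log_accept:
            return True
        self.params = old_params
        self.calc = old_calc
        self.fact = old_fact
        self._refresh_product()
        return False

    # -- founder-state draw -------------------------------------------------

    def draw_founder_states(self) -> np.ndarray:
        """Sample the MRCA state at each analysed site from its conditional
        distribution given leaves, outgroup and current parameters."""
        pi = np.asarray(self.params.freqs)
        V = len(self.data.analysis_pattern_index)
        out = np.empty(V, dtype=np.int8)
        if V == 0:
            return out
        post = pi[None, :] * self.prod  # (S, 4) unnormalised
        post = post / post.sum(axis=1, keepdims=True)
        probs = post[self.data.analysis_pattern_index]  # (V, 4)
        u = self.rng.random(V)
        out = (u[:, None] > probs.cumsum(axis=1)).sum(axis=1).astype(np.int8)
        return out


def _dirichlet_logpdf(x: np.ndarray, alpha: np.ndarray) -> float:
    return float(
        gammaln(alpha.sum())
        - gammaln(alpha).sum()
        + ((alpha - 1) * np.log(x)).sum()
    )


def mcmc_sample(
    data: StarModelData,
    config: ChainConfig,
    seed: int,
    family: str = "",
) -> PosteriorSamples:
    """Run the configured number of independent chains and collect draws."""
    burn = int(config.n_iterations * config.burn_in)
    n_retained = (config.n_iterations - burn) // config.thin
    if n_retained < 1:
        raise ValueError("chain settings retain no samples")
    k = data.n_leaves
    V = len(data.analysis_pattern_index)
    founder = np.empty((config.n_chains, n_retained, V), dtype=np.int8)
    loglik = np.empty((config.n_chains, n_retained))
    tree_len = np.empty((config.n_chains, n_retained))
    branch_samples = np.empty((config.n_chains, n_retained, k + 2))
    accepted = total = 0
    seeds = np.random.SeedSequence(seed).spawn(config.n_chains)
    for c in range(config.n_chains):
        rng = np.random.default_rng(seeds[c])
        sampler = _StarSampler(data, config, rng)
        kept = 0
        for it in range(config.n_iterations):
            accepted += sampler.step()
            total += 1
            if it >= burn and (it - burn) % config.thin == 0 and kept < n_retained:
                founder[c, kept] = sampler.draw_founder_states()
                loglik[c, kept] = sampler.loglik
                tree_len[c, kept] = sampler.branches.sum()
                branch_samples[c, kept] = sampler.branches
                kept += 1
    return PosteriorSamples(
        family=family,
        leaf_ids=data.leaf_ids,
        analysis_positions=data.analysis_positions,
        target_states=data.target_states,
        founder_states=founder,
        log_likelihood=loglik,
        tree_length=tree_len,
        branch_lengths=branch_samples,
        acceptance_rate=accepted / max(total, 1),
    )


# ---------------------------------------------------------------------------
# posterior summary


@dataclass(frozen=True)
class FounderPosterior:
    family: str
    n_leaves: int
    posterior_match: float
    mc_se: float
    ess: float
    rhat: float
    converged: bool
    n_samples: int
    warning: str = ""

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "n_leaves": self.n_leaves,
            "p_founder_haplotype": self.posterior_match,
            "mc_se": self.mc_se,
            "ess": self.ess,
            "rhat": self.rhat,
            "converged": self.converged,
            "n_samples": self.n_samples,
            "warning": self.warning,
        }


def _diagnostics(samples: PosteriorSamples) -> tuple[float, float]:
    """(min ESS, max split-Rhat) over tree length and log-likelihood."""
    import arviz as az

    ess_vals = []
    rhat_vals = []
    for trace in (samples.tree_length, samples.log_likelihood):
        if np.allclose(trace.std(), 0.0):
            continue
        ess_vals.append(float(az.ess(az.convert_to_dataset(trace)).x))
        rhat_vals.append(float(az.rhat(az.convert_to_dataset(trace)).x))
    if not ess_vals:
        n = samples.founder_states.shape[0] * samples.founder_states.shape[1]
        return float(n), 1.0
    return min(ess_vals), max(rhat_vals)


def founder_posterior(
    samples: PosteriorSamples,
    target_states: np.ndarray | None = None,
    config: ChainConfig | None = None,
) -> FounderPosterior:
    """Posterior probability that the founder carried the shared haplotype."""
    cfg = config or ChainConfig()
    target = (
        np.asarray(target_states, dtype=np.int8)
        if target_states is not None
        else samples.target_states
    )
    n_total = samples.founder_states.shape[0] * samples.founder_states.shape[1]
    if n_total < 1000:
        raise ValueError("need at least 1000 post-burn-in samples")
    match = np.all(samples.founder_states == target[None, None, :], axis=2)
    p = float(match.mean())
    ess, rhat = _diagnostics(samples)
    mc_se = float(np.sqrt(max(p * (1 - p), 0.0) / max(ess, 1.0)))
    converged = (rhat < cfg.rhat_threshold) and (ess > cfg.ess_threshold)
    warning = "" if converged else "convergence diagnostics failed"
    if not samples.monomorphic:
        warning = (
            "family leaves not monomorphic; matched against majority haplotype"
            + ("; " + warning if warning else "")
        )
    return FounderPosterior(
        family=samples.family,
        n_leaves=len(samples.leaf_ids),
        posterior_match=p,
        mc_se=mc_se,
        ess=ess,
        rhat=rhat,
        converged=converged,
        n_samples=n_total,
        warning=warning,
    )


# ---------------------------------------------------------------------------
# orchestration


def run_founder_inference(
    sequences: Sequence[DloopSequence],
    pedigree: PedigreeSet,
    assignment: HaplotypeAssignment,
    table: VariableSiteTable,
    reference: ReferenceSequence,
    config: ChainConfig | None = None,
    seed: int = 0,
    min_family: int = 4,
) -> tuple[list[FounderPosterior], dict[str, str], list[MatrilineTree]]:
    """Founder-haplotype posteriors for every eligible family.

    ``sequences`` must already be hotspot-masked and ``table``/``assignment``
    derived from them.  Returns (posteriors, exclusion reasons, trees).
    """
    cfg = config or ChainConfig()
    by_id = {s.sample_id: s for s in sequences}
    eligible, excluded = select_inference_set(
        pedigree,
        sampled_ids=[s for s in by_id if s in pedigree],
        min_family=min_family,
    )
    results: list[FounderPosterior] = []
    trees: list[MatrilineTree] = []
    family_seeds = np.random.SeedSequence(seed).spawn(len(eligible))
    for fam_seed, (family, leaf_ids) in zip(family_seeds, eligible.items()):
        leaves = [by_id[i] for i in leaf_ids]
        labels = [assignment.sample_to_haplotype.get(i) for i in leaf_ids]
        counts: dict[str, int] = {}
        for lab in labels:
            if lab is not None:
                counts[lab] = counts.get(lab, 0) + 1
        shared = max(counts, key=counts.get)
        monomorphic = len(counts) == 1
        target = table.haplotypes[shared]
        data = build_star_data(leaves, reference, table.positions, target)
        trees.append(build_family_tree(family, leaf_ids, min_leaves=min_family))
        samples = mcmc_sample(
            data, cfg, seed=int(fam_seed.generate_state(1)[0] % (2**31)), family=family
        )
        samples.monomorphic = monomorphic
        results.append(founder_posterior(samples, config=cfg))
    return results, excluded, trees


def posteriors_to_tsv(results: Sequence[FounderPosterior]) -> str:
    lines = ["family\tn_leaves\tp_founder\tmc_se\tess\trhat\tconverged"]
    for r in results:
        lines.append(
            f"{r.family}\t{r.n_leaves}\t{r.posterior_match:.4f}\t"
            f"{r.mc_se:.2e}\t{r.ess:.0f}\t{r.rhat:.4f}\t"
            f"{'yes' if r.converged else 'no'}"
        )
    return "\n".join(lines) + "\n"


def posteriors_to_json(
    results: Sequence[FounderPosterior], excluded: Mapping[str, str]
) -> str:
    return json.dumps(
        {
            "families": [r.to_dict() for r in results],
            "excluded": dict(excluded),
        },
        indent=2,
        sort_keys=True,
    )
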