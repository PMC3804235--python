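"""Neutral coalescent null distributions under the selected strain's
demographic history.

The resistant strain was founded from a susceptible stock and maintained for a
known, short window of generations with per-generation effective sizes and
introgression (replacement by susceptible individuals).  Backwards in time the
simulator therefore runs

* an exact discrete Wright–Fisher phase over that window: every lineage picks
  a parent uniformly among the 2·Ne(g) chromosomes of its population (multiple
  mergers allowed), after migrating into the source population with the
  generation's introgression fraction;
* then a standard continuous-time (exponential) coalescent in the
  constant-size source population, into which all remaining focal lineages
  are absorbed at the founding of the strain.

Mutations fall on branches as a Poisson process with per-generation rate μ
per locus under the infinite-sites model.  The corrected p-value for an
observed neutrality statistic is the one-tailed empirical rank of the
observation among simulated replicates (plus-one estimator), skipping
replicates without polymorphism, where the statistic is undefined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence

import numpy as np

from .diversity_neutrality import (
    HaplotypeAlignment,
    fu_li_d_star_from_summaries,
    fu_li_f_star_from_summaries,
    site_summaries_from_counts,
    tajimas_d_from_summaries,
)

__all__ = [
    "DemographicScenario",
    "CoalescentParams",
    "CorrectedPValue",
    "selection_experiment_scenario",
    "simulate_neutral_sample",
    "simulate_site_counts",
    "corrected_pvalue",
]


@dataclass(frozen=True)
class DemographicScenario:
    """Per-generation history of the focal strain, most recent first.

    ``ne_per_generation[g]`` is the diploid effective size during generation
    ``g`` back from the present; ``introgression_per_generation[g]`` the
    fraction of the strain replaced from the source stock in that generation.
    The source population is constant at ``source_ne`` and also hosts all
    lineages before the strain was founded.
    """

    ne_per_generation: tuple
    introgression_per_generation: tuple
    source_ne: int
    sample_size: int

    def __post_init__(self):
        if len(self.ne_per_generation) != len(self.introgression_per_generation):
            raise ValueError("per-generation lists must have equal length")
        if any(ne < 2 for ne in self.ne_per_generation) or self.source_ne < 2:
            raise ValueError("all effective sizes must be >= 2")
        if any(not (0.0 <= m <= 1.0) for m in self.introgression_per_generation):
            raise ValueError("introgression fractions must lie in [0, 1]")
        if self.sample_size < 2:
            raise ValueError("sample_size must be >= 2")
        min_ne = min((*self.ne_per_generation, self.source_ne))
        if self.sample_size > 2 * min_ne:
            raise ValueError(
                f"sample_size {self.sample_size} exceeds 2*Ne at the "
                f"narrowest epoch (2*{min_ne})"
            )

    @property
    def n_generations(self) -> int:
        return len(self.ne_per_generation)


@dataclass(frozen=True)
class CoalescentParams:
    """Mutation and replication settings.

    θ = 4·Ne·μ per locus; when μ is not given it is derived from θ using the
    source population's effective size as the reference.
    """

    theta: float
    n_replicates: int = 1000
    mu: Optional[float] = None

    def __post_init__(self):
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be positive")

    def mutation_rate(self, reference_ne: int) -> float:
        if self.mu is not None:
            return self.mu
        return self.theta / (4.0 * reference_ne)


def selection_experiment_scenario(
    sample_size: int,
    n_generations: int = 20,
    ne: int = 6000,
    introgression: float = 0.025,
    bottleneck_generation: int = 10,
    bottleneck_ne: int = 600,
    rescue_introgression: float = 0.20,
    source_ne: int = 6000,
) -> DemographicScenario:
    """History of a strain selected for ``n_generations`` with steady
    introgression from the susceptible stock, a population crash at
    ``bottleneck_generation`` (forward time) and two post-crash generations
    of heavy rescue introgression.
    """
    ne_fwd = [ne] * n_generations
    mig_fwd = [introgression] * n_generations
    if 0 < bottleneck_generation <= n_generations:
        ne_fwd[bottleneck_generation - 1] = bottleneck_ne
        for g in (bottleneck_generation, bottleneck_generation + 1):
            if g < n_generations:
                mig_fwd[g] = rescue_introgression
    return DemographicScenario(
        ne_per_generation=tuple(reversed(ne_fwd)),
        introgression_per_generation=tuple(reversed(mig_fwd)),
        source_ne=source_ne,
        sample_size=sample_size,
    )


# ---------------------------------------------------------------------------
# genealogy simulation
# ---------------------------------------------------------------------------

def _simulate_tree(scenario: DemographicScenario, rng: np.random.Generator):
    """Simulate one genealogy; returns (parent, branch_len, n_leaves).

    Nodes 0..n-1 are the sampled haplotypes; internal nodes are appended as
    coalescences happen.  ``parent[i]`` is -1 for the root and
    ``branch_len[i]`` the length (generations) of the branch above node i.
    """
    n = scenario.sample_size
    parent: List[int] = [-1] * n
    node_time: List[float] = [0.0] * n
    # active lineage -> (node id, population); pop 0 = focal strain, 1 = source
    active = [(i, 0) for i in range(n)]

    def coalesce_group(members, t, pops):
        nonlocal active
        new = len(parent)
        parent.append(-1)
        node_time.append(t)
        for node, _ in members:
            parent[node] = new
        return (new, pops)

    # --- discrete Wright-Fisher window -------------------------------------
    for g in range(scenario.n_generations):
        t_child, t_parent = float(g), float(g + 1)
        mig = scenario.introgression_per_generation[g]
        if mig > 0.0:
            active = [
                (node, 1 if pop == 0 and rng.random() < mig else pop)
                for node, pop in active
            ]
        next_active = []
        for pop, two_ne in ((0, 2 * scenario.ne_per_generation[g]),
                            (1, 2 * scenario.source_ne)):
            members = [(node, p) for node, p in active if p == pop]
            if not members:
                continue
            parents = rng.integers(0, two_ne, size=len(members))
            groups: dict = {}
            for (node, p), par in zip(members, parents):
                groups.setdefault(par, []).append((node, p))
            for group in groups.values():
                if len(group) == 1:
                    next_active.append(group[0])
                else:
                    next_active.append(coalesce_group(group, t_parent, pop))
        active = next_active
        if len(active) == 1:
            break

    # --- continuous phase in the source/ancestral population ---------------
    if len(active) > 1:
        t = float(scenario.n_generations)
        k = len(active)
        nodes = [node for node, _ in active]
        two_ne = 2.0 * scenario.source_ne
        while k > 1:
            rate = k * (k - 1) / 2.0 / two_ne
            t += rng.exponential(1.0 / rate)
            i, j = rng.choice(k, size=2, replace=False)
            new = len(parent)
            parent.append(-1)
            node_time.append(t)
            parent[nodes[i]] = new
            parent[nodes[j]] = new
            nodes = [nd for idx, nd in enumerate(nodes) if idx not in (i, j)]
            nodes.append(new)
            k -= 1

    branch_len = np.zeros(len(parent))
    times = np.asarray(node_time)
    for i, par in enumerate(parent):
        if par >= 0:
            branch_len[i] = times[par] - times[i]
    return np.asarray(parent), branch_len, n


def _leaf_sets(parent: np.ndarray, n_leaves: int):
    """For each node, the number and identity of descendant leaves."""
    n_nodes = len(parent)
    sets = [set() for _ in range(n_nodes)]
    for leaf in range(n_leaves):
        node = leaf
        while node != -1:
            sets[node].add(leaf)
            node = parent[node]
    return sets


def simulate_site_counts(
    scenario: DemographicScenario,
    params: CoalescentParams,
    rng: np.random.Generator,
) -> tuple:
    """One replicate; returns (derived_counts, carriers) for each mutation.

    ``derived_counts[s]`` is the number of sampled haplotypes carrying
    mutation s; ``carriers[s]`` the frozenset of carrier indices.
    """
    mu = params.mutation_rate(scenario.source_ne)
    parent, branch_len, n = _simulate_tree(scenario, rng)
    n_mut = rng.poisson(mu * branch_len)
    if n_mut.sum() == 0:
        return np.zeros(0, dtype=int), []
    sets = _leaf_sets(parent, n)
    counts, carriers = [], []
    for node in np.nonzero(n_mut)[0]:
        leaves = sets[node]
        if 0 < len(leaves) < n:
            for _ in range(int(n_mut[node])):
                counts.append(len(leaves))
                carriers.append(frozenset(leaves))
    return np.asarray(counts, dtype=int), carriers


def simulate_neutral_sample(
    scenario: DemographicScenario,
    params: CoalescentParams,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> HaplotypeAlignment:
    """One neutral sample as an infinite-sites haplotype alignment.

    Sites are encoded A (ancestral) / T (derived), one column per mutation,
    so the alignment feeds directly into the diversity statistics.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    counts, carriers = simulate_site_counts(scenario, params, rng)
    n = scenario.sample_size
    n_sites = max(1, len(carriers))  # monomorphic sample -> single A column
    mat = np.full((n, n_sites), b"A", dtype="S1")
    for s, leaves in enumerate(carriers):
        for leaf in leaves:
            mat[leaf, s] = b"T"
    return HaplotypeAlignment(
        names=tuple(f"hap{i+1}" for i in range(n)),
        sequences=tuple(row.tobytes().decode() for row in mat),
        label="coalescent",
    )


# ---------------------------------------------------------------------------
# corrected significance
# ---------------------------------------------------------------------------

_STATISTICS: dict = {
    "D": lambda n, S, eta, eta_s, K: tajimas_d_from_summaries(n, S, K),
    "D*": lambda n, S, eta, eta_s, K: fu_li_d_star_from_summaries(n, eta, eta_s),
    "F*": lambda n, S, eta, eta_s, K: fu_li_f_star_from_summaries(n, K, eta, eta_s),
}


@dataclass
class CorrectedPValue:
    statistic: str
    observed: float
    p_value: float
    n_valid: int
    n_monomorphic: int
    two_tailed_p: float
    band: str

    @staticmethod
    def _band(p: float) -> str:
        for cut in (0.01, 0.02, 0.05):
            if p < cut:
                return f"P < {cut}"
        return "n.s."


def corrected_pvalue(
    observed: float,
    statistic: str,
    scenario: DemographicScenario,
    params: CoalescentParams,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> CorrectedPValue:
    """Empirical significance of a neutrality statistic under the scenario.

    One-tailed in the direction of the observed sign, with the plus-one
    estimator p = (#{as-or-more extreme} + 1) / (n_valid + 1).  Replicates
    with no polymorphism are skipped (the statistic is undefined there) and
    counted in ``n_monomorphic``.
    """
    if statistic not in _STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; use one of {list(_STATISTICS)}")
    if params.n_replicates < 100:
        raise ValueError("need at least 100 replicates for an empirical p")
    if rng is None:
        rng = np.random.default_rng(seed)
    fn = _STATISTICS[statistic]
    n = scenario.sample_size
    sims: List[float] = []
    n_mono = 0
    for _ in range(params.n_replicates):
        counts, _ = simulate_site_counts(scenario, params, rng)
        S, eta, eta_s, K = site_summaries_from_counts(counts, n)
        if S == 0:
            n_mono += 1
            continue
        sims.append(fn(n, S, eta, eta_s, K))
    if not sims:
        raise ValueError(
            "all replicates were monomorphic; increase theta or replicates"
        )
    sim = np.asarray(sims)
    n_valid = sim.size
    if observed >= 0:
        extreme = int(np.sum(sim >= observed))
    else:
        extreme = int(np.sum(sim <= observed))
    p = (extreme + 1) / (n_valid + 1)
    lo = int(np.sum(sim <= -abs(observed)))
    hi = int(np.sum(sim >= abs(observed)))
    p_two = min(1.0, (lo + hi + 1) / (n_valid + 1))
    return CorrectedPValue(
        statistic=statistic,
        observed=observed,
        p_value=p,
        n_valid=n_valid,
        n_monomorphic=n_mono,
        two_tailed_p=p_two,
        band=CorrectedPValue._band(p),
    )
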