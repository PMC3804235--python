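"""Synthetic data generators for every input the pipeline consumes.

The generators reproduce the statistical structure the analyses assume:

* ``simulate_pooled_experiment`` — two strains derived from a common ancestor
  drift apart for ``t`` generations of binomial Wright–Fisher sampling; a
  minority of loci additionally experience genic selection in the second
  (resistant) strain.  Read counts are drawn binomially at negative-binomial
  (overdispersed) coverage, emulating pool sequencing.
* ``simulate_genotype_panel`` — an island model: population allele
  frequencies follow the Balding–Nichols Beta distribution around a common
  ancestral frequency, individuals are binomial draws, and the population
  phenotype is a linear function of causal allele frequencies plus noise
  (every individual inherits its population's phenotype, mirroring bioassay
  LC95 values measured per population).
* ``simulate_bioassay`` — binomial deaths from a log-probit dose-mortality
  curve with optional natural control mortality.

Defaults mirror the laboratory design: Ne = 6000 with 18 + 2 generations of
divergence for the pooled experiment, and six populations of 30 individuals
for the genotype panel.  Every generator is deterministic given its seed and
ships a truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dose_response import BioassayTable
from .io_formats import GenotypeMatrix, SyncRecord

__all__ = [
    "PoolSimSpec",
    "PanelSimSpec",
    "simulate_pooled_experiment",
    "simulate_genotype_panel",
    "simulate_bioassay",
]


@dataclass
class PoolSimSpec:
    """Two-strain pooled-sequencing experiment.

    ``selection_s`` is the per-generation genic selection coefficient applied
    in strain 2 at selected loci.  Coverage is negative-binomial with the
    given mean and dispersion (smaller dispersion = more overdispersed),
    floored at ``min_coverage``.
    """

    n_snps: int = 1520
    ne: int = 6000
    t_generations: int = 20
    selected_fraction: float = 0.01
    selection_s: float = 0.5
    coverage_mean: float = 100.0
    coverage_dispersion: float = 5.0
    min_coverage: int = 10
    freq_low: float = 0.05
    freq_high: float = 0.95
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.freq_low < self.freq_high < 1.0):
            raise ValueError("ancestral frequency range must lie inside (0, 1)")
        if self.t_generations < 0:
            raise ValueError("t_generations must be >= 0")
        if not (0.0 <= self.selected_fraction <= 1.0):
            raise ValueError("selected_fraction must lie in [0, 1]")
        if self.coverage_mean < self.min_coverage:
            raise ValueError("coverage_mean must be >= min_coverage")


@dataclass
class PanelSimSpec:
    """Island-model genotype panel with population-level phenotypes."""

    n_populations: int = 6
    individuals_per_population: int = 30
    n_snps: int = 100
    fst: float = 0.10
    n_causal: int = 2
    effect_size: float = 2.0  # phenotype units per unit allele frequency
    phenotype_noise_sd: float = 0.1  # population-level noise
    individual_noise_sd: float = 0.0  # set > 0 for an exchangeable phenotype
    baseline: float = 1.0
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.fst < 1.0):
            raise ValueError("fst must lie in (0, 1)")
        if self.n_causal > self.n_snps:
            raise ValueError("causal SNPs must be a subset of the panel")
        if self.n_populations < 2:
            raise ValueError("need at least 2 populations")


def _wright_fisher_drift(p0: np.ndarray, ne: int, t: int,
                         rng: np.random.Generator,
                         s: Optional[np.ndarray] = None) -> np.ndarray:
    """Drift an array of frequencies t generations; optional genic selection."""
    p = p0.copy()
    for _ in range(t):
        if s is not None:
            p = p * (1.0 + s) / (1.0 + p * s)
        p = rng.binomial(2 * ne, p) / (2.0 * ne)
    return p


def _nb_coverage(mean: float, dispersion: float, size, minimum: int,
                 rng: np.random.Generator) -> np.ndarray:
    # negative binomial parameterized by mean and size (dispersion)
    p = dispersion / (dispersion + mean)
    cov = rng.negative_binomial(dispersion, p, size=size)
    return np.maximum(cov, minimum)


def simulate_pooled_experiment(spec: PoolSimSpec,
                               rng: Optional[np.random.Generator] = None):
    """Returns (records, truth): sync records for two pools plus the truth table.

    Truth columns: chrom, pos, p_ancestral, p_pool1, p_pool2, selected, s.
    Pool 1 is the unselected (susceptible) strain.  The reference/major
    allele is written as A, the alternative as G.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    m = spec.n_snps
    p0 = rng.uniform(spec.freq_low, spec.freq_high, size=m)
    selected = rng.random(m) < spec.selected_fraction
    s = np.where(selected, spec.selection_s, 0.0)

    p1 = _wright_fisher_drift(p0, spec.ne, spec.t_generations, rng)
    p2 = _wright_fisher_drift(p0, spec.ne, spec.t_generations, rng, s=s)

    cov = _nb_coverage(spec.coverage_mean, spec.coverage_dispersion,
                       (m, 2), spec.min_coverage, rng)
    alt1 = rng.binomial(cov[:, 0], p1)
    alt2 = rng.binomial(cov[:, 1], p2)

    records: List[SyncRecord] = []
    idx_a, idx_g = 0, 3  # slots in the A:T:C:G:N:del tuple
    for i in range(m):
        pools = []
        for alt, c in ((alt1[i], cov[i, 0]), (alt2[i], cov[i, 1])):
            counts = [0] * 6
            counts[idx_a] = int(c - alt)
            counts[idx_g] = int(alt)
            pools.append(tuple(counts))
        records.append(
            SyncRecord(chrom="sim1", pos=i + 1, ref="A", pool_counts=tuple(pools))
        )
    truth = pd.DataFrame(
        {
            "chrom": "sim1",
            "pos": np.arange(1, m + 1),
            "p_ancestral": p0,
            "p_pool1": p1,
            "p_pool2": p2,
            "selected": selected,
            "s": s,
        }
    )
    return records, truth


def simulate_genotype_panel(spec: PanelSimSpec,
                            rng: Optional[np.random.Generator] = None):
    """Returns (GenotypeMatrix, truth).

    Truth columns: snp, p_ancestral, causal, effect, plus one column of
    population frequencies per population.  QC scores are attached to the
    matrix: most SNPs pass the array thresholds, a few are drawn below them
    so the QC filter is exercised.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    P, N, M = spec.n_populations, spec.individuals_per_population, spec.n_snps
    F = spec.fst
    p_anc = rng.uniform(0.1, 0.9, size=M)
    a = p_anc * (1.0 - F) / F
    b = (1.0 - p_anc) * (1.0 - F) / F
    pop_freq = rng.beta(a, b, size=(P, M))  # populations x snps

    genotypes = rng.binomial(2, pop_freq[:, None, :], size=(P, N, M)).astype(float)
    genotypes = genotypes.reshape(P * N, M)
    if spec.missing_rate > 0:
        miss = rng.random(genotypes.shape) < spec.missing_rate
        genotypes[miss] = np.nan

    causal_idx = rng.choice(M, size=spec.n_causal, replace=False)
    effects = np.zeros(M)
    effects[causal_idx] = spec.effect_size
    pop_pheno = (
        spec.baseline
        + pop_freq[:, causal_idx] @ effects[causal_idx]
        + rng.normal(0.0, spec.phenotype_noise_sd, size=P)
    )
    phenotypes = np.repeat(pop_pheno, N)
    if spec.individual_noise_sd > 0:
        phenotypes = phenotypes + rng.normal(0.0, spec.individual_noise_sd,
                                             size=P * N)

    snp_names = [f"snp{j+1:04d}" for j in range(M)]
    # QC scores: ~5% of SNPs fail one of the array thresholds
    gc50 = np.where(rng.random(M) < 0.95, rng.uniform(0.4, 1.0, M),
                    rng.uniform(0.0, 0.35, M))
    gentrain = np.where(rng.random(M) < 0.97, rng.uniform(0.55, 1.0, M),
                        rng.uniform(0.0, 0.50, M))
    cr = 1.0 - np.mean(np.isnan(genotypes), axis=0)
    qc = pd.DataFrame(
        {"gc50": gc50, "gentrain": gentrain, "cr": cr},
        index=pd.Index(snp_names, name="snp"),
    )
    gm = GenotypeMatrix(
        individuals=[f"ind{i+1:03d}" for i in range(P * N)],
        populations=[f"pop{p+1}" for p in range(P) for _ in range(N)],
        phenotypes=phenotypes,
        snp_names=snp_names,
        genotypes=genotypes,
        qc=qc,
    )
    truth = pd.DataFrame(
        {
            "snp": snp_names,
            "p_ancestral": p_anc,
            "causal": np.isin(np.arange(M), causal_idx),
            "effect": effects,
        }
    )
    for p in range(P):
        truth[f"freq_pop{p+1}"] = pop_freq[p]
    return gm, truth


def simulate_bioassay(
    lc50: float,
    slope: float,
    doses: Sequence[float],
    n_per_dose: int,
    replicates: int = 4,
    control_mortality: float = 0.0,
    n_control: Optional[int] = None,
    population: str = "sim",
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> BioassayTable:
    """Binomial deaths from a log-probit curve with a control-mortality floor.

    Mortality at dose d is c + (1-c) * Phi(slope * (log10 d - log10 LC50)).
    Control rows (dose 0, mortality c) are included when c > 0 or n_control
    is given.
    """
    if lc50 <= 0 or slope <= 0:
        raise ValueError("lc50 and slope must be positive")
    doses = np.asarray(doses, dtype=float)
    if (doses <= 0).any():
        raise ValueError("doses must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, replicates + 1):
        if control_mortality > 0 or n_control:
            nc = n_control or n_per_dose
            rows.append(
                (0.0, nc, int(rng.binomial(nc, control_mortality)), rep)
            )
        for d in doses:
            p = control_mortality + (1.0 - control_mortality) * stats.norm.cdf(
                slope * (np.log10(d) - np.log10(lc50))
            )
            rows.append((d, n_per_dose, int(rng.binomial(n_per_dose, p)), rep))
    df = pd.DataFrame(
        rows, columns=["concentration", "n_exposed", "n_dead", "replicate"]
    )
    return BioassayTable(population=population, records=df)
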