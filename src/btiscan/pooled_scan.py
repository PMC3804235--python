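"""Pooled-sequencing genome scan: SNP filters, pool allele frequencies,
pairwise Fst, per-site Fisher exact tests, Storey q-values and empirical
outlier calling.

The scan compares read counts from two pools (e.g. a selected and a
susceptible strain).  A site is retained when, in each pool, nucleotide read
coverage reaches ``min_coverage``, the minor allele is supported by at least
``min_supporting_reads`` reads overall, and its overall frequency reaches
``min_maf``.  Differentiation per SNP is the heterozygosity-based Fst

    Fst = (pi_T - pi_S) / pi_T

with within-pool diversity corrected for finite read depth,
``pi_pool = 2 p (1-p) * c/(c-1)`` at coverage ``c``, pi_S the mean of the two
pool values and pi_T computed the same way from the pooled counts.  A SNP is
an outlier when its Fst reaches the empirical upper ``fst_tail_fraction``
quantile of all retained SNPs *and* its q-value falls below ``q_max``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import NUCLEOTIDES, RunConfig, SyncRecord

__all__ = [
    "SnpRecord",
    "ScanResult",
    "filter_sites",
    "pool_allele_freq",
    "pairwise_fst",
    "fisher_exact_site",
    "storey_qvalues",
    "detect_outliers",
    "run_scan",
]


@dataclass
class SnpRecord:
    """A retained biallelic SNP with per-pool counts and scan statistics."""

    chrom: str
    pos: int
    major_allele: str
    minor_allele: str
    pool_minor_counts: tuple  # minor-allele reads per pool
    pool_coverages: tuple  # major+minor reads per pool
    fst: float = np.nan
    fisher_p: float = np.nan
    qvalue: float = np.nan
    outlier: bool = False

    @property
    def pool_freqs(self) -> tuple:
        return tuple(
            pool_allele_freq(m, c)
            for m, c in zip(self.pool_minor_counts, self.pool_coverages)
        )


@dataclass
class ScanResult:
    snps: List[SnpRecord]
    fst_threshold: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.snps:
            rows.append(
                {
                    "chrom": s.chrom,
                    "pos": s.pos,
                    "major": s.major_allele,
                    "minor": s.minor_allele,
                    "freq_pool1": s.pool_freqs[0],
                    "freq_pool2": s.pool_freqs[1],
                    "cov_pool1": s.pool_coverages[0],
                    "cov_pool2": s.pool_coverages[1],
                    "fst": s.fst,
                    "fisher_p": s.fisher_p,
                    "qvalue": s.qvalue,
                    "outlier": s.outlier,
                }
            )
        return pd.DataFrame(rows)


def pool_allele_freq(minor_count: int, coverage: int) -> float:
    """Read-count allele frequency minor_count / coverage."""
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if not (0 <= minor_count <= coverage):
        raise ValueError("minor count must lie in [0, coverage]")
    return minor_count / coverage


def filter_sites(records: Sequence[SyncRecord], cfg: RunConfig) -> List[SnpRecord]:
    """Apply the SNP-calling filters and reduce sites to biallelic records.

    Sites with a third observed allele are dropped (no attempt to rescue);
    a site is biallelic when exactly two nucleotides carry reads.  Ties in
    total counts are broken alphabetically so output is deterministic.
    """
    if not records:
        raise ValueError("no sync records supplied")
    snps: List[SnpRecord] = []
    for rec in records:
        if rec.n_pools != 2:
            raise ValueError(
                f"{rec.chrom}:{rec.pos}: scan requires exactly 2 pools, "
                f"got {rec.n_pools}"
            )
        totals = {
            a: rec.pool_counts[0][i] + rec.pool_counts[1][i]
            for i, a in enumerate(NUCLEOTIDES)
        }
        observed = [a for a in NUCLEOTIDES if totals[a] > 0]
        if len(observed) != 2:
            continue  # monomorphic, or a real third allele -> dropped
        # major = larger total; alphabetical tie-break
        observed.sort(key=lambda a: (-totals[a], a))
        major, minor = observed
        idx = {a: NUCLEOTIDES.index(a) for a in (major, minor)}
        cov = tuple(
            rec.pool_counts[p][idx[major]] + rec.pool_counts[p][idx[minor]]
            for p in (0, 1)
        )
        minor_counts = tuple(rec.pool_counts[p][idx[minor]] for p in (0, 1))
        if min(cov) < cfg.min_coverage:
            continue
        if totals[minor] < cfg.min_supporting_reads:
            continue
        if totals[minor] / (totals[major] + totals[minor]) < cfg.min_maf:
            continue
        snps.append(
            SnpRecord(
                chrom=rec.chrom,
                pos=rec.pos,
                major_allele=major,
                minor_allele=minor,
                pool_minor_counts=minor_counts,
                pool_coverages=cov,
            )
        )
    return snps


def _pi_from_counts(minor: float, coverage: float) -> float:
    """Heterozygosity 2p(1-p) with the finite-depth correction c/(c-1)."""
    p = minor / coverage
    return 2.0 * p * (1.0 - p) * coverage / (coverage - 1.0)


def pairwise_fst(snp: SnpRecord, corrected: bool = True) -> float:
    """Heterozygosity-based Fst between the two pools, clamped to [0, 1].

    With ``corrected=False`` the finite-coverage factors c/(c-1) are dropped
    (plain 2p(1-p) heterozygosities) for sensitivity checks.
    """
    (m1, m2), (c1, c2) = snp.pool_minor_counts, snp.pool_coverages
    if c1 < 2 or c2 < 2:
        raise ValueError("Fst requires coverage >= 2 in each pool")
    if corrected:
        pi1 = _pi_from_counts(m1, c1)
        pi2 = _pi_from_counts(m2, c2)
        pi_t = _pi_from_counts(m1 + m2, c1 + c2)
    else:
        p1, p2 = m1 / c1, m2 / c2
        pbar = (m1 + m2) / (c1 + c2)
        pi1, pi2 = 2 * p1 * (1 - p1), 2 * p2 * (1 - p2)
        pi_t = 2 * pbar * (1 - pbar)
    pi_s = 0.5 * (pi1 + pi2)
    if pi_t <= 0.0:
        return 0.0
    return float(min(1.0, max(0.0, (pi_t - pi_s) / pi_t)))


def fisher_exact_site(snp: SnpRecord) -> float:
    """Two-sided Fisher exact p for the 2x2 (minor/major x pool) read table."""
    (m1, m2), (c1, c2) = snp.pool_minor_counts, snp.pool_coverages
    table = [[m1, c1 - m1], [m2, c2 - m2]]
    if min(min(row) for row in table) < 0:
        raise ValueError("negative counts in contingency table")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def storey_qvalues(p_values: Sequence[float], pi0: Optional[float] = None,
                   lam: float = 0.5) -> np.ndarray:
    """Storey q-values with the single-λ π0 estimator.

    π0 is estimated as #{p > λ} / ((1-λ) m), capped at 1 (pass ``pi0=1`` to
    reduce to Benjamini–Hochberg).  q_i = π0 · min_{t ≥ p_i} m·t / #{p ≤ t},
    order-preserving with p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        pi0 = np.sum(p > lam) / ((1.0 - lam) * m)
        pi0 = float(min(1.0, max(pi0, 1.0 / m)))
    order = np.argsort(p, kind="stable")
    q_sorted = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def detect_outliers(snps: Sequence[SnpRecord], cfg: RunConfig) -> ScanResult:
    """Flag SNPs in the upper Fst tail with small q-values.

    The Fst threshold is the empirical (1 - fst_tail_fraction) quantile with
    linear interpolation; ties at the threshold are included (>=).  The
    threshold is returned alongside the flagged records.
    """
    if not snps:
        raise ValueError("no SNPs to test")
    fst = np.array([s.fst for s in snps], dtype=float)
    q = np.array([s.qvalue for s in snps], dtype=float)
    if np.isnan(fst).any() or np.isnan(q).any():
        raise ValueError("fst and qvalue must be populated before outlier calling")
    threshold = float(np.quantile(fst, 1.0 - cfg.fst_tail_fraction))
    degenerate = np.allclose(fst, fst[0])
    flagged = []
    for s in snps:
        is_out = (not degenerate) and s.fst >= threshold and s.qvalue < cfg.q_max
        flagged.append(replace(s, outlier=bool(is_out)))
    return ScanResult(snps=flagged, fst_threshold=threshold)


def run_scan(records: Sequence[SyncRecord], cfg: RunConfig) -> ScanResult:
    """Full scan: filter -> Fst -> Fisher -> q-values -> outlier flags."""
    snps = filter_sites(records, cfg)
    if not snps:
        raise ValueError("no SNPs pass the calling filters")
    for s in snps:
        s.fst = pairwise_fst(s)
        s.fisher_p = fisher_exact_site(s)
    qvals = storey_qvalues([s.fisher_p for s in snps])
    for s, qv in zip(snps, qvals):
        s.qvalue = float(qv)
    return detect_outliers(snps, cfg)
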