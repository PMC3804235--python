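"""Validation of pool-seq allele-frequency estimates against individual
genotyping.

SNPs first pass array quality control (GC50, GenTrain and call-rate
thresholds).  For SNPs with little missing data, pooled read-count frequencies
are compared with individual dosage frequencies via Pearson's correlation, and
each SNP gets a Fisher exact test of pooled reads vs individual allele counts
(2N chromosomes), Bonferroni-corrected.  A summary block recomputes the
headline validation percentages from their integer counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenotypeMatrix

__all__ = [
    "GenotypeQC",
    "qc_filter",
    "individual_allele_freq",
    "concordance_report",
    "validation_summary",
    "ConcordanceReport",
]

QC_THRESHOLDS = {"gc50": 0.35, "gentrain": 0.50, "cr": 0.50}


@dataclass(frozen=True)
class GenotypeQC:
    """Per-SNP array quality scores."""

    snp: str
    gc50: float
    gentrain: float
    cr: float

    def __post_init__(self):
        for name in ("gc50", "gentrain", "cr"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{self.snp}: {name}={v} outside [0, 1]")

    @property
    def passes(self) -> bool:
        return (
            self.gc50 > QC_THRESHOLDS["gc50"]
            and self.gentrain > QC_THRESHOLDS["gentrain"]
            and self.cr > QC_THRESHOLDS["cr"]
        )


def qc_filter(qc: Sequence[GenotypeQC]) -> set:
    """SNPs passing all three thresholds (strict inequalities)."""
    return {rec.snp for rec in qc if rec.passes}


def individual_allele_freq(gm: GenotypeMatrix, snp) -> float:
    """Counted-allele frequency from dosages: sum(dosage) / (2 * non-missing)."""
    j = snp if isinstance(snp, (int, np.integer)) else gm.snp_names.index(snp)
    g = gm.genotypes[:, j]
    g = g[~np.isnan(g)]
    if g.size == 0:
        raise ValueError(f"SNP {snp!r}: all genotypes missing")
    return float(g.sum() / (2.0 * g.size))


@dataclass
class ConcordanceReport:
    pearson_r: float
    pearson_p: float
    n_compared: int
    per_snp: pd.DataFrame  # snp, freq_pooled, freq_individual, fisher_p, p_bonferroni
    n_discordant: int  # Bonferroni-significant frequency differences


def concordance_report(
    pooled: pd.DataFrame,
    gm: GenotypeMatrix,
    max_missing: float = 0.10,
    alpha: float = 0.05,
) -> ConcordanceReport:
    """Compare pooled and individual allele frequencies SNP by SNP.

    ``pooled`` needs columns ``snp``, ``minor_count``, ``coverage`` (reads for
    the pooled minor allele and total nucleotide coverage) and optionally
    ``counted_allele_matches`` (False when the genotype table counts the
    other allele, in which case dosages are flipped to harmonize).  Only SNPs
    present in both data sets and with a missing fraction below
    ``max_missing`` in the genotype panel are compared.
    """
    if "snp" not in pooled.columns:
        raise ValueError("pooled frame needs a 'snp' column")
    pooled = pooled.set_index("snp")
    missing_frac = dict(zip(gm.snp_names, gm.missing_fraction()))
    shared = [s for s in gm.snp_names if s in pooled.index]
    if not shared:
        raise ValueError("no overlapping SNPs between pooled and individual data")
    shared = [s for s in shared if missing_frac[s] < max_missing]
    if not shared:
        raise ValueError(
            f"no shared SNPs with missing fraction below {max_missing:.0%}"
        )

    rows = []
    for s in shared:
        minor = int(pooled.loc[s, "minor_count"])
        cov = int(pooled.loc[s, "coverage"])
        fp = minor / cov
        j = gm.snp_names.index(s)
        g = gm.genotypes[:, j]
        g = g[~np.isnan(g)]
        if (
            "counted_allele_matches" in pooled.columns
            and not bool(pooled.loc[s, "counted_allele_matches"])
        ):
            g = 2.0 - g
        dos = int(g.sum())
        chroms = 2 * g.size
        fi = dos / chroms
        table = [[minor, cov - minor], [dos, chroms - dos]]
        p = float(stats.fisher_exact(table)[1])
        rows.append((s, fp, fi, p))

    per_snp = pd.DataFrame(
        rows, columns=["snp", "freq_pooled", "freq_individual", "fisher_p"]
    )
    m = len(per_snp)
    per_snp["p_bonferroni"] = np.minimum(1.0, per_snp["fisher_p"] * m)
    if m >= 2 and per_snp["freq_pooled"].std() > 0 and per_snp["freq_individual"].std() > 0:
        r, rp = stats.pearsonr(per_snp["freq_pooled"], per_snp["freq_individual"])
    else:
        r, rp = np.nan, np.nan
    return ConcordanceReport(
        pearson_r=float(r),
        pearson_p=float(rp),
        n_compared=m,
        per_snp=per_snp,
        n_discordant=int((per_snp["p_bonferroni"] < alpha).sum()),
    )


def validation_summary(
    n_arrayed: int,
    n_genotyped: int,
    n_monomorphic_both: int,
    n_transferred: int,
    n_polymorphic_natural: int,
    n_monomorphic_recovered: int,
) -> dict:
    """Headline validation percentages from integer counts.

    * genotyping success: SNPs successfully genotyped / SNPs on the array;
    * laboratory validation: genotyped SNPs polymorphic in at least one
      laboratory strain / genotyped SNPs;
    * transferability: SNPs successfully genotyped in the second (natural)
      panel / SNPs on the array;
    * natural polymorphism: transferred SNPs polymorphic in >= 2 individuals;
    * overall validation: SNPs polymorphic in at least one data set
      (laboratory-monomorphic SNPs recovered in the second panel count) /
      SNPs on the array.

    Percentages are rounded to one decimal, the precision they are reported
    at.
    """
    if not (0 <= n_monomorphic_both <= n_genotyped <= n_arrayed):
        raise ValueError("inconsistent counts: need mono <= genotyped <= arrayed")
    if not (0 <= n_monomorphic_recovered <= n_monomorphic_both):
        raise ValueError("recovered count cannot exceed monomorphic count")
    if not (0 <= n_polymorphic_natural <= n_transferred <= n_arrayed):
        raise ValueError("inconsistent natural-panel counts")
    unvalidated = n_monomorphic_both - n_monomorphic_recovered
    return {
        "genotyping_success_pct": round(100.0 * n_genotyped / n_arrayed, 1),
        "lab_validation_pct": round(
            100.0 * (n_genotyped - n_monomorphic_both) / n_genotyped, 1
        ),
        "transferability_pct": round(100.0 * n_transferred / n_arrayed, 1),
        "natural_polymorphic_pct": round(
            100.0 * n_polymorphic_natural / n_transferred, 1
        ),
        "overall_validation_pct": round(
            100.0 * (n_arrayed - unvalidated) / n_arrayed, 1
        ),
    }
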