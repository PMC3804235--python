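#!/usr/bin/env python
"""Pooled-vs-individual allele-frequency concordance.

Builds an individual genotype panel whose allele frequencies match pool 1 of
the pooled experiment (the susceptible strain), compares pooled read-count
frequencies with individual dosage frequencies for SNPs with < 10% missing
data (Pearson r, per-SNP Fisher tests with Bonferroni correction), and
prints the validation summary percentages.  Writes
results/concordance.tsv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from btiscan.concordance import concordance_report, validation_summary
from btiscan.io_formats import GenotypeMatrix, read_sync
from btiscan.pooled_scan import filter_sites, run_scan
from btiscan.io_formats import RunConfig

def main(seed: int, out_dir: Path):
    rng = np.random.default_rng(seed)
    records = read_sync(out_dir / "data" / "pools.sync")
    cfg = RunConfig(seed=seed)
    snps = filter_sites(records, cfg)[:372]  # array-sized subset

    # individual genotyping of 58 larvae at the pool-1 frequencies
    n_ind = 58
    freqs = np.array([s.pool_minor_counts[0] / s.pool_coverages[0] for s in snps])
    geno = rng.binomial(2, freqs, size=(n_ind, len(snps))).astype(float)
    geno[rng.random(geno.shape) < 0.05] = np.nan
    gm = GenotypeMatrix(
        individuals=[f"larva{i}" for i in range(n_ind)],
        populations=["lab"] * n_ind,
        phenotypes=np.zeros(n_ind),
        snp_names=[f"{s.chrom}_{s.pos}" for s in snps],
        genotypes=geno,
    )
    pooled = pd.DataFrame(
        {
            "snp": [f"{s.chrom}_{s.pos}" for s in snps],
            "minor_count": [s.pool_minor_counts[0] for s in snps],
            "coverage": [s.pool_coverages[0] for s in snps],
        }
    )
    rep = concordance_report(pooled, gm, max_missing=0.10)
    print(f"{rep.n_compared} SNPs with <10% missing data compared")
    print(f"Pearson r = {rep.pearson_r:.3f} (p = {rep.pearson_p:.2g}); "
          f"{rep.n_discordant} SNPs discordant after Bonferroni")

    n_geno = gm.n_snps
    mono = int(
        sum(
            np.unique(col[~np.isnan(col)]).size < 2
            for col in gm.genotypes.T
        )
    )
    summary = validation_summary(
        n_arrayed=len(snps), n_genotyped=n_geno, n_monomorphic_both=mono,
        n_transferred=n_geno, n_polymorphic_natural=n_geno - mono,
        n_monomorphic_recovered=0,
    )
    for k, v in summary.items():
        print(f"{k}: {v}")
    rep.per_snp.to_csv(out_dir / "concordance.tsv", sep="\t", index=False)
    print(f"-> {out_dir/'concordance.tsv'}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    main(args.seed, args.out)
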