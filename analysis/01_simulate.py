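#!/usr/bin/env python
"""Generate every synthetic input downstream steps consume.

Emits, under results/data/:
  pools.sync / pools_truth.tsv  — two-strain pooled read counts (1520 SNPs,
                                  Ne 6000, 20 generations of divergence, ~1%
                                  of loci under selection in strain 2)
  panel.tsv / panel_qc.tsv / panel_truth.tsv — six-population island-model
                                  genotype panel with population phenotypes
  bioassays.csv                 — dose-mortality tables for a susceptible
                                  reference and five test populations
  candidate_*.fa                — neutral haplotype samples for two loci
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from btiscan.coalescent_null import (
    CoalescentParams,
    selection_experiment_scenario,
    simulate_neutral_sample,
)
from btiscan.io_formats import write_fasta_alignment, write_genotype_table, write_sync
from btiscan.synthetic_data import (
    PanelSimSpec,
    PoolSimSpec,
    simulate_bioassay,
    simulate_genotype_panel,
    simulate_pooled_experiment,
)

def main(seed: int, out_dir: Path):
    out = out_dir / "data"
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    records, truth = simulate_pooled_experiment(PoolSimSpec(seed=seed), rng)
    write_sync(records, out / "pools.sync")
    truth.to_csv(out / "pools_truth.tsv", sep="\t", index=False)
    print(f"pooled experiment: {len(records)} sites, "
          f"{int(truth.selected.sum())} under selection -> {out/'pools.sync'}")

    gm, ptruth = simulate_genotype_panel(PanelSimSpec(seed=seed), rng)
    write_genotype_table(gm, out / "panel.tsv", qc_path=out / "panel_qc.tsv")
    ptruth.to_csv(out / "panel_truth.tsv", sep="\t", index=False)
    print(f"genotype panel: {gm.n_individuals} individuals x {gm.n_snps} SNPs, "
          f"{int(ptruth.causal.sum())} causal -> {out/'panel.tsv'}")

    # bioassays: susceptible reference LC50 = 1, populations up to ~2.3x
    frames = []
    for pop, lc50 in [("BoraBora", 1.0), ("RSAL", 1.40), ("LAM", 1.88),
                      ("GRMN", 1.88), ("SAN", 2.27), ("ILA", 1.03)]:
        tbl = simulate_bioassay(lc50=lc50, slope=3.0,
                                doses=[0.4, 0.8, 1.6, 3.2, 6.4],
                                n_per_dose=25, replicates=4,
                                control_mortality=0.02, population=pop, rng=rng)
        df = tbl.records.copy()
        df.insert(0, "population", pop)
        frames.append(df)
    pd.concat(frames).to_csv(out / "bioassays.csv", index=False)
    print(f"bioassays: 6 populations -> {out/'bioassays.csv'}")

    # candidate-locus haplotypes: one neutral sample per strain and locus
    for locus, theta in (("candidate_A", 6.0), ("candidate_B", 1.5)):
        for strain in ("susceptible", "resistant"):
            sc = selection_experiment_scenario(sample_size=22)
            aln = simulate_neutral_sample(
                sc, CoalescentParams(theta=theta),
                rng=np.random.default_rng(rng.integers(2**31)),
            )
            write_fasta_alignment(aln, out / f"{locus}_{strain}.fa")
    print(f"candidate haplotypes -> {out}/candidate_*.fa")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    main(args.seed, args.out)
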