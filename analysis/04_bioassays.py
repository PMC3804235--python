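#!/usr/bin/env python
"""Probit analysis of the simulated bioassays.

Fits probit(mortality) = alpha + beta*log10(dose) per population after
Abbott's control-mortality correction, derives LC50/LC95 with Fieller
fiducial limits, and computes resistance ratios against the susceptible
reference with the dual significance rule (disjoint fiducial intervals and
ratio CI excluding 1).  Writes results/resistance_ratios.tsv.
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from btiscan.dose_response import (
    BioassayTable,
    fit_probit,
    lethal_concentration,
    resistance_ratio,
)

REFERENCE = "BoraBora"

def main(seed: int, out_dir: Path):
    df = pd.read_csv(out_dir / "data" / "bioassays.csv")
    fits = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for pop, sub in df.groupby("population"):
            fits[pop] = fit_probit(BioassayTable(pop, sub.reset_index(drop=True)))

    rows = []
    for pop, fit in fits.items():
        lc50, lo50, hi50 = lethal_concentration(fit, 0.5)
        lc95, lo95, hi95 = lethal_concentration(fit, 0.95)
        row = {"population": pop, "slope": round(fit.beta, 2),
               "LC50": round(lc50, 3), "LC50_CI": f"{lo50:.3f}-{hi50:.3f}",
               "LC95": round(lc95, 3), "LC95_CI": f"{lo95:.3f}-{hi95:.3f}",
               "h": round(fit.heterogeneity, 2)}
        if pop != REFERENCE:
            for q, tag in ((0.5, "RR50"), (0.95, "RR95")):
                rr = resistance_ratio(fit, fits[REFERENCE], q)
                row[tag] = round(rr.ratio, 2)
                row[f"{tag}_CI"] = f"{rr.ci_low:.2f}-{rr.ci_high:.2f}"
                row[f"{tag}_sig"] = rr.significant
        rows.append(row)
    table = pd.DataFrame(rows).sort_values("LC50").reset_index(drop=True)
    out = out_dir / "resistance_ratios.tsv"
    table.to_csv(out, sep="\t", index=False)
    print(table.to_string(index=False))
    print(f"-> {out}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    main(args.seed, args.out)
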