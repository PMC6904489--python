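#!/usr/bin/env python
"""Characterize behavioural variability: per-trait coefficients of
variation with their median/IQR per genotype, genotype contrasts by
Mann-Whitney U, and week-13 minus week-11 progression rates.  Reads
results/data/, writes results/phenotype/."""

from pathlib import Path

import pandas as pd

from phenoscreen import io
from phenoscreen.phenotype import cv_summary, mann_whitney, progression_rate

TRAITS = ["rotarod", "clasping", "weight"]
OUT = Path("results/phenotype")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    phen = io.read_phenotypes("results/data/phenotypes.csv")

    rows = []
    for genotype in ("wt", "mut"):
        cv, summary = cv_summary(phen, TRAITS, genotype, timepoint="wk13")
        for trait, v in cv.items():
            rows.append({"genotype": genotype, "trait": trait, "cv_pct": v})
        print(f"{genotype}: median CV {summary['median']:.1f}% "
              f"(IQR {summary['q25']:.1f}-{summary['q75']:.1f}%)")
    pd.DataFrame(rows).to_csv(OUT / "cv_by_trait.csv", index=False)

    tests = []
    for trait in TRAITS:
        wide = phen[(phen["trait"] == trait) & (phen["timepoint"] == "wk13")]
        x = wide.loc[wide["genotype"] == "mut", "value"]
        y = wide.loc[wide["genotype"] == "wt", "value"]
        u, p = mann_whitney(x, y)
        tests.append({"trait": trait, "U": u, "p": p})
        print(f"{trait}: mutant vs wt Mann-Whitney U={u:.1f}, p={p:.2e}")
    pd.DataFrame(tests).to_csv(OUT / "genotype_contrasts.csv", index=False)

    deltas = pd.DataFrame({
        t: progression_rate(phen, t, "wk13", "wk11") for t in TRAITS})
    deltas.to_csv(OUT / "progression_rates.csv")
    print(f"progression rates written for {len(deltas)} animals "
          f"(mean rotarod delta {deltas['rotarod'].mean():+.1f} s)")


if __name__ == "__main__":
    main()
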