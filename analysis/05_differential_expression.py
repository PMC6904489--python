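#!/usr/bin/env python
"""Negative-binomial Wald differential expression for the three performer
contrasts: poor vs pooled wild type, good vs pooled wild type, and poor vs
good.  Only the 16 classified animals (4 per genotype x label) are
profiled, mirroring the sequencing design.  Writes results/de/."""

from pathlib import Path

import numpy as np
import pandas as pd

from phenoscreen import io
from phenoscreen.diffexpr import call_degs, nb_wald_test

OUT = Path("results/de")
CONTRASTS = {
    "poor_vs_wt": ("poor", "wt"),
    "good_vs_wt": ("good", "wt"),
    "poor_vs_good": ("poor", "good"),
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    counts, _ = io.read_counts("results/data/counts.tsv", "results/data/meta.csv")
    labels = pd.read_csv("results/classification/labels.csv",
                         index_col="animal_id")["label"]
    genotype = pd.read_csv("results/data/meta.csv",
                           index_col="animal_id")["genotype"]
    group = pd.Series(
        np.where(genotype.loc[counts.columns] == "wt", "wt",
                 labels.loc[counts.columns]),
        index=counts.columns)
    use = labels.loc[counts.columns].isin(["good", "poor"])
    sub = counts.loc[:, use[use].index]

    for name, contrast in CONTRASTS.items():
        res = nb_wald_test(sub, group.loc[sub.columns], contrast)
        res.table.rename_axis("gene").to_csv(OUT / f"de_{name}.tsv", sep="\t")
        up, down = call_degs(res, fdr=0.05)
        print(f"{name}: {len(up)} up, {len(down)} down at FDR 0.05")


if __name__ == "__main__":
    main()
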