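#!/usr/bin/env python
"""Composite Z-score classification: orient and standardize the week-11/13
trait battery within genotype, rank animals by signed-score counts then
mean Z, and label the 4 extremes per genotype good/poor.  Checks the labels
against the planted severity ranking.  Writes results/classification/."""

import json
from pathlib import Path

import pandas as pd

from phenoscreen import io
from phenoscreen.phenotype import classify_performers, zscore_traits

OUT = Path("results/classification")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    phen = io.read_phenotypes("results/data/phenotypes.csv")
    ztable, summary = zscore_traits(phen)
    labels = classify_performers(summary, k=4)
    ztable.to_csv(OUT / "zscores.csv", index=False)
    summary.assign(label=labels.loc[summary["animal_id"]].values).to_csv(
        OUT / "animal_summary.csv", index=False)
    labels.rename_axis("animal_id").to_csv(OUT / "labels.csv")
    print(labels.value_counts().to_string())

    truth = json.loads(Path("results/data/ground_truth.json").read_text())
    sev = pd.Series(truth["severity"])
    poor = set(labels[labels == "poor"].index) & set(sev.index)
    lowest4 = set(sev.nsmallest(4).index)
    print(f"mutant 'poor' overlap with 4 lowest planted severities: "
          f"{len(poor & lowest4)}/4")


if __name__ == "__main__":
    main()
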