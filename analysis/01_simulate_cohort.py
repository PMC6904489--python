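#!/usr/bin/env python
"""Simulate the study cohort: 24 wild-type + 29 mutant males, three
behavioural traits at weeks 11/13, striatal counts for every animal, and
the planted ground truth.  Writes results/data/."""

from pathlib import Path

from phenoscreen import io
from phenoscreen.simulate import SimulationConfig, generate_cohort, generate_counts

SEED = 1
OUT = Path("results/data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(seed=SEED)
    phen, truth = generate_cohort(cfg)
    io.write_phenotypes(phen, OUT / "phenotypes.csv")
    samples = phen.drop_duplicates("animal_id")[["animal_id", "genotype"]]
    counts, _ = generate_counts(truth, samples, cfg)
    io.write_counts(counts, OUT / "counts.tsv",
                    samples.assign(tissue="striatum"), OUT / "meta.csv")
    import json

    (OUT / "ground_truth.json").write_text(
        json.dumps(truth.to_json_dict(), indent=2, sort_keys=True) + "\n")
    n = phen.groupby("genotype")["animal_id"].nunique()
    print(f"cohort: {n['wt']} wt + {n['mut']} mutant animals, "
          f"{counts.shape[0]} genes; {len(truth.signature_genes)} signature "
          f"genes ({len(truth.severity_genes)} severity-linked)")
    print(f"wrote {OUT}/phenotypes.csv, counts.tsv, meta.csv, ground_truth.json")


if __name__ == "__main__":
    main()
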