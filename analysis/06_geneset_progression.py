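#!/usr/bin/env python
"""Four-way severity gene-set partition from the three DE contrasts, a
hypergeometric over-representation check of the planted signature in each
set, the synthetic CAG x age allelic series, and the presence of each set
among the top same-direction external DEGs.  Writes results/genesets/."""

import json
from pathlib import Path

import pandas as pd

from phenoscreen import io
from phenoscreen.diffexpr import DEResult
from phenoscreen.genesets import (
    hypergeometric_ora,
    partition_gene_sets,
    progression_profile,
)
from phenoscreen.pipeline import AGE_GRID, CAG_GRID, _series_scaling
from phenoscreen.simulate import SimulationConfig, generate_external_series

SEED = 1
N_TOP = 150  # scaled to the 2000-gene synthetic universe
OUT = Path("results/genesets")


def _load(name: str) -> DEResult:
    t = pd.read_csv(f"results/de/de_{name}.tsv", sep="\t", index_col=0)
    b, a = name.split("_vs_")
    return DEResult(table=t, group_a=a, group_b=b)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    part = partition_gene_sets(_load("poor_vs_wt"), _load("good_vs_wt"),
                               _load("poor_vs_good"), fdr=0.05)
    for name, members in part.all_sets().items():
        if members:
            io.write_gene_list(members, OUT / f"{name}.txt")
        print(f"{name}: {len(members)} genes")

    truth = json.loads(Path("results/data/ground_truth.json").read_text())
    universe = set(truth["planted_log2fc"])
    signature = set(truth["signature_genes"])
    ora = []
    for name, members in part.all_sets().items():
        if not members:
            continue
        k, p = hypergeometric_ora(members, signature, universe, ease=True)
        ora.append({"set": name, "overlap": k, "ease_p": p})
        print(f"ORA {name} vs planted signature: k={k}, EASE p={p:.3g}")
    pd.DataFrame(ora).to_csv(OUT / "ora_signature.csv", index=False)

    cfg = SimulationConfig(seed=SEED)
    progressive = {}
    if part.down_poor:
        progressive["down_poor"] = (part.down_poor, -1)
    if part.up_good:
        progressive["up_good"] = (part.up_good, 1)
    if part.rest_down:
        progressive["rest_down"] = (part.rest_down, -1)
    grid = [(c, a) for c in CAG_GRID for a in AGE_GRID]
    series = generate_external_series(progressive, grid, _series_scaling(), cfg)
    io.write_series(series, OUT / "series")

    profile, mono = progression_profile(part, series, n_top=N_TOP)
    profile.to_csv(OUT / "presence.tsv", sep="\t", index=False)
    (OUT / "monotonicity.json").write_text(
        json.dumps(mono, indent=2, sort_keys=True, default=float) + "\n")
    for name, by_age in mono["vs_cag"].items():
        vals = [f"{v:.2f}" if v == v else "n/a" for v in by_age.values()]
        print(f"presence-vs-CAG rho for {name}: {', '.join(vals)} "
              f"(ages {list(by_age)})")


if __name__ == "__main__":
    main()
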