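#!/usr/bin/env python
"""Trait-expression correlation screen on the mutant striatum: Spearman and
Pearson coefficients for every trait x gene pair, regression t-test,
panel-wide BH adjustment, and flag counts — with the wild-type panel as the
negative control.  Writes results/screen/."""

from pathlib import Path

import numpy as np

from phenoscreen import io
from phenoscreen.correlation import trait_gene_screen
from phenoscreen.diffexpr import size_factors

OUT = Path("results/screen")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    phen = io.read_phenotypes("results/data/phenotypes.csv")
    counts, _ = io.read_counts("results/data/counts.tsv", "results/data/meta.csv")
    expr = np.log2(counts / size_factors(counts) + 1.0).T

    for genotype in ("mut", "wt"):
        keep = phen[phen["genotype"] == genotype]
        traits = keep.assign(col=keep["trait"] + "_" + keep["timepoint"]).pivot(
            index="animal_id", columns="col", values="value")
        res = trait_gene_screen(traits, expr.loc[traits.index],
                                tissue="striatum", genotype=genotype)
        res.to_csv(OUT / f"screen_{genotype}.tsv", sep="\t", index=False)
        print(f"{genotype}: {len(res)} tests, {int(res['tilde'].sum())} at "
              f"p<0.05 (~), {int(res['star'].sum())} at q<0.1 (*)")
    print(f"wrote {OUT}/screen_mut.tsv and screen_wt.tsv")


if __name__ == "__main__":
    main()
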