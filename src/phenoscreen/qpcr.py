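"""Relative expression from qPCR Ct tables (delta-Ct against a reference).

Each sample is normalized to a reference gene (Gapdh in the source assays):
rel = 2**-(Ct_gene - Ct_ref), assuming doubling per cycle (efficiency fixed
at 2, no standard-curve correction).  Folds are then expressed relative to
the geometric mean of a baseline group (wild type by default) within the
same tissue, so the baseline group has geometric-mean fold 1 and folds stay
strictly positive.  Because everything is a difference of Ct values, adding
a constant to all Ct of a sample (a plate shift) cancels exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["relative_expression"]


def relative_expression(
    qpcr: pd.DataFrame,
    genotypes: pd.Series | dict,
    reference_gene: str = "Gapdh",
    baseline_group: str = "wt",
) -> pd.DataFrame:
    """Per-(animal, tissue, gene) fold values, baseline-normalized.

    ``qpcr`` has columns animal_id, tissue, gene, ct; ``genotypes`` maps
    animal_id -> group label.  Returns a tidy frame with columns
    animal_id, tissue, gene, genotype, delta_ct, rel, fold.
    """
    if isinstance(genotypes, dict):
        genotypes = pd.Series(genotypes)
    df = qpcr.copy()
    df["genotype"] = df["animal_id"].map(genotypes)
    if df["genotype"].isna().any():
        missing = sorted(df.loc[df["genotype"].isna(), "animal_id"].unique())
        raise KeyError(f"animals without genotype labels: {missing[:5]}")

    ref = df[df["gene"] == reference_gene].set_index(["animal_id", "tissue"])["ct"]
    targets = df[df["gene"] != reference_gene].copy()
    key = pd.MultiIndex.from_frame(targets[["animal_id", "tissue"]])
    have_ref = key.isin(ref.index)
    if not have_ref.all():
        missing = sorted({(a, t) for a, t in key[~have_ref]})
        raise ValueError(
            f"reference gene {reference_gene!r} missing for samples: {missing[:5]}")
    targets["delta_ct"] = targets["ct"].to_numpy() - ref.loc[key].to_numpy()
    targets["rel"] = 2.0 ** (-targets["delta_ct"])

    def _norm(grp: pd.DataFrame) -> pd.DataFrame:
        base = grp.loc[grp["genotype"] == baseline_group, "rel"]
        if base.empty:
            raise ValueError(
                f"no {baseline_group!r} animals for gene {grp.name} baseline")
        gm = float(np.exp(np.log(base).mean()))
        grp = grp.copy()
        grp["fold"] = grp["rel"] / gm
        return grp

    out = (
        targets.groupby(["tissue", "gene"], group_keys=False)[targets.columns]
        .apply(_norm)
        .reset_index(drop=True)
    )
    return out[["animal_id", "tissue", "gene", "genotype", "delta_ct", "rel", "fold"]]
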