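"""End-to-end orchestration of the synthetic phenotype-to-transcriptome run.

Stage order mirrors the study: simulate (or load) the cohort, Z-score and
classify extreme performers, screen traits against expression, run the three
DE contrasts (poor vs pooled wt, good vs pooled wt, poor vs good), partition
the severity gene sets and score their progression on an allelic-series
grid.  All artifacts are plain text under the output directory, the report
is JSON plus a short human-readable summary, and a fixed seed reproduces
every deterministic output byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .correlation import trait_gene_screen
from .diffexpr import call_degs, nb_wald_test, size_factors
from .genesets import partition_gene_sets, progression_profile
from .phenotype import DEFAULT_ORIENTATIONS, classify_performers, zscore_traits
from .simulate import SimulationConfig, generate_cohort, generate_counts, generate_external_series

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

CAG_GRID = (80, 92, 111, 140, 175)  # expanded strains, scored against Q20
AGE_GRID = (2, 6, 10)  # months


@dataclass
class PipelineConfig:
    """Everything one run needs; validated before any stage executes."""

    seed: int = 0
    out_dir: str = "results/pipeline"
    phenotypes_path: str | None = None  # None -> simulate
    counts_path: str | None = None
    meta_path: str | None = None
    series_dir: str | None = None
    k: int = 4
    fdr: float = 0.05
    n_top: int = 150  # scaled to the synthetic gene universe
    family_scope: str = "panel"
    simulation: SimulationConfig | None = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")
        if self.family_scope not in ("panel", "global"):
            raise ValueError("family_scope must be 'panel' or 'global'")
        for p in (self.phenotypes_path, self.counts_path, self.series_dir):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"input not found: {p}")
        if self.simulation is None:
            self.simulation = SimulationConfig(seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = SimulationConfig(seed=cfg.seed, **sim)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _series_scaling() -> dict[tuple[int, int], float]:
    sc = {}
    for ci, cag in enumerate(CAG_GRID):
        for ai, age in enumerate(AGE_GRID):
            sc[(cag, age)] = ((ci + 1) / len(CAG_GRID) + (ai + 1) / len(AGE_GRID)) / 2
    return sc


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the report dict (also written to disk)."""
    t0 = time.perf_counter()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    report: dict = {"version": __version__, "seed": config.seed,
                    "config": {"k": config.k, "fdr": config.fdr, "n_top": config.n_top},
                    "stages": {}}

    def stage(name):
        log.info("stage %s", name)
        return report["stages"].setdefault(name, {})

    # --- cohort -----------------------------------------------------------
    st = stage("cohort")
    truth = None
    if config.phenotypes_path is None:
        phen, truth = generate_cohort(sim)
        io.write_phenotypes(phen, out / "phenotypes.csv")
        (out / "ground_truth.json").write_text(
            json.dumps(truth.to_json_dict(), indent=2, sort_keys=True) + "\n")
    else:
        phen = io.read_phenotypes(config.phenotypes_path)
    sizes = phen.groupby("genotype")["animal_id"].nunique().to_dict()
    st.update({"n_wt": int(sizes.get("wt", 0)), "n_mut": int(sizes.get("mut", 0))})

    # --- classification ---------------------------------------------------
    st = stage("classify")
    ztable, zsummary = zscore_traits(phen, DEFAULT_ORIENTATIONS)
    labels = classify_performers(zsummary, k=config.k)
    ztable.to_csv(out / "zscores.csv", index=False)
    labels.rename_axis("animal_id").to_csv(out / "labels.csv")
    st.update({lab: int((labels == lab).sum()) for lab in ("good", "poor", "average")})

    # --- expression -------------------------------------------------------
    st = stage("expression")
    genotype_of = phen.drop_duplicates("animal_id").set_index("animal_id")["genotype"]
    if config.counts_path is None:
        if truth is None:
            raise FileNotFoundError("counts_path required when phenotypes are loaded")
        samples = pd.DataFrame({"animal_id": genotype_of.index,
                                "genotype": genotype_of.values})
        counts, _ = generate_counts(truth, samples, sim)
        meta = samples.assign(label=labels.loc[samples["animal_id"]].values,
                              tissue="striatum")
        io.write_counts(counts, out / "counts.tsv", meta, out / "meta.csv")
    else:
        counts, meta = io.read_counts(config.counts_path, config.meta_path)
        if meta is None or "label" not in meta.columns:
            meta = pd.DataFrame({"animal_id": counts.columns}).merge(
                labels.rename("label").rename_axis("animal_id").reset_index())
            meta["genotype"] = genotype_of.loc[meta["animal_id"]].values
    st.update({"n_genes": int(counts.shape[0]), "n_samples": int(counts.shape[1])})

    # --- correlation screen (mutant panel) --------------------------------
    st = stage("screen")
    factors = size_factors(counts)
    logexpr = np.log2(counts / factors + 1.0).T  # samples x genes
    mut_ids = genotype_of.index[genotype_of == "mut"]
    mut_ids = [a for a in mut_ids if a in logexpr.index]
    traits_wide = phen.assign(col=phen["trait"] + "_" + phen["timepoint"]).pivot(
        index="animal_id", columns="col", values="value")
    screen = trait_gene_screen(traits_wide.loc[mut_ids], logexpr.loc[mut_ids],
                               tissue="striatum", genotype="mut")
    screen.to_csv(out / "screen.tsv", sep="\t", index=False)
    st.update({"n_tests": int(len(screen)),
               "n_tilde": int(screen["tilde"].sum()) if len(screen) else 0,
               "n_star": int(screen["star"].sum()) if len(screen) else 0})

    # --- differential expression ------------------------------------------
    st = stage("diffexpr")
    meta_idx = meta.set_index("animal_id")
    labels_col = meta_idx["label"].loc[counts.columns]
    geno_col = meta_idx["genotype"].loc[counts.columns]
    # only the classified extremes are profiled; wild types are pooled
    group = pd.Series(np.where(geno_col == "wt", "wt", labels_col),
                      index=counts.columns)
    use = labels_col.isin(["good", "poor"])
    sub_counts = counts.loc[:, use[use].index]
    sub_group = group.loc[sub_counts.columns]
    de = {}
    deg_counts = {}
    for name, contrast in {
        "poor_vs_wt": ("poor", "wt"),
        "good_vs_wt": ("good", "wt"),
        "poor_vs_good": ("poor", "good"),
    }.items():
        de[name] = nb_wald_test(sub_counts, sub_group, contrast)
        de[name].table.rename_axis("gene").to_csv(out / f"de_{name}.tsv", sep="\t")
        up, down = call_degs(de[name], fdr=config.fdr)
        deg_counts[name] = {"up": len(up), "down": len(down)}
    st.update(deg_counts)

    # --- gene-set partition -----------------------------------------------
    st = stage("partition")
    part = partition_gene_sets(de["poor_vs_wt"], de["good_vs_wt"],
                               de["poor_vs_good"], fdr=config.fdr)
    sets_dir = out / "sets"
    sets_dir.mkdir(exist_ok=True)
    for name, members in part.all_sets().items():
        path = sets_dir / f"{name}.txt"
        if members:
            io.write_gene_list(members, path)
        else:
            path.write_text("")
    st.update({name: len(members) for name, members in part.all_sets().items()})
    st["conflicts"] = len(part.conflicts)

    # --- allelic series + progression -------------------------------------
    st = stage("progression")
    if config.series_dir is not None:
        series = io.read_series(config.series_dir)
    else:
        progressive = {}
        if part.down_poor:
            progressive["down_poor"] = (part.down_poor, -1)
        if part.up_good:
            progressive["up_good"] = (part.up_good, 1)
        if part.rest_down:
            progressive["rest_down"] = (part.rest_down, -1)
        grid = [(c, a) for c in CAG_GRID for a in AGE_GRID]
        series = generate_external_series(progressive, grid, _series_scaling(), sim)
        io.write_series(series, out / "series")
    profile, mono = progression_profile(part, series, n_top=config.n_top)
    profile.to_csv(out / "presence.tsv", sep="\t", index=False)
    (out / "monotonicity.json").write_text(
        json.dumps(mono, indent=2, sort_keys=True) + "\n")
    st["n_cells"] = len(series)
    st["monotonicity_vs_cag"] = {
        s: {str(a): (None if v != v else round(v, 4)) for a, v in d.items()}
        for s, d in mono["vs_cag"].items()}

    report["elapsed_s"] = round(time.perf_counter() - t0, 2)
    (out / "report.json").write_text(
        json.dumps({k: v for k, v in report.items() if k != "elapsed_s"},
                   indent=2, sort_keys=True) + "\n")
    (out / "report.txt").write_text(_human_report(report))
    return report


def _human_report(report: dict) -> str:
    s = report["stages"]
    lines = [
        f"phenoscreen {report['version']} run (seed {report['seed']})",
        f"cohort: {s['cohort']['n_wt']} wt, {s['cohort']['n_mut']} mutant animals",
        f"labels: {s['classify']}",
        f"expression: {s['expression']['n_genes']} genes x "
        f"{s['expression']['n_samples']} samples",
        f"screen: {s['screen']['n_tests']} tests, {s['screen']['n_tilde']} at p<0.05, "
        f"{s['screen']['n_star']} at q<0.1",
        f"DEG counts: {s['diffexpr']}",
        f"gene sets: { {k: v for k, v in s['partition'].items()} }",
        f"progression cells: {s['progression']['n_cells']}",
        "",
    ]
    return "\n".join(lines)
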