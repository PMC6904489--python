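"""Synthetic cohorts with planted structure.

Emulates the design of an early-symptomatic R6/1 study: ~24 wild-type and
~29 mutant males from a few litters, a battery of behavioural traits measured
at two timepoints (weeks 11 and 13), striatal RNA-seq counts, and external
knock-in allelic-series DE tables (CAG length x age grid).

The generative model plants a single latent per-animal factor in the mutants:

* ``severity`` : s_i ~ N(0, 1), stored per mutant. LOWER values mean a worse
  phenotype ("poor" performers sit at the bottom of the scale).
* trait value = baseline + genotype_effect * is_mut + loading * s_i * is_mut
  + timepoint drift + Gaussian noise.  Wild-type animals carry no severity
  component, reproducing the genotype asymmetry of the study design.
* signature-gene counts ~ NB with mean
  base_mean * libfactor * 2**(effect_log2fc * is_mut + severity_slope * s_i),
  variance m + alpha * m**2 (alpha = 0 degenerates to Poisson).

Every public generator draws from its own pseudorandom stream, seeded from
(config.seed, call tag), so adding a generator never shifts another's output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TraitSpec",
    "SimulationConfig",
    "GroundTruth",
    "default_traits",
    "generate_cohort",
    "generate_counts",
    "generate_external_series",
]


@dataclass(frozen=True)
class TraitSpec:
    """One behavioural trait of the battery.

    orientation: +1 if a larger value means better performance (rotarod
    latency, weight), -1 if larger means worse (feet-clasping duration).
    loading is in trait units per severity s.d. and is applied to mutants
    only; its sign should align with orientation so that a low latent factor
    produces poor performance on every trait.
    """

    name: str
    orientation: int = 1
    baseline: float = 0.0
    genotype_effect: float = 0.0
    loading: float = 0.0
    noise_sd: float = 1.0
    timepoint_drift: float = 0.0  # added per timepoint index (progression)

    def __post_init__(self) -> None:
        if self.orientation not in (-1, 1):
            raise ValueError(f"orientation must be +/-1, got {self.orientation}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def default_traits(loading_scale: float = 2.0, noise_sd: float = 1.0) -> tuple[TraitSpec, ...]:
    """The three classification traits on realistic week-11/13 R6/1 scales.

    ``loading_scale``/``noise_sd`` set the planted signal-to-noise per trait
    (defaults give loading/noise = 2, the study condition used throughout).
    """
    return (
        TraitSpec("rotarod", 1, 220.0, -90.0, 20.0 * loading_scale, 20.0 * noise_sd, -15.0),
        TraitSpec("clasping", -1, 4.0, 55.0, -12.0 * loading_scale, 12.0 * noise_sd, 20.0),
        TraitSpec("weight", 1, 27.5, -3.0, 0.8 * loading_scale, 0.8 * noise_sd, -0.5),
    )


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_wt: int = 24
    n_mut: int = 29
    traits: tuple[TraitSpec, ...] = field(default_factory=default_traits)
    timepoints: tuple[str, ...] = ("wk11", "wk13")
    n_litters: int = 3
    n_genes: int = 2000
    n_signature: int = 100
    base_mean: float = 100.0
    dispersion: float = 0.05
    lib_size_range: tuple[float, float] = (0.7, 1.4)
    effect_log2fc: float = -1.0
    severity_slope: float = 0.5
    up_fraction: float = 0.3  # share of signature genes planted opposite to effect_log2fc
    severity_fraction: float = 0.6  # share of signature genes that track severity
    good_linked_fraction: float = 0.3  # share of severity genes deeper in "good" animals

    def __post_init__(self) -> None:
        if self.n_wt <= 0 or self.n_mut <= 0:
            raise ValueError("n_wt and n_mut must be positive")
        if self.n_signature > self.n_genes:
            raise ValueError("n_signature must be <= n_genes")
        if self.dispersion < 0:
            raise ValueError("dispersion (NB alpha) must be >= 0")
        if min(self.lib_size_range) <= 0:
            raise ValueError("lib_size_range must be positive")
        if not self.timepoints:
            raise ValueError("at least one timepoint required")
        if not 0.0 <= self.up_fraction <= 1.0 or not 0.0 <= self.severity_fraction <= 1.0:
            raise ValueError("up_fraction and severity_fraction must be in [0, 1]")

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


@dataclass
class GroundTruth:
    """Planted structure recorded per seed; severity only for mutants.

    ``signature_genes`` carry a planted genotype log2 fold change (a share of
    them, ``up_fraction``, in the direction opposite to ``effect_log2fc``);
    ``severity_genes`` is the subset whose expression additionally tracks the
    latent severity factor (deeper dysregulation in "poor" animals).
    """

    severity: dict[str, float]
    signature_genes: list[str]
    severity_genes: list[str]
    good_linked_genes: list[str]
    planted_log2fc: dict[str, float]
    seed: int

    def poor_linked_genes(self) -> list[str]:
        good = set(self.good_linked_genes)
        return [g for g in self.severity_genes if g not in good]

    def to_json_dict(self) -> dict:
        return {
            "seed": self.seed,
            "severity": self.severity,
            "signature_genes": self.signature_genes,
            "severity_genes": self.severity_genes,
            "good_linked_genes": self.good_linked_genes,
            "planted_log2fc": self.planted_log2fc,
        }


def _rng(config: SimulationConfig, tag: str) -> np.random.Generator:
    # one stream per (seed, call tag): adding a generator does not shift others
    return np.random.default_rng([config.seed & 0x7FFFFFFF, zlib.crc32(tag.encode())])


def _gene_ids(n_genes: int) -> list[str]:
    width = max(4, len(str(n_genes)))
    return [f"g{i:0{width}d}" for i in range(n_genes)]


def generate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate the behavioural table and record the planted ground truth.

    Returns a long-form phenotype table with columns
    (animal_id, genotype, litter, trait, timepoint, value) and the
    :class:`GroundTruth` carrying per-mutant severity, the signature gene ids
    and the planted per-gene log2 fold changes.
    """
    rng = _rng(config, "cohort")
    wt_ids = [f"wt{i:03d}" for i in range(config.n_wt)]
    mut_ids = [f"mut{i:03d}" for i in range(config.n_mut)]
    animals = wt_ids + mut_ids
    genotype = ["wt"] * config.n_wt + ["mut"] * config.n_mut
    litters = [f"litter{1 + i % config.n_litters}" for i in range(len(animals))]

    severity = rng.standard_normal(config.n_mut)
    sev_by_animal = dict(zip(mut_ids, severity))

    rows = []
    for trait in config.traits:
        for t_idx, tp in enumerate(config.timepoints):
            noise = rng.normal(0.0, trait.noise_sd, size=len(animals))
            for j, (aid, gt) in enumerate(zip(animals, genotype)):
                is_mut = gt == "mut"
                value = trait.baseline + trait.timepoint_drift * t_idx + noise[j]
                if is_mut:
                    value += trait.genotype_effect + trait.loading * sev_by_animal[aid]
                rows.append((aid, gt, litters[j], trait.name, tp, value))

    table = pd.DataFrame(
        rows, columns=["animal_id", "genotype", "litter", "trait", "timepoint", "value"]
    )

    genes = _gene_ids(config.n_genes)
    signature = sorted(rng.choice(genes, size=config.n_signature, replace=False).tolist())
    n_up = int(round(config.up_fraction * len(signature)))
    up_genes = set(rng.choice(signature, size=n_up, replace=False).tolist()) if n_up else set()
    planted = {g: 0.0 for g in genes}
    for g in signature:
        planted[g] = -config.effect_log2fc if g in up_genes else config.effect_log2fc
    n_sev = int(round(config.severity_fraction * len(signature)))
    severity_genes = (
        sorted(rng.choice(signature, size=n_sev, replace=False).tolist()) if n_sev else []
    )
    n_good = int(round(config.good_linked_fraction * len(severity_genes)))
    good_linked = (
        sorted(rng.choice(severity_genes, size=n_good, replace=False).tolist())
        if n_good else []
    )
    truth = GroundTruth(
        severity={a: float(s) for a, s in sev_by_animal.items()},
        signature_genes=signature,
        severity_genes=severity_genes,
        good_linked_genes=good_linked,
        planted_log2fc=planted,
        seed=config.seed,
    )
    return table, truth


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mean m, variance m + alpha m^2); alpha = 0 falls back to Poisson."""
    if alpha == 0:
        return rng.poisson(mean)
    size = 1.0 / alpha  # NB number-of-failures parameterization
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate_counts(
    truth: GroundTruth,
    samples: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a genes x samples count matrix for the given sample sheet.

    ``samples`` needs columns animal_id and genotype; mutant animal ids must
    appear in ``truth.severity``.  Returns (counts DataFrame indexed by gene id
    with sample columns, per-sample library factors).
    """
    required = {"animal_id", "genotype"}
    if not required.issubset(samples.columns):
        raise ValueError(f"sample sheet needs columns {sorted(required)}")
    unknown = [
        a
        for a, g in zip(samples["animal_id"], samples["genotype"])
        if g == "mut" and a not in truth.severity
    ]
    if unknown:
        raise KeyError(f"mutant animal ids not in ground truth: {unknown}")

    rng = _rng(config, "counts")
    genes = _gene_ids(config.n_genes)
    lo, hi = config.lib_size_range
    libfac = rng.uniform(lo, hi, size=len(samples))

    is_mut = (samples["genotype"] == "mut").to_numpy()
    sev = np.array(
        [truth.severity.get(a, 0.0) for a in samples["animal_id"]], dtype=float
    )
    lfc = np.array([truth.planted_log2fc[g] for g in genes])  # 0 off-signature
    sev_set = set(truth.severity_genes)
    good_set = set(truth.good_linked_genes)
    in_sev = np.array([g in sev_set for g in genes])
    # severity-linked genes deepen their dysregulation along their own
    # direction in low-score ("poor") animals; good-linked genes couple the
    # other way (deeper change in well-performing animals)
    couple = np.array([1.0 if g in good_set else -1.0 for g in genes])
    log2_shift = np.outer(lfc, is_mut.astype(float))
    sev_term = config.severity_slope * (sev * is_mut)[None, :]
    log2_shift[in_sev] += (couple * np.sign(lfc))[in_sev][:, None] * sev_term
    mean = config.base_mean * libfac[None, :] * 2.0 ** log2_shift

    counts = _nb_draw(rng, mean, config.dispersion)
    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"),
                             columns=samples["animal_id"].tolist())
    return counts_df, pd.Series(libfac, index=counts_df.columns, name="libfactor")


def generate_external_series(
    progressive_sets: dict[str, tuple[set[str], int]],
    grid: list[tuple[int, int]],
    scaling: dict[tuple[int, int], float],
    config: SimulationConfig,
    noise_sd: float = 1.0,
    effect_scale: float = 3.0,
    lfc_per_z: float = 0.25,
) -> dict[tuple[int, int], pd.DataFrame]:
    """Simulate ranked allelic-series DE tables over the full gene universe.

    ``progressive_sets`` maps a set name to (gene ids, direction +/-1); member
    genes receive a signed z-shift ``direction * effect_scale * scaling[cell]``.
    Each gene draws one z per cell: log2fc = lfc_per_z * z and
    p = 2 * Phi(-|z|), so p-rank within a direction equals |z|-rank and a zero
    scaling gives an exact uniform-rank null.  Cells are keyed (cag, age).
    """
    from scipy import stats

    genes = _gene_ids(config.n_genes)
    shift = np.zeros(config.n_genes)
    idx = {g: i for i, g in enumerate(genes)}
    out: dict[tuple[int, int], pd.DataFrame] = {}
    for cell in grid:
        rng = _rng(config, f"series_cag{cell[0]}_age{cell[1]}")
        shift[:] = 0.0
        for _, (members, direction) in progressive_sets.items():
            if direction not in (-1, 1):
                raise ValueError("set direction must be +/-1")
            for g in members:
                if g in idx:
                    shift[idx[g]] = direction * effect_scale * scaling[cell]
        z = shift + (rng.standard_normal(config.n_genes) * noise_sd if noise_sd > 0 else 0.0)
        p = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
        out[cell] = pd.DataFrame({"gene": genes, "log2fc": lfc_per_z * z, "p": p})
    return out
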