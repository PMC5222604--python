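"""Synthetic expression data with the structure the pipeline assumes.

Three generators emulate the three data regimes the selection and
detection stages are designed for:

* :func:`simulate_panel` — a targeted hybridisation-counting panel over
  8 age classes x 12 zeitgeber times x 2 replicates (192 individually
  measured samples), with per-gene circadian rhythms, age-related
  fold-changes, negative-binomial counting noise whose dispersion
  inflates with age (aging livers are transcriptionally noisier), and
  log-normal per-sample technical factors.
* :func:`simulate_rnaseq_screen` — a genome-wide screen with one pooled
  library per age class; pooling across times of day removes circadian
  structure, and log-normal baselines spanning roughly four orders of
  magnitude reproduce the wide spread of expression levels and clr
  variances seen genome-wide.
* :func:`simulate_meta_studies` — per-study fold-change magnitudes for
  the meta-analysis assessment, drawn log-normally with a per-gene
  stability scale.

Every generator takes an integer seed and is bit-reproducible; a
:class:`SimTruth` records the generating parameters so recovery tests
can compare estimates against ground truth.

The expected value of a panel count for gene g in sample s is

    baseline_g * exp(lfc_g * a(s)) * (1 + amp_g * cos(2*pi*(ZT_s - phi_g)/24)) * tech_s

where ``a(s)`` ramps linearly from 0 at the youngest to 1 at the oldest
age class, so ``lfc_g`` is the full old-versus-young log fold-change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, SampleDesign, StudyFoldChangeTable

__all__ = [
    "GeneSimParams",
    "SimTruth",
    "make_panel_design",
    "reference_panel_params",
    "simulate_panel",
    "simulate_positive_controls",
    "simulate_rnaseq_screen",
    "simulate_meta_studies",
    "DEFAULT_CANDIDATES",
    "EXTENDED_SET",
    "CORE_SET",
]

# The 16 mouse-liver candidate reference genes screened by the pipeline.
DEFAULT_CANDIDATES = (
    "Aox3", "Atp5h", "Gapdh", "S100a1", "Tspo", "Ttr", "Tomm7", "Tprkb",
    "Pqbp1", "H3f3a", "H3f3b", "Gr", "Gsk3b", "Nono", "Rora", "Sirt2",
)
CORE_SET = ("Atp5h", "Gsk3b", "Sirt2")
EXTENDED_SET = ("Atp5h", "Gsk3b", "Sirt2", "Nono", "Tprkb", "Tspo", "Ttr")

#: default ladder of spike-in control input amounts (arbitrary units)
DEFAULT_CONTROL_AMOUNTS = (0.125, 0.5, 2.0, 8.0, 32.0, 128.0)


@dataclass(frozen=True)
class GeneSimParams:
    """Generating parameters of one gene.

    ``baseline`` is the expected count at the youngest age, averaged
    over the day.  ``circadian_amplitude`` is the relative amplitude in
    [0, 1); ``acrophase_h`` the peak time in hours.
    ``age_log_fold_change`` is the log fold-change of the oldest versus
    the youngest age class.  ``dispersion`` is the negative-binomial
    overdispersion (variance = mu + dispersion * mu^2) and
    ``noise_inflation_per_age`` its linear increase per month of age,
    modelling transcriptional noise rising in old animals.
    ``condition_log_sd`` is between-condition biological variability
    (log scale) used by the pooled screen generator.
    """

    gene_id: str
    baseline: float
    circadian_amplitude: float = 0.0
    acrophase_h: float = 0.0
    age_log_fold_change: float = 0.0
    dispersion: float = 0.01
    noise_inflation_per_age: float = 0.0002
    condition_log_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError(f"baseline must be positive for {self.gene_id!r}")
        if not 0 <= self.circadian_amplitude < 1:
            raise ValueError(f"amplitude must be in [0, 1) for {self.gene_id!r}")
        if self.dispersion < 0 or self.noise_inflation_per_age < 0:
            raise ValueError(f"dispersion terms must be non-negative for {self.gene_id!r}")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of a simulated dataset, for recovery tests."""

    params: dict
    tech_factors: pd.Series | None
    stable_genes: tuple[str, ...]
    perturbed_genes: tuple[str, ...]


def make_panel_design(
    ages: Sequence[int] = (3, 6, 9, 12, 15, 18, 21, 24),
    zeitgeber_times: Sequence[float] = tuple(range(0, 24, 2)),
    replicates: int = 2,
) -> SampleDesign:
    """Balanced age x zeitgeber-time x replicate design (default 192 samples)."""
    rows = []
    for age in ages:
        for zt in zeitgeber_times:
            for rep in range(1, replicates + 1):
                rows.append(
                    {
                        "sample_id": f"a{int(age):02d}_zt{int(zt):02d}_r{rep}",
                        "age_months": int(age),
                        "zeitgeber_time_h": float(zt),
                        "replicate": rep,
                        "condition_label": f"a{int(age):02d}",
                    }
                )
    return SampleDesign(pd.DataFrame(rows))


def _rng_for(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def reference_panel_params(seed: int = 0) -> tuple[dict, tuple[str, ...], tuple[str, ...]]:
    """Generating parameters of the 52-gene reference panel.

    Composition mirrors a targeted liver panel: the 16 candidate
    reference genes plus 36 test genes (core clock genes with circadian
    amplitudes, four age-perturbed genes at 1.25-1.52-fold magnitudes,
    and arrhythmic filler genes).  Returns ``(params, stable_candidates,
    perturbed_genes)``.  Baselines are drawn reproducibly from ``seed``;
    the qualitative structure is fixed.
    """
    rng = _rng_for(seed, 900)
    params: dict[str, GeneSimParams] = {}

    stable_candidates = tuple(g for g in DEFAULT_CANDIDATES if g in EXTENDED_SET)
    for gene in DEFAULT_CANDIDATES:
        stable = gene in EXTENDED_SET
        params[gene] = GeneSimParams(
            gene_id=gene,
            baseline=float(rng.uniform(2000, 10000)) if stable else float(rng.uniform(500, 5000)),
            circadian_amplitude=0.0 if stable else float(rng.uniform(0.05, 0.25)),
            acrophase_h=float(rng.uniform(0, 24)),
            age_log_fold_change=0.0 if stable else float(rng.normal(0, 0.25)),
            dispersion=0.002 if stable else 0.02,
            noise_inflation_per_age=0.0001 if stable else 0.0004,
        )

    clock = {
        "Cry2": 0.25, "Cry1": 0.55, "Per1": 0.6, "Per2": 0.7, "Arntl": 0.8,
        "Nr1d1": 0.9, "Dbp": 0.9, "Clock": 0.2, "Per3": 0.6, "Nr1d2": 0.7,
        "Rorc": 0.4, "Ciart": 0.6,
    }
    for gene, amp in clock.items():
        params[gene] = GeneSimParams(
            gene_id=gene,
            baseline=float(rng.uniform(500, 5000)),
            circadian_amplitude=amp,
            acrophase_h=float(rng.uniform(0, 24)),
            dispersion=0.01,
        )

    perturbed = {
        "Csnk1e": np.log(1.52),
        "Glut2": np.log(0.74),
        "Sfpq": np.log(1.33),
        "Csnk1d": np.log(1.25),
    }
    for gene, lfc in perturbed.items():
        params[gene] = GeneSimParams(
            gene_id=gene,
            baseline=float(rng.uniform(800, 4000)),
            circadian_amplitude=float(rng.uniform(0.05, 0.2)),
            acrophase_h=float(rng.uniform(0, 24)),
            age_log_fold_change=float(lfc),
            dispersion=0.01,
        )

    n_filler = 52 - len(params)
    for i in range(n_filler):
        gene = f"Liv{i + 1:02d}"
        params[gene] = GeneSimParams(
            gene_id=gene,
            baseline=float(rng.uniform(200, 5000)),
            circadian_amplitude=float(rng.uniform(0.0, 0.15)),
            acrophase_h=float(rng.uniform(0, 24)),
            dispersion=0.01,
        )
    return params, stable_candidates, tuple(perturbed)


def _panel_means(
    params: Mapping[str, GeneSimParams], design: SampleDesign, tech: np.ndarray
) -> np.ndarray:
    ages = design.table["age_months"].to_numpy(dtype=float)
    zts = design.table["zeitgeber_time_h"].to_numpy(dtype=float)
    amin, amax = ages.min(), ages.max()
    scale = (ages - amin) / (amax - amin) if amax > amin else np.zeros_like(ages)
    means = np.empty((len(params), len(ages)))
    for gi, p in enumerate(params.values()):
        rhythm = 1.0 + p.circadian_amplitude * np.cos(2 * np.pi * (zts - p.acrophase_h) / 24.0)
        means[gi] = p.baseline * np.exp(p.age_log_fold_change * scale) * rhythm * tech
    if (means <= 0).any():
        raise ValueError("non-positive expected count; check amplitudes and fold-changes")
    return means


def _nb_counts(
    rng: np.random.Generator, means: np.ndarray, dispersion: np.ndarray
) -> np.ndarray:
    """Gamma-Poisson draws; dispersion 0 degenerates to Poisson."""
    disp = np.broadcast_to(dispersion, means.shape)
    lam = np.where(
        disp > 0,
        rng.gamma(np.where(disp > 0, 1.0 / np.maximum(disp, 1e-12), 1.0), means * disp, size=means.shape),
        means,
    )
    return rng.poisson(lam).astype(float)


def simulate_panel(
    design: SampleDesign,
    params: Mapping[str, GeneSimParams],
    seed: int,
    tech_sigma: float = 0.2,
) -> tuple[ExpressionMatrix, SimTruth]:
    """Simulate a targeted panel over the given design.

    Counts are negative-binomial around the mean model described in the
    module docstring, with per-gene dispersion inflated linearly with
    age; per-sample technical factors are log-normal with log-sd
    ``tech_sigma``.  Bit-reproducible for a fixed seed.
    """
    rng = _rng_for(seed, 1)
    sample_ids = design.sample_ids
    tech = np.exp(rng.normal(0.0, tech_sigma, size=len(sample_ids)))
    means = _panel_means(params, design, tech)
    ages = design.table["age_months"].to_numpy(dtype=float)
    disp = np.array(
        [[p.dispersion + p.noise_inflation_per_age * a for a in ages] for p in params.values()]
    )
    counts = _nb_counts(rng, means, disp)
    matrix = ExpressionMatrix(pd.DataFrame(counts, index=list(params), columns=sample_ids))
    stable = tuple(
        g for g, p in params.items()
        if p.circadian_amplitude == 0 and p.age_log_fold_change == 0
    )
    perturbed = tuple(g for g, p in params.items() if p.age_log_fold_change != 0)
    truth = SimTruth(
        params=dict(params),
        tech_factors=pd.Series(tech, index=sample_ids),
        stable_genes=stable,
        perturbed_genes=perturbed,
    )
    return matrix, truth


def simulate_positive_controls(
    truth: SimTruth,
    seed: int,
    expected: pd.Series | None = None,
    counts_per_unit: float = 1000.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Spike-in control counts sharing the samples' technical factors.

    Controls are present at known input amounts (a geometric ladder by
    default); observed counts are Poisson around
    ``amount * counts_per_unit * tech_factor``.  Returns ``(observed
    controls x samples, expected amounts)`` ready for
    :func:`clrnorm.normalisation.positive_control_constants` (which will
    recover constants on the ``amount * counts_per_unit`` scale).
    """
    if truth.tech_factors is None:
        raise ValueError("truth carries no technical factors")
    if expected is None:
        expected = pd.Series(
            list(DEFAULT_CONTROL_AMOUNTS),
            index=[f"POS_{chr(ord('A') + i)}" for i in range(len(DEFAULT_CONTROL_AMOUNTS))],
        )
    rng = _rng_for(seed, 2)
    tech = truth.tech_factors.to_numpy(dtype=float)
    means = expected.to_numpy(dtype=float)[:, None] * counts_per_unit * tech[None, :]
    observed = rng.poisson(means).astype(float)
    observed = pd.DataFrame(observed, index=expected.index, columns=truth.tech_factors.index)
    # the expected amounts on the count scale, so constants are near 1/tech
    return observed, expected * counts_per_unit


def simulate_rnaseq_screen(
    n_genes: int = 500,
    n_age_pools: int = 4,
    stable_fraction: float = 0.1,
    seed: int = 0,
    candidate_stable: Iterable[str] = (),
    candidate_variable: Iterable[str] = (),
    pool_ages: Sequence[int] | None = None,
) -> tuple[ExpressionMatrix, SimTruth]:
    """Genome-wide screen with one pooled library per age class.

    ``stable_fraction`` of the anonymous genes are constructed stable
    (high expression, tiny between-age variability); the rest vary
    between age classes with per-gene log-sd drawn log-normally, giving
    the characteristic spread of clr variances over several orders of
    magnitude.  Named candidates are appended with the stable or the
    variable construction; ``n_genes`` counts all genes including them.
    """
    if n_genes < 10:
        raise ValueError("need at least 10 genes for a meaningful screen")
    candidate_stable = list(candidate_stable)
    candidate_variable = list(candidate_variable)
    n_anon = n_genes - len(candidate_stable) - len(candidate_variable)
    if n_anon < 0:
        raise ValueError("more candidates than n_genes")
    rng = _rng_for(seed, 3)
    if pool_ages is None:
        pool_ages = [3 + 6 * i for i in range(n_age_pools)]
    columns = [f"pool_{a}m" for a in pool_ages]

    n_stable_anon = int(round(stable_fraction * n_anon))
    gene_ids, baselines, sds, stable_flags = [], [], [], []

    def add_stable(name: str) -> None:
        gene_ids.append(name)
        baselines.append(float(10 ** rng.uniform(2.5, 3.7)))
        sds.append(0.05)
        stable_flags.append(True)

    def add_variable(name: str, sd: float | None = None) -> None:
        gene_ids.append(name)
        baselines.append(float(10 ** rng.normal(2.0, 1.0)))
        sds.append(float(10 ** rng.normal(-0.7, 0.5)) if sd is None else sd)
        stable_flags.append(False)

    for i in range(n_stable_anon):
        add_stable(f"stab{i + 1:04d}")
    for i in range(n_anon - n_stable_anon):
        add_variable(f"gene{i + 1:04d}")
    for g in candidate_stable:
        add_stable(g)
    for g in candidate_variable:
        add_variable(g, sd=0.5)

    base = np.array(baselines)[:, None]
    jitter = np.exp(rng.normal(0.0, np.array(sds)[:, None], size=(len(gene_ids), len(columns))))
    libsize = np.exp(rng.normal(0.0, 0.3, size=len(columns)))
    means = base * jitter * libsize[None, :]
    counts = _nb_counts(rng, means, np.full_like(means, 0.01))
    matrix = ExpressionMatrix(pd.DataFrame(counts, index=gene_ids, columns=columns))
    truth = SimTruth(
        params={
            g: {"baseline": b, "condition_log_sd": s, "stable": f}
            for g, b, s, f in zip(gene_ids, baselines, sds, stable_flags)
        },
        tech_factors=pd.Series(libsize, index=columns),
        stable_genes=tuple(g for g, f in zip(gene_ids, stable_flags) if f),
        perturbed_genes=(),
    )
    return matrix, truth


def simulate_meta_studies(
    genes: Iterable[str],
    n_studies: int = 130,
    stability_profile: Mapping[str, float] | None = None,
    seed: int = 0,
    default_log_fc_sd: float = 0.05,
) -> StudyFoldChangeTable:
    """Per-study fold-change magnitudes for the meta-analysis assessment.

    Each gene's log fold-change in each study is drawn N(0, sd_g) and
    reported as the magnitude ``exp(|.|)``; ``stability_profile`` maps
    gene -> sd_g (default ``default_log_fc_sd``, which concentrates
    fold-changes well below 1.2).  As the sd tends to 0, every
    fold-change tends to 1.
    """
    if n_studies < 1:
        raise ValueError("need at least one study")
    rng = _rng_for(seed, 4)
    profile = dict(stability_profile or {})
    rows = []
    for gene in genes:
        sd = float(profile.get(gene, default_log_fc_sd))
        lfc = np.abs(rng.normal(0.0, sd, size=n_studies)) if sd > 0 else np.zeros(n_studies)
        for j, v in enumerate(lfc):
            rows.append(
                {"gene_id": gene, "study_id": f"study{j + 1:03d}", "fold_change": float(np.exp(v))}
            )
    return StudyFoldChangeTable(pd.DataFrame(rows))
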