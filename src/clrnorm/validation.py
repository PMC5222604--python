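"""Synthetic-data validation studies of the pipeline.

Each study simulates data with known ground truth, runs the relevant
pipeline stage, and returns summary numbers (calibration rates,
recovery fractions, correlations).  They are used both by the test
suite and by the repository's acceptance script.

The calibration studies simulate genes without per-sample technical
factors: a technical factor is shared by every gene of a sample, so
with it the genes of one simulated dataset are not independent
Monte-Carlo replicates of the single-gene null.  Technical factors and
their removal are exercised separately by the normalisation-recovery
and detection-power studies, which run the full normalise-then-detect
path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import clr, detection, normalisation, selection
from .io import ExpressionMatrix
from .detection import _blocked_age_anova
from .simulate import (
    DEFAULT_CANDIDATES,
    EXTENDED_SET,
    GeneSimParams,
    make_panel_design,
    reference_panel_params,
    simulate_meta_studies,
    simulate_panel,
    simulate_positive_controls,
    simulate_rnaseq_screen,
)

__all__ = [
    "null_calibration_study",
    "familywise_error_study",
    "factor_recovery_study",
    "marker_inversion_study",
    "detection_power_study",
    "selection_recovery_study",
]

TWO_AGE_DESIGN = (3, 24)


def _null_panel_params(rng: np.random.Generator, n_genes: int, tag: str) -> dict:
    """Rhythmic genes with no age effect, at the default noise level."""
    return {
        f"{tag}{i:05d}": GeneSimParams(
            gene_id=f"{tag}{i:05d}",
            baseline=float(rng.uniform(500, 5000)),
            circadian_amplitude=float(rng.uniform(0, 0.5)),
            acrophase_h=float(rng.uniform(0, 24)),
            dispersion=0.01,
            noise_inflation_per_age=0.0002,
        )
        for i in range(n_genes)
    }


def null_calibration_study(seed: int, n_genes: int = 2000, level: float = 0.05) -> dict:
    """Rejection rate of the age test on independent null genes.

    Genes carry circadian signal but no age effect (N = 24 per group);
    a calibrated test rejects at close to ``level``.
    """
    rng = np.random.default_rng(seed)
    design = make_panel_design(ages=TWO_AGE_DESIGN)
    params = _null_panel_params(rng, n_genes, "null")
    matrix, _ = simulate_panel(design, params, seed=seed, tech_sigma=0.0)
    table = detection.detect_age_effects(matrix, design, *TWO_AGE_DESIGN, family_size=36)
    rate = float((table["p_value"] < level).mean())
    return {"rate": rate, "n": n_genes, "level": level}


def familywise_error_study(
    seed: int, n_panels: int = 2000, panel_size: int = 36, alpha: float = 0.05
) -> dict:
    """Probability of any Bonferroni-significant gene on fully null panels."""
    rng = np.random.default_rng(seed)
    design = make_panel_design(ages=TWO_AGE_DESIGN)
    params = _null_panel_params(rng, n_panels * panel_size, "fw")
    matrix, _ = simulate_panel(design, params, seed=seed + 1, tech_sigma=0.0)
    ages = design.table["age_months"].to_numpy(dtype=float)
    zts = design.table["zeitgeber_time_h"].to_numpy(dtype=float)
    pvals = _blocked_age_anova(
        np.log(matrix.values), (ages == max(TWO_AGE_DESIGN)).astype(float), zts
    )
    threshold = detection.bonferroni_threshold(alpha, panel_size)
    fwer = float((pvals.reshape(n_panels, panel_size) < threshold).any(axis=1).mean())
    return {"fwer": fwer, "n": n_panels, "threshold": threshold}


def factor_recovery_study(seed: int, n_seeds: int = 20) -> dict:
    """Correlation of estimated with true per-sample technical factors.

    Runs the full normalisation chain (positive-control constants, then
    marker-gene factors from the 7-gene extended set) on the 192-sample
    reference panel with default count noise; the correlation between
    log estimated and log true factors is pooled over all runs.
    """
    params, _, _ = reference_panel_params(seed)
    design = make_panel_design()
    est_all, truth_all = [], []
    for i in range(n_seeds):
        matrix, truth = simulate_panel(design, params, seed=seed + i)
        observed, expected = simulate_positive_controls(truth, seed=seed + i)
        constants = normalisation.positive_control_constants(observed, expected)
        work = normalisation.apply_normalisation(matrix, constants.combined)
        factors = normalisation.marker_normalisation_factors(work, EXTENDED_SET)
        est_all.append(np.log(constants.combined.to_numpy() * factors.to_numpy()))
        truth_all.append(-np.log(truth.tech_factors.to_numpy()))
    # pool within-run centred values: each run recovers factors up to a constant
    est = np.concatenate([e - e.mean() for e in est_all])
    tru = np.concatenate([t - t.mean() for t in truth_all])
    corr = float(np.corrcoef(est, tru)[0, 1])
    return {"correlation": corr, "n": n_seeds * len(design)}


def marker_inversion_study(seed: int, n_genes: int = 30, n_samples: int = 16) -> dict:
    """Exactness of marker normalisation when markers are truly constant.

    Injects random per-sample multiplicative factors into a noise-free
    matrix and measures the worst relative error after marker-based
    recovery (up to one global constant).
    """
    rng = np.random.default_rng(seed)
    base = rng.uniform(100, 10000, size=(n_genes, 1)) * np.ones((1, n_samples))
    factors_true = np.exp(rng.normal(0, 0.4, size=n_samples))
    perturbed = ExpressionMatrix(
        pd.DataFrame(
            base * factors_true[None, :],
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"s{j}" for j in range(n_samples)],
        )
    )
    markers = [f"g{i}" for i in range(7)]
    est = normalisation.marker_normalisation_factors(perturbed, markers)
    recovered = normalisation.apply_normalisation(perturbed, est)
    ratio = recovered.values / base
    rel_err = np.abs(ratio / ratio[0, 0] - 1.0)
    return {"max_rel_error": float(rel_err.max()), "n": n_genes * n_samples}


def detection_power_study(seed: int, n_seeds: int = 20) -> dict:
    """Sensitivity and false positives on perturbed 36-gene panels.

    The reference panel carries four genes perturbed between the
    youngest and oldest age at 1.25-1.52-fold magnitudes among 32 null
    test genes; each run normalises by the 7 extended-set markers and
    screens the 36 non-candidate genes at the Bonferroni threshold.
    """
    params, _, perturbed = reference_panel_params(seed)
    design = make_panel_design(ages=TWO_AGE_DESIGN)
    sens, fps = [], []
    for i in range(n_seeds):
        matrix, _ = simulate_panel(design, params, seed=seed + i)
        factors = normalisation.marker_normalisation_factors(matrix, EXTENDED_SET)
        normalised = normalisation.apply_normalisation(matrix, factors)
        test_genes = [g for g in matrix.gene_ids if g not in DEFAULT_CANDIDATES]
        table = detection.detect_age_effects(
            normalised, design, *TWO_AGE_DESIGN, genes=test_genes
        )
        sig = set(table.loc[table["significant"], "gene_id"])
        sens.append(len(sig & set(perturbed)) / len(perturbed))
        fps.append(len(sig - set(perturbed)))
    return {
        "sensitivity": float(np.mean(sens)),
        "max_false_positives": int(max(fps)),
        "mean_false_positives": float(np.mean(fps)),
        "n": n_seeds,
    }


def _recovery_panel_params(rng: np.random.Generator, stable: list, decoys: list) -> dict:
    params = {}
    for g in stable:
        params[g] = GeneSimParams(
            gene_id=g,
            baseline=float(rng.uniform(2000, 10000)),
            dispersion=0.002,
            noise_inflation_per_age=0.0001,
        )
    for g in decoys:
        params[g] = GeneSimParams(
            gene_id=g,
            baseline=float(rng.uniform(500, 5000)),
            circadian_amplitude=float(rng.uniform(0.25, 0.5)),
            acrophase_h=float(rng.uniform(0, 24)),
            age_log_fold_change=float(rng.normal(0, 0.4)),
            dispersion=0.03,
        )
    params["Cry2"] = GeneSimParams(
        gene_id="Cry2", baseline=2000.0, circadian_amplitude=0.25, acrophase_h=16.0
    )
    return params


def selection_recovery_study(
    seed: int, n_seeds: int = 20, n_screen_genes: int = 500,
    n_stable: int = 20, n_decoys: int = 20,
) -> dict:
    """Recovery of constructed-stable candidates by the four assessments.

    Each run screens ``n_stable`` constructed-stable candidates and
    ``n_decoys`` constructed-variable decoys through two genome-wide
    screens (median criterion), the panel reference-gene criterion and
    the meta-analysis criterion, then combines verdicts.  Reports the
    fraction of stable candidates reaching the extended set and the
    number of decoys contaminating the core set.
    """
    stable = [f"S{i:02d}" for i in range(n_stable)]
    decoys = [f"D{i:02d}" for i in range(n_decoys)]
    candidates = stable + decoys
    profile = {g: (0.05 if g in stable else 0.39) for g in candidates}
    recovered, contamination = [], []
    for i in range(n_seeds):
        run_seed = seed + i
        rng = np.random.default_rng(run_seed + 500)
        screen, _ = simulate_rnaseq_screen(
            n_screen_genes, seed=run_seed, candidate_stable=stable, candidate_variable=decoys
        )
        screen2, _ = simulate_rnaseq_screen(
            n_screen_genes, seed=run_seed + 10_000,
            candidate_stable=stable, candidate_variable=decoys,
        )
        panel, _ = simulate_panel(
            make_panel_design(), _recovery_panel_params(rng, stable, decoys), seed=run_seed
        )
        meta = simulate_meta_studies(candidates, stability_profile=profile, seed=run_seed)

        columns = {}
        for name, scr in (("screen", screen), ("validation", screen2)):
            kept = selection.expression_prefilter(scr)
            stats = clr.clr_gene_stats(clr.clr_transform(scr.select_genes(kept), pseudocount=0.5))
            columns[name] = selection.median_criterion(stats, candidates)
        panel_stats = clr.clr_gene_stats(clr.clr_transform(panel, pseudocount=0.5))
        columns["panel"] = selection.reference_gene_criterion(panel_stats, candidates, "Cry2")
        columns["meta"] = selection.meta_criterion(meta, candidates)
        sets = selection.combine_assessments(selection.AssessmentTable.from_columns(columns))
        recovered.append(len(set(sets.extended) & set(stable)) / n_stable)
        contamination.append(len(set(sets.core) & set(decoys)))
    return {
        "stable_recovery": float(np.mean(recovered)),
        "min_stable_recovery": float(min(recovered)),
        "max_core_contamination": int(max(contamination)),
        "n": n_seeds,
    }
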