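"""End-to-end orchestration: select -> normalise -> detect.

A single :class:`RunConfig` drives the whole analysis so a run can be
reproduced exactly from its emitted configuration.  Inputs are either
simulated (the default, driven by the configured seed) or loaded from
TSV files; the stages are always executed in the order

1. *select*  — the four stability assessments (genome-wide screen
   median criterion, validation screen median criterion, panel
   reference-gene criterion, meta-analysis criterion) combined into
   core and extended marker sets;
2. *normalise* — positive-control constants followed by marker-gene
   geometric-mean factors on the panel;
3. *detect*  — repeated-measures ANOVA age screen with Bonferroni
   control on the non-candidate panel genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import clr, detection, normalisation, selection, simulate
from .io import (
    CandidateSet,
    ExpressionMatrix,
    SampleDesign,
    StudyFoldChangeTable,
    config_digest,
    read_candidate_list,
    read_expression_matrix,
    read_sample_design,
    read_study_fold_changes,
    write_report,
)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    With ``inputs`` unset the run is simulation-backed: the reference
    panel, two genome-wide screens, spike-in controls and a meta-study
    table are generated from ``seed``.  ``inputs`` may instead name TSV
    paths (keys ``screen``, ``validation_screen``, ``panel``,
    ``design``, ``meta``, ``candidates``, optionally ``controls`` /
    ``control_amounts``).
    """

    seed: int = 0
    candidates: list[str] = field(default_factory=list)
    reference_gene: str = "Cry2"
    min_count: int = 20
    pseudocount: float = 0.5
    meta_threshold: float = 1.2
    meta_fraction: float = 0.9
    alpha: float = 0.05
    family_size: int | None = None
    young_age: int = 3
    old_age: int = 24
    marker_set: str = "extended"
    n_screen_genes: int = 2000
    inputs: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        return config_digest(self.to_dict())


@dataclass
class PipelineResult:
    """Bundle of the artefacts of one pipeline run."""

    assessments: selection.AssessmentTable
    marker_sets: selection.MarkerSets
    normalised: ExpressionMatrix
    detection: pd.DataFrame
    config_hash: str
    log: list[str]
    truth: simulate.SimTruth | None = None


def _simulated_inputs(config: RunConfig):
    params, stable_candidates, _perturbed = simulate.reference_panel_params(config.seed)
    candidates = tuple(config.candidates) or simulate.DEFAULT_CANDIDATES
    variable_candidates = [g for g in candidates if g not in stable_candidates]
    design = simulate.make_panel_design()
    panel, truth = simulate.simulate_panel(design, params, seed=config.seed)
    controls, amounts = simulate.simulate_positive_controls(truth, seed=config.seed)
    screen, _ = simulate.simulate_rnaseq_screen(
        n_genes=config.n_screen_genes,
        seed=config.seed,
        candidate_stable=[g for g in candidates if g in stable_candidates],
        candidate_variable=variable_candidates,
    )
    validation, _ = simulate.simulate_rnaseq_screen(
        n_genes=config.n_screen_genes,
        seed=config.seed + 10_000,
        candidate_stable=[g for g in candidates if g in stable_candidates],
        candidate_variable=variable_candidates,
    )
    profile = {g: (0.05 if g in stable_candidates else 0.39) for g in candidates}
    meta = simulate.simulate_meta_studies(
        candidates, stability_profile=profile, seed=config.seed
    )
    return candidates, screen, validation, panel, design, controls, amounts, meta, truth


def _file_inputs(config: RunConfig):
    inp = config.inputs
    required = ["screen", "panel", "design", "meta", "candidates"]
    missing = [k for k in required if k not in inp]
    if missing:
        raise ValueError(f"missing input paths: {missing}")
    candidates = tuple(read_candidate_list(inp["candidates"]))
    screen = read_expression_matrix(inp["screen"])
    validation = (
        read_expression_matrix(inp["validation_screen"])
        if "validation_screen" in inp
        else None
    )
    panel = read_expression_matrix(inp["panel"])
    design = read_sample_design(inp["design"])
    meta = read_study_fold_changes(inp["meta"])
    controls = amounts = None
    if "controls" in inp:
        ctrl = pd.read_csv(inp["controls"], sep="\t", index_col=0, comment="#")
        if "expected_amount" not in ctrl.columns:
            raise ValueError("controls table needs an expected_amount column")
        amounts = ctrl["expected_amount"]
        controls = ctrl.drop(columns=["expected_amount"])
    return candidates, screen, validation, panel, design, controls, amounts, meta, None


def _screen_assessment(
    screen: ExpressionMatrix, candidates, config: RunConfig
) -> dict[str, str]:
    kept = selection.expression_prefilter(screen, min_count=config.min_count)
    filtered = screen.select_genes(kept)
    stats = clr.clr_gene_stats(clr.clr_transform(filtered, pseudocount=config.pseudocount))
    return selection.median_criterion(stats, candidates)


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Execute select -> normalise -> detect and optionally write the bundle.

    Deterministic given the configuration (the seed covers all simulated
    randomness); every emitted table carries the configuration hash.
    """
    if not config.candidates and config.inputs:
        raise ValueError("file-based runs must list candidate genes")
    log: list[str] = []
    chash = config.digest()
    log.append(f"config hash {chash}")

    if config.inputs:
        loaded = _file_inputs(config)
    else:
        loaded = _simulated_inputs(config)
    candidates, screen, validation, panel, design, controls, amounts, meta, truth = loaded
    CandidateSet(tuple(candidates))  # validates non-empty / duplicate-free
    design.check_matches(panel)

    # --- select ---------------------------------------------------------
    columns: dict[str, dict[str, str]] = {}
    columns["rnaseq_screen"] = _screen_assessment(screen, candidates, config)
    if validation is not None:
        columns["validation_screen"] = _screen_assessment(validation, candidates, config)
    panel_stats = clr.clr_gene_stats(clr.clr_transform(panel, pseudocount=config.pseudocount))
    columns["panel_reference"] = selection.reference_gene_criterion(
        panel_stats, candidates, reference_gene=config.reference_gene
    )
    columns["meta_analysis"] = selection.meta_criterion(
        meta, candidates, threshold=config.meta_threshold,
        required_fraction=config.meta_fraction,
    )
    assessments = selection.AssessmentTable.from_columns(columns)
    marker_sets = selection.combine_assessments(assessments)
    log.append(
        f"selected core={list(marker_sets.core)} extended={list(marker_sets.extended)}"
    )
    markers = marker_sets.core if config.marker_set == "core" else marker_sets.extended
    if len(markers) < 2:
        raise ValueError(
            f"{config.marker_set} marker set has fewer than two genes; cannot normalise"
        )

    # --- normalise ------------------------------------------------------
    work = panel
    if controls is not None:
        constants = normalisation.positive_control_constants(controls, amounts)
        work = normalisation.apply_normalisation(work, constants.combined)
        log.append("applied positive-control constants")
    factors = normalisation.marker_normalisation_factors(work, markers)
    normalised = normalisation.apply_normalisation(work, factors)
    log.append(f"marker normalisation with {len(markers)} genes")

    # --- detect ---------------------------------------------------------
    test_genes = [g for g in panel.gene_ids if g not in set(candidates)]
    detection_table = detection.detect_age_effects(
        normalised,
        design,
        young_age=config.young_age,
        old_age=config.old_age,
        alpha=config.alpha,
        family_size=config.family_size,
        genes=test_genes,
    )
    n_sig = int(detection_table["significant"].sum())
    log.append(f"detection: {n_sig} significant of {len(test_genes)} genes tested")

    result = PipelineResult(
        assessments=assessments,
        marker_sets=marker_sets,
        normalised=normalised,
        detection=detection_table,
        config_hash=chash,
        log=log,
        truth=truth,
    )
    if outdir is not None:
        _write_bundle(result, config, Path(outdir))
    return result


def _write_bundle(result: PipelineResult, config: RunConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    sets = pd.DataFrame(
        {
            "gene_id": list(result.marker_sets.extended),
            "set": [
                "core" if g in result.marker_sets.core else "extended"
                for g in result.marker_sets.extended
            ],
        }
    )
    write_report(
        {
            "assessments": result.assessments.to_codes(),
            "marker_sets": sets,
            "detection": result.detection,
        },
        outdir,
        config_hash=result.config_hash,
    )
    with open(outdir / "normalised_matrix.tsv", "w", encoding="utf-8") as fh:
        fh.write(f"# config_hash: {result.config_hash}\n")
        df = result.normalised.data.copy()
        df.index.name = "gene_id"
        df.to_csv(fh, sep="\t")
    (outdir / "config.yaml").write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True), encoding="utf-8"
    )
    (outdir / "run.log").write_text("\n".join(result.log) + "\n", encoding="utf-8")
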