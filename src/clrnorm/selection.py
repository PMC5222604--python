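"""Stability assessments of candidate reference genes and their combination.

A candidate gene is a useful normalisation marker only if its expression
is stable across the conditions of interest (age classes, circadian
time, sex, tissue, and the heterogeneous conditions of published
studies).  Each assessment here scores every candidate as ``pass``,
``fail`` or ``not_detectable`` and the verdicts are combined into

* a *core* set — candidates with zero failed assessments, and
* an *extended* set — the core plus candidates failing at most one
  assessment, included to make the geometric-mean normalisation robust
  against a single outlying marker.

``not_detectable`` (the gene was not measured in that assay) counts as
neither pass nor fail.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from statsmodels.distributions.empirical_distribution import ECDF

from .io import CandidateSet, ExpressionMatrix, FormatError, StudyFoldChangeTable

__all__ = [
    "PASS",
    "FAIL",
    "NOT_DETECTABLE",
    "AssessmentTable",
    "MarkerSets",
    "expression_prefilter",
    "median_criterion",
    "reference_gene_criterion",
    "fold_change_cdf",
    "meta_criterion",
    "combine_assessments",
]

PASS = "pass"
FAIL = "fail"
NOT_DETECTABLE = "not_detectable"

_STATUS_CODES = {PASS: "X", FAIL: "-", NOT_DETECTABLE: "ND"}
_CODE_STATUS = {v: k for k, v in _STATUS_CODES.items()}


@dataclass(frozen=True)
class AssessmentTable:
    """Candidate-gene x assessment status matrix.

    ``statuses`` is a frame indexed by gene with one column per
    assessment; every cell is one of ``pass`` / ``fail`` /
    ``not_detectable``.  Serialised as TSV using the compact codes
    ``X`` / ``-`` / ``ND``.
    """

    statuses: pd.DataFrame

    def __post_init__(self) -> None:
        bad = set(self.statuses.to_numpy().ravel()) - set(_STATUS_CODES)
        if bad:
            raise ValueError(f"invalid assessment statuses: {sorted(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.statuses.index.astype(str))

    @property
    def assessment_ids(self) -> list[str]:
        return list(self.statuses.columns.astype(str))

    def fail_counts(self) -> pd.Series:
        return (self.statuses == FAIL).sum(axis=1)

    def to_codes(self) -> pd.DataFrame:
        """Wide frame with ``gene_id`` column and X / - / ND codes."""
        codes = self.statuses.replace(_STATUS_CODES)
        codes = codes.reset_index().rename(columns={"index": "gene_id"})
        codes.columns = ["gene_id", *self.assessment_ids]
        return codes

    @classmethod
    def from_codes(cls, codes: pd.DataFrame) -> "AssessmentTable":
        if "gene_id" not in codes.columns:
            raise FormatError("assessment table needs a gene_id column")
        df = codes.set_index("gene_id")
        unknown = set(df.to_numpy().ravel()) - set(_CODE_STATUS)
        if unknown:
            raise FormatError(f"unknown assessment codes: {sorted(unknown)}")
        return cls(df.replace(_CODE_STATUS))

    @classmethod
    def from_columns(cls, columns: Mapping[str, Mapping[str, str]]) -> "AssessmentTable":
        """Build from ``{assessment_id: {gene_id: status}}`` mappings."""
        df = pd.DataFrame({k: pd.Series(v) for k, v in columns.items()})
        if df.isna().any().any():
            missing = df.index[df.isna().any(axis=1)][0]
            raise ValueError(f"gene {missing!r} lacks a status in some assessment")
        return cls(df)


@dataclass(frozen=True)
class MarkerSets:
    """Core (zero fails) and extended (at most one fail) marker sets."""

    core: tuple[str, ...]
    extended: tuple[str, ...]

    def __post_init__(self) -> None:
        if not set(self.core) <= set(self.extended):
            raise ValueError("core set must be contained in the extended set")


def expression_prefilter(matrix: ExpressionMatrix, min_count: int = 20) -> list[str]:
    """Genes considered expressed: maximum count across samples >= ``min_count``."""
    keep = matrix.values.max(axis=1) >= min_count
    return [g for g, k in zip(matrix.gene_ids, keep) if k]


def _statuses_to_rows(assessment_id, statuses: Mapping[str, str]) -> dict[str, str]:
    return dict(statuses)


def median_criterion(
    stats: pd.DataFrame,
    candidates: CandidateSet | Iterable[str],
    background: Iterable[str] | None = None,
) -> dict[str, str]:
    """Mean-above-median and variance-below-median screen.

    A candidate passes iff its ``mean_clr`` is strictly above the median
    mean and its ``var_clr`` strictly below the median variance of the
    background (by default every assayed gene, candidates included —
    removing a handful of candidates from thousands of genes does not
    move the median).  Candidates absent from ``stats`` are
    ``not_detectable``.  Ties at either median fail.
    """
    bg = stats if background is None else stats.loc[list(background)]
    if bg.empty:
        raise ValueError("empty background for the median criterion")
    med_mean = float(bg["mean_clr"].median())
    med_var = float(bg["var_clr"].median())
    out: dict[str, str] = {}
    for gene in candidates:
        if gene not in stats.index:
            out[gene] = NOT_DETECTABLE
            continue
        row = stats.loc[gene]
        ok = (row["mean_clr"] > med_mean) and (row["var_clr"] < med_var)
        out[gene] = PASS if ok else FAIL
    return out


def reference_gene_criterion(
    stats: pd.DataFrame,
    candidates: CandidateSet | Iterable[str],
    reference_gene: str,
) -> dict[str, str]:
    """Variance strictly below that of a reference gene.

    The reference is typically the least variable rhythmic clock gene in
    the panel (Cry2 in the mouse-liver design): a useful marker must be
    more stable than any gene with genuine circadian variation.
    """
    if reference_gene not in stats.index:
        raise KeyError(f"reference gene {reference_gene!r} not in the statistics table")
    ref_var = float(stats.at[reference_gene, "var_clr"])
    out: dict[str, str] = {}
    for gene in candidates:
        if gene not in stats.index:
            out[gene] = NOT_DETECTABLE
        else:
            out[gene] = PASS if float(stats.at[gene, "var_clr"]) < ref_var else FAIL
    return out


def symmetrise_fold_changes(fc) -> np.ndarray:
    """Unsigned fold-change magnitudes ``max(fc, 1/fc)``."""
    arr = np.asarray(fc, dtype=float)
    return np.maximum(arr, 1.0 / arr)


def fold_change_cdf(table: StudyFoldChangeTable, gene_id: str) -> ECDF:
    """Empirical CDF of a gene's symmetrised fold-changes across studies.

    Right-continuous step function, evaluable at any threshold.
    """
    fc = symmetrise_fold_changes(table.for_gene(gene_id))
    return ECDF(fc)


def meta_criterion(
    table: StudyFoldChangeTable,
    candidates: CandidateSet | Iterable[str],
    threshold: float = 1.2,
    required_fraction: float = 0.9,
    inclusive: bool = False,
) -> dict[str, str]:
    """Meta-analysis stability screen over many independent studies.

    A candidate passes iff the fraction of studies in which its
    symmetrised fold-change is strictly below ``threshold`` exceeds
    ``required_fraction`` (strictly; ``inclusive`` allows equality).
    Candidates with no studies in the table are ``not_detectable``.
    """
    out: dict[str, str] = {}
    for gene in candidates:
        try:
            fc = symmetrise_fold_changes(table.for_gene(gene))
        except KeyError:
            out[gene] = NOT_DETECTABLE
            continue
        frac = float((fc < threshold).mean())
        ok = frac >= required_fraction if inclusive else frac > required_fraction
        out[gene] = PASS if ok else FAIL
    return out


def combine_assessments(
    table: AssessmentTable, max_fails_for_extended: int = 1
) -> MarkerSets:
    """Combine assessment verdicts into core and extended marker sets.

    Core: zero fails.  Extended: core plus genes with at most
    ``max_fails_for_extended`` fails.  ``not_detectable`` entries count
    as neither pass nor fail.  The result is invariant to row and column
    permutations of the table; genes are reported in table order.
    """
    fails = table.fail_counts()
    core = tuple(g for g in table.gene_ids if fails[g] == 0)
    extended = tuple(g for g in table.gene_ids if fails[g] <= max_fails_for_extended)
    return MarkerSets(core=core, extended=extended)
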