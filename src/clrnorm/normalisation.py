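"""Per-sample normalisation: spike-in controls, then marker genes.

Hybridisation-counting panels include positive-control probes spiked in
at known concentrations; the ratio expected/observed per control gives a
per-sample constant converting counts to the input-amount scale, and the
geometric mean across controls combines them into one constant per
sample.  On the control-normalised matrix, a second factor built from
the geometric mean of selected stable marker genes removes residual
per-sample (biological input / efficiency) scale.  Using the geometric
mean over several markers means one outlying marker shifts a sample's
factor by at most ``outlier_fold ** (1/n_markers)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .io import ExpressionMatrix

__all__ = [
    "NormalisationConstants",
    "positive_control_constants",
    "marker_normalisation_factors",
    "apply_normalisation",
]


@dataclass(frozen=True)
class NormalisationConstants:
    """Per-sample, per-control constants and their geometric-mean combination.

    ``per_reference`` is controls x samples; ``combined`` is the
    per-sample geometric mean over controls.
    """

    per_reference: pd.DataFrame
    combined: pd.Series

    def __post_init__(self) -> None:
        if (self.per_reference.to_numpy(dtype=float) <= 0).any():
            raise ValueError("normalisation constants must be positive")
        expected = np.exp(np.log(self.per_reference.to_numpy(dtype=float)).mean(axis=0))
        if not np.allclose(self.combined.to_numpy(dtype=float), expected, rtol=1e-9):
            raise ValueError("combined constants are not the geometric mean of per-reference ones")


def positive_control_constants(
    observed: pd.DataFrame, expected: pd.Series
) -> NormalisationConstants:
    """Infer per-sample constants from positive-control counts.

    ``observed`` holds control counts (controls x samples); ``expected``
    the known input amount per control.  The constant for sample ``s``
    and control ``i`` is ``expected_i / observed_si``, so multiplying a
    sample's counts by its combined constant converts them to the
    input-amount scale.  A zero observed count indicates a failed
    hybridisation and is an error.
    """
    exp = expected.reindex(observed.index)
    if exp.isna().any():
        missing = list(exp.index[exp.isna()])
        raise KeyError(f"controls without expected amounts: {missing}")
    if (exp.to_numpy(dtype=float) <= 0).any():
        raise ValueError("expected control amounts must be positive")
    obs = observed.to_numpy(dtype=float)
    if (obs <= 0).any():
        ci, si = np.argwhere(obs <= 0)[0]
        raise ValueError(
            f"non-positive observed count for control {observed.index[ci]!r} in "
            f"sample {observed.columns[si]!r} (failed hybridisation?)"
        )
    per_ref = exp.to_numpy(dtype=float)[:, None] / obs
    per_ref = pd.DataFrame(per_ref, index=observed.index, columns=observed.columns)
    combined = pd.Series(_sps.gmean(per_ref.to_numpy(), axis=0), index=observed.columns)
    return NormalisationConstants(per_reference=per_ref, combined=combined)


def marker_normalisation_factors(
    matrix: ExpressionMatrix, markers: Iterable[str]
) -> pd.Series:
    """Per-sample factors from the geometric mean of marker genes.

    For each marker gene the per-sample constant is (gene's geometric
    mean across samples) / (gene's value in the sample); the sample's
    factor is the geometric mean of these constants over all markers.
    Anchoring each gene to its own cross-sample geometric mean makes the
    factors symmetric in the samples and gives them geometric mean 1
    by construction.
    """
    markers = list(markers)
    if not markers:
        raise ValueError("marker list is empty")
    missing = [g for g in markers if g not in matrix.data.index]
    if missing:
        raise KeyError(f"marker genes absent from the matrix: {missing}")
    sub = matrix.data.loc[markers]
    vals = sub.to_numpy(dtype=float)
    if (vals <= 0).any():
        gi, si = np.argwhere(vals <= 0)[0]
        raise ValueError(
            f"marker gene {markers[gi]!r} has non-positive value in sample "
            f"{sub.columns[si]!r}; cannot anchor normalisation on it"
        )
    logv = np.log(vals)
    # per-gene constant: gene gmean across samples / value in sample
    log_const = logv.mean(axis=1, keepdims=True) - logv
    factors = np.exp(log_const.mean(axis=0))
    return pd.Series(factors, index=sub.columns)


def apply_normalisation(matrix: ExpressionMatrix, factors: pd.Series) -> ExpressionMatrix:
    """Multiply every sample column by its per-sample factor."""
    fac = factors.reindex(matrix.data.columns)
    if fac.isna().any():
        missing = list(fac.index[fac.isna()])
        raise KeyError(f"samples without a normalisation factor: {missing}")
    if (fac.to_numpy(dtype=float) <= 0).any():
        bad = fac.index[fac.to_numpy(dtype=float) <= 0][0]
        raise ValueError(f"non-positive factor for sample {bad!r}")
    return ExpressionMatrix(matrix.data * fac.to_numpy(dtype=float)[None, :])
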