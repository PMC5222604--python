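r"""Centered log-ratio (clr) transformation and per-gene clr statistics.

Expression measurements from sequencing or hybridisation counting are
compositional: each sample carries an arbitrary multiplicative scale
(library size, input amount), so only ratios between genes are
informative.  For a sample vector :math:`x = (x_1, \dots, x_N)` the clr
transform is

.. math:: \mathrm{clr}(x) = \bigl(\log(x_1/g(x)), \dots, \log(x_N/g(x))\bigr),

where :math:`g(x)` is the geometric mean of the vector.  The clr is
invariant to rescaling a sample by any positive constant, and the
difference of clr values of one gene between two conditions is the log
fold-change after aligning the conditions to a common geometric mean.
The variance of a gene's clr across many conditions therefore extends
the familiar two-condition fold-change analysis to arbitrarily many
conditions, without requiring known normalisation genes.

Natural logarithms are used throughout; fold-changes are reported as
``exp`` of clr differences, so the base cancels.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .io import ExpressionMatrix

__all__ = [
    "geometric_mean",
    "ClrMatrix",
    "clr_transform",
    "clr_gene_stats",
    "pairwise_fold_changes",
    "pairwise_correlations",
]


def geometric_mean(values) -> float:
    """Geometric mean ``exp(mean(log(values)))`` of strictly positive values.

    Scale-equivariant: ``geometric_mean(k * v) == k * geometric_mean(v)``.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("geometric mean of an empty collection is undefined")
    if (arr <= 0).any() or not np.isfinite(arr).all():
        raise ValueError("geometric mean requires strictly positive finite values")
    return float(_sps.gmean(arr))


@dataclass(frozen=True)
class ClrMatrix:
    """Gene-by-sample matrix of clr values.

    Every sample column sums to zero (within ``1e-9 * n_genes``), which
    is checked at construction.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        col_sums = self.data.to_numpy(dtype=float).sum(axis=0)
        tol = 1e-9 * max(1, self.data.shape[0])
        if np.abs(col_sums).max(initial=0.0) > tol:
            worst = self.data.columns[int(np.abs(col_sums).argmax())]
            raise ValueError(
                f"clr column {worst!r} does not sum to zero (got {col_sums.max():.3g})"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index.astype(str))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns.astype(str))


def clr_transform(matrix: ExpressionMatrix, pseudocount: float = 0.0) -> ClrMatrix:
    """Apply the clr transform to every sample column.

    ``pseudocount`` is added to all values first, which is how zero
    counts in genome-wide matrices are handled (0.5 is the pipeline
    default upstream; panels without zeros can use 0).
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    x = matrix.values + pseudocount
    if (x <= 0).any():
        raise ValueError(
            "clr undefined: matrix contains zeros and pseudocount is 0"
        )
    logx = np.log(x)
    clr = logx - logx.mean(axis=0, keepdims=True)
    return ClrMatrix(pd.DataFrame(clr, index=matrix.data.index, columns=matrix.data.columns))


def _condition_means(clr: ClrMatrix, grouping: Mapping[str, str] | pd.Series | None) -> pd.DataFrame:
    """Average clr values within each condition; columns become conditions.

    ``grouping`` maps sample id -> condition label.  ``None`` treats every
    sample as its own condition (the convention for individually measured
    panel samples).
    """
    df = clr.data
    if grouping is None:
        return df.copy()
    labels = pd.Series(dict(grouping) if not isinstance(grouping, pd.Series) else grouping)
    missing = [s for s in df.columns if s not in labels.index]
    if missing:
        raise KeyError(f"samples without a condition label: {missing[:5]}")
    return df.T.groupby(labels.reindex(df.columns)).mean().T


def clr_gene_stats(
    clr: ClrMatrix, grouping: Mapping[str, str] | pd.Series | None = None
) -> pd.DataFrame:
    """Mean and unbiased variance of clr values per gene across conditions.

    Replicate samples sharing a condition label are first collapsed to
    the condition mean, then the mean and the (n-1)-denominator variance
    are taken across the condition-level values.  Returns a frame indexed
    by gene with columns ``mean_clr``, ``var_clr``, ``n_conditions``.
    """
    cond = _condition_means(clr, grouping)
    n_conditions = cond.shape[1]
    if n_conditions < 2:
        raise ValueError("clr statistics need at least two conditions")
    values = cond.to_numpy(dtype=float)
    out = pd.DataFrame(
        {
            "mean_clr": values.mean(axis=1),
            "var_clr": values.var(axis=1, ddof=1),
            "n_conditions": n_conditions,
        },
        index=cond.index,
    )
    out.index.name = "gene_id"
    return out


def pairwise_fold_changes(
    matrix: ExpressionMatrix,
    grouping: Mapping[str, str] | pd.Series | None = None,
    pseudocount: float = 0.0,
    symmetrise: bool = False,
) -> pd.DataFrame:
    """Per-gene fold-changes between every unordered pair of conditions.

    Fold-changes are computed on the clr scale (i.e. after aligning all
    conditions to a common geometric mean) as ``exp(clr_b - clr_a)`` for
    conditions ``a < b`` in sorted label order; with ``symmetrise`` the
    magnitude ``max(fc, 1/fc)`` is reported instead.  For C conditions
    the result has C(C-1)/2 columns named ``"a_vs_b"``.
    """
    clr = clr_transform(matrix, pseudocount=pseudocount)
    cond = _condition_means(clr, grouping)
    labels = sorted(cond.columns.astype(str))
    if len(labels) < 2:
        raise ValueError("fold-changes need at least two conditions")
    cond = cond[labels] if list(cond.columns) != labels else cond
    out = {}
    for a, b in combinations(labels, 2):
        fc = np.exp(cond[b].to_numpy(dtype=float) - cond[a].to_numpy(dtype=float))
        if symmetrise:
            fc = np.maximum(fc, 1.0 / fc)
        out[f"{a}_vs_{b}"] = fc
    res = pd.DataFrame(out, index=cond.index)
    res.index.name = "gene_id"
    return res


def pairwise_correlations(matrix: ExpressionMatrix, gene_subset=None) -> pd.DataFrame:
    """Pearson correlations between genes across samples.

    Computed on the (normalised) expression values as given.  The result
    is symmetric with unit diagonal; genes with zero variance across
    samples have undefined correlations, reported as NaN.
    """
    data = matrix.data if gene_subset is None else matrix.select_genes(gene_subset).data
    if data.shape[1] < 3:
        raise ValueError("correlations need at least three samples")
    corr = data.T.corr(method="pearson")
    return corr
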