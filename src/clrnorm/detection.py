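"""Detection of age-related expression changes on normalised panels.

The reference design compares two age classes sampled at the same
zeitgeber times (12 time points, duplicates; N = 24 per group).  Because
many panel genes are rhythmic, the age comparison must block on time of
day: the repeated-measures ANOVA here models age as a fixed effect with
a (random) intercept per shared time point.  In a balanced design the
age inference from that mixed model coincides with the ordinary
least-squares F-test of age adjusted for time-point blocks, which is how
it is computed; with one replicate per time point it reduces exactly to
the paired t-test.  Models are fitted on the log scale by default
(noise and age effects are multiplicative); family-wise error over a
panel is controlled by Bonferroni.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .io import ExpressionMatrix, SampleDesign

__all__ = [
    "bonferroni_threshold",
    "repeated_measures_anova",
    "TwoWayAnovaResult",
    "two_way_anova",
    "fold_change_estimate",
    "detect_age_effects",
]


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold ``alpha / m`` for a family of m tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("family size must be a positive integer")
    return alpha / m


def _zt_codes(zt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    levels, codes = np.unique(np.asarray(zt, dtype=float), return_inverse=True)
    return levels, codes


def _block_design(age: np.ndarray, zt_codes: np.ndarray, n_levels: int) -> tuple[np.ndarray, np.ndarray]:
    """Full (intercept + age + time blocks) and reduced (no age) design matrices."""
    n = age.shape[0]
    blocks = np.zeros((n, n_levels - 1))
    for t in range(1, n_levels):
        blocks[:, t - 1] = zt_codes == t
    reduced = np.column_stack([np.ones(n), blocks])
    full = np.column_stack([np.ones(n), np.asarray(age, dtype=float), blocks])
    return full, reduced


def _blocked_age_anova(Y: np.ndarray, age: np.ndarray, zt: np.ndarray) -> np.ndarray:
    """Vectorised age F-test blocked on time point.

    ``Y`` is genes x observations; returns one p-value per gene from
    F = ((SSR_reduced - SSR_full) / 1) / (SSR_full / df_full).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    levels, codes = _zt_codes(zt)
    if levels.size < 2:
        raise ValueError("need at least two time points")
    full, reduced = _block_design(age, codes, levels.size)
    df_full = Y.shape[1] - full.shape[1]
    if df_full < 1:
        raise ValueError("design leaves no residual degrees of freedom")

    def ssr(X: np.ndarray) -> np.ndarray:
        coef, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
        resid = Y.T - X @ coef
        return (resid**2).sum(axis=0)

    ssr_full = ssr(full)
    ssr_red = ssr(reduced)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssr_red - ssr_full) / (ssr_full / df_full)
    f = np.clip(f, 0.0, np.inf)
    p = _sps.f.sf(f, 1, df_full)
    # a saturated noiseless fit (ssr_full == 0) is infinitely significant
    p = np.where((ssr_full == 0) & (ssr_red > 0), 0.0, p)
    p = np.where((ssr_full == 0) & (ssr_red == 0), 1.0, p)
    return p


def _check_matched_grids(young_zt: np.ndarray, old_zt: np.ndarray) -> None:
    y = np.sort(np.asarray(young_zt, dtype=float))
    o = np.sort(np.asarray(old_zt, dtype=float))
    if y.shape != o.shape or not np.allclose(y, o):
        raise ValueError("young and old groups must share the same zeitgeber-time grid")


def repeated_measures_anova(young: pd.Series, old: pd.Series) -> float:
    """P-value for an age effect between two groups matched on time of day.

    ``young`` and ``old`` are expression values indexed by zeitgeber
    time (replicates appear as repeated index entries); the two grids
    must be identical.  Values are analysed on the scale given (callers
    log-transform first for multiplicative data).  Deterministic for a
    fixed input.
    """
    young_zt = young.index.to_numpy(dtype=float)
    old_zt = old.index.to_numpy(dtype=float)
    _check_matched_grids(young_zt, old_zt)
    y = np.concatenate([young.to_numpy(dtype=float), old.to_numpy(dtype=float)])
    age = np.concatenate([np.zeros(len(young)), np.ones(len(old))])
    zt = np.concatenate([young_zt, old_zt])
    return float(_blocked_age_anova(y[None, :], age, zt)[0])


@dataclass(frozen=True)
class TwoWayAnovaResult:
    """Two-factor decomposition with per-time-point Bonferroni post-tests.

    ``posthoc`` has one row per time point with the age difference, the
    Bonferroni-adjusted p-value and significance flags at the adjusted
    0.05 / 0.01 / 0.001 levels.
    """

    p_interaction: float
    p_age: float
    p_time: float
    posthoc: pd.DataFrame

    def __post_init__(self) -> None:
        for p in (self.p_interaction, self.p_age, self.p_time):
            if not 0 <= p <= 1:
                raise ValueError("p-values must lie in [0, 1]")


def two_way_anova(values, age, time) -> TwoWayAnovaResult:
    """Two-way ANOVA (age x time) with per-time-point post-tests.

    Requires a replicated balanced two-factor layout; without replicates
    the interaction is not estimable and an error is raised.  Post-tests
    compare the two age groups at each time point with the pooled
    residual variance, Bonferroni-adjusted across time points.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame(
        {
            "y": np.asarray(values, dtype=float),
            "age": pd.Categorical(np.asarray(age)),
            "time": pd.Categorical(np.asarray(time, dtype=float)),
        }
    )
    cells = df.groupby(["age", "time"], observed=True).size()
    if (cells < 2).any():
        raise ValueError("unreplicated cells: interaction is not estimable")
    times = list(df["time"].cat.categories)
    if df["y"].var() == 0:
        # degenerate constant response: no evidence for any effect
        posthoc = pd.DataFrame(
            {
                "time": [float(t) for t in times],
                "difference": 0.0,
                "p_adjusted": 1.0,
                "sig_05": False,
                "sig_01": False,
                "sig_001": False,
            }
        )
        return TwoWayAnovaResult(1.0, 1.0, 1.0, posthoc)
    fit = smf.ols("y ~ C(age) * C(time)", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)

    def _p(term: str) -> float:
        p = float(table.loc[term, "PR(>F)"])
        # degenerate (e.g. all-constant) data carries no evidence at all
        return p if np.isfinite(p) else 1.0

    p_age = _p("C(age)")
    p_time = _p("C(time)")
    p_inter = _p("C(age):C(time)")

    ms_resid = float(fit.mse_resid)
    df_resid = int(fit.df_resid)
    ages = list(df["age"].cat.categories)
    if len(ages) != 2:
        raise ValueError("post-tests require exactly two age groups")
    rows = []
    for t in times:
        a = df.loc[(df["age"] == ages[0]) & (df["time"] == t), "y"]
        b = df.loc[(df["age"] == ages[1]) & (df["time"] == t), "y"]
        diff = b.mean() - a.mean()
        se = np.sqrt(ms_resid * (1.0 / len(a) + 1.0 / len(b)))
        if se > 0:
            tstat = diff / se
            p_adj = min(1.0, 2.0 * _sps.t.sf(abs(tstat), df_resid) * len(times))
        else:
            p_adj = 0.0 if diff != 0 else 1.0
        rows.append(
            {
                "time": float(t),
                "difference": float(diff),
                "p_adjusted": float(p_adj),
                "sig_05": p_adj < 0.05,
                "sig_01": p_adj < 0.01,
                "sig_001": p_adj < 0.001,
            }
        )
    return TwoWayAnovaResult(
        p_interaction=p_inter, p_age=p_age, p_time=p_time, posthoc=pd.DataFrame(rows)
    )


def fold_change_estimate(young: pd.Series, old: pd.Series, average: str = "geometric") -> float:
    """Average old/young fold-change across matched time points.

    Within each zeitgeber time the replicate means are ratioed and the
    per-time ratios combined with a geometric mean (arithmetic available
    via ``average="arithmetic"``).  Exactly multiplicative: scaling the
    old group by k multiplies the estimate by k.
    """
    _check_matched_grids(young.index.to_numpy(dtype=float), old.index.to_numpy(dtype=float))
    ym = young.groupby(level=0).mean()
    om = old.groupby(level=0).mean()
    if (ym <= 0).any() or (om <= 0).any():
        raise ValueError("zero or negative mean at a time point; fold-change undefined")
    ratios = (om / ym).to_numpy(dtype=float)
    if average == "geometric":
        return float(np.exp(np.log(ratios).mean()))
    if average == "arithmetic":
        return float(ratios.mean())
    raise ValueError("average must be 'geometric' or 'arithmetic'")


def detect_age_effects(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    young_age: int,
    old_age: int,
    alpha: float = 0.05,
    family_size: int | None = None,
    genes=None,
    log_scale: bool = True,
    fc_average: str = "geometric",
) -> pd.DataFrame:
    """Screen a normalised panel for genes whose expression changes with age.

    Compares ``young_age`` with ``old_age`` per gene using the blocked
    repeated-measures ANOVA and reports the average fold-change
    (old/young).  Significance is declared at the Bonferroni threshold
    ``alpha / family_size`` with ``family_size`` defaulting to the
    number of genes tested.  Returns a frame with columns ``gene_id``,
    ``p_value``, ``fold_change``, ``significant`` sorted by p-value.
    """
    design.check_matches(matrix)
    young_samples = design.samples_for_age(young_age)
    old_samples = design.samples_for_age(old_age)
    if not young_samples or not old_samples:
        raise ValueError("both age classes must be present in the design")
    zt = design.table.set_index("sample_id")["zeitgeber_time_h"]
    young_zt = zt.loc[young_samples].to_numpy(dtype=float)
    old_zt = zt.loc[old_samples].to_numpy(dtype=float)
    _check_matched_grids(young_zt, old_zt)

    gene_list = matrix.gene_ids if genes is None else list(genes)
    sub = matrix.select_genes(gene_list)
    m = family_size if family_size is not None else len(gene_list)
    threshold = bonferroni_threshold(alpha, m)

    yv = sub.data[young_samples].to_numpy(dtype=float)
    ov = sub.data[old_samples].to_numpy(dtype=float)
    Y = np.concatenate([yv, ov], axis=1)
    if log_scale:
        if (Y <= 0).any():
            raise ValueError("log-scale analysis requires strictly positive values")
        Y = np.log(Y)
    age = np.concatenate([np.zeros(len(young_samples)), np.ones(len(old_samples))])
    zts = np.concatenate([young_zt, old_zt])
    pvals = _blocked_age_anova(Y, age, zts)

    fcs = []
    for gi, gene in enumerate(gene_list):
        young_series = pd.Series(yv[gi], index=young_zt)
        old_series = pd.Series(ov[gi], index=old_zt)
        fcs.append(fold_change_estimate(young_series, old_series, average=fc_average))

    out = pd.DataFrame(
        {
            "gene_id": gene_list,
            "p_value": pvals,
            "fold_change": fcs,
            "significant": pvals < threshold,
        }
    )
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)
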