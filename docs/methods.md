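# Methods

## The problem

Quantitative comparisons of gene expression — between ages, times of
day, sexes, or treatments — require dividing out each sample's
arbitrary multiplicative scale (library size, RNA input amount,
hybridisation efficiency). The usual remedy is to anchor measurements
to "housekeeping" genes assumed constant. In aging tissue this
assumption is fragile: transcriptional noise rises with age and can
affect the reference genes themselves, so a poorly chosen anchor
manufactures spurious age effects or hides real ones. `clrnorm`
implements a selection procedure for normalisation marker genes that
does not presuppose any known-stable gene, followed by a
geometric-mean normalisation built from the selected markers and a
blocked ANOVA screen for genuine age-related expression changes.

## Centered log-ratio stability screening

Expression vectors are compositional: only ratios between genes carry
information. For a sample vector *x* = (x₁, …, x_N) the centered
log-ratio is

  clr(x) = ( ln(x₁/g(x)), …, ln(x_N/g(x)) ),  g(x) = (∏ᵢ xᵢ)^{1/N},

which is invariant to rescaling the sample by any positive constant.
The difference of one gene's clr values between two conditions is the
log fold-change after aligning the conditions to a common geometric
mean, so the **variance of a gene's clr across many conditions** is the
natural multi-condition generalisation of fold-change analysis — and it
requires no pre-declared reference genes. Per-gene statistics use the
unbiased (n−1) variance over condition-level values; replicates sharing
a condition label are averaged first. Natural logarithms are used
throughout; reported fold-changes are `exp` of clr differences, so the
base cancels.

Candidate reference genes are scored by four assessments:

1. **Genome-wide screen (median criterion).** On a screen with one
   pooled library per age class, after dropping genes never reaching 20
   counts in any library and adding a 0.5 pseudocount (genome-wide count
   matrices contain zeros; panels without zeros can use 0), a candidate
   passes iff its mean clr is strictly above, and its clr variance
   strictly below, the median of all assayed genes. Ties fail. The
   background includes the candidates themselves: removing a handful of
   candidates from thousands of genes does not move the median, and
   keeping them makes the criterion self-contained (configurable).
2. **Validation screen.** The same criterion on an independent screen.
3. **Panel reference-gene criterion.** On a targeted panel where every
   sample is measured individually (each of the 192 samples is its own
   condition), a candidate passes iff its clr variance is strictly below
   that of a designated reference — the least variable gene with genuine
   circadian rhythm (Cry2 in the mouse-liver panel). A useful marker
   must beat any rhythmic gene.
4. **Meta-analysis criterion.** Across many published studies, a
   candidate passes iff its symmetrised fold-change magnitude
   max(fc, 1/fc) stays strictly below 1.2 in strictly more than 90 % of
   studies (both thresholds configurable; an `inclusive` flag admits
   equality at the required fraction). Magnitudes are used because
   down-regulation counts against stability as much as up-regulation.

Verdicts are pass / fail / not-detectable (gene absent from the assay).
The **core set** contains candidates with zero fails; the **extended
set** adds candidates with exactly one fail. Not-detectable counts as
neither pass nor fail — that is the only reading under which a gene
with one fail plus one missing assay still belongs to the extended set.
The combination is invariant to row/column permutations of the table.

## Normalisation

Two multiplicative corrections, applied in order:

1. **Positive-control constants.** Hybridisation panels carry spike-in
   controls at known amounts. The constant for sample *s* and control
   *i* is c_{s,i} = expectedᵢ / observed_{s,i}; the per-sample constant
   is the geometric mean over controls, so multiplying a sample's
   counts by it converts them to the input-amount scale. A zero control
   count signals a failed hybridisation and is an error.
2. **Marker-gene factors.** For each selected marker the per-sample
   constant is (the gene's cross-sample geometric mean) / (its value in
   the sample); a sample's factor is the geometric mean of these
   constants over the markers. Anchoring each gene to its own
   cross-sample geometric mean (rather than to an arbitrary reference
   sample) makes the factors symmetric in the samples and gives them
   geometric mean 1 by construction. Markers enter with equal weight.

When the markers are truly constant, the factors invert any per-sample
multiplicative perturbation exactly (machine precision), and a genuine
fold-change on a non-marker gene passes through unchanged. With *k*
markers, corrupting a single marker by a factor *f* in one sample moves
that sample's factor by at most f^{1/k} — with the 7-gene extended set a
3-fold outlier shifts the factor by ≤ 1.17×, which is the point of
using several markers instead of one.

## Detecting age-related changes

The reference comparison is two age classes sampled on the same
zeitgeber-time grid (12 times × 2 replicates, N = 24 per group). Many
panel genes are rhythmic, so the age test blocks on time of day: age is
a fixed effect and the shared time points act as the repeated/blocking
factor. In a balanced design the mixed model with a random intercept
per time point yields exactly the same age inference as the
ordinary-least-squares F-test of age adjusted for time-point blocks,
which is how it is computed (one F-test with 1 and N−T−1 degrees of
freedom); with a single replicate per time point it reduces exactly to
the paired t-test, which the test suite asserts to 1e-6. Models are
fitted on log-transformed normalised values (noise and effects are
multiplicative); a flag allows the raw scale.

Fold-changes are reported as the geometric mean over time points of the
ratio of replicate means (old/young); an arithmetic option exists. The
estimator is exactly multiplicative.

Family-wise error over a panel is controlled by Bonferroni: with α =
0.05 and the 36-gene test family the per-gene threshold is 0.05/36 ≈
0.0013889. The family size defaults to the number of genes actually
tested and is configurable.

A two-way ANOVA (age × time, with interaction) plus Bonferroni-adjusted
per-time-point comparisons is provided for follow-up of individual
genes; unreplicated cells make the interaction inestimable and are
rejected.

## The synthetic-data generator

The generator reproduces the statistical structure the analysis
assumes, with known ground truth:

- **Panel**: 8 ages (3–24 months) × 12 zeitgeber times (0–22 h) × 2
  replicates. Expected counts are
  baseline · exp(lfc · a(s)) · (1 + amp · cos(2π(ZT − φ)/24)) · tech_s,
  with a(s) ramping 0→1 from the youngest to the oldest age, so `lfc`
  is the full old-vs-young log fold-change. Counts are gamma-Poisson
  (negative binomial), variance μ + α μ², with α inflating linearly
  with age in months — the simplest monotone model of transcriptional
  noise rising in old animals. Technical factors are log-normal with
  σ = 0.2 (typical library-size variation). The 52-gene reference panel
  holds the 16 candidate reference genes (the 7 stable ones with
  dispersion 0.002 and baselines 2000–10000, reflecting the low CVs of
  abundant, deliberately stable genes in digital counting assays), 12
  clock genes with relative amplitudes 0.2–0.9 (Cry2 lowest at 0.25),
  4 designated age-perturbed genes at the 1.52 / 0.74 / 1.33 / 1.25
  fold-changes, and arrhythmic filler genes (dispersion 0.01).
- **Spike-in controls**: a 6-step geometric ladder observed as Poisson
  counts sharing the sample's technical factor.
- **Genome-wide screen**: one pooled library per age class (pooling
  over times of day removes circadian structure). Log-normal baselines
  span ~4 orders of magnitude; variable genes receive per-age-class
  log-normal perturbations whose gene-level scale is itself log-normal,
  reproducing the orders-of-magnitude spread of clr variances;
  constructed-stable genes sit in the upper expression range with 0.05
  between-age log-sd.
- **Meta studies**: per-study log fold-changes N(0, sd_g) reported as
  magnitudes; stable genes use sd 0.05 (fold-changes concentrate well
  below 1.2), unstable ones larger scales.

All generators are bit-reproducible from an integer seed.

What the generator does **not** emulate: correlated gene modules,
age-dependent amplitude or phase changes, batch structure beyond a
per-sample scalar, zero-inflation, and assay-specific artefacts
(probe affinities, GC bias). Passing recovery tests therefore shows the
pipeline does what it claims under its own model assumptions — clean
multiplicative technical effects and negative-binomial counting noise —
not that any particular real dataset satisfies those assumptions.

## Numerical and design choices

- Strict inequalities in every pass criterion; ties fail (a literal
  reading of "above/below the median" and "below the reference").
- Pseudocount 0.5 before clr on count matrices with zeros; configurable,
  and an error is raised if zeros meet a zero pseudocount.
- clr column sums are validated to |Σ| < 1e-9 · N at construction.
- Degenerate inputs: identical groups give p = 1; a saturated noiseless
  fit (zero residual with a real age difference) gives p = 0; constant
  data in the two-way ANOVA returns p = 1 for all effects.
- Monte-Carlo validation sizes: 2000 null genes for calibration, 2000
  36-gene null panels for family-wise error, 20 seeds for the recovery,
  power and factor-recovery studies. Calibration simulations omit the
  per-sample technical factor because it is shared by all genes of one
  simulated dataset: with it, the genes would not be independent null
  replicates. Technical factors are exercised by the factor-recovery and
  power studies, which run the full normalise→detect chain.
- The factor-recovery correlation is pooled over the 20 seed runs
  (within-run centred), which estimates the estimator's accuracy rather
  than the seed-to-seed fluctuation of a 192-sample correlation.

## Known limitations

- The repeated-measures test assumes a balanced shared time grid;
  unbalanced designs are rejected rather than approximated.
- Variance heterogeneity between age groups (the aging-noise model)
  is tolerated by the balanced F-test but not explicitly modelled.
- The median criterion's background is the assayed gene universe of
  each screen; screens with very few genes make the median unstable.
- Marker selection and downstream detection are run on the same panel
  data, as in the motivating design; the selection's strictness, not a
  data split, is what guards against circularity.
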