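# Methods

`pyroherit` separates three sources of variance in high-throughput
pyrolysis molecular-beam mass spectrometry (py-MBMS) phenotyping of a
clonally replicated tree pedigree — instrumental drift, microspatial
environmental variation in the field, and genetics — and estimates
broad-sense heritability of spectral and derived cell-wall traits after the
first two have been removed. This note records the models, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter.

## Data model

A trial consists of runs (vials) organized in autosampler trays. Each run
is either a biomass sample (one technical replicate of one ramet, i.e. one
clonal copy of a genotype planted at a known field position) or one of six
quality-control standards replicated throughout the run sequence. A
spectrum is a vector of intensities over integer m/z channels 30–450
(421 channels). All analysis operates on TIC-normalized spectra (each
spectrum divided by its summed intensity), making samples comparable as
proportions. TIC normalization is idempotent and scale invariant; a
zero-total spectrum is treated as an acquisition failure and raises.

## Stage order

normalize → tray correction → technical-replicate collapse → thin-plate
spline (TPS) spatial correction → traits/heritability. The order follows
the nesting of the measurement process: drift is a property of runs (so it
is removed before replicates are averaged), while the field surface is a
property of positions (so it is fitted on ramet means). Derived scalar
traits (lignin wt%, S/G) are computed from the normalized spectra *before*
any per-ion correction and are then corrected as traits — first for tray,
then spatially — rather than being recomputed from corrected ions.

## Tray (batch) correction

For every ion, the standards' intensities are modeled as

    y[tray, standard] = mu + Tray_t + Standard_s + e,

with `Tray` and `Standard` independent random effects, fitted by EM-REML
through Henderson's mixed-model equations (dense Cholesky per sweep;
convergence when every variance component changes by a relative amount
below 1e-8, at most 500 sweeps). The *shrunken* (BLUP) tray predictions —
not raw tray means — are centered across trays and subtracted from every
spectrum in the tray. Shrinkage matters: trays carry only a handful of
standards, and raw means would subtract noise. For a tray with no
standards, a fallback model over all samples with tray as the only random
effect supplies that tray's offsets; randomization of genotypes into trays
makes the in-tray genotype mean approximately zero, which is what the
fallback relies on.

Corrected intensities live on a deviations scale and may be slightly
negative; rows are deliberately *not* re-normalized after subtraction,
because re-normalizing would mix corrected and uncorrected channels.
By default all analysis ions are corrected; the estimated per-ion tray
variance in the summary table shows which ions actually carried drift.

## Spatial correction and Surface Complexity

Genotypes are randomized within complete blocks, so a smooth surface fitted
to per-position trait values estimates the microspatial environmental
component; residuals carry genetics plus error. Per ion, a thin plate
spline is fitted over metric coordinates (row × 3 m, position × 1 m): it
minimizes `sum (z - f)^2 + lambda * J(f)` with the 2-D bending-energy
penalty, radial kernel `r^2 log r`, and an affine null space. Consequences
used as oracles in the tests: the `lambda -> inf` limit is exactly the
least-squares plane, and with one knot per point `lambda -> 0`
interpolates.

Numerical choices:

* **Reduced rank.** With all ~2700 positions as knots a single fit would
  need an O(n^3) eigendecomposition. Above 300 unique positions a
  deterministic 300-knot subset is used (thin-plate regression spline); the
  affine null space remains exact and a study-scale fit takes ~0.3 s.
* **Smoothing selection.** `lambda` minimizes GCV over 40 log-spaced values
  spanning 1e-6–1e+6 times an eigenvalue-scale heuristic. The GCV
  denominator uses an effective-df inflation `gamma = 1.4`: plain GCV
  occasionally picks a near-interpolating `lambda` on structureless
  fields, which would turn pure-noise ions into spuriously "complex" ones.
  1.4 is the standard guard value in the smoothing literature.

The fitted surface is summarized by Surface Complexity,

    SC = -log10 prod_i | cor(yhat_i, t_i) |,

the product running over field rows `i`, with `t_i` the within-row tree
positions and `cor` the Pearson correlation. A surface that varies linearly
along every row gives |cor| = 1 in each row and SC = 0; patchy surfaces
give small within-row correlations and large SC. Rows with fewer than 3
trees contribute nothing; rows where the fitted values (or positions) have
zero variance contribute a factor of 1 — "no within-row structure" is
evidence of simplicity, and the correlation is undefined there. |cor| is
floored at 1e-300 before the log and SC is capped at 300 to keep the
arithmetic finite. SC is invariant to affine rescaling of the fitted
values.

Ions with SC above the threshold (default 1) are *complex* and corrected by
replacing values with `residual + ion mean` (projecting residuals back to
the original scale, which preserves the trait mean exactly); simple ions
pass through. The product in SC runs over planting rows only; a
column-wise variant can be computed by swapping the row/position arguments
but is not the default.

## Variance components and heritability

Clonal replication identifies total genotypic variance directly. The
genotype-only model `y = mu + g + e` (g i.i.d. by genotype) is fitted by
*exact* REML: the residual variance is profiled out analytically, leaving a
one-dimensional restricted likelihood in `theta = sigma2_g / sigma2_e`
optimized on a log grid plus bounded refinement (xatol 1e-12 on the log
scale), with the boundary `theta = 0` always evaluated. On balanced designs
this coincides with the ANOVA method-of-moments estimator
`sigma2_g = max(0, (MSB - MSW)/r)` whenever that is interior — an oracle
the tests check at 1e-6. Broad-sense heritability is
`H2 = sigma2_g / (sigma2_g + sigma2_e)`, defined as 0 when the total is 0.

**Permutation thresholds.** Significance is calibrated per trait by
shuffling trait values across all ramets (the design stays fixed; blocks
are randomized, so unrestricted shuffling is the natural null), 1000
permutations by default, using the closed-form ANOVA statistic as a fast
path (one bincount pass per permutation; 1000 permutations of a
2721-ramet trait take ~50 ms). The reported threshold is the 95th
percentile of the permuted (clamped) H². The p-value compares the
*unclamped* variance-ratio statistic, which is continuous under the null:
clamped H² has an atom at zero, so p-values computed from it are not
uniform. With the unclamped statistic the test is exact
(`p = (1 + #{perm >= obs}) / (n_perm + 1)`, floored at `1/(n_perm+1)`).
No cross-ion multiple-testing adjustment is applied; each ion carries its
own per-trait threshold at alpha = 0.05.

**Parental shares.** Maternal and paternal contributions come from the
crossed model `y = mu + genotype + mother + father + e` fitted by the same
EM-REML machinery. Genotype is nested within mother × father, so the
genotype component here captures within-family (Mendelian-sampling)
variance; convergence is flagged and the last iterate returned if the EM
cap is reached. Open-pollinated offspring get one unknown-father level per
mother (`OP:<mother>`), so unknown pollen is not pooled across mothers;
founder genotypes with no recorded parents get singleton parent levels and
inform neither parental component. Each share is that component's variance
over the total (genotype + mother + father + residual).

## Composition traits

Lignin content is the sum of 17 diagnostic ion intensities
(120, 124, 137, 138, 150, 152, 154, 164, 167, 168, 178, 180, 181, 182,
194, 208, 210), converted to weight percent by a single multiplicative
response factor (RF) calibrated as the mean over standards of
`known wt% / lignin index`; with no standard composition available RF is a
configuration value (default 200). S/G is the ratio of the syringyl ion sum
(154, 167, 168, 182, 194, 208, 210) to the guaiacyl ion sum
(124, 137, 138, 150, 164, 178); it is invariant to spectrum rescaling and
undefined (an error) when the G sum is zero. Coumaryl (H) content is not
reported because of overlaps with coumarate-derived ions. Composition is
computed per technical replicate and averaged at ramet level.

## Synthetic trial generator

The generator emulates the study design the analysis assumes, so parameter
recovery is the test surface:

* **Pedigree.** 7 × 7 full factorial (19 offspring per cross) plus
  open-pollinated families trimmed round-robin to exactly 986 offspring,
  plus the 14 parents: 1000 genotypes.
* **Field.** 30 rows × 100 trees (3 m × 1 m), three contiguous 10-row
  blocks, each genotype planted once per block, uniform survival at 0.907
  (~2721 live ramets), and a flagged double border of recycled genotypes
  that never enters analysis tables. Contiguous bands were chosen so
  environmental surfaces cross block boundaries.
* **Genetics.** Per-trait genotype deviations
  `G = mother + father + SCA + Mendelian`, each term normal with its
  configured variance. The finite founder draws (7 + 7 levels, 49 cells)
  are standardized to mean 0 and *exact* configured variance: with 6
  degrees of freedom, raw draws realize the parental variance with ~58%
  relative spread, which would dominate every recovery test; standardizing
  makes the simulated population hit its nominal components. Unknown
  fathers of open-pollinated genotypes are drawn fresh per genotype.
* **Environment.** A planar trend or a sum of ≤5 seeded Gaussian bumps
  (patchy, soil-moisture-like), centered over live interior positions and
  range-scaled to the configured amplitude. Per-trait loadings couple the
  surface into the latent traits (lignin and S/G positively, C6 sugars
  negatively, echoing the observation that lignin falls and sugars rise in
  wet patches).
* **Spectra.** Seven phenomenological component templates (S-lignin,
  G-lignin, C5 and C6 carbohydrates, phenolics, acetyl, baseline); S and G
  templates live entirely on their diagnostic ion sets, so a noiseless
  spectrum's S/G equals the composition-level ratio exactly and lignin
  index equals the summed lignin fractions. Latent lignin wt% maps to
  fractions via a truth response factor of 200 (the diagnostic ions carry
  half the lignin mass). Channel noise is mean-one multiplicative lognormal
  (intensities are nonnegative and heteroscedastic); tray drift is additive
  on the normalized scale on fragment ions 167, 181 and 193 (193 sits on a
  zero baseline, so it becomes a pure instrumental channel). Runs are
  assigned to 125 48-vial trays, standards (509 runs of 6 fixed
  compositions) spread evenly, two technical replicates per ramet in
  independently randomized order.
* **Calibration.** Defaults are set by variance bookkeeping: lignin latent
  mean 25.5, genotypic variance 0.4536 and biological residual 0.325
  (plus ~0.03 measurement noise after replicate averaging) give a
  post-correction population SD of ~0.9 wt% and H² ≈ 0.56; S/G mean 2.10,
  genotypic 0.0234 and residual 0.0049 give SD ≈ 0.17 and H² ≈ 0.81.
  Channel noise sigma 0.03 and tray drift sd 0.001 reproduce a
  between-replicate lignin correlation of ~0.87–0.89 on uncorrected data.
  Phenolics are strongly maternal (a highly heritable, maternally driven
  ion family); carbohydrates lean paternal.

What the generator does **not** emulate: real fragment chemistry (templates
are phenomenological, and most of the 421 channels are empty), spatial
autocorrelation of survival, time-ordered drift within trays (drift is
exchangeable across trays by construction, consistent with the absence of
a time trend in the instrument model), genotype-by-environment interaction,
and non-Gaussian trait architectures. Passing recovery tests therefore
shows the estimators are correct under the stated model, not that real
spectra satisfy that model.

## Problem sizes used in tests

The default test suite runs the full study scale where the statistic
depends on it (heritability recovery, permutation thresholds, type-I
error at ~1000 genotypes / ~2721 ramets; TPS on the 30 × 100 grid) and a
structurally complete miniature trial (3 × 3 factorial, 6 × 30 grid, 8
trays) elsewhere. The parental-model recovery test uses a 7 × 7 × 7
factorial with 3 clones and 5 replicates, enough for the 20%-wide
Monte-Carlo bands it asserts. The demo pipeline reports heritability for
a 35-ion diagnostic subset by default (`analysis_ions="all"` covers all
421 channels) — per-ion results are per-column independent, so the subset
choice affects runtime only.

## Known limitations

* EM-REML is first-order and can be slow near variance boundaries; the
  convergence flag is carried into all result tables.
* The genotype term in the parental model is partially confounded with
  mother × father cells when clone counts are small; estimates remain
  identifiable through the clonal replication but their sampling
  covariance is large, which is why shares are validated against
  simulation truth rather than closed forms.
* SC compares fitted values only within rows; a surface varying
  nonlinearly *across* rows but linearly within them scores 0.
* The response-factor conversion to wt% is a single multiplicative
  constant; population mean targets validate the generator + estimator
  round trip, not absolute chemistry.
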