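# Methods

This note documents the statistical machinery in `primatefaces`, the
assumptions behind it, and the choices made where the design was open.

## Overview of the analysis chain

The package models human-perceived attractiveness of primate faces.
Stimuli are RGBA face images (transparent background); each species also
carries 19 facial landmarks, a sexual size dimorphism index, and two
Likert rating matrices (a "beauty" panel and a smaller "human-likeness"
panel, both scored 1–7 with 1 = most beautiful / most human-like).  The
chain is:

1. **Color/pattern quantification** per image (`imagequant`).
2. **Morphometric traits and factors** from landmarks (`morphometry`).
3. **Rater agreement and demographic screens** (`raterstats`).
4. **Species-level attractiveness models** — linear models with
   backward AIC reduction, Tukey group comparison, redundancy analysis
   with permutation tests, and a LOWESS attractiveness–human-likeness
   curve (`models`).

`synthdata` generates complete studies with known truth so every stage
is testable end to end; `pipeline` orchestrates the chain for synthetic
or file-based inputs.

## Color quantification

Pixels are converted to HSL and assigned to exactly one of eight
classes.  Hue bins (degrees, half-open, lower bound inclusive):
red [350, 360) ∪ [0, 18), orange [18, 45), yellow [45, 75), bluish
[170, 270).  Achromatic gates: black L < 0.20, white L > 0.71, gray
S < 0.15.  Remaining hues ([75, 170) and [270, 350)) form an explicit
`unclassified` class so the classes always partition the opaque pixels —
this keeps the partition property testable instead of silently dropping
pixels.

**Precedence.**  The criteria overlap (a dark red pixel is both "red"
and "black").  The order is excluded → black → white → gray → hue bin →
unclassified: achromatic content is separated before hue is consulted,
uniformly for every pixel.  Mean lightness and saturation are averaged
over *all* opaque pixels, including achromatic ones (no exclusion rule
is imposed).

**Opacity.**  A pixel counts as opaque when alpha ≥ 0.5.  Binary
stimuli use alpha ∈ {0, 1}, so the threshold only matters for
anti-aliased edges.

**Masking.**  An optional exclusion mask removes named regions (e.g.
genuinely blue facial parts) before the fractions are computed; the
fractions are renormalized over the remaining pixels, and this
renormalization is a documented choice.

**Pattern.**  The texture score is the fraction of *interior* opaque
pixels whose Sobel gradient magnitude (Rec. 601 luminance, `skimage`
kernels) exceeds a threshold (default 0.1 on the [0, 1] scale).  The
opaque mask is eroded by one pixel first, so the face outline against
the background never counts.  The operator (`sobel`, `prewitt`,
`scharr`) and threshold are configurable; only ordinal behavior of the
score is relied on anywhere.  One caveat worth knowing: any centered
3-tap derivative, Sobel included, is mathematically blind to a
1-pixel-period checkerboard (the Nyquist pattern), so "fine texture"
means structure at the 2-pixel scale or coarser.  Fractions entering
the models are arcsine-square-root transformed (radians) to improve
normality, as is conventional for proportions.

**Note on the pattern score vs. whole-image translation.**  Class
fractions and mean L/S depend only on the multiset of opaque pixels and
are invariant to translation or row/column permutation; the pattern
score depends on spatial arrangement and is not.  This asymmetry is by
design — texture *is* arrangement.

## Morphometric traits and factors

Fourteen interlandmark distances (pixels): face height A–D, face width
B–C, forehead height A–F, eye size (mean of E1–E2 and G1–G2), nose
length F–I, nose width H–J, mouth width K–M, side hair (mean of O1–B
and C–O2), top hair N–A, beard D–P, interocular E2–G2, eyes-to-mouth
F–L, philtrum I–L, chin L–D.  The nose measurements follow the
published trait list verbatim even though F–J / H–I would be the
geometrically natural choices; `nose_convention="geometric"` switches
to the latter.  Traits are used raw (the stimuli are size-standardized
upstream); distances are invariant to rigid motions and scale linearly
under uniform scaling.

**Factor analysis.**  Traits are z-scored; maximum-likelihood factors
are extracted (sklearn's EM-based `FactorAnalysis`) and rotated by
varimax with Kaiser row normalization.  Factor scores use the
regression (Thurstone) method, `F = Z R⁻¹ Λ`.  Uniquenesses at or below
zero (Heywood cases) are floored at 1e-3 with a warning.  Each factor
is oriented so its largest-|loading| trait loads positively.  Because
extraction order and orientation are arbitrary, the pipeline labels the
two facial factors by *loading pattern*: the factor with more absolute
loading mass on {eye size, interocular, mouth width, eyes-to-mouth,
philtrum} becomes the **inner** facial factor (factor2, oriented so
eyes-to-mouth loads positively), the other the **outer** factor
(factor1, oriented on face height).  Variance explained is reported as
the sum of squared loadings over the number of traits (correlation
metric), in percent.

**CVA.**  Canonical axes are eigenvectors of `W⁻¹B` with `W` the
unbiased pooled within-group covariance (divisor n − g) and `B` the
between-group scatter, solved as a symmetric-definite generalized
eigenproblem.  Items are reassigned to the nearest group centroid in
canonical space; a leave-one-out variant refits without each item.  A
ridge (`ridge * trace(W)/p` on the diagonal) handles panels with fewer
within-group degrees of freedom than traits; the pipeline falls back to
`ridge=1e-8` automatically in that case.

**PCA** is a centered (by default standardized, since traits have
heterogeneous scales) SVD; variance fractions sum to 1.

**Landmark files.**  TPS records (`LM=19`, coordinate pairs, `ID=` /
`IMAGE=` lines) and tidy CSV (`image_id, point_name, x, y`) are
supported.  TPS uses a bottom-left origin; y is negated on read and
write so internal coordinates are always top-left-origin.  Distances
are unaffected by the flip.

## Rater agreement

Ratings form a complete raters × stimuli matrix of integers 1–7.
Stimuli are the objects and raters the judges, so k in the
Spearman–Brown relation is the number of raters — transposing would
change k, hence the convention is fixed and validated.

**ICC.**  From the two-way ANOVA without interaction (rows = stimuli,
columns = raters):

    single  = (MS_rows − MS_err) / (MS_rows + (k − 1) MS_err)
    average = (MS_rows − MS_err) / MS_rows

the "consistency" forms: rater main effects are absorbed by the column
term, so raters that agree up to a constant offset agree perfectly.
`average` equals the Spearman–Brown transform `k·s / (1 + (k−1)·s)` of
the single measure algebraically, and the identity is property-tested
to 1e-10.  At the published regimes this arithmetic gives
(0.182, k=286) → 0.985, (0.147, 91) → 0.940, (0.204, 199) → 0.981.

**Gender screen.**  Per-stimulus two-sided Mann–Whitney U of male vs.
female raw scores; exact enumeration when both groups have ≤ 8 raters,
otherwise the normal approximation with tie and continuity corrections.
Significance is Bonferroni-corrected with divisor = number of stimuli.

**MANOVA.**  Per-term Wilks' Λ with Rao's F approximation, computed
directly from the multivariate OLS SSCP matrices on a patsy design
(Type-III hypotheses, treatment contrasts).  With one response this
reduces exactly to the univariate F.  When the response dimension is
too large for the error degrees of freedom, responses are first reduced
by PCA retaining 95% of variance (capped at n − p − 2 components) with
a warning; the reduction is an assumption, recorded in the result.

**Nested variance components.**  Method-of-moments estimates from the
balanced nested ANOVA (group ⊃ genus ⊃ species ⊃ individual): each
level's component is the scaled difference of adjacent expected mean
squares; negative estimates are truncated at zero and flagged.  Only
balanced designs are supported — REML would handle unbalanced data but
is out of scope here; the estimator is unbiased on the balanced designs
the tests use.

**Scale inversion** maps x ↦ 8 − x (an involution) for displays where
higher should mean more attractive; ICC is invariant under it.

## Attractiveness models

**LG ratio.**  Sexual size dimorphism as (larger-sex mass /
smaller-sex mass) − 1, negative when males are larger, zero for
monomorphic species.  Typical primate values run from about −1.4
(strongly male-larger great apes) to +0.3.

**Linear models.**  OLS via statsmodels with treatment contrasts;
the group factor uses Catarrhini as the reference level.  The ANOVA is
sequential (Type I) in the declared term order.  The response is the
per-species *raw* mean score (1 = most beautiful); inversion is applied
only for display.

**Backward AIC reduction.**  Repeatedly drop the single term whose
removal lowers AIC most; stop when no drop lowers AIC or when a
likelihood-ratio test of the candidate reduced model against the
*original full* model becomes significant at 0.05.  The elimination
trace is recorded.  Note the well-known behavior of AIC selection:
an inert 1-df term survives with probability P(χ²₁ > 2) ≈ 0.157, so
with two inert candidates the exactly-true model is selected in ~71%
of replicates — the procedure bounds expected predictive loss, not the
false-inclusion rate.

**Tukey.**  Studentized-range pairwise comparisons of group means
(Tukey–Kramer for unbalanced groups), via `scipy.stats.tukey_hsd`.

**RDA.**  Responses are centered column-wise; constrained axes are the
PCA of the fitted values of the multivariate regression on the
constraints, unconstrained axes the PCA of the residuals.  Eigenvalues
use divisor n − 1, so constrained + unconstrained sums equal the total
variance exactly; this matches R vegan's `rda()` to ~1e-7 (verified
directly and frozen into a test).  Biplot scores are correlations of
each numeric constraint with the constrained site scores.  The default
response matrix is species × raters (each rater one response column);
species × {male mean, female mean} is available by flag.

**Sequential permutation tests.**  Each ordered term is tested
conditional on the earlier terms by permuting residuals of the reduced
model: `Y* = fitted(reduced) + permuted residuals(reduced)`, with the
pseudo-F denominator recomputed from the full model on `Y*`;
`p = (exceedances + 1)/(n_perm + 1)`.  Whole-row permutation is the
special case of an empty conditioning set.

**Forward model building.**  At each step every remaining candidate is
tested conditional on the selected set; the smallest p (ties broken by
added constrained variance) enters if it clears
`max(alpha / n_remaining, 1/(n_perm + 1))`.  The Bonferroni factor over
the candidates examined at that step keeps the null inclusion rate near
alpha regardless of how many inert candidates are screened —
uncorrected per-candidate entry would admit an inert term with
family-wise probability ≈ 1 − (1 − α)^m; the floor keeps the smallest
achievable permutation p admissible.  An AIC-like criterion
(n·log(RSS/n) + 2k on the pooled residual sum of squares) is computed
alongside and logged at every step; the permutation p is the primary
stopping rule and the AIC analogue is advisory.

**LOWESS.**  Robust locally weighted regression (tricube weights,
3 robustness iterations, span 2/3 by default) through statsmodels; a
span too small to hold a 4-point neighborhood is widened with a
warning.  The pipeline draws the curve for the Catarrhini on inverted
scales (higher = more attractive / more human-like), the view in which
an "uncanny valley" appears as a dip.

## The synthetic-data generator

The generator emulates the statistical structure of the target study:
107 species-level stimuli in three groups (33 prosimians, 24
Platyrrhini, 50 Catarrhini), 286 beauty raters (about 32% male, ages
~15–69, mean 22.7) and 60 human-likeness raters, all rating every
stimulus.

**Species truth.**  Each species carries: two latent morphology factors
(outer/inner, standard normal) that displace a group-specific landmark
template along fixed displacement fields; a human-likeness true value
(group means ≈ 2.6 / 4.2 / 5.4 for Catarrhini / Platyrrhini /
prosimians on the 1–7 scale, 1 = most human-like); an LG ratio drawn in
the group-typical range (Catarrhini most male-larger, overall within
[−1.4, 0.32]); a color-composition vector (Dirichlet around
group-typical means: prosimians achromatic black/white/gray, New World
monkeys yellow-orange, Catarrhini red-brown; a small bluish-tint
component everywhere); and a fur-pattern level (Beta draws, prosimians
most agouti-like).

**Stimuli.**  An axis-aligned elliptical face on a transparent white
background.  Opaque pixels are apportioned among the color classes in
exact integer counts (largest-remainder method) and painted as
contiguous angular sectors, so quantification recovers the generating
fractions *exactly*, not approximately.  The pattern level sets the
area fraction of a central region textured as a 2×2-pixel checkerboard
of darker/lighter variants of each class's own color — the variants
stay inside the class's HSL bin, so texture never changes class
membership, and the 2-pixel cell size is chosen because Sobel cannot
see 1-pixel alternation.  Landmark digitization adds isotropic Gaussian
noise (default SD 1.5 px), with eye-row vertical noise clipped so the
four eye points stay within 3·SD of a common horizontal line.

**Ratings.**  The latent score of rater i for species j is
`Σ_k w_k c_jk + b_i + e_ij` — a linear combination of species
covariates, a rater intercept (SD `rater_sd`) and residual noise (SD
`residual_sd`) — discretized through six fixed cutpoints into 1–7.
The default weights (raw scale, 1 = most beautiful)
are: inner facial factor +0.35, LG −0.5, human-likeness +0.21, bluish
tint −1.6, Platyrrhini +0.29, prosimians −0.8.  The large direct
prosimian offset is deliberate: prosimians carry a human-likeness
penalty of ≈ +1.1 through the +0.21 weight, and the offset must
outweigh it for prosimians to come out the most attractive group
overall — the qualitative pattern the generator is meant to reproduce.
The survey's true latent rating model is unknown; the linear-latent +
cutpoint model is an explicit assumption.

Cutpoints default to equal-probability standard-normal septiles scaled
by the model-implied latent SD and centered on the mean signal, so the
seven categories are used roughly uniformly.  Categorization attenuates
correlations by a factor λ² ≈ 0.92 (λ = Cov(Z, s(Z))/σ_s for septile
scoring of a standard normal); `simulate_icc_matrix` inverts this
analytically to hit a target observed ICC, and the calibrated defaults
(`rater_sd` 0.5, `residual_sd` 1.1 for beauty; 0.3 / 1.36 for
human-likeness) land the single-measure beauty ICC near 0.18 (hence
average-measure ≈ 0.985 at 286 raters) and the human-likeness single
measure near 0.55.

A configurable subset of species (default 5) receives an additive
male-rater offset (default −1.0 latent, i.e. men find them more
attractive), emulating a small gender effect and giving the
Mann–Whitney screen something to find.

**Determinism.**  One global integer seed; all stage seeds derive from
it by fixed offsets.  Identical seeds give byte-identical studies.

**What the generator does not emulate.**  Faces are flat-colored
ellipses: no photographic texture, lighting, pose, or fur; landmark
configurations are linear displacements of templates rather than
biological shape variation; raters have no ordinal response styles
(e.g. end-aversion) beyond an additive intercept; species are
phylogenetically independent draws.  Passing tests therefore certify
the *estimators* — exact color recovery, factor/CVA geometry, ICC
arithmetic, selection behavior, permutation calibration — not the
photographic pipeline or the behavior of the statistics under real
rater pathologies.

## Problem sizes and defaults used in checks

End-to-end checks run the default study (107 species, 286 + 60 raters)
with 64–96 px stimuli; permutation tests use 99–499 permutations in
routine checks (the `n_perm` switch accepts anything ≥ 99, and 10 000
is the conventional choice for final inference).  Replicate-based
checks use 20–200 replicates depending on the Monte-Carlo precision the
assertion needs.  These sizes are the package's test conditions, chosen
so Monte-Carlo error is small relative to each assertion's tolerance.

## Known limitations

* The original color-extraction software's exact edge-detection
  normalization is unknown; only ordinal properties of the pattern
  score are meaningful.
* Variance components require balanced designs (method of moments);
  REML is not implemented.
* MANOVA response reduction by PCA is an assumption; results with
  reduced responses are not comparable across different reductions.
* The RDA AIC analogue is advisory; model building is governed by the
  permutation p-values.
* With the deposited study data (images, landmarks, ratings laid out as
  in `pipeline.InputPaths`), the file-input mode recomputes the
  data-dependent statistics (model r², constrained variance, factor
  variances); without it those numbers are only defined for synthetic
  studies.
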