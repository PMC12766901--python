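# Methods notes

This note records the statistical models the package implements, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical conventions adopted where the published
descriptions of these methods leave room.

## Regional homogeneity

ReHo is Kendall's coefficient of concordance *W* computed over a voxel's
cubic neighbourhood (centre plus 26 neighbours by default; 7- and 19-voxel
variants are available). Each series is ranked independently along time with
mean ranks at ties, and the tie-corrected denominator K²(n³−n) − K·ΣTⱼ is
used; uncorrected *W* is upward-biased whenever BOLD quantisation produces
tied samples. Neighbours outside the brain mask are dropped (K shrinks at
mask edges) rather than zero-padded, which would inject artificial ties. A
voxel with no in-mask neighbours gets W = 0, as does an all-constant
neighbourhood (zero denominator). W is computed on unsmoothed data; maps are
then normalised by the whole-brain mean (making the in-mask mean exactly 1)
and finally smoothed — this order matters, because smoothing first would mix
neighbourhoods before the concordance is measured.

Smoothing is a mask-restricted Gaussian with σ = FWHM/(2√(2 ln 2)) per axis
in voxel units; kernel mass falling outside the mask is renormalised away by
dividing by the smoothed mask, so a constant in-mask map is a fixed point
and FWHM 0 is the identity. Default FWHM 4 mm.

## Degree centrality

For every in-mask voxel, DC is the sum of its Pearson correlations with all
other in-mask voxels that exceed r = 0.25; only positive correlations
contribute and the self-correlation is excluded. A binary-count variant is
available. Zero-variance series are given zero correlations and logged. The
common description of the final step as a "Fisher-Z transformation" is
ambiguous for a sum of correlations (artanh is undefined past 1); this
package follows the dominant toolbox convention and z-scores the map within
the mask (subtract in-mask mean, divide by in-mask SD). An
artanh-of-mean-suprathreshold-r variant is provided behind
`DcParams.standardization` for comparability. Whether DC maps are smoothed
is likewise left open in common usage; the pipeline smooths them with the
same 4 mm kernel as ReHo for symmetric treatment, and this is configurable.

## Group inference

Scalar comparisons use the pooled-variance Student t (the convention of the
clinical baseline table this mirrors, in both raw-sample and
summary-statistic form) and the Pearson χ² without continuity correction.
Partial correlation residualises both variables on the covariates plus an
intercept via OLS and correlates the residuals; p-values use
t = r√((n−k−2)/(1−r²)) on n−k−2 degrees of freedom. A variable fully
explained by the covariates has no residual variation and its partial
correlation is reported as 0. Bonferroni adjustment is min(1, p·m).

Voxel-wise maps come from per-voxel OLS on a design of group indicators
(dummy-coded against the alphabetically first group) plus age, gender
(0/1), education and mean framewise displacement. Three-group F maps use the
nested-model comparison (covariates-only vs covariates + group); post hoc t
maps are the pairwise group contrasts of the full model and are not
restricted to ANOVA-significant voxels (configurable by masking afterwards).

Multiple-comparison control is permutation max-cluster-extent inference:
threshold |t| at the two-tailed voxel-level quantile (default p < 0.001),
label 26-connected supra-threshold components (matching the ReHo
neighbourhood convention; 6/18 available), and compare each observed extent
against the permutation distribution of the *maximum* extent obtained by
permuting the subject maps relative to the design. Corrected p-values use
the add-one estimator (1 + #{≥})/(1 + n_perm), so the smallest attainable
p is 1/(1+n_perm). This is exact under exchangeability of subjects, which
holds for the two-group null with covariates drawn independently of group;
it replaces closed-form random-field corrections, whose smoothness
machinery is both heavier and untestable at these grid sizes. Calibration is
verified empirically: across 50 null cohorts the family-wise error count
must fall inside the central 95% interval of Binomial(50, 0.05).

## Connectome-based prediction

Connectivity matrices are artanh-transformed Pearson correlations of
region-mean series (perfect correlations clipped to artanh(1−10⁻⁷) and
flagged; the diagonal is zero by convention). Edge selection correlates each
edge with the behaviour across training subjects and keeps p < 0.001 edges,
split by sign. The negative-network model is the headline model; positive
and combined (bivariate) models are implemented. Prediction is a univariate
linear regression of behaviour on network strength, evaluated by
leave-one-out cross-validation with selection redone inside every fold —
the held-out subject never influences its own fold's edge mask, which a
dedicated outlier test enforces. Significance permutes the behaviour vector
and repeats the whole procedure (one-tailed add-one p).

A fold whose selected-edge set is empty predicts the training mean and is
flagged. If *every* fold is empty the run has produced no connectome model
at all, and the prediction correlation is reported as 0: leave-one-out
training means are a strictly decreasing function of the held-out value, so
their correlation with the observations is −1 identically, and propagating
that artifact would make a completely null run look like a strong
(anti-)signal.

## Clinical improvement criteria

RC = 1.96·SD₁·√(2(1−α)) with SD₁ the baseline SD of the scale and α its
Cronbach reliability (a required input — the package does not estimate it
from item data, but ships `back_solve_alpha` to audit a published RC).
CS = (M_clin·SD_norm + M_norm·SD_clin)/(SD_norm + SD_clin) is a convex
combination of the two group means and therefore always lies between them.
Improvement at a visit requires all three of: positive change, change
strictly greater than RC, follow-up score strictly greater than CS.
"Exceeding" and "surpassing" are read as strict; a change exactly equal to
RC does not count, and the boundary convention is stated in the output.

## Leave-pair-out SVM

Every (positive, negative) subject pair is held out in turn; the classifier
(RBF kernel by default; the 2-parameter accuracy surface over C and kernel
width is exported for inspection) is trained on the remaining subjects with
features standardised by training statistics only. A subject's final call is
the majority vote over all pairs containing it, ties going to the positive
class and logged; metrics are always recomputable from the confusion counts.
The default grid is a log₂ lattice C ∈ 2⁻⁵…2¹⁵, γ ∈ 2⁻¹⁵…2³ at exponent
step 4 — the conventional coarse grid — because leave-pair-out evaluates
every cell with n_pos × n_neg fits; a finer lattice can be passed in. Ties
in grid accuracy resolve to the smallest C, then the smallest γ.

## The synthetic cohort generator

Each voxel in region r follows
x(t) = c_r·s_r(t) + w_r·h(t) + a·u_e(t) + σ·ε(t): an i.i.d. standard-normal
region signal s_r shared by the region's voxels, a brain-wide latent h, an
optional per-edge latent u_e shared by the two regions of a planted
behaviour edge, and white voxel noise. The knobs map one-to-one onto what
the downstream stages measure:

* `coherence_boost` raises c_r in chosen regions for the targeted group —
  a ReHo effect. Baseline coherence is 0.2 everywhere (real grey matter is
  never locally incoherent; a zero floor would make "no effect" regions
  unrealistically flat).
* `hub_strength` sets w_r = strength in hub regions and 0.3 × strength
  elsewhere; the weak broadcast echo is what makes hub voxels correlate
  with the whole brain (a DC effect) rather than only with each other.
* `edge_coupling` ± `edge_coupling_sd` give each subject a trait amplitude
  a for the planted edges' shared latents; the trait makes edge strength
  vary *between* subjects, which is the variance CPM feeds on, and the
  behaviour score is a weighted edge sum plus Gaussian noise.

Clinical score tables are drawn Gaussian and affinely rescaled so each
group's sample mean and unbiased (ddof = 1) SD match the requested values
exactly, to ~10⁻⁹ regardless of seed. This turns printed summary statistics
into deterministic targets: the pooled t computed from a generated table
equals the t computed from the summaries. The default clinic is 55 controls
vs 92 patients with the baseline RBANS/demographic summaries in
`BASELINE_GROUP_STATS`; patient follow-up RBANS T is generated at
90 ± 12 (week 12) and 92 ± 12 (week 24) — a modest mean gain with widened
spread, chosen once to yield a realistic mix of reliably improved and
non-improved patients under the RC/cutoff rule. Gender is Bernoulli (or
exact counts when given) coded 0/1 for covariate use.

Determinism: one master seed spawns an independent stream per subject by
counter; identical (design, seed) reproduces a cohort bit-identically, and
the pipeline's rerun test checks artifact hashes.

What the generator does **not** emulate: hemodynamic response shape,
physiological (cardiac/respiratory) noise, scanner drift, motion artifacts,
spatial autocorrelation beyond region structure, and any preprocessing
(series are born "clean"). Passing recovery tests therefore demonstrates
that the estimators measure what they claim on data satisfying their
assumptions — not that those assumptions survive contact with raw scanner
data, whose preprocessing is out of scope here.

## Problem sizes used in validation

The calibration and recovery checks run at sizes chosen to make their
statistical claims meaningful while remaining desk-scale: family-wise-error
calibration uses 50 null cohorts of 10+10 subjects on an 8×8×8 grid with
500 permutations each; CPM recovery uses 60 subjects, 20 regions and a
planted 10-edge negative network at 2:1 signal-to-noise over 20 seeds;
SVM chance-level calibration uses 20 replicates of 30+30 subjects. The
pipeline demo cohort is 12 patients and 8 controls on an 8×8×8 grid.

## Known limitations

* Permutation cluster correction permutes whole subject maps, which also
  permutes covariate assignments; this is valid under full exchangeability
  but is not a Freedman–Lane residual permutation, and may be conservative
  or slightly liberal when covariates are strongly group-imbalanced.
* The cutoff formula assumes roughly normal score distributions in both
  groups; heavily skewed scales would need a different criterion.
* Leave-pair-out majority voting has no universally agreed aggregation;
  the per-subject majority vote used here is one defensible choice and is
  configurable in spirit (the mean decision value is recoverable from the
  vote fractions).
* CPM edge selection uses plain Pearson correlation without covariate
  adjustment; a partial-correlation selection mode would change which edges
  pass the threshold when behaviour is confounded.
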