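# Methods

This note documents the models, estimators, and numerical choices behind
`episcale`, and what the synthetic-data validations do and do not show.

## Paradigm model

The generator reproduces the structure of a timeline placement experiment:
3 runs × 16 episodes × 5 objects (defaults). Each episode is a green
boundary screen (0.6 s), five objects (0.6 s each), and a red boundary
screen (0.6 s), separated by six gaps — three drawn uniformly from
(0.1, 2.0) s and three from (2.1, 3.5) s, assigned to gap positions by a
uniformly random permutation. The expected stimulus-period duration is
therefore 7·0.6 + 3·1.05 + 3·2.8 = 15.75 s. Each episode is followed by a
10 s cross-fixation, a 10 s odd–even task, a timeline test (duration drawn
from N(50.5, 13²) s, split into a fixed 5 s planning segment and an
execution segment), and a second odd–even task that downstream GLMs leave
unmodeled as the implicit baseline. Object identifiers are unique across
the experiment; the recognition pool holds the 240 presented objects plus
145 lures (385 items).

## Timeline decomposition

Given true times *t* and recalled times *r* (matched by item identity),
the similarity alignment is solved in closed form:

* translation: `r → r + (mean t − mean r)`; the reported `translation` is
  the inverse of the applied shift, i.e. the signed centroid offset.
* scale: `s* = ⟨t̃, r̃⟩/⟨r̃, r̃⟩` on centered patterns (the 1-D
  least-squares/Procrustes scale mapping recalled onto true). The reported
  `scaling = 1/s*` is the recalled spread relative to the true-fit spread,
  so `< 1` reads as compression in memory. The joint (shift, scale)
  least-squares optimum coincides with this sequential solution, which the
  test suite verifies against an independent grid-search oracle refined to
  1e-4.
* pattern score: residuals of the aligned positions to the **closest**
  true position (ties broken toward the earlier true position), squared,
  summed, negated. Closest-position matching never yields a larger
  residual sum than identity matching.

Degenerate responses (all items at one point) leave the scale undefined:
`scaling` is NaN, the residuals are computed at scale 1, and the trial is
flagged rather than dropped. Anti-correlated responses (negative `s*`)
report the spread-ratio magnitude.

Item-level scaling is the ratio of the smallest gap from an item to its
temporal neighbor(s) in the recalled versus the true pattern (endpoints
have a single neighbor). Order scores are absolute rank deviations after
sorting placement times (stable sort; ties keep placement order).
Between-episode analyses apply the same decomposition to episode
placements within a run — the ground-truth position of an episode is its
stimulus-period midpoint — in full runs, fixed windows (1–4, 5–8, 9–12,
13–16; five-episode variant 1–5, 6–10, 12–16), and expanding windows
1–5 … 1–16.

## Response simulation

A participant is an affine-plus-noise distortion model: recalled =
centroid + scaling_bias·(true − centroid) + translation_bias + Gaussian
noise, clipped to the timeline bounds (a drag-and-drop interface cannot
place items outside the timeline), with adjacent placements swapped with a
configurable probability so order and timing errors stay coupled. The
identity participant reproduces truth exactly and anchors every metric's
zero point. Clipping truncates strongly expanded patterns near the
boundaries; parameter recovery is therefore assessed on participant-level
estimates (mean over 48 episodes), which recover planted scaling biases of
0.7/1.0/1.3 to ±0.02 without noise and to ±0.05 at 0.3 s pattern noise
(the least-squares scale carries a small noise-dependent bias of order
σ²/(b·Var(t)) that does not vanish per episode).

`simulate_population` draws heterogeneous participants with log-normal
scaling biases; with positive `noise_coupling`, compressors also place
items more precisely, which is the regime in which compression predicts
better relative-timing and order memory downstream.

## Shuffle nulls and the 2-Wasserstein test

Labeled distributions are participant averages of scores against each
trial's own truth; shuffled distributions rescore each response against
every other episode's truth (timing measures; K − 1 = 47 comparisons per
episode), score 5000 random rank sequences against the ordered sequence
(order measures), draw 5 items repeatedly from the selection or the full
pool (recognition; both sides scored as non-lure counts so they share a
scale), or compare random to correct groupings (association).

The 1-D 2-Wasserstein distance is computed from the quantile
representation (exactly the RMS difference of sorted samples at equal
sizes; a 1000-point midpoint grid otherwise). The null is a pooled
resampling bootstrap (default 5000); when the observed distance exceeds
the 90th null percentile, the tail p-value is refined by a
maximum-likelihood generalized Pareto fit to the exceedances (falling back
to the empirical p with a flag if the fit fails). The pooled bootstrap is
mildly conservative at n ≈ 30 (empirical type-I ≈ 0.035 at α = 0.05 over
1000 simulations), which the calibration test tolerates within the
binomial envelope. ROC analysis orients the classifier so AUC ≥ 0.5 and
takes the Youden-index cutpoint; FDR is Benjamini–Hochberg.

## Mixed models and mediation

All trial-level models are Gaussian random-intercept mixed models
estimated by maximum likelihood (statsmodels `MixedLM`); AIC is computed
as −2ℓ + 2k with k counting fixed effects, the intercept variance, and
the residual variance. Term selection is forward-only: the candidate that
most lowers AIC enters until none improves, with quadratic companions
available for the scaling and position terms; the selection path is
logged. VIF is 1/(1 − R²) per term; p-values are pooled into one BH
family across models. Mediation is quasi-Bayesian: coefficient vectors
are drawn from each fitted model's asymptotic normal, ACME draws are the
product a·b, ADE draws are the direct coefficient, with percentile 95%
intervals over 5000 draws (1000 in the calibration loop) and significance
gating of the two constituent paths at p < 0.05. Coverage of a planted
a·b = 0.30 indirect effect is ≥ 93% over 100 simulated 40-participant
studies when the mediator and outcome equations carry independent
participant intercepts; a shared intercept makes the mediator endogenous
and biases ACME upward — a property of the data, not the estimator.

## First-level GLM

The canonical HRF is the SPM-convention double gamma (response gamma
shape 6, undershoot shape 16, unit scales, undershoot ratio 1/6, 32 s
support, unit peak). Events are boxcars of their stated durations
convolved at 16× oversampling. Model one has one regressor per object
event plus cross-fixation, post-fixation odd–even, timeline planning and
timeline execution regressors and an intercept (245 columns on the full
design); model two has one regressor per episode for each of the five
periods plus an intercept (241). Runs are concatenated on a session
timeline with a 32 s gap. No drift regressors are included, matching the
modeled regressor set. DVARS is the frame-to-frame RMS signal change;
outliers (box-plot rule, > Q3 + 1.5·IQR) each receive a spike regressor.
Simulated motion spikes are sustained displacements, so each planted
spike flags exactly one frame. Estimation is per-voxel OLS; residuals are
retained for noise normalization. Rank deficiency raises an error naming
a dependent column.

## Searchlight RSA

Searchlights are the 10 nearest in-mask voxels (center included) within a
10 mm cap at 3 mm resolution; ties at the cutoff break by lexicographic
grid order and centers that cannot reach 10 members are skipped with a
report. Within each searchlight the residual covariance is estimated
with analytic shrinkage of the off-diagonal toward the diagonal
(Schäfer–Strimmer form), patterns are multiplied by its inverse matrix
square root, and squared Euclidean distances on the whitened patterns
(= Mahalanobis on the raw patterns) form the RDM — within-episode object
pairs (10 per episode) or all episode pairs.

The within-episode model RDM assigns each pair its episode's signed
scaling contrast `scaling − 1` (compressed episodes predicted more
similar); the between-episode model is `|vᵢ − vⱼ|` on a per-episode
scaling variable (expansion dissimilarity). Observed-model association is
Spearman's rho, vectorized over searchlights. For within-episode analyses
a partial rank correlation controls temporal proximity; the covariate is
the design-induced noise multiplier of each pair's beta difference,
`C_ii + C_jj − 2C_ij` with `C = (X'X)⁻¹` over the event regressors — a
deterministic function of the inter-object millisecond timing. A plain
|Δt| covariate leaves a systematic positive null bias, because tightly
spaced episodes simultaneously inflate the noise in the scaling estimate
(raising the model value) and the collinearity of their event regressors
(raising the estimated distances); the design-variance form captures that
artifact exactly and restores a clean null.

Subject rho maps are Fisher-z transformed, smoothed with a 6 mm FWHM
mask-renormalized Gaussian kernel, and tested at the group level with
one-sample t statistics, a cluster-forming threshold at one-sided
p = 0.001 (26-connectivity), and a max-cluster-mass sign-flip null — all
2ⁿ flips for n ≤ 12 subjects, Monte Carlo otherwise, identity included —
with cluster significance at corrected p ≤ 0.05. Empirical FWER on
pure-noise maps is ≈ 0.047 over 1000 simulations.

## BOLD simulator

Each object event carries a latent voxel pattern. Within episode k the
object patterns are mixtures `√w·episode + √(1−w)·unique` with a logistic
weight `w = σ(integration_strength·(1 − S_k))` driven by the episode's
response-derived scaling — exactly 0.5 (no coupling) at zero strength.
Episode patterns lie along a fixed direction at coordinate
`differentiation_strength · EpisodeScaling^Exp_k` plus unique components.
Time series are HRF-convolved event boxcars weighted by the patterns,
plus AR(1) Gaussian noise and a 100-unit baseline. TR defaults to 2.57 s,
voxels to 3 mm. The simulator does not model regional hemodynamic
variability, physiological noise spectra, or scanner drift; passing
recovery tests therefore demonstrates the pipeline's statistical
correctness under planted effects, not performance on real acquisitions.

## Validation problem sizes

The end-to-end recovery studies use a compact design (1 run × 16 episodes
with shortened consolidation and test periods), 16³ voxel grids, 12
subjects per dataset, 512 sign flips, 5 planted and 10 null datasets per
mode; calibration loops use 200 simulations (Wasserstein type-I, cluster
FWER) and 100 (mediation coverage). These sizes were chosen so the whole
suite runs comfortably on one CPU while leaving the binomial envelopes
meaningful.

## Known limitations

* The scaling estimator's noise bias (order σ²/Var(t)) is inherent to
  least-squares alignment of 5-point patterns; analyses treating scaling
  as a response variable inherit it.
* The shuffle null for between-episode timing compares four-episode
  windows across runs, which assumes window-level exchangeability.
* The GLM omits temporal autocorrelation correction (OLS betas with AR(1)
  noise are unbiased but not minimum-variance); prewhitening happens only
  spatially, in the RSA stage.
* Searchlight inference assumes a common mask across subjects; no
  anatomical registration or atlas labeling is provided.
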