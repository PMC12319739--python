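# episcale

Temporal distortion analysis for timeline-based episodic memory
experiments: from ground-truth schedules and simulated participants to
mixed-model inference and searchlight fMRI pattern analysis.

## The scientific problem

In a timeline placement paradigm, participants watch short "episodes" —
five unique objects presented at irregular intervals between a green
(start) and a red (end) boundary screen, 16 episodes per run, three runs —
and afterwards reconstruct *when* each object (and later, each episode)
occurred by dragging it onto an empty timeline. Memory for time is
systematically distorted: people compress or expand intervals, shift whole
patterns, and scramble order. The analytical question is how these
distortions decompose, whether precise timing is encoded at all (against a
shuffle null), how timing distortions relate to order and recognition
memory, and whether temporal compression/expansion in memory maps onto the
integration/differentiation of brain activation patterns.

`episcale` implements that full analysis chain as a tested library on
synthetic data, with known generative parameters at every stage.

## The core decomposition

For a true pattern *t₁…tₙ* and recalled pattern *r₁…rₙ* (matched by item
identity), the response is aligned by a 1-D similarity transform estimated
in two least-squares steps:

1. **Translation** — shift the recalled pattern so its centroid matches the
   true centroid; the reported `Translation` is the signed centroid offset
   `mean(r) − mean(t)` (distortion relative to the episode boundaries).
2. **Scaling** — the least-squares scale `s* = ⟨t̃, r̃⟩ / ⟨r̃, r̃⟩` maps the
   centered recalled pattern onto the centered truth; the reported
   `Scaling = 1/s*` is in memory orientation: `< 1` means the participant
   compressed the intervals, `> 1` expanded them. One-sided magnitudes
   `Scaling^Compr = max(0, 1 − S)` and `Scaling^Exp = max(0, S − 1)` feed
   the directional analyses.
3. **Temporal pattern score** — after translation and scaling, each aligned
   position is matched to the *closest* true position; the squared
   residuals are summed and negated (`0` = perfect relative timing).

Item-level measures (absolute deviation per item, the ratio of smallest
neighbor gaps), rank-order deviations, windowed between-episode variants,
and recognition/association scores complete the trial-level measure table.
Downstream, the package provides:

* **Shuffle-null testing** — correctly-labeled vs mislabeled score
  distributions compared with the 1-D 2-Wasserstein distance, a pooled
  bootstrap null with a generalized Pareto tail refinement, ROC/Youden
  cutpoints, and BH-FDR.
* **Mixed models** — random-intercept linear mixed models (ML), forward
  AIC term selection, VIF collinearity checks, quasi-Bayesian causal
  mediation (ACME/ADE with percentile intervals), Spearman matrices.
* **First-level GLM** — double-gamma HRF, per-object-event (model one,
  245 regressors on the full design) and per-episode-period (model two,
  241) designs, DVARS spike scrubbing, per-voxel OLS.
* **Searchlight RSA** — 10-voxel searchlights within a 10 mm radius,
  multivariate noise normalization (shrinkage covariance prewhitening,
  squared Euclidean ≡ Mahalanobis), behavioral model RDMs from the scaling
  measures, partial Spearman correlation, 6 mm mask-normalized smoothing,
  and one-sample sign-flip max-cluster-mass group inference.
* **Synthetic data** — schedule generation, parameterized participants
  (scaling/translation biases, pattern noise, order swaps), and a BOLD
  simulator that plants within-episode pattern integration coupled to
  temporal compression and between-episode differentiation coupled to
  temporal expansion.

## Worked example

```python
import numpy as np
import episcale as e

design = e.ExperimentDesign(rng_seed=0)          # 3 runs x 16 episodes x 5 objects
schedules = e.generate_schedule(design)

# a participant who compresses time by 30% and places items with 0.4 s noise
pm = e.ParticipantModel(global_scaling_bias=0.7, pattern_noise_sd=0.4,
                        episode_noise_sd=8.0, rng_seed=1)
resp = e.simulate_responses(schedules, pm, design)

s = schedules[0]
dec = e.decompose(s.relative_onsets(),
                  resp.object_placements[(1, 1)], bounds=(0, s.duration))
print(f"scaling {dec.scaling:.3f}  translation {dec.translation:+.3f} s  "
      f"pattern {dec.pattern_score:.3f}")

table = e.build_measure_table(schedules, [resp], design)
print(f"mean Scaling_P1 {table.scaling_p1.mean():.3f}  "
      f"mean Object order_O1 {table.order_o1.mean():.3f}")
```

prints

```
scaling 0.686  translation +0.088 s  pattern -1.010
mean Scaling_P1 0.709  mean Object order_O1 0.042
```

i.e. the decomposition recovers the planted 0.7 compression from the noisy
placements (per-episode scaling estimates average 0.709 across the 48
episodes), the centroid of this episode drifted 0.09 s late, the residual
relative-timing error after optimal translation and scaling is
−1.01 s² summed over the five objects, and the placement noise produced
occasional order inversions (mean rank deviation 0.04).

The `episcale` command exposes the same stages as subcommands
(`simulate`, `score`, `nulltest`, `models`, `glm`, `rsa`); see
`episcale --help`.

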