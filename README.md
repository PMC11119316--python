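# gazexplore

Exploration metrics and classifiers for **short eye-tracking recordings**,
aimed at screening research on gaze dynamics in autism spectrum disorder
(ASD) versus typically developed (TD) children.

Long recording sessions are hard to obtain from young children. This
package implements an analysis that needs only the **first five seconds**
of a 60 Hz gaze trajectory:

* **Kinematics.** Gaze speed is the raw first difference
  `v(tᵢ) = ‖(X(tᵢ), Y(tᵢ)) − (X(tᵢ₋₁), Y(tᵢ₋₁))‖ / (tᵢ − tᵢ₋₁)`
  in degrees of visual angle per second. Within each eye-movement state
  (fixation F, saccade S) speeds are approximately log-normal, so all
  statistics work on `log₁₀ v`.
* **Two-state Markov features.** Six quantities summarise a trajectory:
  the log-velocity mean and population SD per state (μ_F, σ_F, μ_S, σ_S)
  and the per-sample switch probabilities P_FS (fixation→saccade) and
  P_SF (saccade→fixation).
* **The exploration metric Λ.** Tile the screen plane with 0.5° grid
  cells and let A(t) be the number of distinct cells visited within the
  first t seconds. Then

  `Λ(τ, N) = (1/N) · Σₖ₌₁ᴺ A(kτ) / (kτ)`,  τ = 1/60 s, N = 300,

  a time-weighted average exploration rate (cells/s) over nested windows
  up to 5 s, with the earliest windows weighted most. Λ needs no
  fixation/saccade labelling at all.
* **Classifiers and statistics.** A threshold rule on Λ (exhaustive
  search maximising training accuracy) and a logistic model on
  (μ_F, σ_S, P_FS), both evaluated with stratified 5-fold
  cross-validation; Welch/pooled t tests and the Mann–Whitney–Wilcoxon
  rank test for group comparisons; |β| and permutation feature
  importance.
* **A generative simulator.** A two-state Markov chain with
  state-specific log-normal speeds produces labelled synthetic
  trajectories, so every stage of the pipeline is testable without
  proprietary recordings. Shipped parameter sets (`TD_PARAMS`,
  `ASD_PARAMS`) are published group means for the two populations.

## Worked example

Simulate a two-group cohort, extract per-trial features, and evaluate:

```sh
gazexplore simulate --out-dir cohort --n-trials 20 --duration 10 --seed 42
gazexplore features --input-dir cohort --out features.csv
gazexplore evaluate --features features.csv --out report.json --seed 42
```

The last command prints

```
lambda classifier pooled accuracy 0.875 (sens 0.850, spec 0.900)
```

and `features.csv` holds one row per trial. Group means from this run:

```
        mu_F  sigma_F   mu_S  sigma_S   p_FS   p_SF  lambda
group
ASD    1.202    0.429  2.152    0.610  0.059  0.335  33.583
TD     1.040    0.430  2.143    0.721  0.052  0.383  25.371
```

The feature estimates recover the generative group parameters (e.g. TD
μ_F = 1.04, P_FS = 0.0502), and the ASD-parameterised group — faster
fixations, more frequent saccades — explores more: its mean Λ is ≈ 8
cells/s higher, the clearest group difference in the report
(MWW p ≈ 8 × 10⁻⁷, versus p ≈ 0.9 for σ_F). `report.json` contains the
full group statistics, pooled and per-fold confusion matrices for both
classifiers, fitted coefficients and feature-importance rankings, plus
the seed and a configuration hash so reruns are reproducible
byte-for-byte.

The same pipeline accepts real eye-tracker exports (delimited text with
time, gaze x/y in pixels, and a fixation/saccade/blink event column);
column names, label vocabulary, screen geometry and every analysis
constant are configurable — see `gazexplore.cli.RunConfig`.

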