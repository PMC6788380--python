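# gaitdyn

Latent-dynamics inference and kinematic decoding for neural population
recordings during locomotion.

A recording session is a continuous stream of 10 ms spike-count bins,
aligned 1:1 with 100 Hz hind-limb marker frames and segmented into trials of
one gait cycle each (foot-strike to foot-strike; stance is 0–60% of the
cycle, swing 60–100%). The package provides:

- **`gaitdyn.synthetic`** — a ground-truth session generator: cyclic
  low-dimensional latent dynamics (rotation planes phase-anchored to the
  gait cycle), conditionally Poisson spike counts through an exponential
  link, marker kinematics that are affine in the latents, per-condition
  speed offsets, and trials with missing kinematics.
- **`gaitdyn.preprocess`** — spike binning, trailing-window firing rates,
  z-scoring with train-fold statistics, joint-angle sine/cosine and leg
  extension from marker triplets, gait-phase interpolation, trial
  segmentation.
- **`gaitdyn.plds`** — Poisson linear dynamical system: simulation,
  Laplace-approximated posterior inference (Newton's method on the
  block-tridiagonal log joint), EM parameter learning, and posterior-mean
  latent decoding for novel trials.
- **`gaitdyn.gaussian_lds`** — exact Kalman smoother and Gaussian-LDS EM,
  used as the reference implementation for validating the Laplace machinery.
- **`gaitdyn.reducers`** — PCA on z-scored rates and greedy predictive
  subset selection (PSS) of units.
- **`gaitdyn.wiener`** — order-10 Wiener-filter decoding, per-trial R²
  scoring, 10-fold cross-validation over four feature sets (full
  population, PLDS, PCA, PSS), and a dimensionality sweep with plateau
  detection.
- **`gaitdyn.trajectory`** — gait-cycle time normalization onto a 100-point
  1% grid and per-grid-point Mahalanobis distance profiles between trial
  types, with SEM and shrinkage-regularised covariances.
- **`gaitdyn.stats_spectral`** — Thomson multitaper PSDs of decoder
  outputs, high-frequency power ratios, exact Wilcoxon signed-rank tests and
  Benjamini–Hochberg FDR control for cross-session decoder comparisons.
- **`gaitdyn.io` / `gaitdyn.cli`** — HDF5 session archives, plain-text
  ingestion, and the `gaitdyn` command-line driver.

## CLI

```bash
gaitdyn simulate --config cfg.yaml --out session.h5 --seed 1
gaitdyn decode --session session.h5 --decoder plds --dims 12 --folds 10 --seed 1 --out r_plds.csv
gaitdyn decode --session session.h5 --decoder fp --folds 10 --seed 1 --out r_fp.csv
gaitdyn sweep --session session.h5 --method plds --max-dim 20 --out sweep.csv
gaitdyn trajectories --session session.h5 --reference TRM --dims 12 --out profiles.csv
gaitdyn report --results r_fp.csv --results r_plds.csv --baseline fp --out report/
gaitdyn run-all --config cfg.yaml --out run/ --seed 1
```

`cfg.yaml` for `simulate` holds `GroundTruthConfig` fields, e.g.

```yaml
n_units: 30
latent_dim: 4
n_trials_per_condition: 20
conditions: [[TRM, 2.4], [TRM, 4.0], [TRM, 6.4]]
gait_period_range: [0.6, 0.9]
speed_offset_axis: 2
speed_offset_gain: 0.3
```

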