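# Methods

This document describes the models, estimators, and numerical choices
implemented in `latentgec`, together with the scope of the synthetic
generator used for validation and the known limitations.

## Overview

The package implements a latent-manifold pipeline for whole-brain dynamics:

1. **Preprocessing** — parcellated BOLD time series are band-pass filtered,
   edge-trimmed, and z-scored into frame-wise activity patterns
   (`latentgec.io`).
2. **Manifold embedding** — a variational autoencoder (VAE) compresses the
   N-region patterns into M latent modes; a scan over M with an elbow rule
   selects the manifold dimensionality (`latentgec.vae`).
3. **Latent dynamical model** — each latent mode is a Stuart–Landau
   oscillator; modes interact through a directed coupling matrix
   (`latentgec.hopf`).
4. **LGEC inference** — the coupling matrix (latent generative effective
   connectivity) is fitted by iteratively matching the model's functional
   connectivity FC and forward-shifted connectivity FCf(τ) to their
   empirical counterparts (`latentgec.gec`, `latentgec.model`).
5. **Interpretation** — latent modes are decoded back to region space by
   noise probes and associated with reference resting-state networks
   (`latentgec.fingerprint`); node statistics and task classification
   operate on the inferred couplings (`latentgec.stats`).
6. **Validation** — a synthetic generator with known ground-truth coupling
   provides closed-form oracles for every stage (`latentgec.synthetic`).

## Preprocessing

- Band-pass: second-order Butterworth, pass band 0.008–0.08 Hz, applied
  forward and backward (`scipy.signal.sosfiltfilt`), which doubles the
  effective order and removes phase distortion.
- Edge trim: `floor(0.05 · T)` frames are discarded from each end to remove
  filter transients.
- Normalization: per-region z-scoring uses mean/SD estimated on the training
  split only; the split is at subject level so no subject contributes frames
  to both splits.

## Variational autoencoder

A deliberately small, fully deterministic numpy implementation (no GPU
frameworks):

- Encoder: two dense ReLU layers (default funnel N/2, N/4) feeding linear
  heads for the posterior mean μ and log-variance; decoder mirrors the
  encoder.
- Loss: per-batch mean of the per-frame sum-of-squares reconstruction error
  plus `kl_weight` times the analytic Gaussian KL divergence (default
  weight 1).
- Optimizer: hand-rolled Adam (lr 1e-3, batch 128), reparameterization
  trick, all randomness drawn from one seeded generator so training is
  bit-reproducible.
- Downstream encoding uses the posterior mean μ (no sampling).

**Training adequacy.** On desk-scale pattern sets (roughly 10³–10⁴ frames)
a few hundred Adam steps underfit badly: reconstruction error stays far
above the PCA floor of the data and is non-monotone in the latent
dimension. Tests and the dimensionality scan therefore use epoch counts
(~1000) chosen so the training error approaches the PCA floor on known-rank
data; this is a convergence diagnostic, not a tuned constant.

**Dimensionality elbow.** The scan trains one VAE per candidate dimension
and computes held-out reconstruction error. With first differences
d(M) = err(M) − err(M+1), the elbow is the first dimension whose outgoing
decrement satisfies |d(M)| ≤ 0.1·|d(M₀)| (one tenth of the initial
decrement), falling back to the largest scanned dimension.

## Latent Stuart–Landau (Hopf) model

Each latent mode j follows the complex normal form

    dz_j = [ (a_j + i ω_j − |z_j|²) z_j + Σ_k C_jk (z_k − z_j) ] dt + σ dW_j

with bifurcation parameter a_j (default −0.02, subcritical), intrinsic
angular frequency ω_j inside the 0.008–0.08 Hz band, diffusive coupling
through the directed matrix C (C[j,k] = influence of mode k on mode j;
zero diagonal), and complex white noise of SD σ (default 0.01) per
component. The observable is Re z_j.

**Integration.** Euler–Maruyama with dt = 0.1 s, per-step noise SD σ√dt per
real component, a 60 s discarded transient, and sampling at the repetition
time (TR, default 0.72 s). The core is numba-jitted with all noise
pre-generated by a seeded numpy generator; a pure-numpy twin implements the
same discretization (trajectories agree up to floating-point association
order).

**Euler radial bias.** The explicit Euler map amplifies rotation:
|1 + iωdt| > 1, so the limit-cycle radius satisfies
(1 + dt(a − r²))² + dt²ω² = 1 rather than r² = a, an upward bias of about
dt·ω²/2 in the effective bifurcation parameter (≈0.5–1.5% in radius at
dt = 0.1 for band frequencies). This is immaterial for LGEC inference, where
generator and model share the discretization, but accuracy tests against
continuum values use dt ≤ 0.01, where the bias is below the test tolerance.

**Intrinsic frequencies.** Estimated per mode as the subject-averaged peak
of the periodogram restricted to the 0.008–0.08 Hz band.

## Observables

- FC: zero-lag Pearson correlation matrix.
- FCf(τ): `FCf[i, j] = corr(x_i[0:T−τ], x_j[τ:T])` — row index is the
  *earlier* signal; τ defaults to 3 frames. FCf(0) coincides with FC.
  The asymmetry of FCf reflects broken detailed balance (temporal
  irreversibility).
- Matrix similarity: Pearson correlation of off-diagonal entries.
- Asymmetry index: ‖C − Cᵀ‖_F / ‖C + Cᵀ‖_F.

## LGEC inference

Starting from C = 0, each iteration simulates `n_sim_avg` (default 10)
model realizations with the current C, averages their FC and FCf(τ), and
applies the pseudo-gradient update

    C_ij ← C_ij + ς [ (FC_emp − FC_mod)_ij + (ΔFCf)_ij ],    ς = 1e-5,

with the diagonal re-zeroed. The returned estimate is the iterate with the
best mean fit (average of FC and FCf off-diagonal similarities to the
empirical targets). An optional early-stopping rule (no fit improvement
larger than `tol` within `tol_window` iterations) is disabled by default:
at ς = 1e-5 the true per-iteration gain is far below the sampling noise of
the fit estimate, so any usefully short window fires long before the
coupling reaches scale.

**Orientation of the FCf term.** With the row-=-earlier FCf convention and
receiver-row coupling convention above, pairing C_ij with ΔFCf_ij entrywise
adjusts the j→i coupling using evidence for the i→j direction and
empirically recovers the *transpose* of a known ground truth. The
implementation therefore feeds the transposed FCf discrepancy
(row = receiver) into the literal update rule, which recovers the ground
truth itself. The update primitive `update_coupling` keeps the literal
entrywise arithmetic; the orientation handling lives in `infer_gec`.

**Identifiability at desk scale.** The FC/FCf → C inverse problem is
ill-conditioned in the near-synchronized regimes the generator produces
(coupling-to-|a| ratios of 5–10 give FC entries of 0.3–0.7 everywhere).
With the fixed step ς = 1e-5 the pseudo-gradient converges quickly along
stiff directions but glacially along soft ones, and residual sampling noise
in both empirical and model observables sets an error floor. Recovery
quality therefore varies substantially across ground truths; see the
acceptance-test discussion in the repository notes.

## Mode decoding and RSN fingerprinting

A trained decoder is probed one latent coordinate at a time with white
noise (all other coordinates zero). The per-region variance of the decoded
output gives the mode's spatial power map; the signed map is the Pearson
correlation between each decoded region and the injected series. Mode maps
are associated with reference resting-state-network membership percentages
by Pearson correlation with Benjamini–Hochberg FDR control across the full
mode × network family.

## Node statistics and classification

- Total connectivity per node: row sum plus column sum of C (diagonal
  excluded).
- Condition comparisons: two-sided Wilcoxon rank-sum (exact p for small
  untied samples) per node with BH correction.
- Task classification: Gaussian-kernel SVM (`sklearn.svm.SVC`, natively
  one-vs-one; `gamma='auto'`, C = 1) on flattened off-diagonal coupling
  features, evaluated over 100 stratified 90/10 shuffles; confusion matrices
  are pooled over repeats and row-normalized. Scrambled-label controls
  reduce any feature set to chance accuracy.

## Synthetic generator

Ground truth construction (`make_ground_truth`):

- Sparse M×M coupling C* with density 0.2 (share of off-diagonal slots),
  magnitudes U(0.05, 0.2). An `asymmetry` parameter λ mixes a symmetric
  support S and a directed support D as (1−λ)S + λD.
- Stuart–Landau parameters: a = −0.02, σ = 0.01, frequencies U(0.01, 0.07) Hz.
- Linear mixing to N regions through a matrix with orthonormal columns
  scaled by U(0.5, 1.5); optional tanh saturation stresses the nonlinear
  path; optional additive observation noise.
- The oracle encoder (pseudo-inverse of the mixing) recovers latents exactly
  in the noise-free linear case, decoupling inference tests from VAE
  quality.

Scope: the generator validates estimator correctness and recovery behaviour
at desk scale; it does not model hemodynamic convolution, subject-level
frequency heterogeneity beyond random draws, or empirical amplitude
distributions.

## Limitations

- The VAE is a small MLP trained on CPU; it targets desk-scale synthetic
  data, not full-resolution empirical datasets.
- Euler–Maruyama at dt = 0.1 s carries the radial bias described above;
  halve dt for continuum-accurate amplitudes.
- LGEC recovery is limited by the conditioning of the FC/FCf inverse
  problem at the fixed spec step size; correlations with ground truth around
  0.5–0.9 across random ground truths are typical at desk scale.
- The rank-sum exact p-value requires untied small samples; tied data fall
  back to the normal approximation.
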