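# Methods

## Model and inference

The core model is a hidden Markov model over time-delay embedded parcel
signals. Embedding uses a symmetric lag window of `round(window_ms/1000 * fs)`
samples, promoted to the next odd integer so lags remain symmetric around
zero (60 ms at 250 Hz gives 15 lags; at 100 Hz, 7). Each embedded column is
standardized with pooled training statistics — one group-level model implies
shared scaling — and PCA retains `n_pca_per_parcel × n_parcels` components
(default 2 per parcel). The PCA sign convention (largest-magnitude loading
positive) and pooled standardization make the embedding deterministic; no
whitening is applied, since the HMM learns full covariances.

Observations are zero-mean Gaussians: state `k` is its covariance `Σ_k` in
the embedded-PCA space, which encodes spectral power and cross-spectral
phase relations. Inference is maximum-likelihood EM (Baum–Welch) with
scaled forward–backward recursions, batched across equal-length trials.
Trials are independent chains sharing `{π, A, Σ_k}`; no transitions bridge
trial boundaries. We chose ML-EM over variational schemes because every
inferential quantity is then exactly testable against brute-force path
enumeration (the tests do this for K ≤ 3, T ≤ 8 at 1e-10). Numerical
details: covariance M-steps receive a ridge floor of `1e-6 ×` mean
diagonal; restarts (default 5; 3 in the desk-scale studies) initialize each
state's covariance from a random contiguous chunk of the pooled data, which
yields spectrally diverse starting points; the winner is chosen by final
log-likelihood; a state whose occupancy drops below K samples is
re-initialized once and the fit aborts if it empties again. Viterbi ties
break toward the lower state index. State labels are aligned across runs
(and to ground truth) by maximizing total column correlation of the
posteriors via optimal assignment.

## Synthetic generator

The generator emulates exactly what the analysis assumes and nothing more:
a per-sample latent Markov chain; within state `k`, designated parcel pairs
driven by damped AR(2) resonators (bandwidth 1.5 Hz) at a state-specific
center frequency; all other parcels independent unit-variance white noise;
additive white measurement noise on top. Pairwise coherence is controlled
in closed form: innovations `e = a·z_shared + b·z_own` with `a² + b² = 1`
give magnitude-squared coherence `a⁴` where the resonator dominates, so a
target coherence `c` uses `a = c^(1/4)` (validated against spectral
estimation in the tests). State switching is instantaneous at sample
resolution — matching the HMM's piecewise-stationary assumption; no
cross-fades, no 1/f background, no leakage or artifacts. Consequently a
passing recovery test shows the estimator is correct under its own
assumptions; it does not show robustness to volume conduction,
nonstationary artifacts, or aperiodic backgrounds, which real recordings
have. Because no 1/f background is simulated, the NNMF broadband mode is
typically absent on synthetic data; the broadband-exclusion rule is
exercised by a dedicated planted-1/f test instead.

The default desk-scale scene is 10 parcels at 100 Hz, K = 3 states with
two coupled pairs each at 10, 22 and 38 Hz (coherence 0.9), self-transition
0.98 (mean lifetime 0.5 s), 4 s epochs, 40 trials × 2 conditions × 10
participants, measurement noise SD 0.3. Full scale (42 parcels, 250 Hz,
K = 6, 8 s epochs) is a configuration away but the tests must run in
minutes. The condition effect is `+0.15` on the `0 → 1` directed transition
(row renormalized) in condition B — the effect size the power analyses use.
Note the renormalization also lowers `A[0,0]` in condition B, so occupancy
and lifetime of state 0 differ between conditions as a side effect; the
analysis drivers report those knock-on detections alongside the planted one.

## Spectral characterization

Per-state cross-spectra use gamma-weighted Welch averaging: Hann-tapered
segments (default 64 samples, 50% overlap) restricted to the embedding's
valid-sample range, each segment's periodogram cross-products weighted by
the segment-mean posterior of each state. With gamma ≡ 1 this reduces
exactly (to floating point) to `scipy.signal.csd`, which the tests assert.
States accumulating fewer than 10 effective segments are flagged
unreliable. A segment mixing two states contributes to both in proportion
to occupancy — a deliberate softness that matches the soft state
assignment; sharp per-state multitaper estimation is a possible extension.

Frequency modes come from NNMF of the coherence spectra stacked over
(state, parcel pair) rows. Each restart runs Lee–Seung multiplicative
updates followed by HALS sweeps; both phases are monotone in the Frobenius
objective, and HALS can reach exact zeros, which the multiplicative rule
only approaches at rate ~1/iteration (on exactly low-rank input the
polished error reaches ~1e-15 where plain MU stalls around 1e-4). Profiles
are normalized to unit sum and sorted by weighted-mean frequency. The
broadband (1/f-like) rule flags a mode that (i) peaks in the lowest
quartile of the grid, (ii) decreases with frequency (Spearman ρ < −0.8),
and (iii) attains ≥ 90% of its maximum at the first bin — condition (iii)
distinguishes genuinely monotone profiles from band-limited low-frequency
bumps, which also satisfy (i)–(ii) on short grids. NNMF is identifiable
only when some rows load (nearly) purely on single modes; the recovery
tests plant such rows, and on real coherence stacks the mode split should
be read as descriptive, not unique.

## Connection significance

Within each (state, mode) family, mode-projected coherence is demeaned
across states — each connection is measured relative to its mean over all
states — and a one-dimensional mixture of two unit-variance Gaussians is
fit by EM (free means and weights; means initialized at the 25th/75th
percentiles). The lower-mean component is the noise model; p-values are its
upper tail, Bonferroni-corrected within the family at alpha 0.001 (the
family definition — per state and mode — is a configurable choice).

"Unit variance" requires a scale. Values are first scaled by a robust
noise-scale estimate (MAD/0.6745 about the median) and the scale is then
calibrated by a few fixed-point steps so that the *noise component's*
responsibility-weighted variance is one. Scaling to unit *total* variance
instead would shrink the noise component well below unit width whenever the
signal component is substantial, pushing genuine signal into the assumed
noise tail; the noise-anchored calibration keeps "unit variance describes
the noise" true by construction. Degenerate fits (a vanishing component, or
an all-constant sample with MAD = 0) fall back to a single-Gaussian null
or an empty mask. The test is one-sided toward strong positive values.

## Connectivity manifolds

Each state's region-by-region similarity graph is built from the
gamma-weighted parcel-space covariance (mode-summed coherence is the
config alternative): region vectors are matrix rows; affinity is a Gaussian
kernel with self-tuning bandwidth equal to the median squared pairwise
distance. The diffusion map uses α = 0.5 density normalization and t = 1,
diagonalized through the symmetric conjugate for stability; coordinates are
`λ_k^t ψ_k` for the top 3 nontrivial eigenvectors, and diffusion distances
use *all* nontrivial components. Kernel and normalization constants are
implementation defaults exposed in config, not facts about any particular
dataset. Closeness testing reuses the mixture machinery verbatim on
negative distances, demeaned across states.

## Dynamics and condition inference

Per-trial transition matrices are row-normalized *expected* transition
counts under the group model — re-fitting an HMM per 4–8 s trial would be
ill-posed — with unvisited rows replaced by uniform rows and flagged (this
uniform-row convention can itself produce condition differences when
occupancy differs; the drivers surface this). Lifetimes and switch rate use
Viterbi (hard) paths, fractional occupancy the soft posteriors — each
metric's standard definition.

The transition test statistic per directed pair is the difference of
condition means of per-trial probabilities. The null permutes condition
labels *within participant* (preserving per-participant condition counts),
respecting the repeated-measures structure; participants observed in only
one condition are excluded. P-values are one-sided per direction with the
add-one correction `p = (1 + #{null ≥ obs}) / (n_perm + 1)` and BH-FDR is
applied per direction across directed pairs, yielding one "increased in A"
and one "increased in B" mask. Calibration studies (type-I error ≤ nominal
at q = 0.05 over 200 replicate datasets; power against the +0.15 planted
effect) operate on per-trial matrices computed from the *true* latent
paths, isolating the statistical machinery from estimation error; they use
500/1000-permutation and replicate counts sized for minute-scale runs
(5,000 permutations remain the analysis default). Temporal metrics use a
classical two-way repeated-measures ANOVA (statsmodels `AnovaRM`; factors
state × condition, both within participant, requiring ≥ 3 participants)
with per-state paired sign-flip permutation tests and BH-FDR post hoc;
switch rate, a single number per trial, collapses to the paired test.

## Decoding

Posteriors over the final 600 ms are averaged in 60 ms bins (bin-major,
state-minor feature order; trailing partial bins dropped with a warning).
The classifier is L1-penalized logistic regression (liblinear), with outer
participant-grouped folds and the penalty chosen per outer fold by inner
grouped cross-validation over a log-spaced grid; reported accuracy is
out-of-fold only, and no participant ever straddles a fold. The
cluster test computes each bin's out-of-fold decodability (accuracy −
0.5), thresholds at the per-bin 95th null percentile (labels permuted
within participant), forms maximal contiguous supra-threshold runs scored
by summed statistic, and compares against the permutation distribution of
the maximum cluster mass. The scheme (primary threshold, mass statistic,
within-participant exchangeability) is a standard construction chosen
here as a documented default; at least 100 permutations are required
because the corrected p lives in the null's extreme tail.

## Reproducibility

All randomness descends from one root seed through a named-stage scheme
(`SeedSequence([root, crc32(stage_name)])`), so a full pipeline run is
bit-reproducible and any single stage can be re-run in isolation with the
stream it had inside the full run. The result manifest records SHA-256
digests of every major array; the determinism test asserts two runs agree
bit-for-bit.

## Known limitations

- The generator omits 1/f backgrounds, spectral leakage/volume conduction
  and nonstationarities; recovery results certify correctness under the
  model's own assumptions only.
- Group-level frequency modes only; no subject-specific mode weights.
- Per-trial transition matrices inherit the uniform-row convention for
  unvisited states, which couples occupancy differences into transition
  differences; interpret flagged pairs together with occupancy results.
- ML point estimates without uncertainty on `A` or `Σ_k`; no model-order
  selection for K.
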