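# Methods

`netstates` implements a complete analysis chain for transient network
states in multichannel electrophysiological recordings, together with a
synthetic-cohort generator that plants exactly the statistical structure the
chain is designed to detect. This note describes the models, the defaults
and why they were chosen, what the generator does and does not emulate, and
the numerical decisions that matter.

## The model

The observable is a per-subject matrix of band-limited (4–30 Hz) amplitude
envelopes over M = 38 channels, sampled at 20 Hz after downsampling. The
analysis assumes these envelopes are generated by a K-state hidden Markov
model: at each time point the system occupies one of K latent network
states, each state k emitting the M-channel envelope vector from its own
multivariate normal distribution N(μ_k, Σ_k) with full covariance, and the
state sequence following a first-order Markov chain with row-stochastic
transition matrix A and initial distribution π.

Fitting is maximum-likelihood Baum–Welch EM on the envelopes of all
subjects concatenated in time, so a single state basis is shared by every
subject; per-subject quantities are computed afterwards by cutting the
decoded sequence at subject boundaries. State time-courses come from the
Viterbi algorithm (the globally most probable path, computed in the log
domain; ties break toward the lower state index). From the decoded path we
derive the four temporal metrics:

* **fractional occupancy** FO_k — fraction of samples spent in state k;
* **fractional count** FC_k — number of visits (contiguous segments) to
  state k divided by the total number of visits over all states;
* **mean lifetime** LT_k — average visit duration in ms; with
  self-transition probability a_kk, dwell times are geometric and
  LT_k → 1000 / (fs·(1 − a_kk)) ms;
* the **empirical transition matrix** of consecutive sample pairs, with or
  without the diagonal.

The fractional-count denominator deserves a note: "number of state
transitions" is ambiguous between visits and visit-boundaries (visits =
transitions + 1 on a finite path). We divide by the total number of
*visits* across states so FC sums to one per subject and is comparable
across subjects of different lengths. Boundary segments count as full
visits.

State topographies are mapped with a GLM: for each subject, each channel's
z-scored envelope is regressed on the full set of z-scored state indicator
time-courses; with all variables standardized, each coefficient is the
partial correlation of that state with the channel given all other states.
A complete indicator set sums to one at every sample, so the z-scored
design always carries exactly one linear redundancy (the implicit
intercept); we use the minimum-norm least-squares solution, which resolves
the redundancy symmetrically across states and leaves between-state
coefficient contrasts — the quantity the maps display — unchanged. Masking
(e.g. to epochs of high state occurrence rate) removes rows before
standardization. Deficiency beyond the intrinsic one (a state absent after
masking, duplicated columns) is an error; per-subject maps tolerate absent
states by dropping them from the regression and reporting zero.

Group inference uses Welch t-statistics with permutation nulls: labels are
randomly reassigned (exhaustively enumerated whenever C(n, n_a) fits within
the permutation budget), two-sided throughout. Channel-wise maps are
corrected for multiple comparisons by threshold-free cluster enhancement
(TFCE; E = 0.5, H = 2, dh = max|t|/100, two-sided by enhancing each sign
separately) followed by max-statistic permutation, which controls the
family-wise error rate. Between-group variance differences use Bartlett's
chi-squared test. Channel adjacency for TFCE comes from the planted
topography blocks (channels that load on a common state are neighbours);
there is no voxel grid in this package.

## The synthetic-data generator

Each subject's latent state path is simulated at the 20 Hz envelope rate
and sample-held to the 200 Hz raw rate, so ground truth stays aligned with
decoded paths sample for sample. Each channel carries unit-variance
Gaussian noise zero-phase filtered into 4–30 Hz; while state k is active the
carrier of channel c is multiplied by 1 + depth·scale_k·topography(k, c).
Optional ingredients: a zero-lag channel-mixing matrix (leakage), additive
white measurement noise (sd 0.2 by default, relative to the unit-variance
carrier), and an ultra-slow sinusoidal modulator (0.05 Hz, random phase)
that scales the probability of entering one coupled state by
1 + gain·m(t) (rows renormalized) and is simultaneously added as a slow
potential to that state's channels.

Default topographies are disjoint contiguous channel blocks (38 channels in
10 blocks), so states are identifiable and the blocks double as TFCE
neighbourhoods. The transition matrix is constructed from target stationary
occupancies π and per-state dwell times d via the reversible family
A_jk = c_j π_k c_k / C (j ≠ k), whose stationary distribution is exactly π
for any positive rates c; the rates are solved by fixed point so every
diagonal hits its dwell target exactly.

Two presets encode the study conditions (10 subjects per group, one
continuous 9-minute session per subject — the concatenation of three
3-minute recordings):

| preset | DMN-like (state 1) | DAN-like (state 6) | other states |
|---|---|---|---|
| `ch_default` | FO 6%, LT 250 ms | FO 14%, LT 225 ms | FO 10%, LT 150 ms |
| `ad_default` | FO 3%, LT 150 ms, depth ×0.8 | FO 7%, LT 150 ms | FO 11.25%, LT 150 ms |

The control-like DAN dwell is set mid-way in the 200–250 ms range reported
for salient states; the Alzheimer-like preset halves the two salient
occupancies, shortens their dwells to the 150 ms typical of the remaining
states, and modestly reduces the DMN-like modulation depth (factor 0.8,
chosen once as a qualitative "reduced depth" contrast).

Surrogate datasets for the stationarity null color white noise with each
reference channel's smoothed amplitude spectrum and then impose the
reference zero-lag covariance through symmetric matrix square roots
(whiten, then color). The order — spectrum first, correlation second — is
one admissible reading of joint matching; imposing the covariance mixes
channels and can slightly blur per-channel spectra when channel spectra
differ strongly, which is immaterial here because all channels share the
4–30 Hz band. The raw periodogram is itself a noisy spectral estimate, so
the coloring filter smooths it over ~2% of the frequency axis.

What the generator does **not** emulate: sensor physics, source leakage
with realistic field spread (leakage is an arbitrary user-supplied mixing
matrix), non-Gaussian artifacts, inter-subject topography variability, and
1/f broadband background. Passing tests therefore demonstrate correctness
of the estimation machinery under the assumed generative model, not
robustness to the full messiness of real recordings.

## Preprocessing choices

* Filters: Butterworth order 5 applied forward–backward (zero phase), as
  second-order sections for numerical stability; zero-phase filtering
  avoids envelope lag against the planted path. Band presets: wide 4–30,
  theta 4–7, alpha 8–12, beta 15–30 Hz, ultra-slow lowpass 0.1 Hz.
* Leakage correction: symmetric orthogonalization of the band-limited
  time-courses *before* envelope computation — the closest set of mutually
  orthogonal columns in the least-squares sense, found by alternating the
  orthogonal-Procrustes solution with per-column magnitude updates
  (convergence: relative objective change < 1e-10, max 1000 iterations).
  Unlike Gram–Schmidt the result is invariant to channel ordering.
  Channel-level map envelopes are not orthogonalized.
* Envelopes: modulus of the analytic (Hilbert) signal, downsampled to
  20 Hz by block means (anti-aliasing the envelope rather than decimating).
* Edge handling: the first and last second of each subject's envelope is
  discarded to suppress filter and Hilbert transients; ground-truth paths
  are trimmed identically.
* Normalization: per subject, channels are demeaned and the whole subject
  matrix is divided by its global standard deviation over all entries (the
  "global variance" phrasing is ambiguous between variance and SD as the
  divisor; we use the SD so the result is unit-scale), then subjects are
  concatenated with recorded boundaries.

## Numerical choices in the HMM

* Restarts: 10 seeded restarts, each initialized by randomly assigning
  time points to states and taking per-state moments. Each restart runs a
  short EM burn-in (15 iterations) and only the best-scoring one continues
  to convergence — the burn-in ranking is stable because restarts differ
  mainly in their basin of attraction, and this keeps the concatenated fit
  (T ≈ 10^5, M = 38, K = 10, full covariances) at desk scale.
* Convergence: relative log-likelihood change < 1e-6, cap 500 iterations.
  The log-likelihood trace is recorded and must be non-decreasing (EM
  guarantee; the test suite enforces it to 1e-6 relative).
* Covariance regularization: every M-step adds a ridge of 1e-6 × mean
  diagonal; if a covariance still fails its Cholesky factorization its
  eigenvalues are floored at 1e-10 and the event is logged. A state whose
  posterior weight collapses below 1e-6·T is re-seeded from a random
  observation with the global covariance (logged; rare under the presets).
* The forward–backward and Viterbi recursions run in the log domain
  (numba-compiled), so paths up to 10^6 samples decode without underflow.
* Model selection across refits or group-specific fits uses optimal
  one-to-one state matching (Hungarian assignment on spatial-map Pearson
  correlations), also used to match decoded states to planted topographies.

The variational-Bayes treatment of the observation model is intentionally
out of scope: the reported quantities depend on the state segmentation, and
maximum-likelihood EM with restart selection is fully specifiable. Free
energies are therefore not comparable with variational implementations;
the restart criterion is the highest log-likelihood.

## Problem sizes

The acceptance computations use the presets at their native size
(10 subjects × 9 min per cohort, K = 10, 10 restarts); chain-level
closed-form checks use 2×10^5-sample paths. Validity simulations use
reduced but structurally identical instances chosen as the smallest sizes
at which the checked statistics are stable: 12–20 subjects of 2–3 minutes,
12 channels, K = 4–5 for the TFCE false-positive and surrogate-contrast
suites. At these sizes the full test suite and the acceptance script each
complete on a single CPU in well under half an hour.

## Known limitations

* FC/LT are Viterbi-path statistics; very short true visits can be absorbed
  by decoding, biasing lifetimes slightly upward at low modulation depth.
* The GLM maps assume envelope stationarity within state visits; slow
  amplitude drifts masquerade as state structure if not removed.
* TFCE parameters are the field's conventional defaults, not optimized for
  the block adjacency used here.
* The minimum-norm resolution of the indicator-design redundancy shifts all
  coefficients of a subject by a common amount along the redundancy
  direction; absolute coefficient values should be interpreted relative to
  the session mean, not as raw correlations.
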