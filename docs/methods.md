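# Methods

This note records the modelling assumptions, parameter choices and numerical
conventions behind `eeglatent`, in the spirit of a model-documentation page:
everything here describes what the code does and why, not empirical claims
beyond what the test suite and `scripts/acceptance.py` themselves compute.

## Session model and data flow

The unit of analysis is a *session*: one text recording of 10 numeric streams
(eight rhythm-band powers plus the attention and meditation indices of a
single-channel headset), summarized by its per-stream arithmetic mean over
all retained samples. Invalid tokens are discarded per token, not per row, so
a corrupted value in one stream does not delete information in the other
nine. Sessions are stacked into `X ∈ R^{N×10}` and standardized per column:

    X_n = (X − μ) / σ

with σ the *population* standard deviation (divisor N). This choice makes
the unit-variance invariant exact and is stored with μ for exact inversion.
A zero-dispersion column raises an error rather than silently emitting zeros
or NaNs — a constant stream in real data indicates a dead sensor channel and
should be confronted, not standardized.

The recording dialect accepts comma- or whitespace-delimited rows with an
optional header naming the streams under common aliases (`lowAlpha`, `β↑`,
…); headerless files must carry exactly 10 columns in the canonical order.
File names follow `Patient<k>_<Before|During|After>_<YYYY[-MM-DD]>.txt`,
encoding the three labels that organize the corpus: participant, therapy
moment, acquisition date.

## Synthetic cohort generator

The generator is the package's ground truth and defines the study conditions
under which everything is tested. A session in standardized units is

    x = o_p + δ_m + σ_n · F ε,      ε ~ N(0, I_10)

where `o_p` is a per-patient offset, `δ_m` the mean shift of therapy moment
m (Before is the reference, δ ≡ 0), and `F` a symmetric square root of the
target correlation matrix Σ. Raw stream values are `baseline + scale ⊙ x`
with plausible headset magnitudes (band powers of tens to hundreds of units,
cognitive indices near the middle of their 0–100 range).

Defaults, and why:

* **Correlation structure** — adjacent low/high sub-bands of one rhythm at
  r = 0.7, the alpha/beta/gamma block at 0.3, slow rhythms (delta, theta) at
  0.4 with each other and 0.2 with the fast block, attention/meditation at
  −0.1 with every band. This encodes coupled sub-band processes, a
  differentiated slow-rhythm regime, and cognitive indices that are not
  linear functions of band power. The matrix is verified positive
  semi-definite at construction (smallest eigenvalue 0.3).
* **Patient offsets** (`patient_sd = 0.3`) are drawn through the *same*
  correlation factor, i.i.d. across patients. Correlated offsets mean
  between-subject variability preserves the planted spectral correlations
  (a subject with elevated low-beta has elevated high-beta too), and they
  keep the effect-size oracle closed-form. 0.3 standardized units makes
  subjects clearly distinguishable without dominating the session noise.
* **Phase shifts** — the During and After shift *directions* follow the
  band-contribution pattern the analysis is designed to resolve: the
  Before→During contrast is delta-dominant (squared shares ≈ 75% delta, with
  small low-gamma/theta/high-gamma/high-beta terms), the Before→After
  contrast spreads over theta, low-gamma and high-beta. Shift *amplitudes*
  are 0.8 (During) and 0.6 (After) standardized units. The amplitude choice
  is a power calculation, fixed before any test was run: per-band group-mean
  contrasts at a few hundred sessions per phase have sampling sd
  ≈ √(2/n) ≈ 0.1, so the gap between the dominant band (0.8·√0.75 ≈ 0.69)
  and its nearest competitor (≈ 0.23) must be several sampling sd for
  "delta ranks first" to be a stable property of the generator rather than a
  coin flip.
* **Archive jitter** — written recordings carry `samples_per_session = 40`
  rows of per-row Gaussian jitter with sd `noise_sd / 4` (standardized
  units), emulating within-session variability one quarter the size of
  between-session noise; re-summarizing recovers session features to within
  `scale · noise_sd / (4 √40)` per stream.

**What the generator does not emulate:** raw time-domain waveforms, 1/f
spectral slopes, non-Gaussian tails, artifacts, within-session
non-stationarity, patient×phase interactions (an optional extension point;
additive offsets keep the oracle closed-form), or drift across acquisition
years. Passing recovery tests therefore demonstrates that the estimators
recover *this* elliptical session-level structure — not that real EEG
satisfies it.

## Closed-form effect-size oracle

For a two-moment contrast with shift difference d, P patients, and m_a, m_b
sessions per patient per moment, every patient appears in both groups with
equal weight, so patient offsets cancel *exactly* from the group-mean
contrast while inflating within-group scatter. The expected SSCP matrices
are

    E[H] = (n_a n_b / N) d d' + σ_n² Σ
    E[E] = (N − 2) σ_n² Σ + (m_a + m_b)(P − 1) σ_p² Σ

and the oracle value is `tr(E[H] (E[H] + E[E])^{-1})` — a plug-in that also
carries the estimator's first-order small-sample bias, which is what a mean
over simulated cohorts actually converges to. Under the null (d = 0) this
reduces to `p σ_n² / ((N−1) σ_n² + (m_a+m_b)(P−1) σ_p²)` ≈ p/N: the Pillai
trace of a two-group MANOVA on p features is biased upward by about p/N,
≈ 0.02 at p = 8 and 200 sessions per group. Estimated effect sizes at that
scale should be read against this floor.

## Autoencoders

Both models operate on the standardized 10-vectors and are trained by Adam
(lr 1e-3, the library default in the absence of a stated value; batch 8,
final partial batch kept) with a plain-numpy reverse-mode autodiff engine.
Float64 arithmetic, Glorot-uniform fan-based initialization and a single
`numpy` Generator per run (initialization, shuffling and VAE noise all drawn
from it in fixed order) make training bit-reproducible per seed. A
non-finite loss aborts with the offending epoch. Gradients of every
primitive are validated against central finite differences in the test
suite.

**VAE.** Encoder 10 → Dense(16, ReLU) → Dense(4), split into μ and log σ²
(2 + 2); decoder mirrors it as 2 → Dense(16, ReLU) → Dense(10, linear). The
objective is the per-sample squared error summed over the 10 features plus
the closed-form diagonal-Gaussian KL, both averaged over the batch and
recorded separately in the training trace. Latent codes are the posterior
means; reconstruction errors are evaluated at ε = 0.

**Transformer autoencoder.** Tokenization is the one genuinely open design
point: a literal single dense embedding produces one 64-vector, over which
self-attention is degenerate (softmax over one score). The default
`per_feature` mode therefore gives each scalar feature its own learned
64-dimensional embedding `e_i = x_i w_i + b_i`, yielding 10 tokens over
which 4-head attention (key dim 16, 4 × 16 = 64) is meaningful "attention
across features"; the degenerate `single_vector` mode is retained behind a
flag for comparison. The latent layer applies a dense map to the *flattened*
10×64 attention output (pooling would discard token identity), giving
`z = ReLU(W₂ vec(MHA(H)) + b₂) ∈ R^16`; the decoder is 16 → Dense(64, ReLU)
→ Dense(10, linear). No layer normalization, residual connections or
positional encodings are used — the tokens are an unordered feature set and
the model is deliberately minimal. One model is fit per cohort (not per
patient).

The two latent spaces (2-D stochastic vs 16-D deterministic) are different
design points, not an ablation: comparisons between them confound
architecture with capacity.

## Latent metrics and anomaly rule

`D_intra` is a mean *squared* distance while `D_inter` is an unsquared
centroid distance; both are kept exactly in those units, and the stability
predicate compares them on a common scale as `min D_inter² > max D_intra`.
kNN consistency uses Euclidean neighbourhoods in both spaces, excludes the
point itself, and breaks distance ties by lower index (stable argsort), which
makes the score deterministic; it is invariant under rigid motions and
uniform scaling of either space. Anomaly flagging thresholds the per-session
reconstruction-error norms at a percentile (default 95, linear
interpolation); a session is flagged on strict exceedance, so equal errors
flag nothing.

A note on phase-geometry stability under z-scoring: columns that carry no
phase shift are standardized to unit variance *whatever* the noise level, so
within-phase dispersion never falls below the number of unshifted columns.
`phase_stability_threshold` accounts for this and returns the largest noise
sd at which the smallest pairwise phase separation still exceeds within-phase
dispersion in the standardized feature space (bisection on the expected
values); with the default between-subject sd the threshold is zero — patient
offsets, not sensor noise, are what blurs phase geometry — and the property
tests exercise both sides of the computed threshold with offsets disabled.

## Manifold views and clustering

UMAP runs with n_neighbors = 15, min_dist = 0.1 and a fixed random state
(requires N > 15); t-SNE uses perplexity 30 clamped to (N−1)/3 for small
cohorts, PCA initialization, fixed seed. PCA is computed on the standardized
matrix (correlation PCA — the streams mix band powers and index units), with
each component's sign fixed by making its largest-magnitude loading
positive. KMeans (k = 3) is seeded; DBSCAN runs on z-scored projection
coordinates so its eps (0.5) is in standardized projection units,
min_samples = 5. These are established algorithms called through
scikit-learn and umap-learn, not reimplemented.

## Phase-effect estimation

The two-group Pillai trace is computed directly from the H and E SSCP
matrices (`tr(H (H+E)^{-1})`, clipped to [0, 1]); for two groups s = 1, so
the trace *is* the multivariate partial eta-squared, and in the univariate
case it reduces exactly to SSB/SST (verified against the statsmodels MANOVA
solver in the tests). The default feature set is the 8 rhythm bands; the
cognitive indices can be included explicitly. Sessions are pooled across
patients with no random effect, matching the session-level design. A total
scatter matrix with condition number above 1e12 raises a singular-covariance
error suggesting feature reduction. Confidence intervals come from a
stratified (within-group) percentile bootstrap, B = 2000 by default, seeded,
with degenerate resamples redrawn. Band contributions are each band's share
of the between-group sum of squares on standardized features; a total SSB at
float round-off (≤ 1e-12) is reported as "no between-group signal" rather
than normalized.

## Problem sizes

The default synthetic corpus is 6 patients × (6, 5, 5) sessions = 96
sessions with a heavier baseline block, mirroring a realistic small
longitudinal cohort. Recovery checks use 5 patients × 40 sessions per phase
(200/phase) over 20 seeds — large enough that oracle comparisons at ±0.02
are meaningful, small enough that the whole suite runs in well under a
minute of estimator time; correlation recovery uses a 2000-session null
cohort where the sampling sd of r is ≈ 0.01. The acceptance script uses the
same sizes and finishes in well under a minute on one CPU.

## Known limitations

* The session mean discards all within-session temporal structure; the
  models see static 10-vectors.
* Gaussian, elliptical generative family; heavy-tailed band-power
  distributions in real recordings will make the planted-recovery guarantees
  optimistic.
* The percentile bootstrap undercovers for variance-bounded statistics near
  zero at small N; intervals at N ≈ 100 sessions are indicative, not exact.
* Pillai-trace effect sizes carry an upward bias of order p/N; at the
  corpus sizes this package targets, effects below ≈ 0.02 are
  indistinguishable from the null floor.
* Latent codes are diagnostics, not clinical outputs: group geometry
  summarizes representation quality and says nothing causal about the
  intervention.
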