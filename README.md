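# eeglatent

Latent-state monitoring of session-level EEG band-power profiles.

Wellness-oriented therapeutic interventions are hard to monitor objectively:
assessment is usually subjective, cohorts are small, and single-channel
consumer EEG recordings are noisy and strongly subject-dependent. `eeglatent`
implements a condition-monitoring view of this problem for longitudinal
therapy corpora in which each session is recorded before, during, or after an
intervention. A session is summarized by the mean of 10 feature streams —
eight rhythm-band powers (delta 0.5–2.75 Hz, theta 3.5–6.75 Hz, low/high
alpha, low/high beta, low/high gamma up to 49.75 Hz) plus the attention and
meditation indices of a single-channel headset — giving a characteristic
matrix `X ∈ R^{N×10}` over N sessions, z-scored per feature before modelling.

The package is for analysts who want the whole chain reproducible from one
seed: ingestion, representation learning, latent diagnostics, and effect
sizes, with a synthetic cohort generator that makes every stage testable
without any data download.

## What it computes

**Representation learning.** Two models compress the standardized session
vectors:

* a baseline **variational autoencoder**: a 16-unit encoder maps `x` to a
  diagonal Gaussian posterior `q_φ(z|x) = N(μ_φ(x), diag(σ²_φ(x)))` with
  `z ∈ R²`, sampled via the reparameterization `z = μ + σ ⊙ ε`, and trained
  for 200 epochs (Adam, batch 8) on
  `‖x − x̂‖² + D_KL(q_φ(z|x) ‖ N(0, I))`, with the closed-form KL
  `−½ Σ_j (1 + log σ²_j − μ²_j − σ²_j)`;
* a deterministic **transformer autoencoder**: each scalar feature becomes a
  learned 64-dimensional token, 4-head self-attention (key dimension 16,
  `softmax(Q K^T / √d_k) V` per head) models cross-band interactions over the
  10 tokens, and a dense layer compresses the attention output to `z ∈ R^16`;
  trained for 100 epochs on mean squared reconstruction error.

Both are trained with a small built-in reverse-mode autodiff engine (plain
numpy, float64), so training is bit-reproducible given a seed.

**Latent diagnostics.** Reconstruction MSE and per-session error norms
`E_i = ‖x_i − x̂_i‖` with percentile-threshold anomaly flagging; latent
variance `Var(Z)`; per-group dispersion `D_intra(G) = mean ‖z_i − z̄_G‖²` and
centroid separation `D_inter(G_a, G_b) = ‖z̄_{G_a} − z̄_{G_b}‖`; and the
k-nearest-neighbour consistency `Cons(k) = mean_i |N_k(z_i) ∩ N_k(u_i)| / k`
between the latent space and its 2-D projection `u = UMAP(z)` (or t-SNE),
followed by seeded KMeans (k = 3) and DBSCAN clustering.

**Phase effects.** For each pair of therapy moments, a two-group one-way
MANOVA on the eight rhythm bands: the reported effect size is the Pillai
trace `V = tr(H (H + E)^{-1})`, which for two groups equals the multivariate
partial eta-squared; a stratified percentile bootstrap gives the 95% CI, and
each band's share of the between-group sum of squares (on standardized
features) gives contribution percentages that sum to 100.

**Synthetic cohorts.** `eeglatent.synth` draws labelled cohorts from a
correlated multivariate-normal session model: per-patient baseline offsets,
per-moment mean shifts concentrated in configurable bands (delta-dominant
during-therapy contrast by default), adjacent sub-bands correlated at 0.7,
and weakly negatively correlated attention/meditation indices. The generator
also writes ZIP archives of per-session text recordings in the ingestion
dialect, and supplies closed-form expected effect sizes
(`oracle_eta_squared`) used as ground truth in recovery tests.

## Worked example

```python
from eeglatent import (
    CohortConfig, PhaseEffectModel, TaeConfig, TransformerAutoencoder,
    sample_cohort, write_archive, read_cohort, zscore_matrix,
)
from eeglatent.latent_eval import knn_consistency
from eeglatent.manifold import project_2d

cfg = CohortConfig(seed=1)                    # 6 patients x (6,5,5) sessions
archive = write_archive(sample_cohort(cfg), cfg, "cohort.zip")
cohort, manifest = read_cohort(archive)
print(manifest["by_moment"])

std = zscore_matrix(cohort)
tae = TransformerAutoencoder(std, TaeConfig(seed=1)).fit()
print(f"final reconstruction MSE: {tae.final_loss():.4f}")

proj = project_2d(tae.codes, method="umap", seed=1)
print(f"Cons(k=10): {knn_consistency(tae.codes, proj.coords, 10).score:.3f}")

effects = PhaseEffectModel(std).fit(bootstrap=1000, seed=1)
print(effects.summary())
```

Output:

```
{'Before': 36, 'During': 30, 'After': 30}
final reconstruction MSE: 0.0084
Cons(k=10): 0.498
Pairwise multivariate phase effects (Pillai partial eta-squared)
==================================================================
Before vs During (n=36/30)  eta_sq = 0.2883  95% CI [0.2213, 0.5183]
        top contributions: delta 73.33%, theta 7.10%, beta_low 6.33%
Before vs After  (n=36/30)  eta_sq = 0.1599  95% CI [0.1185, 0.4352]
        top contributions: delta 49.82%, gamma_low 17.23%, theta 16.07%
During vs After  (n=30/30)  eta_sq = 0.0601  95% CI [0.0589, 0.3553]
        top contributions: delta 47.55%, gamma_low 27.66%, alpha_low 16.34%
```

Reading the numbers: the 96-session archive ingests with the expected
per-moment counts; the transformer reconstructs the standardized features
almost exactly (MSE 0.008 against unit-variance inputs); about half of each
session's 10 latent-space neighbours survive the UMAP projection
(Cons(10) ≈ 0.5); and the before-vs-during contrast explains ~29% of
multivariate band variance at this small cohort size, driven mainly by delta
— the structure the generator planted.

The same run is available from the shell:

```bash
eeglatent simulate --out cohort.zip --seed 1
eeglatent ingest cohort.zip --out-csv cohort.csv --out-manifest manifest.json
eeglatent effects cohort.csv --bootstrap 1000 --out-json effects.json
eeglatent run-all --synthetic --out-dir run1 --seed 1   # full pipeline
```

`run-all` writes every artifact (cohort CSVs, latent codes, training traces,
metric reports, projections with cluster labels, effects tables) plus a run
manifest whose config echo reproduces the run bit-for-bit.

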