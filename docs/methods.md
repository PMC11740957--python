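# Methods

## The model

`BatchVAE` is a conditional variational autoencoder trained adversarially
against a source discriminator. The encoder maps a normalized expression
profile x (log2 CPM with pseudocount 1, samples x genes) to a diagonal
Gaussian posterior Q(z|x) = N(mu, diag(exp(logvar))) over a latent space
with standard-normal prior. A draw z = mu + exp(logvar/2)·eps is decoded
together with a one-hot source vector s, so the decoder — not the latent
code — supplies dataset-specific style. The discriminator is a softmax
classifier on z. Training alternates, per minibatch, between

1. adversary update(s): minimise the multi-class negative log-likelihood
   −E[log p(s|z)] with respect to the adversary's weights only;
2. VAE update: minimise `recon + w_KL·kl − lambda·adv_nll` with respect to
   encoder and decoder, the adversary frozen, the adversarial gradient
   flowing through z into the encoder.

A single-optimizer gradient-reversal mode is available
(`adversarial_mode="gradient_reversal"`) and reaches the same equilibrium
on the synthetic fixture; alternating updates are the default because they
keep the two objectives' optimizer states independent.

Architecture defaults: encoder 256–128–64 with SELU activations and linear
mu/logvar heads on the last 64-wide layer (latent dimension 64); decoder
mirrors it (z ⊕ s → 64–128–256 → genes) with SELU between hidden layers and
a final ReLU so outputs stay in the non-negative log2-CPM range; adversary
64–32–K with softmax. Weights are LeCun-normal initialised (appropriate
for SELU); biases start at zero, which makes a freshly initialised
discriminator uninformative by construction.

### Loss scaling

The reconstruction term is the unit-variance Gaussian negative
log-likelihood up to constants, computed as the **per-element** mean
squared error (averaged over batch and genes). This choice matters: with
squared error summed over genes, the adversarial weight lambda = 0.11 is
four orders of magnitude smaller than the reconstruction gradient on
realistic gene counts, the encoder never feels the adversary, and the
discriminator converges to near-perfect — not random — source prediction.
With the per-element mean (the default reduction in the major deep-learning
frameworks), reconstruction is O(1), the printed weights behave as
intended, and the adversary ends at chance. The KL term keeps its full
per-sample form, 0.5·Σ_d(mu² + e^logvar − 1 − logvar), averaged over the
batch, with weight w_KL = 1.1e-5.

### Hyperparameters

| parameter | default | meaning |
|---|---|---|
| `latent_dim` | 64 | embedding width |
| `w_kl` | 1.1e-5 | weight of the KL regularizer |
| `lambda_adv` | 0.11 | weight of the adversarial term |
| `learning_rate` | 1e-3 | Adam, both optimizers |
| `batch_size` | 1600 | minibatch size at full data scale |
| `adversary_steps` | 3 | discriminator updates per VAE update |
| `grad_clip` | 10 | global L2 gradient-norm bound per update |
| `epochs` | 300 | fixed budget, no early stopping |

`adversary_steps` and `grad_clip` are this package's additions. Without
clipping, the minimax optimization occasionally diverges (the encoder
chases extreme embedding magnitudes to defeat the adversary, saturating the
SELU layers); without extra discriminator steps the adversary lags the
encoder and residual source information survives that a post-hoc kNN probe
detects even though the adversary itself is at chance. Three discriminator
steps and a norm bound of 10 are conventional, conservative values; both
are exposed as parameters.

Numerical guards: logvar clipped to [−20, 20] with a pass-through gradient
mask; softmax probabilities clamped at 1e-12 before logs; non-finite batch
losses abort training with a diagnostic rather than propagate.

### Fixture-scale training

For the 600-sample synthetic fixture the published-scale minibatch of 1600
would collapse each epoch into one full-batch step and 300 epochs into 300
optimizer steps, too few to reach equilibrium. The canonical fixture
configuration (`batchvae.training.FIXTURE_TRAINING`) is therefore
`batch_size=100, epochs=300, adversary_steps=3`, preserving the minibatch
regime at fixture scale. Under it, across independent weight-init seeds, a
fresh 5-NN source probe on the embeddings scores 0.29–0.40 (chance 1/3)
while k-means recovers the true clusters at ARI ≈ 1.0.

## Preprocessing

Gene sets are intersected across datasets and sorted lexicographically so
independent runs agree exactly. Indications with fewer than
`min_samples` (default 5) samples are removed; samples lacking an
indication are retained. Scaling factors follow the trimmed-mean-of-M-values
recipe: reference = sample whose upper-quartile count fraction is closest
to the mean upper-quartile; gene-wise log-ratios M and abundances A over
doubly-positive genes; double rank trim (30% on M, 5% on A); weighted mean
of the surviving M with precision (inverse delta-method-variance) weights;
factors rescaled to geometric mean 1. The implementation matches edgeR's
`calcNormFactors(method="TMM")` to below 1e-6 (verified in the test suite
by calling edgeR through Rscript). Expression values are
log2(count / (libsize·factor) · 1e6 + 1); TMM is applied jointly over the
concatenated datasets by default, with a per-dataset option. Genes with
zero counts everywhere are kept. The `TMMNormalizer` estimator stores the
reference sample at `fit` so new data are normalized consistently.

## Synthetic data

The generator emulates the integration problem's structure: shared
biological clusters measured under several sources whose effects confound
the biology. Counts are negative binomial,
mean = L_i · exp(profile_c(g)) · effect_s(g), var = mean + dispersion·mean²,
with per-sample library scale L_i log-normal around the source's scale.
The canonical fixture: 200 genes with a N(0,1) baseline log-profile, 4
clusters each up-regulating a private block of 20 genes by +2 (natural
log), 3 sources with gene-wise log-normal(0, 0.5²) multiplicative effects,
dispersion 0.3, 60 samples per present (cluster, source) block, and the
fourth cluster present **only** in the first source — a private population
that correct integration must align without merging. These conditions make
the batch effect dominant (a 5-NN source classifier on raw log-CPM is
essentially perfect) while keeping clusters separable.

What the generator does not emulate: gene–gene correlation beyond cluster
structure, length/GC biases, outlier samples, dropout, or non-multiplicative
batch distortions. Passing tests therefore demonstrate that the machinery
behaves as designed under the assumed generative structure, not that any
particular real cell-line/tumor pairing will align.

## Evaluation

Tumor-type assignment embeds the reference set with centered, unscaled PCA
(70 components at full scale; fitted on the reference only to avoid
query leakage, with a joint-fit option) and takes the majority label among
each query's k = 25 nearest reference samples (Euclidean). Vote ties break
by smaller summed distance, then lexicographic label order — fixed rules so
reports are deterministic; equality with a brute-force all-pairs oracle is
tested on hundreds of random instances. Differential expression uses
Welch's t-test per gene on the log-space values (Student's variant
selectable), Benjamini–Hochberg adjustment, genes with adjusted p below
alpha (default 0.01) ranked by |log2 fold change| and truncated to the top
100. Genes constant in both groups get p = 1 and a `degenerate` flag.
Batch mixing is quantified as the Shannon entropy of source composition in
each sample's k-neighborhood, normalized by ln K.

## Design choices made where the design was open

- **Reconstruction likelihood.** Gaussian with unit variance on log2-CPM
  (i.e., squared error); the decoder's ReLU output matches the
  non-negative range of log2(CPM+1). Count likelihoods (negative binomial)
  are out of scope since the model consumes normalized values.
- **Latent dimension 64** — the last encoder width feeding linear heads;
  decoder expands 64→128→256 rather than repeating the literal 256/128/64,
  the standard autoencoder shape (the literal reading is configurable).
- **Conditioning** by concatenating s to z at the decoder input.
- **Discriminator input** is the sampled z, not mu.
- **Projection default is the posterior mean** (`mode="mean"`): downstream
  analyses are reproducible without a sampling seed; `mode="sampled"`
  decodes one seeded draw.
- **Minibatches are uniformly shuffled** by default; a stratified option
  keeps per-batch source composition proportional for strongly imbalanced
  designs.

## Determinism

All randomness — weight init, shuffling, reparameterization noise,
simulation — flows from explicit integer seeds through
`numpy.random.default_rng`. Identical seeds reproduce training histories,
projections, and reports bitwise on a single device (floating-point
reductions can differ across BLAS builds).

## Limitations

- Equilibrium is empirical, not guaranteed: the minimax objective has no
  convergence proof, and the adversary bound (chance + 0.15) is a property
  of the fixture conditions, not of arbitrary data.
- The Gaussian reconstruction ignores the mean–variance relation of
  expression data; strongly heteroskedastic genes are weighted by their
  raw scale.
- A probe classifier stronger than the discriminator family can in
  principle recover source information the adversary cannot see; the test
  suite checks a 5-NN probe, not all probes.
- At full published scale (tens of thousands of genes and samples) the
  NumPy implementation trains on CPU only; it is adequate for the fixture
  scale this package targets and for moderate real datasets, but provides
  no GPU path.
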