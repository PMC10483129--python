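# Methods

## The model

`scdgd` implements a decoder-only deep generative model for integer count
matrices. Three sets of quantities are estimated jointly by maximum a
posteriori (MAP) gradient descent:

1. **Representations** `Z` — one free m-dimensional vector per cell,
   treated exactly like a model parameter and updated by backpropagation.
2. **Decoder** `f_θ` — a fully connected network (default three hidden
   layers of 100 ReLU units) mapping `z` to one sigmoid output per gene.
3. **Latent distribution** `P(z|φ)` — a mixture of K diagonal-covariance
   Gaussians with trainable means `μ_k`, negative log-variances `β_k`
   (so variances `exp(−β)` stay positive under unconstrained updates) and
   mixture coefficients `c_k` passed through a softmax.

The objective is the log joint
`Σ_i [log P(x_i|z_i,θ) + log P(z_i|φ)] + log P(φ) + log P(θ)`.
There is no encoder and no variational approximation: uncertainty in `z` is
not represented, only its MAP value.

### Observation model

Counts are modelled per gene as negative binomial in the mean/dispersion
parameterization, `Var = μ + μ²/r`. The NB mean for gene j of cell i is
`y_ij · s_i`, where `y = f_θ(z) ∈ (0,1)` and `s_i` is the cell's largest
count. Row-max scaling bounds the normalized data in `[0, 1]`, which is what
makes a sigmoid output layer appropriate. The NB is always evaluated at the
raw integer counts with the scaled mean — a proper pmf on the observed
integers (an NB "density" of the normalized fraction itself would not be a
distribution on `[0,1]`). Dispersions `r_j` are gene-specific and learned as
`log r_j` (initialized at 0, i.e. r = 1).

### Priors

- **Component means** — the softball distribution: a mollified uniform over
  the m-ball with radius `scale` and boundary slope `sharpness`,
  `log p(v) = log C − log(1 + exp(sharpness·(‖v‖/scale − 1)))`.
  `log C` is computed exactly at construction: the ideal-ball constant
  `Γ(m/2+1) / (π^{m/2} scale^m)` times a radial quadrature correction for
  the mass the soft boundary adds. The correction tends to 1 as sharpness
  grows; at small sharpness it is far from negligible (≈ `1 + π²/(3a²)` in
  2-D), and including it keeps the log-density a true normalized
  distribution at every sharpness.
- **Mixture weights** — Dirichlet(α), entering the loss as
  `(α−1)·Σ_k log w_k`; normalization constants that do not depend on
  parameters are dropped consistently (losses are comparable across runs
  with the same K, not across different K).
- **Negative log-variances** — `N(−2 log σ₀, 1)` elementwise, with
  `σ₀ = 0.2 · scale / K` by default (an absolute `sigma0` can be given).
  Small σ₀ keeps components tight relative to the prior ball so that they
  separate rather than overlap.
- **Decoder weights** — a Gaussian prior realized as Adam weight decay
  (default 1e−4), not as an explicit loss term.

## Training procedure

Three independent Adam optimizers (betas 0.5/0.7) run side by side:

| parameters        | learning rate | steps                  |
|-------------------|---------------|------------------------|
| decoder + log r   | 1e−3          | once per minibatch     |
| mixture (μ, β, c) | 1e−2          | once per minibatch     |
| representations Z | 1e−2          | once per epoch         |

Representation gradients accumulate over all minibatches of an epoch and a
single optimizer step is taken at epoch end (the batch loop reads a stable
copy of `Z` throughout the epoch; the alternative — stepping a stale
per-batch copy — is defensible but the accumulate-then-step reading is
implemented). The decoder learning rate drops to 1e−4 from epoch 500
(0-based) by default. The mixture-parameter prior `log P(φ)` is added once
per batch, unscaled; its effective pull is governed by the mixture learning
rate. Batches are reshuffled every epoch from the run seed, so runs are
bit-reproducible on one device.

Defaults follow the rule of thumb that representations need roughly 10×
and the mixture 10–20× the decoder's learning rate. The Dirichlet α
defaults to 2 (the mixture-weight prior that keeps components populated
when classes are roughly balanced); `batch_size` defaults to 128.

**Supervised mode.** With labels, each cell's latent loss uses only its
assigned component: `log w_k + log N(z; μ_k, Σ_k)`. Means and variances of
all other components receive exactly zero gradient from such a term. The
mixture *coefficients* remain weakly coupled through the softmax
normalization — `log w_k` depends on every `c_j` — which is an unavoidable
property of softmax weights, not an implementation choice.

**Inference for new cells.** The decoder and mixture are frozen; each new
cell's representation is initialized either at zero or (default) at the
component mean with the lowest reconstruction loss, then optimized for 10
epochs (batch 32) on `log P(x|z,θ) + log P(z|φ)`. An optional restart mode
runs one optimization per component mean and keeps the lowest final loss.
The inference learning rate defaults to the training representation rate.

## Synthetic data

The generator draws data from a fully known instance of the model itself:
a K-component mixture with means sampled from the softball prior and
rescaled so every pairwise distance is at least `separation` (default 6)
times the component standard deviation (default 0.1); a fixed random
decoder; gene dispersions log-uniform on `[0.5, 5]`; and a per-cell
sequencing depth drawn log-uniformly from `[50, 500]`. Counts follow by
ancestral sampling (component → z → depth → NB counts), with all-zero
cells resampled and counted.

Two design choices matter:

- **Per-gene baselines are calibrated, not emergent.** Each gene's output
  bias is set so that its sigmoid output at the centroid of the component
  means equals a log-uniform draw from `[2e−4, 2e−2]` (the same shape of
  gene-mean law that standard count simulators use). Every gene is
  therefore expressed at some level, and sparsity comes from low depth.
- **Component contrast is explicit.** The output-layer weights are scaled
  by a gain of 12, giving severalfold between-component expression
  differences on many genes — the synthetic analogue of marker genes.
  With this design, classifying cells by reconstruction loss under the
  *true* model succeeds for ≈ 99% of cells, so recovery failures in tests
  indicate estimation problems rather than unidentifiable data.

The standard fixture (K=3, m=2, 50 genes, 600 cells, seed 0) realizes
about 59% zero entries. What the generator does **not** emulate: the
extreme sparsity (≳ 90% zeros) and gene counts (tens of thousands) of real
droplet data, batch effects, doublets, ambient RNA, or cell-type
imbalance. Passing the recovery tests therefore shows the estimation
machinery works when the model is correctly specified and the signal is
identifiable; it does not certify performance on real tissues.

## Numerical choices

- Sigmoid outputs are clamped to `[1e−6, 1 − 1e−6]` so NB means stay
  positive for cells observing zeros at high-expression genes; clamped
  entries pass zero gradient.
- Mixture densities and responsibilities go through log-sum-exp; the
  softmax subtracts its maximum.
- Hard assignment breaks ties toward the lowest component index.
- All-zero count rows are rejected at normalization (the caller filters);
  readers drop such cells with a logged count.
- Non-finite losses or representations abort training with the epoch and
  batch in the diagnostic rather than continuing silently.
- Gradients for every module are hand-derived and are checked against
  central finite differences in the test suite.

## Problem sizes

Tests and the acceptance script use the desk-scale fixture above
(600 training cells, 100 held-out cells, 300 training epochs), chosen so
the full suite completes in well under a minute of compute while leaving
the recovery signal unambiguous. Oracle-equivalence checks run on hundreds
of small random instances; Monte-Carlo normalization checks use 10⁶ points.

## Component collapse and restarts

With few genes the early reconstruction gradient is weak, and a mixture
component whose mean starts far from the (initially zero) representation
cloud can lose its weight before the cloud spreads — the familiar
empty-component failure mode of gradient-fit mixtures. Representations
must start at zero regardless: spread random initializations let the
decoder memorize arbitrary structure and destroy label recovery. The
remedy used in the reproduction script is the standard one when K is set
to the expected number of populations: run a few replicate fits and keep
the one whose smallest mixture weight is largest (all components in use).
The selection is label-free; collapsed runs are easy to recognize because
one weight falls well below `1/K` while healthy runs keep all weights
near it. With tens of thousands of genes the reconstruction term
dominates from the start and this failure mode is far less likely.

## Known limitations

- MAP point estimates only; no posterior uncertainty over `z` or `φ`.
- Unsupervised fits can leave a component unused for some optimizer seeds
  at desk scale (see above); supervised fits do not have this problem.
- K is fixed by the user (or by the number of unique labels); no automatic
  component selection.
- Diagonal component covariances.
- Row-max scaling is the only library-size treatment; no batch or
  covariate correction, no zero inflation.
- Training is single-device; the numpy implementation is intended for
  desk-scale data, not atlas-scale matrices.
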