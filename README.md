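# scdgd

An encoder-free deep generative model for single-cell RNA count data.

Instead of amortizing inference through an encoder (as a VAE does), every
cell owns a free low-dimensional latent vector **z** that is estimated by
gradient descent together with the decoder weights and with a learnable
Gaussian-mixture distribution over latent space. Clustering falls out of the
model: a cell belongs to the mixture component most responsible for its
representation.

## Model

For counts `x_i` (cells × genes), representations `Z = {z_i}`, decoder
parameters `θ` and mixture parameters `φ`, the package maximizes the log
joint posterior

```
log P(X, Z, φ, θ) = Σ_i [ log P(x_i | z_i, θ) + log P(z_i | φ) ] + log P(φ) + log P(θ)
```

with

- **Observation model** — negative binomial per gene:
  `x_ij ~ NB(mean = y_ij · s_i, dispersion = r_j)`, where `y = f_θ(z)` is a
  fully connected network (three hidden layers of 100 ReLU units) with
  sigmoid outputs, `s_i` is the cell's maximum count (the scale factor), and
  `r_j` is a gene-specific dispersion learned on the log scale
  (`Var = μ + μ²/r`).
- **Latent distribution** — a mixture of K diagonal-covariance Gaussians
  with trainable means, negative log-variances and softmax-transformed
  mixture coefficients.
- **Parameter priors** — a "softball" prior (mollified uniform over an
  m-ball; `scale` = radius, `sharpness` = boundary slope) on component
  means, Dirichlet(α) on mixture weights, `N(−2 log σ₀, 1)` on negative
  log-variances, and weight decay on the decoder (its Gaussian prior).

Training (MAP by backpropagation, all hand-derived in numpy): the decoder
and mixture step once per minibatch with Adam; representation gradients
accumulate over the epoch and step once at epoch end, with separate Adam
instances and learning rates (1e−3 decoder / 1e−2 representations / 1e−2
mixture, betas 0.5/0.7). New cells are embedded with the model frozen:
each cell starts at the component mean with the lowest reconstruction loss
and its `z` is optimized for a few epochs.

A supervised variant restricts each cell's latent loss to its labelled
component, so unlabelled structure cannot leak across classes.

## Worked example

Everything runs from synthetic data with a known ground truth (a fixed
mixture and decoder), so recovery can be scored exactly:

```python
import numpy as np, scdgd
from scipy.stats import spearmanr

# ground truth: 3 components, 2-D latent space, 50 genes, 600 cells
gt, data, labels, true_z, report = scdgd.default_fixture()

config = scdgd.TrainConfig(n_components=3, latent_dim=2, epochs=300,
                           batch_size=128, seed=0)
decoder, gmm, reps, history = scdgd.fit(data, config)

assign = gmm.hard_assign(reps.values)
print("ARI vs true components:",
      round(scdgd.adjusted_rand_index(labels, assign), 3))
print("dispersion Spearman:",
      round(spearmanr(decoder.log_dispersion,
                      gt.decoder.log_dispersion).statistic, 3))
nll = scdgd.test_negative_log_likelihood(data, reps, decoder)
print(f"NLL {nll.mean:.2f} +/- {nll.sem:.2f}   RMSE {scdgd.rmse(data, reps, decoder):.4f}")
```

prints

```
ARI vs true components: 0.995
dispersion Spearman: 0.78
NLL 93.94 +/- 0.77   RMSE 0.1300
```

Clustering recovers the generating components almost perfectly (ARI 0.995;
1.0 means identical partitions), the learned gene-wise dispersions rank-
correlate strongly with the generating ones, the per-cell negative
log-likelihood is the NB log-density summed over all 50 genes, and the RMSE
is on the row-max-normalized scale of the decoder output.

The same pipeline is available from the shell:

```sh
scdgd simulate --n-cells 600 --outdir sim/
scdgd train --counts sim/ --labels sim/labels.tsv --epochs 300 --latent-dim 2 --outdir run/
scdgd evaluate --checkpoint run/checkpoint.npz --counts sim/ --labels sim/labels.tsv
```

`train` also reads real 10x-style data (`matrix.mtx` + `barcodes.tsv` +
`features.tsv`); when labels are given, the number of mixture components
defaults to the number of unique cell-type labels.

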