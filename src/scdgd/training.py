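"""Joint MAP estimation of representations, decoder and mixture by gradient descent.

Every training sample owns a free latent vector.  Three Adam optimizers run
side by side with individually chosen learning rates: decoder and mixture
parameters step once per minibatch, while representation gradients accumulate
over the epoch and the representation optimizer steps exactly once at epoch
end.  The objective is the log joint: NB reconstruction log-likelihood plus
mixture log-density of the representations plus the log prior over mixture
parameters; the Gaussian prior on decoder weights is realized as Adam weight
decay.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .decoder import CountDataset, DecoderModel
from .priors import GaussianMixture, SoftballPrior


@dataclass
class TrainConfig:
    """Hyperparameters for MAP training.

    Learning rates follow the rule of thumb that representations move ~10x
    and the mixture 10-20x faster than the decoder.  The decoder learning
    rate drops to ``lr_decoder_after_drop`` from epoch ``decoder_lr_drop_epoch``
    onward (0-based; set the epoch to None to disable).
    """

    n_components: int = 9
    latent_dim: int = 20
    epochs: int = 800
    batch_size: int = 128
    lr_decoder: float = 1e-3
    lr_representation: float = 1e-2
    lr_gmm: float = 1e-2
    adam_betas: Tuple[float, float] = (0.5, 0.7)
    decoder_lr_drop_epoch: Optional[int] = 500
    lr_decoder_after_drop: float = 1e-4
    weight_decay: float = 1e-4
    softball_scale: float = 1.0
    softball_sharpness: float = 1.0
    dirichlet_alpha: float = 2.0
    sigma0_factor: float = 0.2
    sigma0: Optional[float] = None  # absolute override of sigma0_factor*scale/K
    hidden_dims: Tuple[int, ...] = (100, 100, 100)
    representation_init: str = "zero"
    seed: int = 0
    supervised: bool = False

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        for name in ("lr_decoder", "lr_representation", "lr_gmm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be non-negative")

    def resolved_sigma0(self) -> float:
        if self.sigma0 is not None:
            return self.sigma0
        return self.sigma0_factor * self.softball_scale / self.n_components


def decoder_lr_schedule(epoch: int, config: TrainConfig) -> float:
    """Decoder learning rate at a 0-based epoch index."""
    if (
        config.decoder_lr_drop_epoch is not None
        and epoch >= config.decoder_lr_drop_epoch
    ):
        return config.lr_decoder_after_drop
    return config.lr_decoder


@dataclass
class RepresentationSet:
    """One trainable latent vector per sample, order-aligned with the dataset."""

    values: np.ndarray
    sample_ids: Optional[np.ndarray] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be n x m")
        if self.sample_ids is None:
            self.sample_ids = np.arange(self.values.shape[0])
        self.grad = np.zeros_like(self.values)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    def zero_grad(self) -> None:
        self.grad[:] = 0.0

    def parameters(self):
        return [("Z", self.values, self.grad)]


def init_representations(
    n: int,
    m: int,
    mode: str = "zero",
    rng: Optional[np.random.Generator] = None,
    softball: Optional[SoftballPrior] = None,
) -> RepresentationSet:
    """Initialize latent vectors to zeros or to softball-prior draws."""
    if mode == "zero":
        values = np.zeros((n, m))
    elif mode == "softball":
        rng = rng or np.random.default_rng()
        softball = softball or SoftballPrior(m)
        values = softball.sample(n, rng)
    else:
        raise ValueError(f"unknown init mode {mode!r}; valid modes: 'zero', 'softball'")
    return RepresentationSet(values=values)


class Adam:
    """Adam over a list of (name, param, grad) triples, updated in place.

    ``weight_decay`` adds an L2 term to the gradient before the moment
    updates (the Gaussian-prior reading of weight decay).
    """

    def __init__(
        self,
        params: Sequence[Tuple[str, np.ndarray, np.ndarray]],
        lr: float,
        betas: Tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = float(weight_decay)
        self.t = 0
        self.m = {name: np.zeros_like(p) for name, p, _ in self.params}
        self.v = {name: np.zeros_like(p) for name, p, _ in self.params}
        self.step_count = 0

    def step(self) -> None:
        self.t += 1
        self.step_count += 1
        for name, p, g in self.params:
            grad = g if self.weight_decay == 0.0 else g + self.weight_decay * p
            m = self.m[name]
            v = self.v[name]
            m *= self.beta1
            m += (1 - self.beta1) * grad
            v *= self.beta2
            v += (1 - self.beta2) * grad * grad
            m_hat = m / (1 - self.beta1**self.t)
            v_hat = v / (1 - self.beta2**self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


@dataclass
class LossParts:
    """Additive pieces of the negative log joint for one batch."""

    total: float
    reconstruction: float
    latent: float
    param_prior: float


def batch_loss(
    x_batch: np.ndarray,
    s_batch: np.ndarray,
    z_batch: np.ndarray,
    decoder: DecoderModel,
    gmm: GaussianMixture,
    labels: Optional[np.ndarray] = None,
    compute_grad: bool = True,
) -> Tuple[LossParts, Optional[np.ndarray]]:
    """Negative log joint for one minibatch, decomposed for logging.

    total = -(sum_i recon_i + sum_i latent_i) - param_log_prior.  When
    ``compute_grad`` is set, gradients accumulate into the decoder and
    mixture buffers and the gradient with respect to the batch
    representations is returned.
    """
    x_batch = np.asarray(x_batch)
    if x_batch.shape[0] == 0:
        raise ValueError("empty batch")
    n = x_batch.shape[0]
    neg = -np.ones(n)

    if compute_grad:
        recon_ll, dz_recon = decoder.reconstruction_backward(
            x_batch, z_batch, s_batch, grad_out=-1.0
        )
        if labels is None:
            latent_ll = gmm.log_density(z_batch)
            dz_latent = gmm.log_density_backward(z_batch, neg)
        else:
            latent_ll = gmm.supervised_log_density(z_batch, labels)
            dz_latent = gmm.supervised_log_density_backward(z_batch, labels, neg)
        gmm.param_log_prior_backward(-1.0)
        dz = dz_recon + dz_latent
    else:
        recon_ll = decoder.reconstruction_log_prob(x_batch, z_batch, s_batch)
        if labels is None:
            latent_ll = gmm.log_density(z_batch)
        else:
            latent_ll = gmm.supervised_log_density(z_batch, labels)
        dz = None

    prior = gmm.param_log_prior()
    parts = LossParts(
        total=-(float(recon_ll.sum()) + float(latent_ll.sum())) - prior,
        reconstruction=-float(recon_ll.sum()),
        latent=-float(latent_ll.sum()),
        param_prior=-prior,
    )
    return parts, dz


def fit(
    data: CountDataset,
    config: TrainConfig,
    labels: Optional[np.ndarray] = None,
) -> Tuple[DecoderModel, GaussianMixture, RepresentationSet, Dict[str, List[float]]]:
    """Train the full model by MAP gradient descent.

    Per epoch: minibatches are shuffled with the run seed; the decoder and
    mixture optimizers step every batch; representation gradients accumulate
    and their optimizer steps once at epoch end.  Returns the trained
    decoder, mixture, representations and a per-epoch loss history with
    optimizer step counters.
    """
    if config.supervised:
        if labels is None and data.labels is not None:
            labels = data.labels
        if labels is None:
            raise ValueError("supervised training requires labels")
        labels = np.asarray(labels, dtype=int)
        if labels.max() >= config.n_components:
            raise ValueError(
                f"label set exceeds n_components: max label {labels.max()} "
                f">= K={config.n_components}"
            )
    rng = np.random.default_rng(config.seed)

    softball = SoftballPrior(
        config.latent_dim, config.softball_scale, config.softball_sharpness
    )
    gmm = GaussianMixture(
        config.n_components,
        config.latent_dim,
        mean_prior=softball,
        dirichlet_alpha=config.dirichlet_alpha,
        sigma0=config.resolved_sigma0(),
        rng=rng,
    )
    decoder = DecoderModel(
        latent_dim=config.latent_dim,
        n_genes=data.n_genes,
        hidden_dims=config.hidden_dims,
        rng=rng,
    )
    reps = init_representations(
        data.n_cells, config.latent_dim, config.representation_init, rng, softball
    )

    opt_decoder = Adam(
        decoder.parameters(),
        lr=config.lr_decoder,
        betas=config.adam_betas,
        weight_decay=config.weight_decay,
    )
    opt_gmm = Adam(gmm.parameters(), lr=config.lr_gmm, betas=config.adam_betas)
    opt_rep = Adam(
        reps.parameters(), lr=config.lr_representation, betas=config.adam_betas
    )

    n = data.n_cells
    history: Dict[str, List[float]] = {
        "epoch": [],
        "total": [],
        "reconstruction": [],
        "latent": [],
        "param_prior": [],
        "lr_decoder": [],
    }
    for epoch in range(config.epochs):
        opt_decoder.lr = decoder_lr_schedule(epoch, config)
        order = rng.permutation(n)
        ep_total = ep_recon = ep_latent = ep_prior = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            x_batch = data.dense_rows(idx)
            s_batch = data.scale_factors[idx]
            z_batch = reps.values[idx]
            batch_labels = labels[idx] if config.supervised else None

            decoder.zero_grad()
            gmm.zero_grad()
            parts, dz = batch_loss(
                x_batch, s_batch, z_batch, decoder, gmm, labels=batch_labels
            )
            if not np.isfinite(parts.total):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch starting {start}: "
                    f"{parts}"
                )
            reps.grad[idx] += dz
            opt_decoder.step()
            opt_gmm.step()
            ep_total += parts.total
            ep_recon += parts.reconstruction
            ep_latent += parts.latent
            ep_prior += parts.param_prior
        opt_rep.step()
        reps.zero_grad()
        if not np.all(np.isfinite(reps.values)):
            raise FloatingPointError(
                f"non-finite representation values after epoch {epoch}"
            )
        history["epoch"].append(epoch)
        history["total"].append(ep_total)
        history["reconstruction"].append(ep_recon)
        history["latent"].append(ep_latent)
        history["param_prior"].append(ep_prior)
        history["lr_decoder"].append(opt_decoder.lr)

    history["n_representation_steps"] = [opt_rep.step_count]
    history["n_decoder_steps"] = [opt_decoder.step_count]
    history["n_gmm_steps"] = [opt_gmm.step_count]
    return decoder, gmm, reps, history
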