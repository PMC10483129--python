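"""Representation inference for unseen cells with a frozen model.

There is no encoder: each new cell gets its own latent vector, initialized
either at zero or at the mixture component mean with the lowest
reconstruction loss, then optimized by gradient descent on the latent
vector alone.  Decoder, dispersions and mixture parameters stay untouched.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from .decoder import CountDataset, DecoderModel, reconstruction_log_prob
from .priors import GaussianMixture
from .training import Adam, RepresentationSet


def per_component_reconstruction_nll(
    data: CountDataset, decoder: DecoderModel, gmm: GaussianMixture
) -> np.ndarray:
    """(n, K) matrix of reconstruction NLL with each cell placed at each mean."""
    y_at_means = decoder.decode(gmm.means)  # (K, G)
    n = data.n_cells
    nll = np.empty((n, gmm.n_components))
    x = data.dense_rows(np.arange(n))
    for k in range(gmm.n_components):
        y = np.broadcast_to(y_at_means[k], x.shape)
        nll[:, k] = -reconstruction_log_prob(
            x, y, data.scale_factors, decoder.log_dispersion
        )
    return nll


def init_new_representations(
    x_new: CountDataset,
    decoder: DecoderModel,
    gmm: GaussianMixture,
    mode: str = "best_component",
) -> RepresentationSet:
    """Starting representations for new cells.

    ``best_component`` (default) places each cell at the component mean with
    the smallest reconstruction loss, which effectively assigns the optimal
    component before any optimization; ``zero`` starts at the origin.
    """
    if mode == "best_component":
        nll = per_component_reconstruction_nll(x_new, decoder, gmm)
        best = np.argmin(nll, axis=1)
        values = gmm.means[best].copy()
    elif mode == "zero":
        values = np.zeros((x_new.n_cells, gmm.dim))
    else:
        raise ValueError(
            f"unknown init mode {mode!r}; valid modes: 'best_component', 'zero'"
        )
    return RepresentationSet(values=values)


def infer_representations(
    x_new: CountDataset,
    decoder: DecoderModel,
    gmm: GaussianMixture,
    epochs: int = 10,
    batch_size: int = 32,
    lr: float = 1e-2,
    adam_betas: Tuple[float, float] = (0.5, 0.7),
    init_mode: str = "best_component",
    seed: int = 0,
    restarts: bool = False,
) -> Tuple[RepresentationSet, np.ndarray]:
    """MAP inference of representations for unseen cells.

    Maximizes reconstruction log-likelihood plus mixture log-density by
    gradient descent on the latent vectors only.  With ``restarts``, one run
    is started from every component mean and the representation with the
    lowest final loss per cell is kept.  Returns the representations and the
    per-cell final negative log joint (reconstruction + latent terms).

    Decoder and mixture parameters are never written to.
    """
    if restarts and init_mode == "best_component":
        candidates = []
        losses = []
        for k in range(gmm.n_components):
            reps_k = RepresentationSet(
                values=np.tile(gmm.means[k], (x_new.n_cells, 1))
            )
            reps_k, loss_k = _optimize(
                x_new, decoder, gmm, reps_k, epochs, batch_size, lr, adam_betas, seed
            )
            candidates.append(reps_k.values)
            losses.append(loss_k)
        losses = np.stack(losses, axis=1)  # (n, K)
        best = np.argmin(losses, axis=1)
        values = np.stack(candidates, axis=1)[np.arange(x_new.n_cells), best]
        return RepresentationSet(values=values), losses[np.arange(x_new.n_cells), best]

    reps = init_new_representations(x_new, decoder, gmm, mode=init_mode)
    return _optimize(
        x_new, decoder, gmm, reps, epochs, batch_size, lr, adam_betas, seed
    )


def _optimize(
    data: CountDataset,
    decoder: DecoderModel,
    gmm: GaussianMixture,
    reps: RepresentationSet,
    epochs: int,
    batch_size: int,
    lr: float,
    adam_betas: Tuple[float, float],
    seed: int,
) -> Tuple[RepresentationSet, np.ndarray]:
    rng = np.random.default_rng(seed)
    opt = Adam(reps.parameters(), lr=lr, betas=adam_betas)
    n = data.n_cells
    for epoch in range(epochs):
        order = rng.permutation(n)
        reps.zero_grad()
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            x = data.dense_rows(idx)
            z = reps.values[idx]
            # gradients on z only: decoder/gmm grad buffers are scratch here
            decoder.zero_grad()
            gmm.zero_grad()
            _, dz_recon = decoder.reconstruction_backward(
                x, z, data.scale_factors[idx], grad_out=-1.0
            )
            dz_latent = gmm.log_density_backward(z, -np.ones(len(idx)))
            reps.grad[idx] += dz_recon + dz_latent
        decoder.zero_grad()
        gmm.zero_grad()
        opt.step()
        reps.zero_grad()
        if not np.all(np.isfinite(reps.values)):
            bad = np.flatnonzero(~np.isfinite(reps.values).all(axis=1))
            raise FloatingPointError(
                f"non-finite representations during inference at epoch {epoch}; "
                f"sample indices {bad[:10].tolist()}"
            )
    x_all = data.dense_rows(np.arange(n))
    recon = decoder.reconstruction_log_prob(x_all, reps.values, data.scale_factors)
    latent = gmm.log_density(reps.values)
    return reps, -(recon + latent)
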