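"""Decoder network and negative-binomial count likelihood.

The decoder is a plain fully connected network mapping latent vectors to one
sigmoid output per gene, so outputs are fractions of each cell's maximum
count (the per-cell scale factor).  Counts are modelled as negative binomial
with mean ``output * scale_factor`` and a gene-specific dispersion learned on
the log scale.  Forward and backward passes are written directly in numpy;
the forward pass caches activations so gradients for weights, biases,
dispersions and the latent inputs come out of one backward call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import scipy.sparse as sp
from scipy.special import digamma, gammaln

OUTPUT_EPS = 1e-6  # sigmoid outputs are clamped to [eps, 1-eps] so NB means stay positive

Matrix = Union[np.ndarray, sp.spmatrix]


@dataclass
class CountDataset:
    """Integer count matrix (cells x genes) with per-cell scale factors.

    ``scale_factors`` are the per-cell maximum counts; the model's sigmoid
    outputs are fractions of them.  ``counts`` may be dense or scipy sparse;
    rows are densified on access.
    """

    counts: Matrix
    scale_factors: np.ndarray
    labels: Optional[np.ndarray] = None
    split: Optional[np.ndarray] = None
    barcodes: Optional[List[str]] = None
    gene_names: Optional[List[str]] = None

    def __post_init__(self):
        self.scale_factors = np.asarray(self.scale_factors, dtype=float)
        if self.counts.shape[0] != self.scale_factors.shape[0]:
            raise ValueError("counts and scale_factors disagree on cell count")
        if np.any(self.scale_factors <= 0):
            raise ValueError("scale factors must be positive (drop all-zero cells)")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def dense_rows(self, idx: np.ndarray) -> np.ndarray:
        """Densify the requested rows as a float array (batch assembly)."""
        block = self.counts[idx]
        if sp.issparse(block):
            block = np.asarray(block.todense())
        return np.asarray(block, dtype=float)

    @classmethod
    def from_counts(
        cls,
        counts: Matrix,
        labels: Optional[np.ndarray] = None,
        barcodes: Optional[List[str]] = None,
        gene_names: Optional[List[str]] = None,
    ) -> "CountDataset":
        """Build a dataset, computing scale factors from the row maxima."""
        dense = np.asarray(counts.todense()) if sp.issparse(counts) else np.asarray(counts)
        _, s = normalize_counts(dense)
        return cls(
            counts=counts,
            scale_factors=s,
            labels=None if labels is None else np.asarray(labels),
            barcodes=barcodes,
            gene_names=gene_names,
        )


def normalize_counts(x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Divide each cell by its largest count; returns (fractions, scale_factors)."""
    x = np.asarray(x)
    if x.ndim != 2:
        raise ValueError("expected a 2-D cells x genes matrix")
    s = x.max(axis=1).astype(float)
    zero_rows = np.flatnonzero(s <= 0)
    if zero_rows.size:
        raise ValueError(
            f"all-zero count rows cannot be normalized; offending cell indices: "
            f"{zero_rows[:20].tolist()}"
        )
    return x / s[:, None], s


# ---- negative binomial -------------------------------------------------------


def _validate_counts(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x)
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    if not np.allclose(x, np.round(x)):
        raise ValueError("counts must be integers")
    return x.astype(float)


def nb_log_pmf(x, mean, r) -> np.ndarray:
    """Negative-binomial log pmf in the mean/dispersion parameterization.

    ``r`` is the dispersion (shape): variance = mean + mean^2 / r.  Vectorized
    with broadcasting over cells and genes.
    """
    x = _validate_counts(x)
    mean = np.asarray(mean, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any(mean <= 0):
        raise ValueError("mean must be positive")
    if np.any(r <= 0):
        raise ValueError("dispersion r must be positive")
    return (
        gammaln(x + r)
        - gammaln(r)
        - gammaln(x + 1.0)
        + r * np.log(r / (r + mean))
        + x * np.log(mean / (r + mean))
    )


def nb_log_pmf_grads(x, mean, r) -> Tuple[np.ndarray, np.ndarray]:
    """(d log pmf / d mean, d log pmf / d r), elementwise."""
    x = np.asarray(x, dtype=float)
    mean = np.asarray(mean, dtype=float)
    r = np.asarray(r, dtype=float)
    d_mean = x / mean - (x + r) / (r + mean)
    d_r = (
        digamma(x + r)
        - digamma(r)
        + np.log(r / (r + mean))
        + (mean - x) / (r + mean)
    )
    return d_mean, d_r


def reconstruction_log_prob(
    x: np.ndarray, y: np.ndarray, s: np.ndarray, log_r: np.ndarray
) -> np.ndarray:
    """Per-cell log P(x | z, theta): NB log pmf summed over genes.

    ``y`` is the decoder output in (0, 1); the NB mean for gene j of cell i is
    ``y[i, j] * s[i]``.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    s = np.asarray(s, dtype=float)
    log_r = np.asarray(log_r, dtype=float)
    if x.shape != y.shape or x.shape[0] != s.shape[0] or x.shape[1] != log_r.shape[0]:
        raise ValueError(
            f"shape mismatch: x {x.shape}, y {y.shape}, s {s.shape}, log_r {log_r.shape}"
        )
    mean = y * s[:, None]
    return nb_log_pmf(x, mean, np.exp(log_r)[None, :]).sum(axis=1)


class DecoderModel:
    """Fully connected latent -> genes network with sigmoid outputs.

    Three hidden layers of 100 units by default, ReLU activations, and a
    per-gene log-dispersion vector for the NB likelihood.  Weight gradients
    accumulate into ``grad_*`` buffers mirroring the parameters.
    """

    def __init__(
        self,
        latent_dim: int = 20,
        n_genes: int = 1,
        hidden_dims: Sequence[int] = (100, 100, 100),
        rng: Optional[np.random.Generator] = None,
    ):
        self.latent_dim = int(latent_dim)
        self.n_genes = int(n_genes)
        self.hidden_dims = list(hidden_dims)
        rng = rng or np.random.default_rng()
        dims = [self.latent_dim] + self.hidden_dims + [self.n_genes]
        self.weights: List[np.ndarray] = []
        self.biases: List[np.ndarray] = []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            # He-style scaling for the ReLU stack
            self.weights.append(rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in))
            self.biases.append(np.zeros(fan_out))
        self.log_dispersion = np.zeros(self.n_genes)
        self._cache = None
        self.zero_grad()

    def parameters(self):
        out = []
        for i, (w, gw) in enumerate(zip(self.weights, self.grad_weights)):
            out.append((f"W{i}", w, gw))
        for i, (b, gb) in enumerate(zip(self.biases, self.grad_biases)):
            out.append((f"b{i}", b, gb))
        out.append(("log_dispersion", self.log_dispersion, self.grad_log_dispersion))
        return out

    def zero_grad(self) -> None:
        # buffers are zeroed in place so optimizer references stay valid
        if not hasattr(self, "grad_weights"):
            self.grad_weights = [np.zeros_like(w) for w in self.weights]
            self.grad_biases = [np.zeros_like(b) for b in self.biases]
            self.grad_log_dispersion = np.zeros_like(self.log_dispersion)
        else:
            for g in self.grad_weights:
                g[:] = 0.0
            for g in self.grad_biases:
                g[:] = 0.0
            self.grad_log_dispersion[:] = 0.0

    def decode(self, z: np.ndarray, cache: bool = False) -> np.ndarray:
        """Forward pass; outputs lie in [eps, 1-eps]."""
        z = np.atleast_2d(np.asarray(z, dtype=float))
        if z.shape[1] != self.latent_dim:
            raise ValueError(
                f"dimension mismatch: expected latent dim {self.latent_dim}, "
                f"got {z.shape[1]}"
            )
        h = z
        pre_acts = []
        hiddens = [h]
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            a = h @ w + b
            pre_acts.append(a)
            h = np.maximum(a, 0.0)
            hiddens.append(h)
        a_out = h @ self.weights[-1] + self.biases[-1]
        sig = 1.0 / (1.0 + np.exp(-a_out))
        y = np.clip(sig, OUTPUT_EPS, 1.0 - OUTPUT_EPS)
        if cache:
            self._cache = (pre_acts, hiddens, sig)
        return y

    def backward(self, d_y: np.ndarray) -> np.ndarray:
        """Backpropagate dLoss/dy from the last cached forward; returns dLoss/dz."""
        if self._cache is None:
            raise RuntimeError("decode(..., cache=True) must precede backward()")
        pre_acts, hiddens, sig = self._cache
        inside = (sig > OUTPUT_EPS) & (sig < 1.0 - OUTPUT_EPS)
        delta = d_y * inside * sig * (1.0 - sig)
        self.grad_weights[-1] += hiddens[-1].T @ delta
        self.grad_biases[-1] += delta.sum(axis=0)
        dh = delta @ self.weights[-1].T
        for i in range(len(self.hidden_dims) - 1, -1, -1):
            da = dh * (pre_acts[i] > 0)
            self.grad_weights[i] += hiddens[i].T @ da
            self.grad_biases[i] += da.sum(axis=0)
            dh = da @ self.weights[i].T
        return dh

    # ---- likelihood with gradients ------------------------------------------

    def reconstruction_log_prob(
        self, x: np.ndarray, z: np.ndarray, s: np.ndarray
    ) -> np.ndarray:
        """Per-cell NB log-likelihood of counts ``x`` at representations ``z``."""
        y = self.decode(z)
        return reconstruction_log_prob(x, y, s, self.log_dispersion)

    def reconstruction_backward(
        self, x: np.ndarray, z: np.ndarray, s: np.ndarray, grad_out: float = 1.0
    ) -> Tuple[np.ndarray, np.ndarray]:
        """Gradients of ``grad_out * sum_i log P(x_i | z_i)``.

        Accumulates decoder and dispersion gradients; returns
        (per-cell log-likelihood, dLoss/dz).
        """
        y = self.decode(z, cache=True)
        s = np.asarray(s, dtype=float)
        mean = y * s[:, None]
        r = np.exp(self.log_dispersion)[None, :]
        ll = nb_log_pmf(x, mean, r).sum(axis=1)
        d_mean, d_r = nb_log_pmf_grads(x, mean, r)
        self.grad_log_dispersion += grad_out * (d_r * r).sum(axis=0)
        dz = self.backward(grad_out * d_mean * s[:, None])
        return ll, dz

    def sample_counts(
        self, z: np.ndarray, s: np.ndarray, rng: np.random.Generator
    ) -> np.ndarray:
        """Draw NB counts with mean decode(z) * s and the learned dispersions."""
        y = self.decode(z)
        mean = y * np.asarray(s, dtype=float)[:, None]
        r = np.exp(self.log_dispersion)[None, :]
        p = r / (r + mean)
        return rng.negative_binomial(np.broadcast_to(r, mean.shape), p)
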