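"""Latent-space distributions: the softball prior and the learnable Gaussian mixture.

The representation space of the deep generative decoder carries a mixture of K
diagonal-covariance Gaussians whose means, negative log-variances and mixture
coefficients are all free parameters, estimated jointly with the decoder by
gradient descent.  Priors over those parameters are part of the model: a
"softball" (mollified uniform ball) prior on the component means, a Dirichlet
prior on the mixture weights and a Gaussian prior on the negative
log-variances.

All gradients are hand-derived and accumulated into ``grad_*`` buffers so the
mixture can participate in the same backpropagation pass as the numpy decoder.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from scipy.integrate import quad
from scipy.special import gammaln, logsumexp


class SoftballPrior:
    """Mollified uniform distribution on the m-ball of radius ``scale``.

    The log-density is ``log C - log(1 + exp(sharpness * (||v||/scale - 1)))``
    where ``C`` is the reciprocal volume of the m-ball, so the distribution
    approaches the exact uniform ball as ``sharpness`` grows.  ``sharpness``
    controls how steeply the density falls off at the boundary.
    """

    def __init__(self, dim: int, scale: float = 1.0, sharpness: float = 1.0):
        if dim < 1:
            raise ValueError(f"dim must be >= 1, got {dim}")
        if scale <= 0:
            raise ValueError(f"scale must be positive, got {scale}")
        if sharpness <= 0:
            raise ValueError(f"sharpness must be positive, got {sharpness}")
        self.dim = int(dim)
        self.scale = float(scale)
        self.sharpness = float(sharpness)
        # exact normalizer: 1/volume of the m-ball corrected for the mass the
        # sigmoidal boundary moves relative to a hard-edged uniform ball; the
        # correction (m * I_m below) tends to 1 as sharpness grows
        log_ball = (
            gammaln(self.dim / 2.0 + 1.0)
            - self.dim * (math.log(self.scale) + 0.5 * math.log(math.pi))
        )
        a, m = self.sharpness, self.dim
        radial, _ = quad(
            lambda u: u ** (m - 1) / (1.0 + math.exp(min(a * (u - 1.0), 700.0))),
            0.0,
            1.0 + 200.0 / a,
            limit=200,
        )
        self.log_norm = log_ball - math.log(m * radial)

    def _check_dim(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        if v.ndim == 1:
            v = v[None, :]
        if v.shape[-1] != self.dim:
            raise ValueError(
                f"dimension mismatch: expected vectors of length {self.dim}, "
                f"got {v.shape[-1]}"
            )
        return v

    def log_prob(self, v: np.ndarray) -> np.ndarray:
        """Log-density at ``v`` (one vector or a matrix of row vectors)."""
        vv = self._check_dim(v)
        r = np.linalg.norm(vv, axis=-1)
        # -log(1 + exp(t)) computed stably via logaddexp
        mollifier = -np.logaddexp(0.0, self.sharpness * (r / self.scale - 1.0))
        out = self.log_norm + mollifier
        return out[0] if np.ndim(v) == 1 else out

    def grad_log_prob(self, v: np.ndarray) -> np.ndarray:
        """d log p / dv; zero at the origin where the radial direction is undefined."""
        vv = self._check_dim(v)
        r = np.linalg.norm(vv, axis=-1, keepdims=True)
        t = self.sharpness * (r / self.scale - 1.0)
        sig = 1.0 / (1.0 + np.exp(-t))
        with np.errstate(invalid="ignore", divide="ignore"):
            direction = np.where(r > 0, vv / np.where(r > 0, r, 1.0), 0.0)
        g = -sig * (self.sharpness / self.scale) * direction
        return g[0] if np.ndim(v) == 1 else g

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` points uniformly from the m-ball (direction x radius law)."""
        if n < 1:
            raise ValueError(f"n must be >= 1, got {n}")
        direction = rng.standard_normal((n, self.dim))
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        radius = self.scale * rng.uniform(size=(n, 1)) ** (1.0 / self.dim)
        return direction * radius


def mixture_weights(coeffs: np.ndarray) -> np.ndarray:
    """Softmax of the unconstrained mixture coefficients (overflow-safe)."""
    c = np.asarray(coeffs, dtype=float)
    shifted = c - c.max()
    e = np.exp(shifted)
    return e / e.sum()


def _log_softmax(c: np.ndarray) -> np.ndarray:
    shifted = c - c.max()
    return shifted - np.log(np.exp(shifted).sum())


class GaussianMixture:
    """K-component diagonal Gaussian mixture over an m-dimensional latent space.

    Parameters are stored unconstrained: per-dimension variances as negative
    log-variances ``neg_log_var`` (so they stay positive after any gradient
    step) and mixture weights as raw coefficients ``coeffs`` passed through a
    softmax.  Matching ``grad_*`` buffers accumulate gradients of whatever
    scalar loss the caller backpropagates.

    Priors on the parameters: softball on the means, Dirichlet(alpha) on the
    weights, N(-2 log sigma0, 1) elementwise on the negative log-variances.
    By default ``sigma0 = 0.2 * scale / K``.
    """

    def __init__(
        self,
        n_components: int,
        dim: int,
        mean_prior: Optional[SoftballPrior] = None,
        dirichlet_alpha: float = 1.0,
        sigma0: Optional[float] = None,
        rng: Optional[np.random.Generator] = None,
    ):
        if n_components < 1:
            raise ValueError(f"n_components must be >= 1, got {n_components}")
        self.n_components = int(n_components)
        self.dim = int(dim)
        self.mean_prior = mean_prior or SoftballPrior(dim)
        if self.mean_prior.dim != self.dim:
            raise ValueError(
                f"mean_prior dim {self.mean_prior.dim} != mixture dim {self.dim}"
            )
        self.dirichlet_alpha = float(dirichlet_alpha)
        if sigma0 is None:
            sigma0 = 0.2 * self.mean_prior.scale / self.n_components
        self.sigma0 = float(sigma0)
        self.logvar_prior_mean = -2.0 * math.log(self.sigma0)
        self.logvar_prior_sd = 1.0  # fixed

        rng = rng or np.random.default_rng()
        self.means = self.mean_prior.sample(self.n_components, rng)
        self.neg_log_var = np.full(
            (self.n_components, self.dim), self.logvar_prior_mean, dtype=float
        )
        self.coeffs = np.ones(self.n_components, dtype=float)
        self.zero_grad()

    # ---- parameter plumbing -------------------------------------------------

    def parameters(self):
        return [
            ("means", self.means, self.grad_means),
            ("neg_log_var", self.neg_log_var, self.grad_neg_log_var),
            ("coeffs", self.coeffs, self.grad_coeffs),
        ]

    def zero_grad(self) -> None:
        # buffers are zeroed in place so optimizer references stay valid
        if not hasattr(self, "grad_means"):
            self.grad_means = np.zeros_like(self.means)
            self.grad_neg_log_var = np.zeros_like(self.neg_log_var)
            self.grad_coeffs = np.zeros_like(self.coeffs)
        else:
            self.grad_means[:] = 0.0
            self.grad_neg_log_var[:] = 0.0
            self.grad_coeffs[:] = 0.0

    def weights(self) -> np.ndarray:
        return mixture_weights(self.coeffs)

    # ---- densities ----------------------------------------------------------

    def _check_z(self, z: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z, dtype=float))
        if z.shape[1] != self.dim:
            raise ValueError(
                f"dimension mismatch: expected latent dim {self.dim}, got {z.shape[1]}"
            )
        return z

    def _component_log_densities(self, z: np.ndarray) -> np.ndarray:
        """(n, K) matrix of log w_k + log N(z_i; mu_k, diag exp(-beta_k))."""
        beta = self.neg_log_var  # (K, m); variance = exp(-beta)
        diff = z[:, None, :] - self.means[None, :, :]  # (n, K, m)
        quad = np.sum(diff * diff * np.exp(beta)[None, :, :], axis=2)
        log_det = np.sum(beta, axis=1)  # sum log(1/var) = -sum log var
        log_n = -0.5 * (self.dim * math.log(2 * math.pi) - log_det + quad)
        return _log_softmax(self.coeffs)[None, :] + log_n

    def log_density(self, z: np.ndarray) -> np.ndarray:
        """Per-sample mixture log-density log sum_k w_k N(z_i; mu_k, Sigma_k)."""
        z = self._check_z(z)
        return logsumexp(self._component_log_densities(z), axis=1)

    def log_responsibilities(self, z: np.ndarray) -> np.ndarray:
        """Per-sample log posterior over components (rows exponentiate to 1)."""
        z = self._check_z(z)
        a = self._component_log_densities(z)
        return a - logsumexp(a, axis=1, keepdims=True)

    def hard_assign(self, z: np.ndarray) -> np.ndarray:
        """Cluster each point to its most responsible component (ties -> lowest index)."""
        return np.argmax(self.log_responsibilities(z), axis=1)

    def log_density_backward(
        self, z: np.ndarray, grad_out: np.ndarray
    ) -> np.ndarray:
        """Backpropagate ``sum_i grad_out[i] * log_density(z)[i]``.

        Accumulates into the mixture's gradient buffers and returns the
        gradient with respect to ``z`` (same shape as ``z``).
        """
        z = self._check_z(z)
        grad_out = np.asarray(grad_out, dtype=float)
        a = self._component_log_densities(z)
        resp = np.exp(a - logsumexp(a, axis=1, keepdims=True))  # (n, K)
        w = self.weights()
        prec = np.exp(self.neg_log_var)  # (K, m), 1/variance
        diff = z[:, None, :] - self.means[None, :, :]  # (n, K, m)
        g_resp = grad_out[:, None] * resp  # (n, K)

        self.grad_means += np.einsum("nk,nkm,km->km", g_resp, diff, prec)
        self.grad_neg_log_var += 0.5 * np.einsum(
            "nk,nkm->km", g_resp, 1.0 - diff * diff * prec[None, :, :]
        )
        self.grad_coeffs += g_resp.sum(axis=0) - grad_out.sum() * w
        dz = -np.einsum("nk,nkm,km->nm", g_resp, diff, prec)
        return dz

    # ---- supervised variant -------------------------------------------------

    def _check_labels(self, labels: np.ndarray, n: int) -> np.ndarray:
        labels = np.asarray(labels)
        if labels.shape != (n,):
            raise ValueError(f"labels must have shape ({n},), got {labels.shape}")
        if labels.min() < 0 or labels.max() >= self.n_components:
            raise ValueError(
                f"label out of range: labels must lie in [0, {self.n_components})"
            )
        return labels.astype(int)

    def supervised_log_density(
        self, z: np.ndarray, labels: np.ndarray
    ) -> np.ndarray:
        """Per-sample log w_k + log N(z_i; mu_k, Sigma_k) for the assigned k only."""
        z = self._check_z(z)
        labels = self._check_labels(labels, z.shape[0])
        a = self._component_log_densities(z)
        return a[np.arange(z.shape[0]), labels]

    def supervised_log_density_backward(
        self, z: np.ndarray, labels: np.ndarray, grad_out: np.ndarray
    ) -> np.ndarray:
        """Backward pass for the supervised (single-component) latent loss.

        Means and negative log-variances of non-assigned components receive
        exactly zero gradient; the mixture coefficients remain coupled through
        the softmax normalization.
        """
        z = self._check_z(z)
        labels = self._check_labels(labels, z.shape[0])
        grad_out = np.asarray(grad_out, dtype=float)
        w = self.weights()
        prec = np.exp(self.neg_log_var)
        diff = z - self.means[labels]  # (n, m)
        prec_l = prec[labels]  # (n, m)
        g = grad_out[:, None]

        np.add.at(self.grad_means, labels, g * diff * prec_l)
        np.add.at(
            self.grad_neg_log_var,
            labels,
            0.5 * g * (1.0 - diff * diff * prec_l),
        )
        onehot_sum = np.zeros(self.n_components)
        np.add.at(onehot_sum, labels, grad_out)
        self.grad_coeffs += onehot_sum - grad_out.sum() * w
        return -g * diff * prec_l

    # ---- parameter prior ----------------------------------------------------

    def param_log_prior(self) -> float:
        """Log prior over mixture parameters.

        Softball on means (full log-density), Dirichlet(alpha) on weights and
        N(-2 log sigma0, 1) on negative log-variances with their
        parameter-independent normalization constants dropped (consistently,
        so losses are comparable across runs with the same K).
        """
        mean_term = float(np.sum(self.mean_prior.log_prob(self.means)))
        w = self.weights()
        dir_term = (self.dirichlet_alpha - 1.0) * float(np.sum(np.log(w)))
        dev = self.neg_log_var - self.logvar_prior_mean
        var_term = -0.5 * float(np.sum(dev * dev))
        return mean_term + dir_term + var_term

    def param_log_prior_backward(self, grad_out: float = 1.0) -> None:
        """Accumulate gradients of ``grad_out * param_log_prior()``."""
        self.grad_means += grad_out * self.mean_prior.grad_log_prob(self.means)
        w = self.weights()
        self.grad_coeffs += (
            grad_out
            * (self.dirichlet_alpha - 1.0)
            * (1.0 - self.n_components * w)
        )
        self.grad_neg_log_var += -grad_out * (
            self.neg_log_var - self.logvar_prior_mean
        )

    # ---- sampling -----------------------------------------------------------

    def sample(
        self,
        n: int,
        component: Optional[int] = None,
        rng: Optional[np.random.Generator] = None,
    ) -> np.ndarray:
        """Draw latent points, ancestrally or from one named component."""
        rng = rng or np.random.default_rng()
        if component is None:
            idx = rng.choice(self.n_components, size=n, p=self.weights())
        else:
            if not 0 <= component < self.n_components:
                raise ValueError(
                    f"component index {component} out of range [0, {self.n_components})"
                )
            idx = np.full(n, component, dtype=int)
        sd = np.exp(-0.5 * self.neg_log_var)  # (K, m)
        return self.means[idx] + rng.standard_normal((n, self.dim)) * sd[idx]
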