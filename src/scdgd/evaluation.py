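"""Performance metrics: clustering agreement, held-out NB likelihood, RMSE."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .decoder import CountDataset, DecoderModel, normalize_counts
from .training import RepresentationSet


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two partitions, in [-1, 1].

    Zero in expectation for random partitions, one for identical ones;
    invariant to relabeling of cluster IDs.
    """
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError(
            f"length mismatch: {labels_a.shape} vs {labels_b.shape}"
        )
    if labels_a.ndim != 1 or labels_a.shape[0] < 2:
        raise ValueError("need two 1-D label vectors with n >= 2")
    return float(adjusted_rand_score(labels_a, labels_b))


@dataclass
class NLLResult:
    per_cell: np.ndarray
    mean: float
    sem: float


def test_negative_log_likelihood(
    data: CountDataset, reps: RepresentationSet, decoder: DecoderModel
) -> NLLResult:
    """Per-cell NB negative log-likelihood, with mean +/- standard error.

    The NLL of a cell is minus the NB log pmf summed over all genes at the
    decoded means.  With a single cell the standard error is undefined and
    reported as 0 with a warning.
    """
    x = data.dense_rows(np.arange(data.n_cells))
    ll = decoder.reconstruction_log_prob(x, reps.values, data.scale_factors)
    per_cell = -ll
    mean = float(per_cell.mean())
    if per_cell.size < 2:
        warnings.warn("standard error undefined for a single cell; reporting 0")
        sem = 0.0
    else:
        sem = float(per_cell.std(ddof=1) / np.sqrt(per_cell.size))
    return NLLResult(per_cell=per_cell, mean=mean, sem=sem)


def rmse(
    data: CountDataset, reps: RepresentationSet, decoder: DecoderModel
) -> float:
    """Root mean squared error between normalized counts and decoder output.

    Computed on the row-max-normalized scale (the decoder's output scale),
    averaged over all cells x genes.
    """
    x = data.dense_rows(np.arange(data.n_cells))
    fractions, _ = normalize_counts(x)
    y = decoder.decode(reps.values)
    return float(np.sqrt(np.mean((fractions - y) ** 2)))
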