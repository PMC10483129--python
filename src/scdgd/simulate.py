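"""Ground-truth generator: known mixture -> fixed random decoder -> NB counts.

Emulates desk-scale droplet scRNA-seq data (a few hundred cells, tens of
genes, mostly-zero counts) from a fully known model, so that training,
inference and evaluation can be scored against ground truth without any
external download.  Sparsity comes from low sequencing depths and strongly
negative output biases (sub-0.5 sigmoid outputs), staying inside the NB
observation model rather than adding zero inflation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .decoder import CountDataset, DecoderModel
from .priors import GaussianMixture, SoftballPrior


@dataclass
class GroundTruth:
    """A fully known generative model used as simulation ground truth."""

    gmm: GaussianMixture
    decoder: DecoderModel
    separation: float  # min pairwise mean distance / max component sd, as built
    depth_range: Tuple[float, float]
    seed: int


def make_ground_truth(
    n_components: int = 3,
    latent_dim: int = 2,
    n_genes: int = 50,
    separation: float = 6.0,
    seed: int = 0,
    component_sd: float = 0.1,
    depth_range: Tuple[float, float] = (50.0, 500.0),
    output_gain: float = 12.0,
    baseline_range: Tuple[float, float] = (2e-4, 2e-2),
) -> GroundTruth:
    """Build a well-separated mixture and a fixed random decoder.

    Component means are drawn from the softball prior and rescaled so every
    pairwise distance is at least ``separation`` times the component
    standard deviation.  Decoder weights are seeded normals with the output
    layer scaled by ``output_gain`` so cell populations differ severalfold
    on many genes, as marker genes do between real cell types.  Per-gene
    baseline expression (the sigmoid output at the centre of the latent
    clusters) is calibrated to a log-uniform draw over ``baseline_range``,
    so every gene is expressed yet counts stay mostly zero at the low
    sequencing depths of the depth law.  Log-dispersions are uniform on
    [log 0.5, log 5].
    """
    rng = np.random.default_rng(seed)
    softball = SoftballPrior(latent_dim, scale=1.0, sharpness=1.0)
    gmm = GaussianMixture(
        n_components, latent_dim, mean_prior=softball, sigma0=component_sd, rng=rng
    )
    gmm.neg_log_var[:] = -2.0 * math.log(component_sd)

    if n_components > 1:
        dists = [
            np.linalg.norm(gmm.means[i] - gmm.means[j])
            for i in range(n_components)
            for j in range(i + 1, n_components)
        ]
        d_min = min(dists)
        if d_min <= 0:
            raise ValueError(
                "sampled component means coincide; separation cannot be enforced"
            )
        required = separation * component_sd
        if d_min < required:
            gmm.means *= required / d_min

    decoder = DecoderModel(
        latent_dim=latent_dim, n_genes=n_genes, hidden_dims=(100, 100, 100), rng=rng
    )
    decoder.weights[-1] *= output_gain
    # calibrate per-gene output biases so that at the centroid of the
    # component means each gene's expressed fraction hits a log-uniform
    # baseline draw; the output gain then adds between-component contrast
    lo_f, hi_f = baseline_range
    baseline = np.exp(rng.uniform(math.log(lo_f), math.log(hi_f), size=n_genes))
    centre = gmm.means.mean(axis=0, keepdims=True)
    h = centre
    for w, b in zip(decoder.weights[:-1], decoder.biases[:-1]):
        h = np.maximum(h @ w + b, 0.0)
    signal_at_centre = (h @ decoder.weights[-1]).ravel()
    decoder.biases[-1][:] = np.log(baseline / (1.0 - baseline)) - signal_at_centre
    decoder.log_dispersion[:] = rng.uniform(math.log(0.5), math.log(5.0), size=n_genes)
    return GroundTruth(
        gmm=gmm,
        decoder=decoder,
        separation=separation,
        depth_range=depth_range,
        seed=seed,
    )


def generate_dataset(
    gt: GroundTruth,
    n_cells: int,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[CountDataset, np.ndarray, np.ndarray, dict]:
    """Ancestral sampling of a count dataset from the ground truth.

    component ~ mixture weights; z ~ component Gaussian; depth ~ log-uniform
    over the configured range; counts ~ NB(decode(z) * depth, dispersion).
    Cells that come out all-zero are resampled (count reported).  Returns
    (dataset, true component labels, true representations, report).
    """
    rng = rng or np.random.default_rng(gt.seed)
    lo, hi = gt.depth_range
    counts = np.empty((n_cells, gt.decoder.n_genes), dtype=np.int64)
    labels = np.empty(n_cells, dtype=int)
    true_z = np.empty((n_cells, gt.gmm.dim))
    n_resampled = 0
    for i in range(n_cells):
        while True:
            k = int(rng.choice(gt.gmm.n_components, p=gt.gmm.weights()))
            sd = np.exp(-0.5 * gt.gmm.neg_log_var[k])
            z = gt.gmm.means[k] + rng.standard_normal(gt.gmm.dim) * sd
            depth = math.exp(rng.uniform(math.log(lo), math.log(hi)))
            row = gt.decoder.sample_counts(z[None, :], np.array([depth]), rng)[0]
            if row.sum() > 0:
                break
            n_resampled += 1
        counts[i] = row
        labels[i] = k
        true_z[i] = z
    dataset = CountDataset.from_counts(counts, labels=labels)
    dataset.labels = labels
    report = {
        "n_resampled": n_resampled,
        "zero_fraction": float((counts == 0).mean()),
    }
    return dataset, labels, true_z, report


def default_fixture(
    n_cells: int = 600, seed: int = 0
) -> Tuple[GroundTruth, CountDataset, np.ndarray, np.ndarray, dict]:
    """The standard regression fixture: K=3, m=2, G=50, n=600, seed 0."""
    gt = make_ground_truth(
        n_components=3, latent_dim=2, n_genes=50, separation=6.0, seed=seed
    )
    data, labels, true_z, report = generate_dataset(
        gt, n_cells, rng=np.random.default_rng(seed + 1)
    )
    return gt, data, labels, true_z, report
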