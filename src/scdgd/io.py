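"""Readers and writers: 10x-style MTX, dense text, labels, checkpoints, configs.

Counts are kept sparse from file to minibatch (droplet data is overwhelmingly
zero); densification happens only at batch assembly inside training.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import scipy.io as sio
import scipy.sparse as sp
import yaml

from .decoder import CountDataset, DecoderModel
from .priors import GaussianMixture, SoftballPrior
from .training import RepresentationSet, TrainConfig

logger = logging.getLogger("scdgd")


def _resolve_mtx_paths(path: Path) -> Tuple[Path, Path, Path]:
    if path.is_dir():
        matrix = path / "matrix.mtx"
        barcodes = path / "barcodes.tsv"
        features = path / "features.tsv"
        if not features.exists() and (path / "genes.tsv").exists():
            features = path / "genes.tsv"
    else:
        matrix = path
        barcodes = path.parent / "barcodes.tsv"
        features = path.parent / "features.tsv"
        if not features.exists() and (path.parent / "genes.tsv").exists():
            features = path.parent / "genes.tsv"
    missing = [str(p) for p in (matrix, barcodes, features) if not p.exists()]
    if missing:
        raise FileNotFoundError(f"missing MTX companion files: {missing}")
    return matrix, barcodes, features


def _read_tsv_column(path: Path) -> List[str]:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_counts(
    path, format: str = "mtx", drop_unexpressed_genes: bool = False
) -> CountDataset:
    """Load a cells x genes integer count matrix.

    ``mtx``: MatrixMarket file with barcodes/features TSV companions (10x
    layout); genes x cells orientation is detected from the companion-file
    lengths and transposed.  ``dense``: delimited text with a header row of
    gene IDs and a leading barcode column.  Cells whose counts are all zero
    are dropped (logged); per-cell scale factors are computed on load.
    """
    path = Path(path)
    if format == "mtx":
        matrix_path, barcodes_path, features_path = _resolve_mtx_paths(path)
        mat = sio.mmread(matrix_path)
        barcodes = _read_tsv_column(barcodes_path)
        genes = _read_tsv_column(features_path)
        if mat.shape == (len(genes), len(barcodes)) and mat.shape != (
            len(barcodes),
            len(genes),
        ):
            mat = mat.T  # 10x convention stores genes x cells
        elif mat.shape != (len(barcodes), len(genes)):
            raise ValueError(
                f"matrix shape {mat.shape} matches neither cells x genes "
                f"({len(barcodes)}, {len(genes)}) nor its transpose"
            )
        mat = sp.csr_matrix(mat)
        if not np.allclose(mat.data, np.round(mat.data)):
            raise ValueError("count matrix contains non-integer entries")
        mat = mat.astype(np.int64)
    elif format == "dense":
        import pandas as pd

        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
        values = df.to_numpy()
        if not np.allclose(values, np.round(values)):
            raise ValueError("count matrix contains non-integer entries")
        mat = sp.csr_matrix(values.astype(np.int64))
        barcodes = [str(b) for b in df.index]
        genes = [str(g) for g in df.columns]
    else:
        raise ValueError(f"unknown format {format!r}; valid formats: 'mtx', 'dense'")

    row_sums = np.asarray(mat.sum(axis=1)).ravel()
    keep = row_sums > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d all-zero cells", n_dropped)
        mat = mat[keep]
        barcodes = [b for b, k in zip(barcodes, keep) if k]
    if drop_unexpressed_genes:
        col_sums = np.asarray(mat.sum(axis=0)).ravel()
        keep_g = col_sums > 0
        logger.info("dropping %d unexpressed genes", int((~keep_g).sum()))
        mat = mat[:, keep_g]
        genes = [g for g, k in zip(genes, keep_g) if k]

    s = np.asarray(mat.max(axis=1).todense()).ravel().astype(float)
    return CountDataset(
        counts=mat, scale_factors=s, barcodes=barcodes, gene_names=genes
    )


def write_counts(outdir, data: CountDataset) -> None:
    """Write a dataset as matrix.mtx (genes x cells) + barcodes/features TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = data.counts
    if not sp.issparse(mat):
        mat = sp.csr_matrix(mat)
    sio.mmwrite(outdir / "matrix.mtx", mat.T.astype(np.int64), field="integer")
    barcodes = data.barcodes or [f"cell{i}" for i in range(data.n_cells)]
    genes = data.gene_names or [f"gene{j}" for j in range(data.n_genes)]
    (outdir / "barcodes.tsv").write_text("\n".join(barcodes) + "\n")
    (outdir / "features.tsv").write_text("\n".join(genes) + "\n")


def read_labels(path, barcodes: List[str]) -> np.ndarray:
    """Load barcode -> label TSV, aligned to the count matrix's barcode order."""
    mapping: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ValueError(f"label file lines need two columns, got {line!r}")
            if parts[0] in mapping:
                raise ValueError(f"duplicate barcode in label file: {parts[0]}")
            mapping[parts[0]] = parts[1]
    missing = [b for b in barcodes if b not in mapping]
    if missing:
        raise ValueError(
            f"{len(missing)} barcodes have no label; first missing: {missing[:10]}"
        )
    return np.array([mapping[b] for b in barcodes])


def encode_labels(labels) -> Tuple[np.ndarray, List[str]]:
    """Map string labels to 0..K-1 component indices (sorted unique order)."""
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    index = {c: i for i, c in enumerate(classes)}
    return np.array([index[l] for l in labels], dtype=int), [str(c) for c in classes]


# ---- checkpointing -----------------------------------------------------------


def save_checkpoint(
    path,
    decoder: DecoderModel,
    gmm: GaussianMixture,
    reps: Optional[RepresentationSet] = None,
    config: Optional[TrainConfig] = None,
) -> None:
    """Serialize the full model into one .npz archive."""
    arrays = {
        "log_dispersion": decoder.log_dispersion,
        "gmm_means": gmm.means,
        "gmm_neg_log_var": gmm.neg_log_var,
        "gmm_coeffs": gmm.coeffs,
    }
    for i, w in enumerate(decoder.weights):
        arrays[f"W{i}"] = w
    for i, b in enumerate(decoder.biases):
        arrays[f"b{i}"] = b
    if reps is not None:
        arrays["representations"] = reps.values
        arrays["sample_ids"] = np.asarray(reps.sample_ids)
    meta = {
        "latent_dim": decoder.latent_dim,
        "n_genes": decoder.n_genes,
        "hidden_dims": decoder.hidden_dims,
        "n_components": gmm.n_components,
        "dirichlet_alpha": gmm.dirichlet_alpha,
        "sigma0": gmm.sigma0,
        "softball_scale": gmm.mean_prior.scale,
        "softball_sharpness": gmm.mean_prior.sharpness,
        "config": None if config is None else asdict(config),
    }
    arrays["meta_json"] = np.array(json.dumps(meta))
    np.savez(path, **arrays)


def load_checkpoint(path):
    """Rebuild (decoder, gmm, reps_or_None, config_or_None) from an archive."""
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["meta_json"]))
        decoder = DecoderModel(
            latent_dim=meta["latent_dim"],
            n_genes=meta["n_genes"],
            hidden_dims=meta["hidden_dims"],
            rng=np.random.default_rng(0),
        )
        for i in range(len(decoder.weights)):
            decoder.weights[i][:] = npz[f"W{i}"]
            decoder.biases[i][:] = npz[f"b{i}"]
        decoder.log_dispersion[:] = npz["log_dispersion"]
        softball = SoftballPrior(
            meta["latent_dim"], meta["softball_scale"], meta["softball_sharpness"]
        )
        gmm = GaussianMixture(
            meta["n_components"],
            meta["latent_dim"],
            mean_prior=softball,
            dirichlet_alpha=meta["dirichlet_alpha"],
            sigma0=meta["sigma0"],
            rng=np.random.default_rng(0),
        )
        gmm.means[:] = npz["gmm_means"]
        gmm.neg_log_var[:] = npz["gmm_neg_log_var"]
        gmm.coeffs[:] = npz["gmm_coeffs"]
        reps = None
        if "representations" in npz:
            reps = RepresentationSet(
                values=npz["representations"], sample_ids=npz["sample_ids"]
            )
        config = None
        if meta["config"] is not None:
            cfg = dict(meta["config"])
            cfg["adam_betas"] = tuple(cfg["adam_betas"])
            cfg["hidden_dims"] = tuple(cfg["hidden_dims"])
            config = TrainConfig(**cfg)
    return decoder, gmm, reps, config


# ---- run configuration -------------------------------------------------------


@dataclass
class RunConfig:
    """TrainConfig plus file paths, serializable to a YAML key-value file."""

    train: TrainConfig
    counts_path: Optional[str] = None
    labels_path: Optional[str] = None
    counts_format: str = "mtx"
    outdir: str = "scdgd_out"

    def to_yaml(self, path) -> None:
        payload = {
            "train": asdict(self.train),
            "counts_path": self.counts_path,
            "labels_path": self.labels_path,
            "counts_format": self.counts_format,
            "outdir": self.outdir,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        tc = dict(payload.pop("train"))
        tc["adam_betas"] = tuple(tc["adam_betas"])
        tc["hidden_dims"] = tuple(tc["hidden_dims"])
        return cls(train=TrainConfig(**tc), **payload)


def write_outputs(
    outdir,
    decoder: DecoderModel,
    gmm: GaussianMixture,
    reps: RepresentationSet,
    barcodes: Optional[List[str]] = None,
    history: Optional[Dict] = None,
    metrics: Optional[Dict] = None,
    config: Optional[TrainConfig] = None,
) -> Dict[str, str]:
    """Write representations, assignments/responsibilities, metrics, checkpoint."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n = reps.n
    barcodes = barcodes or [f"cell{i}" for i in range(n)]
    paths = {}

    rep_path = outdir / "representations.tsv"
    with open(rep_path, "w") as fh:
        fh.write("barcode\t" + "\t".join(f"z{d}" for d in range(reps.dim)) + "\n")
        for b, row in zip(barcodes, reps.values):
            fh.write(b + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
    paths["representations"] = str(rep_path)

    resp = np.exp(gmm.log_responsibilities(reps.values))
    assign = gmm.hard_assign(reps.values)
    asg_path = outdir / "assignments.tsv"
    with open(asg_path, "w") as fh:
        fh.write(
            "barcode\tcomponent\t"
            + "\t".join(f"resp{k}" for k in range(gmm.n_components))
            + "\n"
        )
        for b, a, row in zip(barcodes, assign, resp):
            fh.write(
                f"{b}\t{a}\t" + "\t".join(f"{v:.12g}" for v in row) + "\n"
            )
    paths["assignments"] = str(asg_path)

    if history is not None:
        hist_path = outdir / "history.tsv"
        keys = [k for k in ("epoch", "total", "reconstruction", "latent",
                            "param_prior", "lr_decoder") if k in history]
        with open(hist_path, "w") as fh:
            fh.write("\t".join(keys) + "\n")
            for i in range(len(history["epoch"])):
                fh.write("\t".join(f"{history[k][i]:.10g}" for k in keys) + "\n")
        paths["history"] = str(hist_path)

    if metrics is not None:
        met_path = outdir / "metrics.json"
        met_path.write_text(json.dumps(metrics, indent=2) + "\n")
        paths["metrics"] = str(met_path)

    ckpt_path = outdir / "checkpoint.npz"
    save_checkpoint(ckpt_path, decoder, gmm, reps, config)
    paths["checkpoint"] = str(ckpt_path)
    return paths
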