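"""Readers and writers for the pipeline's plain-text artifacts.

Expression matrices are TSV with genes as rows (first column ``gene_id``),
clinical tables are TSV with columns sample_id / rfs_months / rfs_event /
subtype, latent matrices are TSV with samples as rows, models are JSON (+
per-layer TSV weights for the autoencoder), and gene sets are standard GMT.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from gseapy.parser import read_gmt as _gseapy_read_gmt

from .autoencoder import DeepAutoencoder, LatentMatrix
from .preprocess import NormalizationModel
from .stratify import LatentStratifier
from .types import ExpressionMatrix, SurvivalTable

__all__ = [
    "read_expression", "write_expression",
    "read_clinical", "write_clinical",
    "read_latent", "write_latent",
    "read_normalization", "write_normalization",
    "read_autoencoder", "write_autoencoder",
    "read_stratification", "write_stratification",
    "read_gmt",
]


def read_expression(path, scale_tag: str = "zscore") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return ExpressionMatrix(df, scale_tag=scale_tag)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.data.to_csv(path, sep="\t", index_label="gene_id")


def read_clinical(path) -> SurvivalTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return SurvivalTable(
        df["sample_id"].tolist(),
        df["rfs_months"].to_numpy(float),
        df["rfs_event"].to_numpy(int),
    )


def write_clinical(tbl: SurvivalTable, path, subtype: str = "LumA") -> None:
    df = tbl.to_frame()
    df["subtype"] = subtype
    df.to_csv(path, sep="\t", index=False)


def read_latent(path) -> LatentMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return LatentMatrix(list(df.index.astype(str)), df.to_numpy(float))


def write_latent(latent: LatentMatrix, path) -> None:
    latent.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def read_normalization(path) -> NormalizationModel:
    return NormalizationModel.from_frame(pd.read_csv(path, sep="\t", dtype={"gene_id": str}))


def write_normalization(model: NormalizationModel, path) -> None:
    model.to_frame().to_csv(path, sep="\t", index=False)


def write_autoencoder(model: DeepAutoencoder, out_dir) -> None:
    """JSON metadata plus one TSV per layer's weights and biases."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "layer_sizes": list(model.layer_sizes_),
        "hidden_dim": model.hidden_dim,
        "epochs": model.epochs,
        "batch_size": model.batch_size,
        "learning_rate": model.learning_rate,
        "random_state": model.random_state,
        "trained": bool(model.trained_),
        "gene_ids": model.gene_ids_,
        "loss_curve": [float(v) for v in model.loss_curve_],
    }
    (out / "model.json").write_text(json.dumps(meta, indent=1))
    for k, (w, b) in enumerate(zip(model.weights_, model.biases_), start=2):
        np.savetxt(out / f"W{k}.tsv", w, delimiter="\t")
        np.savetxt(out / f"b{k}.tsv", b, delimiter="\t")


def read_autoencoder(model_dir) -> DeepAutoencoder:
    out = Path(model_dir)
    meta = json.loads((out / "model.json").read_text())
    model = DeepAutoencoder(
        hidden_dim=meta["hidden_dim"],
        epochs=meta["epochs"],
        batch_size=meta["batch_size"],
        learning_rate=meta["learning_rate"],
        random_state=meta["random_state"],
    )
    model.initialize(meta["layer_sizes"][0])
    model.weights_ = [
        np.loadtxt(out / f"W{k}.tsv", delimiter="\t", ndmin=2) for k in range(2, 6)
    ]
    model.biases_ = [
        np.loadtxt(out / f"b{k}.tsv", delimiter="\t", ndmin=1) for k in range(2, 6)
    ]
    model.trained_ = meta["trained"]
    model.gene_ids_ = meta["gene_ids"]
    model.loss_curve_ = list(meta["loss_curve"])
    return model


def write_stratification(model: LatentStratifier, path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=1))


def read_stratification(path) -> LatentStratifier:
    return LatentStratifier.from_dict(json.loads(Path(path).read_text()))


def read_gmt(path) -> dict:
    """Gene sets as {term: [genes]} from a standard GMT file."""
    return _gseapy_read_gmt(str(path))
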