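"""End-to-end discovery and validation pipelines.

Discovery: MAD gene filter -> min-max renormalization anchored to the
training cohort -> autoencoder sweep over hidden widths -> K-means on the
latent features with survival-driven (dim, k) selection -> BPS/WPS naming
-> baseline comparison arms. Validation: renormalize the external cohort
with the TRAINING min/max, encode with the trained autoencoder of the
selected width, assign samples to the nearest subgroup centroid, and
compare survival between assigned subgroups.

Every stage writes plain-text artifacts (TSV/JSON) plus a manifest with
the configuration hash and seeds, so a run is regenerable from the
manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio
from .autoencoder import LatentMatrix, encode, sweep_hidden_dims
from .baselines import run_baselines
from .preprocess import apply_minmax, fit_minmax, select_top_variable_genes
from .stratify import LatentStratifier, StratificationResult, select_stratification
from .survival import kaplan_meier, logrank_test
from .types import ExpressionMatrix, SurvivalTable

__all__ = ["RunConfig", "DiscoveryResult", "ValidationResult",
           "run_discovery", "run_validation"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline thresholds; defaults follow the reference protocol."""

    top_k: int = 5000
    dims_sweep: tuple = (16, 32, 64, 128, 256, 512, 1024, 2048)
    dims_survival: tuple = (16, 32, 64, 128)
    k_range: tuple = (2, 3, 4, 5)
    epochs: int = 100
    batch_size: int = 16
    learning_rate: float = 1e-3
    alpha_pairwise: float = 0.05
    deg_threshold: float = 0.01
    enrichment_threshold: float = 1e-4
    edge_fraction: float = 0.10
    seed: int = 0

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class DiscoveryResult:
    config: RunConfig
    gene_ids: list
    norm_model: object
    sweep: pd.DataFrame
    models: dict                      # dim -> DeepAutoencoder
    latents: dict                     # dim -> LatentMatrix
    selection: StratificationResult
    cluster_labels: np.ndarray | None
    prognosis_labels: list | None
    baselines: pd.DataFrame | None
    km_curves: dict = field(default_factory=dict)
    logrank_p: float | None = None

    @property
    def stratifier(self) -> LatentStratifier | None:
        return self.selection.model


@dataclass
class ValidationResult:
    cluster_labels: np.ndarray
    prognosis_labels: list
    sample_ids: list
    logrank_p: float | None
    km_curves: dict = field(default_factory=dict)


def run_discovery(
    train_expr: ExpressionMatrix,
    train_surv: SurvivalTable,
    config: RunConfig | None = None,
    val_expr: ExpressionMatrix | None = None,
    out_dir=None,
) -> DiscoveryResult:
    """Execute the discovery pipeline on a training cohort.

    ``val_expr`` (z-score scale, same genes) supplies the sweep's
    validation MSE; without it, a deterministic 80/20 split of the training
    samples stands in. Artifacts are written under ``out_dir`` when given.
    """
    config = config or RunConfig()
    if train_surv.sample_ids != train_expr.sample_ids:
        raise KeyError("clinical table samples do not match the expression matrix")
    t0 = time.perf_counter()

    # --- preprocess
    top_k = min(config.top_k, train_expr.n_genes)
    genes = select_top_variable_genes(train_expr, top_k)
    train_top = ExpressionMatrix(train_expr.data.loc[genes], scale_tag="zscore")
    norm = fit_minmax(train_top)
    train_mm = apply_minmax(train_top, norm)

    if val_expr is not None:
        val_mm = apply_minmax(val_expr, norm)
    else:
        n = train_mm.n_samples
        rng = np.random.default_rng(config.seed)
        order = rng.permutation(n)
        cut = int(0.8 * n)
        cols = [train_mm.sample_ids[i] for i in order[cut:]]
        val_mm = ExpressionMatrix(train_mm.data[cols], scale_tag="minmax")

    # --- autoencoder sweep
    logger.info("sweeping hidden widths %s", list(config.dims_sweep))
    sweep = sweep_hidden_dims(
        train_mm, val_mm, list(config.dims_sweep), seed=config.seed,
        epochs=config.epochs, batch_size=config.batch_size,
        learning_rate=config.learning_rate,
    )
    models = sweep.attrs["models"]

    # --- latent features for the admitted widths
    admitted = [d for d in config.dims_survival if d in models]
    latents = {d: encode(models[d], train_mm) for d in admitted}

    # --- survival-driven (dim, k) selection
    selection = select_stratification(
        latents, train_surv, k_range=config.k_range,
        alpha_pairwise=config.alpha_pairwise, seed=config.seed,
    )

    cluster_labels = prognosis = baselines = None
    km_curves, logrank_p = {}, None
    if selection.stratified:
        strat = selection.model
        cluster_labels = strat.labels_
        prognosis = strat.prognosis_labels(cluster_labels)
        logrank_p = strat.selection_record_["multivariate_p"]
        for c in range(strat.k):
            name = strat.prognosis_map_[c]
            km_curves[name] = kaplan_meier(train_surv.subset(cluster_labels == c))
        baselines = run_baselines(
            train_expr, train_top, latents[strat.hidden_dim], train_surv,
            k=strat.k, seed=config.seed,
        )
    else:
        logger.info("no admissible stratification found")

    result = DiscoveryResult(
        config=config, gene_ids=genes, norm_model=norm, sweep=sweep,
        models=models, latents=latents, selection=selection,
        cluster_labels=cluster_labels, prognosis_labels=prognosis,
        baselines=baselines, km_curves=km_curves, logrank_p=logrank_p,
    )
    logger.info("discovery finished in %.1f s", time.perf_counter() - t0)
    if out_dir is not None:
        _write_discovery(result, train_surv, Path(out_dir))
    return result


def run_validation(
    discovery: DiscoveryResult,
    val_expr: ExpressionMatrix,
    val_surv: SurvivalTable | None = None,
    out_dir=None,
) -> ValidationResult:
    """Assign an external cohort to the discovered subgroups.

    The external matrix is renormalized with the TRAINING min/max model and
    encoded with the trained autoencoder of the selected width; samples go
    to the nearest subgroup centroid. A missing training gene raises a
    KeyError naming it.
    """
    if not discovery.selection.stratified:
        raise ValueError("discovery produced no stratification to validate against")
    strat = discovery.stratifier
    val_mm = apply_minmax(val_expr, discovery.norm_model)
    latent = encode(discovery.models[strat.hidden_dim], val_mm)
    labels = strat.predict(latent) if len(latent.sample_ids) else np.empty(0, dtype=int)
    prognosis = strat.prognosis_labels(labels)

    km_curves, logrank_p = {}, None
    if val_surv is not None and len(val_surv):
        if val_surv.sample_ids != val_expr.sample_ids:
            raise KeyError("validation clinical samples do not match expression")
        groups = [val_surv.subset(labels == c) for c in range(strat.k)]
        if all(len(g) > 0 for g in groups):
            logrank_p = logrank_test(groups).p
            for c in range(strat.k):
                km_curves[strat.prognosis_map_[c]] = kaplan_meier(groups[c])
    result = ValidationResult(
        cluster_labels=labels, prognosis_labels=prognosis,
        sample_ids=list(val_expr.sample_ids), logrank_p=logrank_p,
        km_curves=km_curves,
    )
    if out_dir is not None:
        _write_validation(result, Path(out_dir))
    return result


# --- artifact writing -----------------------------------------------------


def _write_manifest(out: Path, config: RunConfig, extra: dict) -> None:
    from . import __version__

    manifest = {
        "config": asdict(config),
        "config_hash": config.digest(),
        "package_version": __version__,
        **extra,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))


def _write_discovery(res: DiscoveryResult, surv: SurvivalTable, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    lio.write_normalization(res.norm_model, out / "normalization.tsv")
    res.sweep.drop(columns=[], errors="ignore").to_csv(
        out / "sweep.tsv", sep="\t", index=False
    )
    res.selection.candidates.to_csv(out / "candidates.tsv", sep="\t", index=False)
    for dim, latent in res.latents.items():
        lio.write_latent(latent, out / f"latent_dim{dim}.tsv")
    stratified = res.selection.stratified
    if stratified:
        strat = res.stratifier
        lio.write_autoencoder(res.models[strat.hidden_dim], out / "autoencoder")
        lio.write_stratification(strat, out / "stratification.json")
        pd.DataFrame(
            {
                "sample_id": surv.sample_ids,
                "cluster": res.cluster_labels,
                "prognosis_label": res.prognosis_labels,
            }
        ).to_csv(out / "labels.tsv", sep="\t", index=False)
        res.baselines.to_csv(out / "baselines.tsv", sep="\t", index=False)
        for name, curve in res.km_curves.items():
            curve.to_frame().to_csv(out / f"km_{name}.tsv", sep="\t", index=False)
    _write_manifest(
        out, res.config,
        {"stage": "discovery", "stratified": stratified,
         "multivariate_logrank_p": res.logrank_p},
    )


def _write_validation(res: ValidationResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "sample_id": res.sample_ids,
            "cluster": res.cluster_labels,
            "prognosis_label": res.prognosis_labels,
        }
    ).to_csv(out / "labels.tsv", sep="\t", index=False)
    for name, curve in res.km_curves.items():
        curve.to_frame().to_csv(out / f"km_{name}.tsv", sep="\t", index=False)
    (out / "report.json").write_text(
        json.dumps({"stage": "validation", "logrank_p": res.logrank_p}, indent=1)
    )
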