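"""Synthetic cohort generator.

Emulates the statistical structure the stratification pipeline assumes in
real data: a tumor cohort whose expression is driven by a low-dimensional
latent factor model with two subgroups separated along a subset of latent
dimensions, block co-expressed gene modules, subgroup-dependent exponential
recurrence-free survival with administrative censoring, a "platform-shifted"
validation cohort sharing the same generative structure but with per-gene
monotone affine distortion, and a normal-tissue cohort with count-like
values for the co-expression analysis.

Expression values are delivered on a median-Z-like scale: each gene is
centred on a finite reference panel's median and the whole cohort is scaled
by a single robust factor (the median of the per-gene reference MADs).
Gene-level differences in mean and spread therefore survive normalization,
so cross-platform rank-concordance diagnostics behave as they do on real
reference-normalized data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .types import CohortTruth, ExpressionMatrix, SimulationConfig, SurvivalTable

__all__ = [
    "generate_tumor_cohort",
    "generate_validation_cohort",
    "generate_normal_tissue",
]

# independent child-seed tags for the RNG streams
_STRUCTURE, _TUMOR, _VALIDATION, _NORMAL = 11, 13, 17, 19


@dataclass
class _Structure:
    """Gene-level generative structure shared by all cohorts of one seed."""

    gene_ids: list
    block_of_gene: np.ndarray      # latent dim index per gene
    loading: np.ndarray            # latent loading magnitude per gene
    module_of_gene: np.ndarray     # module id per gene, 0 = none
    module_index: np.ndarray       # 0-based factor column per gene (-1 = none)
    gamma_shape: np.ndarray        # per-gene noise shape (skewness control)
    noise_scale: np.ndarray        # per-gene noise multiplier
    baseline: np.ndarray           # per-gene raw-scale baseline
    count_baseline: np.ndarray     # per-gene log2 baseline for normal tissue


def _build_structure(config: SimulationConfig) -> _Structure:
    config.validate()
    if config.module_count * config.module_size > config.n_genes:
        raise ValueError("module_count * module_size exceeds n_genes")
    rng = np.random.default_rng([_STRUCTURE, config.seed])
    g = config.n_genes
    gene_ids = [f"g{i:05d}" for i in range(g)]

    # contiguous latent blocks: gene i belongs to latent dim floor(i / block)
    block = np.minimum(np.arange(g) * config.latent_dim // g, config.latent_dim - 1)
    loading = rng.uniform(0.6, 1.4, size=g)

    # modules drawn preferentially from genes outside the signal blocks so
    # planted DEG structure and planted co-expression stay distinguishable
    candidates = np.flatnonzero(block >= config.n_signal_dims)
    need = config.module_count * config.module_size
    pool = candidates if len(candidates) >= need else np.arange(g)
    chosen = np.sort(rng.choice(pool, size=need, replace=False))
    module_of_gene = np.zeros(g, dtype=int)
    module_index = np.full(g, -1, dtype=int)
    for m in range(config.module_count):
        idx = chosen[m * config.module_size : (m + 1) * config.module_size]
        module_of_gene[idx] = m + 1
        module_index[idx] = m

    gamma_shape = rng.uniform(2.0, 20.0, size=g)
    noise_scale = rng.uniform(0.7, 1.3, size=g)
    baseline = rng.normal(6.0, 2.0, size=g)
    count_baseline = np.where(
        module_of_gene > 0, rng.normal(7.0, 1.0, size=g), rng.normal(5.0, 2.0, size=g)
    )
    return _Structure(
        gene_ids, block, loading, module_of_gene, module_index,
        gamma_shape, noise_scale, baseline, count_baseline,
    )


def _skew_noise(rng: np.random.Generator, shape: np.ndarray, n: int) -> np.ndarray:
    """Standardized (mean 0, sd 1) gamma noise, one shape per gene."""
    k = shape[:, None]
    return (rng.gamma(k, size=(len(shape), n)) - k) / np.sqrt(k)


def _raw_expression(
    st: _Structure, config: SimulationConfig, latent: np.ndarray,
    factors: np.ndarray, noise: np.ndarray,
) -> np.ndarray:
    """Genes x samples raw-scale values from latent + module + noise parts."""
    rho = config.intra_module_correlation
    x = st.baseline[:, None] + st.loading[:, None] * latent.T[st.block_of_gene, :]
    in_mod = st.module_index >= 0
    if in_mod.any() and rho > 0:
        x[in_mod] += np.sqrt(rho) * factors.T[st.module_index[in_mod], :]
    x += config.noise_sd * st.noise_scale[:, None] * noise
    return x


def _reference_normalize(
    raw: np.ndarray, raw_ref: np.ndarray
) -> np.ndarray:
    """Centre per gene on the reference median; scale by a cohort-level
    robust factor (median of per-gene reference MADs)."""
    ref_median = np.median(raw_ref, axis=1)
    ref_mad = np.median(np.abs(raw_ref - ref_median[:, None]), axis=1)
    scale = np.median(ref_mad)
    if scale <= 0:
        scale = 1.0
    return (raw - ref_median[:, None]) / scale


def _solve_base_hazard(config: SimulationConfig) -> float:
    """Base (better-prognosis) hazard giving the target overall event
    fraction under Uniform(0, horizon) administrative censoring."""
    tau = config.censoring_horizon
    hr = config.hazard_ratio

    def p_event(h: float) -> float:
        return 1.0 - (1.0 - np.exp(-h * tau)) / (h * tau)

    def objective(h: float) -> float:
        return 0.5 * (p_event(h) + p_event(h * hr)) - config.event_fraction

    return brentq(objective, 1e-8, 50.0, xtol=1e-12)


def _draw_survival(
    rng: np.random.Generator, labels: np.ndarray, hazards: tuple, tau: float,
    sample_ids: list,
) -> SurvivalTable:
    n = len(labels)
    rate = np.where(labels == 0, hazards[0], hazards[1])
    t_event = rng.exponential(1.0, size=n) / rate if n else np.empty(0)
    t_cens = rng.uniform(0.0, tau, size=n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return SurvivalTable(sample_ids, time, event)


def _sample_cohort(
    config: SimulationConfig,
    st: _Structure,
    rng: np.random.Generator,
    prefix: str,
    distort: bool,
):
    n = config.n_samples
    delta = config.subgroup_separation
    labels = rng.integers(0, 2, size=n)
    latent = rng.standard_normal((n, config.latent_dim))
    latent[labels == 1, : config.n_signal_dims] += delta
    factors = rng.standard_normal((n, config.module_count))
    noise = _skew_noise(rng, st.gamma_shape, n)
    raw = _raw_expression(st, config, latent, factors, noise)

    # reference panel: subgroup-free draws from the same gene model
    n_ref = config.n_reference_samples
    ref_latent = rng.standard_normal((n_ref, config.latent_dim))
    ref_factors = rng.standard_normal((n_ref, config.module_count))
    ref_noise = _skew_noise(rng, st.gamma_shape, n_ref)
    raw_ref = _raw_expression(st, config, ref_latent, ref_factors, ref_noise)

    if distort:
        a = rng.uniform(*config.platform_scale_range, size=config.n_genes)
        c = rng.uniform(*config.platform_offset_range, size=config.n_genes)
        raw = a[:, None] * raw + c[:, None]
        raw_ref = a[:, None] * raw_ref + c[:, None]

    z = _reference_normalize(raw, raw_ref)
    sample_ids = [f"{prefix}{j:04d}" for j in range(n)]
    expr = ExpressionMatrix(
        pd.DataFrame(z, index=st.gene_ids, columns=sample_ids), scale_tag="zscore"
    )

    base = _solve_base_hazard(config)
    hazards = (base, base * config.hazard_ratio)
    survival = _draw_survival(rng, labels, hazards, config.censoring_horizon, sample_ids)

    deg = (
        {st.gene_ids[i] for i in np.flatnonzero(st.block_of_gene < config.n_signal_dims)}
        if delta > 0
        else set()
    )
    means = np.zeros((2, config.latent_dim))
    means[1, : config.n_signal_dims] = delta
    truth = CohortTruth(
        subgroup_label=labels,
        latent_means=means,
        deg_gene_ids=deg,
        module_assignment={
            st.gene_ids[i]: int(st.module_of_gene[i]) for i in range(config.n_genes)
        },
        hazard_rates=hazards,
        censoring_horizon=config.censoring_horizon,
        latent=latent,
    )
    return expr, survival, truth


def generate_tumor_cohort(config: SimulationConfig):
    """Generate the discovery (training) cohort.

    Returns
    -------
    (ExpressionMatrix, SurvivalTable, CohortTruth)
        Median-Z-like expression (genes x samples), recurrence-free survival
        with administrative censoring, and the planted ground truth.
    """
    st = _build_structure(config)
    rng = np.random.default_rng([_TUMOR, config.seed])
    return _sample_cohort(config, st, rng, "T", distort=False)


def generate_validation_cohort(config: SimulationConfig, truth: CohortTruth):
    """Generate a platform-shifted cohort from the same generative structure.

    New samples are drawn from the latent model of ``config.seed``; each
    gene is then passed through a monotone affine distortion (scale and
    offset drawn from the configured ranges) before reference normalization,
    so per-gene mean/MAD ranks stay positively correlated with the training
    cohort while absolute scales differ.
    """
    if len(truth.module_assignment) != config.n_genes:
        raise ValueError(
            "gene count mismatch between truth "
            f"({len(truth.module_assignment)}) and config ({config.n_genes})"
        )
    st = _build_structure(config)
    rng = np.random.default_rng([_VALIDATION, config.seed])
    return _sample_cohort(config, st, rng, "V", distort=True)


def generate_normal_tissue(config: SimulationConfig):
    """Generate a normal-tissue cohort with count-like positive values.

    Genes in module m share a latent factor with loading sqrt(rho), giving
    pairwise correlation ~= rho on the log2 scale; non-module genes are
    independent noise. Values are 2**(log2-scale signal) rounded to integers
    so a median-read-count filter is exercisable.
    """
    st = _build_structure(config)
    rng = np.random.default_rng([_NORMAL, config.seed])
    n = config.n_samples
    rho = config.intra_module_correlation
    factors = rng.standard_normal((n, config.module_count))
    noise = rng.standard_normal((config.n_genes, n))
    x = np.sqrt(1.0 - rho) * noise
    in_mod = st.module_index >= 0
    if in_mod.any() and rho > 0:
        x[in_mod] += np.sqrt(rho) * factors.T[st.module_index[in_mod], :]
    x = np.where(in_mod[:, None], x, noise)  # non-module genes: unit noise
    counts = np.round(2.0 ** (st.count_baseline[:, None] + x))
    counts = np.maximum(counts, 0.0)
    sample_ids = [f"N{j:04d}" for j in range(n)]
    expr = ExpressionMatrix(
        pd.DataFrame(counts, index=st.gene_ids, columns=sample_ids),
        scale_tag="counts",
    )
    truth = CohortTruth(
        subgroup_label=np.zeros(n, dtype=int),
        latent_means=np.zeros((2, config.latent_dim)),
        deg_gene_ids=set(),
        module_assignment={
            st.gene_ids[i]: int(st.module_of_gene[i]) for i in range(config.n_genes)
        },
        hazard_rates=(1.0, 1.0),
        censoring_horizon=config.censoring_horizon,
    )
    return expr, truth
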