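"""Weighted co-expression network analysis of normal tissue (WGCNA-lite).

Builds an unsigned weighted network a_ij = |cor(x_i, x_j)|^beta from
expression, derives the topological overlap matrix (TOM), detects modules
by average-linkage hierarchical clustering of 1 - TOM with a flat cut,
tests module preservation in a held-out split with a permutation null,
filters each module's graph view to its top-weight edges, scores module/DEG
overlap, and runs hypergeometric gene-set enrichment over GMT collections.

This is deliberately not a full WGCNA reimplementation: no dynamic tree
cut, no eigengenes, no Zsummary suite. The surrogate choices (flat cut +
minimum module size; mean within-module test TOM against a random-gene-set
null) are exposed as parameters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom

from .diffexp import bh_adjust
from .types import ExpressionMatrix

__all__ = [
    "CoexpressionNetwork",
    "filter_by_read_count",
    "split_train_test",
    "pick_soft_threshold",
    "tom_from_expression",
    "detect_modules",
    "module_preservation",
    "filter_top_edges",
    "module_deg_overlap",
    "module_enrichment",
]

logger = logging.getLogger(__name__)


@dataclass
class CoexpressionNetwork:
    """Adjacency + TOM over a fixed gene order, plus module assignment."""

    gene_ids: list
    beta: float
    adjacency: np.ndarray
    tom: np.ndarray
    modules: np.ndarray | None = None  # module id per gene, 0 = unassigned


def filter_by_read_count(
    counts: ExpressionMatrix, tpm: ExpressionMatrix, min_median: float = 10.0
) -> list:
    """Genes whose median raw read count strictly exceeds ``min_median``.

    Expression for downstream steps is then taken from the companion
    abundance matrix (``tpm``); both matrices must share the gene ids kept.
    """
    shared = [g for g in counts.gene_ids if g in set(tpm.gene_ids)]
    med = counts.data.loc[shared].median(axis=1)
    keep = [g for g in shared if med[g] > min_median]
    if not keep:
        raise ValueError("no genes pass the median read-count filter")
    return keep


def split_train_test(samples, fraction: float, seed: int):
    """Deterministic disjoint/exhaustive split; train gets
    floor(fraction * n) samples."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    samples = list(samples)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))
    n_train = math.floor(fraction * len(samples))
    train = sorted(samples[i] for i in order[:n_train])
    test = sorted(samples[i] for i in order[n_train:])
    return train, test


def _abs_correlation(expr: ExpressionMatrix) -> np.ndarray:
    x = expr.values
    sd = x.std(axis=1)
    if (sd == 0).any():
        bad = [expr.gene_ids[i] for i in np.flatnonzero(sd == 0)[:5]]
        raise ValueError(f"constant gene(s) make correlation undefined: {bad}")
    return np.abs(np.corrcoef(x))


def pick_soft_threshold(
    expr: ExpressionMatrix, candidate_powers=None, r2_target: float = 0.8
) -> float:
    """Smallest power whose scale-free topology fit reaches ``r2_target``.

    The fit regresses log10(frequency) on log10(mean connectivity) over 10
    connectivity bins; R^2 counts only when the slope is negative (scale-free
    degree distributions are decreasing). If no candidate reaches the target
    the maximal-R^2 power is returned with a warning.
    """
    if candidate_powers is None:
        candidate_powers = list(range(1, 11)) + list(range(12, 21, 2))
    candidate_powers = list(candidate_powers)
    if len(candidate_powers) < 2:
        raise ValueError("need at least two candidate powers")
    base = _abs_correlation(expr)
    np.fill_diagonal(base, 0.0)
    fits = []
    for beta in candidate_powers:
        k = (base**beta).sum(axis=1)
        fits.append((beta, _scale_free_r2(k)))
    for beta, (r2, slope) in fits:
        if slope < 0 and r2 >= r2_target:
            return float(beta)
    best = max(fits, key=lambda t: t[1][0])
    logger.warning(
        "no candidate power reached scale-free R^2 %.2f; falling back to "
        "beta=%s (R^2=%.3f)", r2_target, best[0], best[1][0]
    )
    return float(best[0])


def _scale_free_r2(connectivity: np.ndarray, n_bins: int = 10):
    k = connectivity[connectivity > 0]
    if k.size < n_bins:
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    idx = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        members = k[idx == b]
        if members.size:
            xs.append(np.log10(members.mean()))
            ys.append(np.log10(members.size / k.size))
    if len(xs) < 3:
        return 0.0, 0.0
    slope, intercept = np.polyfit(xs, ys, 1)
    pred = slope * np.asarray(xs) + intercept
    ss_res = float(np.sum((np.asarray(ys) - pred) ** 2))
    ss_tot = float(np.sum((np.asarray(ys) - np.mean(ys)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return r2, float(slope)


def _tom_from_adjacency(a: np.ndarray) -> np.ndarray:
    """TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)."""
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def tom_from_expression(expr: ExpressionMatrix, beta: float) -> CoexpressionNetwork:
    """Unsigned adjacency |cor|^beta (zero diagonal) and its TOM."""
    if expr.n_genes < 3:
        raise ValueError("need at least 3 genes")
    if expr.n_samples < 4:
        raise ValueError("need at least 4 samples")
    a = _abs_correlation(expr) ** beta
    np.fill_diagonal(a, 0.0)
    return CoexpressionNetwork(
        gene_ids=expr.gene_ids, beta=float(beta), adjacency=a,
        tom=_tom_from_adjacency(a),
    )


def detect_modules(
    network: CoexpressionNetwork, min_module_size: int = 20, cut_height: float = 0.95
) -> np.ndarray:
    """Flat cut of average-linkage clustering on 1 - TOM.

    Clusters smaller than ``min_module_size`` become unassigned (module 0);
    surviving modules are renumbered 1, 2, ... by decreasing size (ties by
    smallest member index). The assignment is also stored on the network.
    """
    dissim = 1.0 - network.tom
    np.fill_diagonal(dissim, 0.0)
    z = linkage(squareform(dissim, checks=False), method="average")
    raw = fcluster(z, t=cut_height, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    keep = [c for c in sizes.index if sizes[c] >= min_module_size]
    first_member = {c: int(np.flatnonzero(raw == c)[0]) for c in keep}
    keep.sort(key=lambda c: (-sizes[c], first_member[c]))
    modules = np.zeros(len(raw), dtype=int)
    for new_id, c in enumerate(keep, start=1):
        modules[raw == c] = new_id
    network.modules = modules
    return modules


def module_preservation(
    train_expr: ExpressionMatrix,
    test_expr: ExpressionMatrix,
    modules: np.ndarray,
    n_perm: int = 200,
    beta: float | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation test of module preservation in the held-out split.

    The observed statistic is the mean within-module off-diagonal TOM in
    the test set; the null draws ``n_perm`` random gene sets of equal size.
    p = (1 + #{null >= observed}) / (1 + n_perm); p < 0.05 flags preserved.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    if train_expr.gene_ids != test_expr.gene_ids:
        raise ValueError("train and test splits must share the same genes")
    if beta is None:
        beta = 6.0
    test_net = tom_from_expression(test_expr, beta)
    tom = test_net.tom
    rng = np.random.default_rng(seed)
    modules = np.asarray(modules)
    n_genes = len(modules)
    rows = []
    for m in sorted(set(modules) - {0}):
        idx = np.flatnonzero(modules == m)
        observed = _mean_offdiag(tom, idx)
        null = np.empty(n_perm)
        for b in range(n_perm):
            rand = rng.choice(n_genes, size=idx.size, replace=False)
            null[b] = _mean_offdiag(tom, rand)
        p = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
        rows.append(
            {"module": m, "size": idx.size, "observed": observed,
             "null_mean": null.mean(), "p": p, "preserved": p < 0.05}
        )
    return pd.DataFrame(rows)


def _mean_offdiag(tom: np.ndarray, idx: np.ndarray) -> float:
    sub = tom[np.ix_(idx, idx)]
    n = idx.size
    if n < 2:
        return 0.0
    return float((sub.sum() - np.trace(sub)) / (n * (n - 1)))


def filter_top_edges(network: CoexpressionNetwork, fraction: float = 0.10) -> dict:
    """Top-weight within-module adjacency edges, per module.

    Keeps ceil(fraction * E_m) edges per module, ranked by weight with
    deterministic (gene-id pair) tie-breaking. Module membership itself is
    unchanged; this is a graph view. Returns
    ``{module: [(gene_a, gene_b, weight), ...]}``.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if network.modules is None:
        raise ValueError("detect_modules must run first")
    out = {}
    for m in sorted(set(network.modules) - {0}):
        idx = np.flatnonzero(network.modules == m)
        edges = []
        for ii in range(idx.size):
            for jj in range(ii + 1, idx.size):
                i, j = idx[ii], idx[jj]
                edges.append(
                    (network.gene_ids[i], network.gene_ids[j],
                     float(network.adjacency[i, j]))
                )
        if not edges:
            out[m] = []
            continue
        n_keep = math.ceil(fraction * len(edges))
        edges.sort(key=lambda e: (-e[2], e[0], e[1]))
        out[m] = edges[:n_keep]
    return out


def module_deg_overlap(modules: dict, degs) -> dict:
    """Percentage of each module's genes that are DEGs.

    ``modules`` maps module id -> gene collection. Empty modules score 0%
    with a warning.
    """
    degs = set(degs)
    out = {}
    for m, genes in modules.items():
        genes = list(genes)
        if not genes:
            logger.warning("module %s is empty; overlap set to 0%%", m)
            out[m] = 0.0
        else:
            out[m] = 100.0 * len(set(genes) & degs) / len(genes)
    return out


def module_enrichment(
    module_genes,
    gene_sets: dict,
    universe,
    adj_threshold: float = 1e-4,
) -> pd.DataFrame:
    """Hypergeometric over-representation of GMT terms in a module.

    For each term: upper-tail probability of an overlap at least as large
    as observed given (|universe|, |term in universe|, |module|); BH
    adjustment across terms; rows with adjusted p below ``adj_threshold``
    are flagged ``significant``. Returns all terms, sorted by p.
    """
    if not gene_sets:
        raise ValueError("gene set collection is empty")
    universe = set(universe)
    module = set(module_genes)
    if not module <= universe:
        raise ValueError("module genes must be contained in the universe")
    rows = []
    for term, members in gene_sets.items():
        members = set(members) & universe
        if not members:
            continue
        overlap = len(module & members)
        p = float(
            hypergeom.sf(overlap - 1, len(universe), len(members), len(module))
        )
        rows.append(
            {"term": term, "overlap": overlap, "term_size": len(members),
             "universe_size": len(universe), "module_size": len(module), "p": p}
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["adj_p"] = bh_adjust(df["p"].to_numpy())
    df["significant"] = df["adj_p"] < adj_threshold
    return df.sort_values("p", kind="mergesort", ignore_index=True)
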