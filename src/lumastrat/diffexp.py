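"""Moderated-t two-group differential expression and cohort consensus.

Per gene, an ordinary pooled-variance two-sample statistic is shrunk with
the empirical-Bayes variance model: the prior (d0, s0^2) is estimated by
moment-matching on log sample variances via digamma/trigamma inversion,
the posterior variance is s~_g^2 = (d0*s0^2 + d_g*s_g^2) / (d0 + d_g), and
the moderated t = dmean / (s~_g * sqrt(1/n1 + 1/n2)) is referred to a
t-distribution on d0 + d_g degrees of freedom. With d0 = 0 this reduces to
the ordinary pooled t; as d0 -> inf every gene is scaled by the common s0.

The two-cohort consensus keeps genes significant (BH-adjusted p below the
threshold) in BOTH cohorts, by default also requiring a concordant sign of
the mean difference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .types import ExpressionMatrix

__all__ = [
    "moderated_t_two_group",
    "bh_adjust",
    "consensus_degs",
    "fit_variance_prior",
]


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iterations on the standard
    closed-form start)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) on log sample variances.

    Parameters
    ----------
    s2 : per-gene sample variances (genes with df > 0 only).
    df : residual degrees of freedom d_g, common to all genes.

    Returns
    -------
    (d0, s0_squared); d0 = inf when the observed log-variance spread is no
    larger than expected under a common variance.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    if s2.size < 2:
        return np.inf, float(np.mean(s2)) if s2.size else 1.0
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    n = z.size
    mean_e = e.mean()
    var_e = np.sum((e - mean_e) ** 2) / (n - 1)
    excess = var_e - special.polygamma(1, df / 2.0)
    if excess <= 0:
        # no extra spread beyond sampling noise: infinitely informative
        # prior; the pooled mean variance is the MLE of the common scale
        return np.inf, float(np.mean(s2))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0 = np.exp(mean_e + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s0)


def moderated_t_two_group(
    expr: ExpressionMatrix,
    labels,
    group_order=None,
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated t-test per gene between two groups.

    Parameters
    ----------
    expr : ExpressionMatrix on the z-score scale (genes x samples).
    labels : per-sample group labels with exactly two levels.
    group_order : optional pair fixing the contrast direction; the mean
        difference reported is ``group_order[1] - group_order[0]``.
    d0_override : force the prior degrees of freedom (0 disables shrinkage,
        numpy.inf gives the fixed-scale limit); mainly for verification.

    Returns
    -------
    DataFrame indexed by gene id with columns mean_diff, s2, df, d0, s0_2,
    s2_post, t, p, adj_p.
    """
    labels = np.asarray(labels)
    levels = group_order if group_order is not None else list(pd.unique(labels))
    if len(levels) != 2:
        raise ValueError("moderated_t_two_group requires exactly two groups")
    m0, m1 = (labels == levels[0]), (labels == levels[1])
    n0, n1 = int(m0.sum()), int(m1.sum())
    if n0 < 2 or n1 < 2:
        raise ValueError("both groups need at least two samples")

    x = expr.values
    x0, x1 = x[:, m0], x[:, m1]
    mean_diff = x1.mean(axis=1) - x0.mean(axis=1)
    df_resid = n0 + n1 - 2
    ss = ((x0 - x0.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (x1 - x1.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / df_resid

    if d0_override is not None:
        d0 = float(d0_override)
        _, s0_2 = fit_variance_prior(s2, df_resid)
        if d0 == 0.0:
            s0_2 = float("nan")
    else:
        d0, s0_2 = fit_variance_prior(s2, df_resid)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    elif d0 == 0.0:
        s2_post = s2
        df_total = df_resid
    else:
        s2_post = (d0 * s0_2 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    se = np.sqrt(s2_post * (1.0 / n0 + 1.0 / n1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_diff / se
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isnan(p), 1.0, p)

    return pd.DataFrame(
        {
            "mean_diff": mean_diff,
            "s2": s2,
            "df": float(df_resid),
            "d0": d0,
            "s0_2": s0_2,
            "s2_post": s2_post,
            "t": t,
            "p": p,
            "adj_p": bh_adjust(p),
        },
        index=expr.gene_ids,
    )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def consensus_degs(
    tableA: pd.DataFrame,
    tableB: pd.DataFrame,
    universe,
    threshold: float = 0.01,
    require_concordant_sign: bool = True,
    use_adjusted: bool = True,
) -> list:
    """Genes significant in BOTH cohorts within ``universe``.

    ``use_adjusted`` switches between BH-adjusted (default) and raw
    p-values; ``require_concordant_sign`` additionally demands the mean
    difference have the same sign in both cohorts.
    """
    universe = list(universe)
    if not universe:
        raise ValueError("consensus universe must be non-empty")
    for name, tbl in (("A", tableA), ("B", tableB)):
        missing = set(universe) - set(tbl.index)
        if missing:
            raise KeyError(f"universe genes missing from table {name}: "
                           f"{sorted(missing)[:5]}")
    col = "adj_p" if use_adjusted else "p"
    out = []
    for g in universe:
        sig = tableA.loc[g, col] < threshold and tableB.loc[g, col] < threshold
        if sig and require_concordant_sign:
            sig = tableA.loc[g, "mean_diff"] * tableB.loc[g, "mean_diff"] > 0
        if sig:
            out.append(g)
    return out
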