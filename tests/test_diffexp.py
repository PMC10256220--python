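"""Moderated-t statistics against a direct-formula oracle, BH adjustment,
and two-cohort consensus."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, special, stats

import pandas as pd
from lumastrat import (
    SimulationConfig,
    bh_adjust,
    consensus_degs,
    generate_tumor_cohort,
    generate_validation_cohort,
    moderated_t_two_group,
)

from conftest import make_expression


def oracle_moderated_t(x0, x1):
    """Independently coded moderated t: per-gene pooled variances, prior
    estimated by solving the log-variance moment equations with a generic
    root finder, posterior shrinkage, t and two-sided p."""
    n0, n1 = x0.shape[1], x1.shape[1]
    df = n0 + n1 - 2
    diff = x1.mean(axis=1) - x0.mean(axis=1)
    s2 = (
        ((x0 - x0.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        + ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ) / df
    z = np.log(s2)
    e = z - special.digamma(df / 2) + np.log(df / 2)
    evar = np.var(e, ddof=1)
    target = evar - special.polygamma(1, df / 2)
    if target > 0:
        half_d0 = optimize.brentq(
            lambda v: special.polygamma(1, v) - target, 1e-6, 1e8
        )
        d0 = 2 * half_d0
        s0 = np.exp(e.mean() + special.digamma(half_d0) - np.log(half_d0))
        s2_post = (d0 * s0 + df * s2) / (d0 + df)
        df_total = d0 + df
    else:
        d0, s0 = np.inf, s2.mean()
        s2_post = np.full_like(s2, s0)
        df_total = np.inf
    t = diff / np.sqrt(s2_post * (1 / n0 + 1 / n1))
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df_total)
    return t, p, d0, s0


class TestModeratedT:
    def test_matches_direct_formula_oracle(self, rng):
        """20-gene random instance agrees with the oracle to 1e-8."""
        x0 = rng.standard_normal((20, 8))
        x1 = rng.standard_normal((20, 10)) + rng.normal(0, 0.5, size=(20, 1))
        expr = make_expression(np.hstack([x0, x1]))
        labels = np.array(["A"] * 8 + ["B"] * 10)
        table = moderated_t_two_group(expr, labels, group_order=["A", "B"])
        t_ref, p_ref, d0_ref, s0_ref = oracle_moderated_t(x0, x1)
        np.testing.assert_allclose(table["t"].to_numpy(), t_ref, atol=1e-8)
        np.testing.assert_allclose(table["p"].to_numpy(), p_ref, atol=1e-8)
        assert table["d0"].iloc[0] == pytest.approx(d0_ref, rel=1e-6)
        assert table["s0_2"].iloc[0] == pytest.approx(s0_ref, rel=1e-6)

    def test_d0_zero_recovers_ordinary_pooled_t(self, rng):
        x = rng.standard_normal((15, 12))
        labels = np.array(["A"] * 6 + ["B"] * 6)
        table = moderated_t_two_group(expr := make_expression(x), labels,
                                      group_order=["A", "B"], d0_override=0.0)
        t_ref, p_ref = stats.ttest_ind(
            x[:, 6:], x[:, :6], axis=1, equal_var=True
        )
        np.testing.assert_allclose(table["t"].to_numpy(), t_ref, atol=1e-10)
        np.testing.assert_allclose(table["p"].to_numpy(), p_ref, atol=1e-10)

    def test_d0_infinite_gives_common_scale(self, rng):
        x = rng.standard_normal((15, 12))
        labels = np.array(["A"] * 6 + ["B"] * 6)
        table = moderated_t_two_group(make_expression(x), labels,
                                      group_order=["A", "B"],
                                      d0_override=np.inf)
        s0 = table["s0_2"].iloc[0]
        diff = table["mean_diff"].to_numpy()
        expected = diff / np.sqrt(s0 * (1 / 6 + 1 / 6))
        np.testing.assert_allclose(table["t"].to_numpy(), expected, atol=1e-10)

    def test_label_swap_negates_t_keeps_p(self, rng):
        x = rng.standard_normal((10, 10))
        labels = np.array(["A"] * 5 + ["B"] * 5)
        expr = make_expression(x)
        a = moderated_t_two_group(expr, labels, group_order=["A", "B"])
        b = moderated_t_two_group(expr, labels, group_order=["B", "A"])
        np.testing.assert_allclose(a["t"].to_numpy(), -b["t"].to_numpy())
        np.testing.assert_allclose(a["p"].to_numpy(), b["p"].to_numpy())

    def test_zero_variance_gene_survives_shrinkage(self, rng):
        x = rng.standard_normal((10, 10))
        x[0] = np.tile([1.0, 2.0], 5)[None, :]  # same values in both groups
        x[1, :5], x[1, 5:] = 1.0, 2.0           # zero within-group variance
        labels = np.array(["A", "B"] * 5)
        expr = make_expression(x)
        table = moderated_t_two_group(expr, np.array(["A"] * 5 + ["B"] * 5))
        assert np.isfinite(table["t"].to_numpy()).all()

    def test_small_group_rejected(self, rng):
        expr = make_expression(rng.standard_normal((5, 4)))
        with pytest.raises(ValueError):
            moderated_t_two_group(expr, np.array(["A", "B", "B", "B"]))


class TestBhAdjust:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.5], [0.5]),
            ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
        ],
    )
    def test_known_values(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p), expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(
        p=st.lists(st.floats(0.0, 1.0), min_size=2, max_size=40),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_and_dominates_raw(self, p):
        q = bh_adjust(p)
        assert (q >= np.asarray(p) - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestConsensus:
    def _two_cohort_tables(self, seed, delta=4.0):
        cfg = SimulationConfig(
            n_genes=300, n_samples=300, module_count=3, module_size=40,
            subgroup_separation=delta, seed=seed,
        )
        expr, _, truth = generate_tumor_cohort(cfg)
        vexpr, _, vtruth = generate_validation_cohort(cfg, truth)
        ta = moderated_t_two_group(expr, truth.subgroup_label, group_order=[1, 0])
        tb = moderated_t_two_group(vexpr, vtruth.subgroup_label, group_order=[1, 0])
        return ta, tb, truth

    def test_self_intersection_is_significant_set(self, rng):
        x = rng.standard_normal((30, 20))
        x[:5, 10:] += 3.0
        expr = make_expression(x)
        table = moderated_t_two_group(expr, np.array(["A"] * 10 + ["B"] * 10))
        sig = set(table.index[table["adj_p"] < 0.05])
        out = consensus_degs(table, table, list(table.index), threshold=0.05)
        assert set(out) == sig

    def test_empty_universe_rejected(self, rng):
        expr = make_expression(rng.standard_normal((6, 8)))
        table = moderated_t_two_group(expr, np.array(["A"] * 4 + ["B"] * 4))
        with pytest.raises(ValueError):
            consensus_degs(table, table, [], threshold=0.05)

    @pytest.mark.parametrize("seed", range(5))
    def test_planted_deg_recovery(self, seed):
        """Consensus DEGs at delta=4 recover the planted set with high
        recall and low false-discovery rate."""
        ta, tb, truth = self._two_cohort_tables(seed)
        found = set(consensus_degs(ta, tb, list(ta.index), threshold=0.01))
        planted = truth.deg_gene_ids
        recall = len(found & planted) / len(planted)
        fdr = len(found - planted) / max(len(found), 1)
        assert recall >= 0.8
        assert fdr <= 0.1


class TestLimmaCrossCheck:
    def test_agrees_with_r_limma(self, tmp_path, rng):
        """Independent route: the same two-group design run through
        Bioconductor limma (lmFit + eBayes) gives the same moderated t,
        p-values and variance prior."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        x = rng.standard_normal((30, 16)) * rng.uniform(0.5, 2.0, size=(30, 1))
        x[:5, 8:] += 1.5
        expr = make_expression(x)
        expr_path = tmp_path / "expr.tsv"
        expr.data.to_csv(expr_path, sep="\t")
        out_path = tmp_path / "limma.tsv"
        rcode = f"""
        suppressMessages(library(limma))
        x <- as.matrix(read.delim("{expr_path}", row.names=1))
        design <- cbind(Intercept=1, Group=c(rep(0,8), rep(1,8)))
        fit <- eBayes(lmFit(x, design))
        out <- data.frame(t=fit$t[,2], p=fit$p.value[,2],
                          d0=fit$df.prior, s0=fit$s2.prior)
        write.table(out, "{out_path}", sep="\\t", quote=FALSE)
        """
        proc = subprocess.run(
            ["Rscript", "-e", rcode], capture_output=True, text=True,
            timeout=120,
        )
        if proc.returncode != 0:
            pytest.skip(f"limma unavailable: {proc.stderr[-200:]}")
        ref = pd.read_csv(out_path, sep="\t")
        labels = np.array(["A"] * 8 + ["B"] * 8)
        table = moderated_t_two_group(expr, labels, group_order=["A", "B"])
        np.testing.assert_allclose(table["t"].to_numpy(), ref["t"].to_numpy(),
                                   atol=1e-6)
        np.testing.assert_allclose(table["p"].to_numpy(), ref["p"].to_numpy(),
                                   atol=1e-6)
        assert table["d0"].iloc[0] == pytest.approx(ref["d0"].iloc[0], rel=1e-4)
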