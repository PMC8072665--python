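"""Moderated-t differential expression: sufficient statistics, the
empirical-Bayes variance prior, the statistic itself (including its limits
and an external limma cross-check), and the screening rule."""

import math
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from netpharm.diffexpr import (
    ExpressionProfile,
    ExpressionError,
    GenePrior,
    call_degs,
    differential_expression,
    estimate_prior,
    gene_stats,
    moderated_t,
)
from netpharm.synthetic import gen_expression


def profile_from(case_rows, ctrl_rows, genes=None):
    case_rows = np.atleast_2d(np.asarray(case_rows, float))
    ctrl_rows = np.atleast_2d(np.asarray(ctrl_rows, float))
    n_genes = case_rows.shape[0]
    genes = genes or [f"g{i}" for i in range(n_genes)]
    cols = [f"c{i}" for i in range(case_rows.shape[1])] + \
           [f"n{i}" for i in range(ctrl_rows.shape[1])]
    values = pd.DataFrame(np.hstack([case_rows, ctrl_rows]), index=genes, columns=cols)
    groups = {c: ("case" if c.startswith("c") else "control") for c in cols}
    return ExpressionProfile(values=values, groups=groups)


class TestGeneStats:
    def test_constant_gene(self):
        st = gene_stats(profile_from([[5, 5, 5]], [[5, 5, 5]]))
        assert st["log2fc"].iloc[0] == 0
        assert st["s2"].iloc[0] == 0

    def test_exact_shift_zero_variance(self):
        st = gene_stats(profile_from([[2, 2]], [[1, 1]]))
        assert st["log2fc"].iloc[0] == 1
        assert st["s2"].iloc[0] == 0

    def test_pooled_variance_hand_computation(self):
        # case {3,5}, control {1,3}: lfc = 2, pooled s2 = (2+2)/2 = 2, d = 2
        st = gene_stats(profile_from([[3, 5]], [[1, 3]]))
        assert st["log2fc"].iloc[0] == pytest.approx(2.0)
        assert st["s2"].iloc[0] == pytest.approx(2.0)
        assert st["d"].iloc[0] == 2

    def test_single_sample_group_rejected(self):
        with pytest.raises(ExpressionError):
            profile_from([[1]], [[1, 2]])


class TestEstimatePrior:
    def test_equal_variances_give_full_shrinkage(self):
        prior = estimate_prior(np.full(100, 0.3), d=4)
        assert math.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(0.3)

    def test_hierarchical_recovery(self):
        # sigma_g^2 ~ s0^2 d0 / chi2_d0; s^2 ~ sigma_g^2 chi2_d / d
        rng = np.random.default_rng(7)
        d0_true, s0_true, d, n = 4.0, 0.05, 10, 5000
        sigma2 = s0_true * d0_true / rng.chisquare(d0_true, n)
        s2 = sigma2 * rng.chisquare(d, n) / d
        prior = estimate_prior(s2, d)
        assert prior.d0 == pytest.approx(d0_true, rel=0.25)
        assert prior.s0_sq == pytest.approx(s0_true, rel=0.10)

    def test_too_few_positive_variances(self):
        with pytest.raises(ExpressionError, match=">= 10"):
            estimate_prior(np.array([0.1] * 5 + [0.0] * 50), d=4)

    def test_all_zero_is_degenerate(self):
        with pytest.raises(ExpressionError, match="constant"):
            estimate_prior(np.zeros(100), d=4)


class TestModeratedT:
    def test_hand_evaluated_formula(self):
        # lfc=1, s2=0.25, d=4, d0=4, s0=0.25, n1=n2=3:
        # posterior variance 0.25, t = 1/sqrt(0.25 * 2/3), df = 8
        st = pd.DataFrame(
            {"log2fc": [1.0], "s2": [0.25], "d": [4], "n1": [3], "n2": [3]},
            index=["g"],
        )
        out = moderated_t(st, GenePrior(d0=4, s0_sq=0.25))
        t_expect = 1.0 / math.sqrt(0.25 * (2 / 3))
        assert out["t"].iloc[0] == pytest.approx(t_expect, abs=1e-12)
        assert t_expect == pytest.approx(2.449, abs=1e-3)
        assert out["p"].iloc[0] == pytest.approx(2 * sps.t.sf(t_expect, 8), abs=1e-12)

    def test_no_shrinkage_limit_equals_ordinary_t(self):
        rng = np.random.default_rng(3)
        prof = profile_from(rng.normal(5, 1, (200, 5)), rng.normal(5, 1, (200, 6)))
        st = gene_stats(prof)
        out = moderated_t(st, GenePrior(d0=0.0, s0_sq=1.0))
        t_ref, p_ref = sps.ttest_ind(
            prof.values.iloc[:, :5], prof.values.iloc[:, 5:], axis=1, equal_var=True
        )
        np.testing.assert_allclose(out["t"], t_ref, atol=1e-10)
        np.testing.assert_allclose(out["p"], p_ref, atol=1e-10)

    def test_full_shrinkage_limit(self):
        st = pd.DataFrame(
            {"log2fc": [0.5], "s2": [99.0], "d": [4], "n1": [4], "n2": [4]},
            index=["g"],
        )
        out = moderated_t(st, GenePrior(d0=math.inf, s0_sq=0.04))
        assert out["t"].iloc[0] == pytest.approx(0.5 / math.sqrt(0.04 * 0.5))

    def test_zero_posterior_variance_flagged_not_called(self):
        st = pd.DataFrame(
            {"log2fc": [1.0], "s2": [0.0], "d": [2], "n1": [2], "n2": [2]},
            index=["g"],
        )
        out = moderated_t(st, GenePrior(d0=0.0, s0_sq=1.0))
        assert np.isnan(out["p"].iloc[0])
        assert call_degs(out).frame["direction"].iloc[0] == "ns"

    def test_group_swap_flips_sign_keeps_p(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(5, 1, (50, 4)), rng.normal(5, 1, (50, 4))
        st1 = gene_stats(profile_from(a, b))
        st2 = gene_stats(profile_from(b, a))
        prior = GenePrior(d0=4.0, s0_sq=1.0)
        o1, o2 = moderated_t(st1, prior), moderated_t(st2, prior)
        np.testing.assert_allclose(o1["t"], -o2["t"], atol=1e-12)
        np.testing.assert_allclose(o1["p"], o2["p"], atol=1e-12)

    def test_agrees_with_limma_ebayes(self, tmp_path):
        """Independent oracle: the Bioconductor limma eBayes pipeline on the
        same matrix must reproduce prior, t and p to near machine precision."""
        rng = np.random.default_rng(42)
        mat = rng.normal(6, 1, (80, 8)) * rng.uniform(0.5, 1.5, 80)[:, None]
        prof = profile_from(mat[:, :4], mat[:, 4:])
        prof.values.to_csv(tmp_path / "m.tsv", sep="\t")
        st = gene_stats(prof)
        prior = estimate_prior(st["s2"].to_numpy(), float(st["d"].iloc[0]))
        mine = moderated_t(st, prior)
        script = textwrap.dedent("""
            suppressMessages(library(limma))
            x <- as.matrix(read.delim("m.tsv", row.names=1))
            design <- cbind(Intercept=1, case=c(rep(1,4), rep(0,4)))
            fit <- eBayes(lmFit(x, design))
            out <- data.frame(t=fit$t[,"case"], p=fit$p.value[,"case"],
                              d0=fit$df.prior, s0=fit$s2.prior)
            write.csv(out, "limma_out.csv")
        """)
        (tmp_path / "cmp.R").write_text(script)
        subprocess.run(["Rscript", "cmp.R"], cwd=tmp_path, check=True,
                       capture_output=True)
        ref = pd.read_csv(tmp_path / "limma_out.csv", index_col=0)
        assert prior.d0 == pytest.approx(ref["d0"].iloc[0], abs=1e-8)
        assert prior.s0_sq == pytest.approx(ref["s0"].iloc[0], abs=1e-10)
        np.testing.assert_allclose(mine["t"], ref["t"], atol=1e-8)
        np.testing.assert_allclose(mine["p"], ref["p"], atol=1e-8)


class TestCallDegs:
    def frame(self, p, lfc):
        return pd.DataFrame({"log2fc": [lfc], "t": [1.0], "p": [p]}, index=["g"])

    def test_p_boundary_strict(self):
        out = call_degs(self.frame(0.05, 1.0))
        assert out.frame["direction"].iloc[0] == "ns"

    def test_lfc_boundary_strict(self):
        out = call_degs(self.frame(0.01, 0.05))
        assert out.frame["direction"].iloc[0] == "ns"

    def test_direction_by_sign(self):
        assert call_degs(self.frame(0.01, -0.2)).frame["direction"].iloc[0] == "down"
        assert call_degs(self.frame(0.01, 0.2)).frame["direction"].iloc[0] == "up"

    def test_planted_recovery_with_direction(self):
        profile, entry = gen_expression(seed=1)  # 300 planted, delta=1, sigma=0.5
        degs = differential_expression(profile)
        up, down = set(entry["up"]), set(entry["down"])
        recovered = len(degs.up_genes() & up) + len(degs.down_genes() & down)
        assert recovered / (len(up) + len(down)) >= 0.95

    def test_counts_invariant_to_orderings(self):
        profile, _ = gen_expression(n_genes=300, n_de=50, seed=2)
        base = differential_expression(profile)
        shuffled = ExpressionProfile(
            values=profile.values.iloc[::-1, ::-1], groups=profile.groups
        )
        other = differential_expression(shuffled)
        assert (base.n_up, base.n_down) == (other.n_up, other.n_down)

    def test_welch_alternative_runs(self):
        profile, _ = gen_expression(n_genes=200, n_de=40, seed=3)
        degs = differential_expression(profile, test="welch")
        assert degs.n_up + degs.n_down > 0
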