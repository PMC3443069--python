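import subprocess
import textwrap

import numpy as np
import pytest

from padog.stats import (
    fit_variance_prior,
    moderated_t,
    ordinary_t,
    trigamma_inverse,
    _shrink_s2,
)

from conftest import make_dataset


class TestOrdinaryT:
    def test_hand_computed_pooled_t(self):
        # control (0,2), case (1,3): effect 1, pooled s2 = 2, df = 2,
        # t = 1 / sqrt(2 * (1/2 + 1/2)) = 0.7071
        ds = make_dataset([[0.0, 2.0, 1.0, 3.0], [1.0, 0.0, 2.0, 5.0]])
        st = ordinary_t(ds)
        assert st.df == 2
        assert st.effect[0] == pytest.approx(1.0)
        assert st.s2[0] == pytest.approx(2.0)
        assert st.t_ordinary[0] == pytest.approx(1.0 / np.sqrt(2.0), abs=1e-10)

    def test_zero_variance_gene_is_flagged_infinite(self):
        ds = make_dataset([[0.0, 0.0, 1.0, 1.0], [0.0, 1.0, 2.0, 4.0]])
        st = ordinary_t(ds)
        assert np.isinf(st.t_ordinary[0]) and st.t_ordinary[0] > 0
        assert st.zero_variance[0] and not st.zero_variance[1]

    def test_all_zero_variance_is_an_error(self):
        ds = make_dataset([[1.0, 1.0, 2.0, 2.0], [0.0, 0.0, 5.0, 5.0]])
        with pytest.raises(ValueError, match="zero variance in every gene"):
            ordinary_t(ds)

    def test_invariant_to_sample_order_within_groups(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((20, 8))
        ds = make_dataset(X)
        shuffled = X[:, [2, 0, 1, 3, 7, 5, 6, 4]]  # permutes within each group
        ds2 = make_dataset(shuffled)
        np.testing.assert_allclose(ordinary_t(ds).t_ordinary,
                                   ordinary_t(ds2).t_ordinary, atol=1e-12)

    def test_paired_design_uses_block_differences(self):
        # blocks (ctrl, case): (0,1), (1,3), (2,4) -> diffs (1,2,2)
        ds = make_dataset(
            [[0.0, 1.0, 1.0, 3.0, 2.0, 4.0]],
            group=["control", "case"] * 3,
            block=["p1", "p1", "p2", "p2", "p3", "p3"],
        )
        st = ordinary_t(ds)
        d = np.array([1.0, 2.0, 2.0])
        expected = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        assert st.df == 2
        assert st.t_ordinary[0] == pytest.approx(expected, abs=1e-10)


class TestTrigammaInverse:
    @pytest.mark.parametrize("x", [0.05, 0.5, 1.0, 4.0, 25.0, 400.0])
    def test_round_trip(self, x):
        from scipy.special import polygamma
        assert trigamma_inverse(float(polygamma(1, x))) == pytest.approx(x, rel=1e-6)


class TestVariancePrior:
    def test_identical_variances_give_infinite_prior_df(self):
        s2 = np.full(200, 1.7)
        d0, s0 = fit_variance_prior(s2, df=4)
        assert np.isinf(d0)
        assert s0 == pytest.approx(1.7, rel=1e-12)
        shrunk = _shrink_s2(s2[None, :], 4, np.array([d0]), np.array([s0]))
        np.testing.assert_allclose(shrunk, 1.7)

    def test_recovers_generating_parameters(self):
        # s2 ~ s0_sq * F(df, d0): the generating parameters are the oracle
        rng = np.random.default_rng(7)
        d0_true, s0_true, df = 4.0, 2.0, 6
        s2 = s0_true * rng.f(df, d0_true, size=5000)
        d0, s0 = fit_variance_prior(s2, df=df)
        assert d0 == pytest.approx(d0_true, rel=0.2)
        assert s0 == pytest.approx(s0_true, rel=0.2)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        s2 = 1.3 * rng.f(4, 8.0, size=2000)
        d0_a, s0_a = fit_variance_prior(s2, df=4)
        d0_b, s0_b = fit_variance_prior(17.0 * s2, df=4)
        assert d0_b == pytest.approx(d0_a, rel=1e-8)
        assert s0_b == pytest.approx(17.0 * s0_a, rel=1e-8)

    def test_few_genes_falls_back_to_no_shrinkage(self):
        d0, _ = fit_variance_prior(np.array([1.0, 2.0, 3.0]), df=4)
        assert d0 == 0.0


class TestModeratedT:
    def test_shrinkage_formula_direct_evaluation(self):
        # d0=4, s0_sq=1, df=2, s2=3: posterior variance (4 + 6)/6 = 1.6667,
        # t = 2 / sqrt(1.6667) = 1.5492 at unit standard-error scale
        shrunk = _shrink_s2(np.array([[3.0]]), 2, np.array([4.0]), np.array([1.0]))
        assert shrunk[0, 0] == pytest.approx(10.0 / 6.0, rel=1e-12)
        assert 2.0 / np.sqrt(shrunk[0, 0]) == pytest.approx(1.5492, abs=1e-4)

    def test_d0_zero_reduces_to_ordinary(self):
        rng = np.random.default_rng(5)
        ds = make_dataset(rng.standard_normal((50, 10)))
        st = moderated_t(ds, d0=0)
        np.testing.assert_allclose(st.t_moderated, st.t_ordinary, atol=1e-12)

    def test_zero_variance_gene_becomes_finite_under_shrinkage(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((60, 8))
        X[0] = np.tile([1.0, 1.0, 1.0, 1.0, 2.0, 2.0, 2.0, 2.0], 1)
        ds = make_dataset(X)
        st = moderated_t(ds)
        assert np.isinf(st.t_ordinary[0])
        assert np.isfinite(st.t_moderated[0])
        assert st.d0 > 0

    def test_sign_matches_effect(self):
        rng = np.random.default_rng(8)
        ds = make_dataset(rng.standard_normal((100, 12)))
        st = moderated_t(ds)
        nonzero = st.effect != 0
        assert np.all(np.sign(st.t_moderated[nonzero]) == np.sign(st.effect[nonzero]))

    def test_infinite_prior_orders_genes_by_absolute_effect(self):
        rng = np.random.default_rng(9)
        ds = make_dataset(rng.standard_normal((40, 10)))
        st = moderated_t(ds)
        forced = _shrink_s2(st.s2[None, :], st.df, np.array([np.inf]),
                            np.array([1.0]))[0]
        t_inf = st.effect / np.sqrt(forced) / st.se_unit
        order = np.argsort(np.abs(t_inf))
        np.testing.assert_array_equal(order, np.argsort(np.abs(st.effect)))


class TestAgainstLimma:
    """Independent oracle: the reference empirical-Bayes implementation in R."""

    def test_moderated_t_matches_limma(self, tmp_path):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((80, 8))
        X[:5] *= 0.05          # a few low-variance genes exercise the shrinkage
        ds = make_dataset(X)
        st = moderated_t(ds)

        expr = tmp_path / "x.tsv"
        np.savetxt(expr, X, delimiter="\t")
        script = tmp_path / "oracle.R"
        script.write_text(textwrap.dedent("""
            suppressMessages(library(limma))
            x <- as.matrix(read.delim('%s', header=FALSE))
            design <- cbind(1, c(rep(0, 4), rep(1, 4)))
            fit <- eBayes(lmFit(x, design))
            out <- cbind(fit$t[, 2], fit$df.prior, fit$s2.prior)
            write.table(out, '%s', sep='\\t', row.names=FALSE, col.names=FALSE)
        """ % (expr, tmp_path / "out.tsv")))
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = np.loadtxt(tmp_path / "out.tsv")
        np.testing.assert_allclose(st.t_moderated, ref[:, 0], rtol=1e-6)
        assert st.d0 == pytest.approx(ref[0, 1], rel=1e-6)
        assert st.s0_sq == pytest.approx(ref[0, 2], rel=1e-6)
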