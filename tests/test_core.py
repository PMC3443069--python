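import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from padog.core import (
    PadogConfig,
    WeightingConfig,
    bh_fdr,
    gene_frequencies,
    gene_weights,
    permutation_p,
    permutation_test,
    set_score,
    standardize_scores,
)
from padog.io import GeneSetCollection

from conftest import make_dataset


class TestFrequencies:
    def test_counts_sets_containing_each_gene(self):
        coll = GeneSetCollection({f"S{i}": [f"u{i}", "shared"] for i in range(50)})
        fw = gene_frequencies(coll, cap_quantile=1.0)
        f = dict(zip(fw.gene_ids, fw.f))
        assert f["u0"] == 1 and f["shared"] == 50

    def test_capping_replaces_tail_by_quantile_value(self):
        sets = {f"S{i}": [f"u{i}", "hub"] for i in range(100)}
        coll = GeneSetCollection(sets)
        fw = gene_frequencies(coll, cap_quantile=0.99)
        f = dict(zip(fw.gene_ids, fw.f))
        cap = np.quantile([1.0] * 100 + [100.0], 0.99)
        assert f["hub"] == pytest.approx(cap)
        assert fw.f_max == pytest.approx(cap)


class TestWeights:
    def _weights(self, f, alpha=0.5):
        from padog.core import GeneWeights
        f = np.asarray(f, float)
        gw = GeneWeights([f"g{i}" for i in range(len(f))], f, None,
                         float(f.min()), float(f.max()))
        return gene_weights(gw, WeightingConfig(cap_quantile=1.0, alpha=alpha)).w

    def test_extremes(self):
        w = self._weights([1, 3, 5])
        assert w[2] == pytest.approx(1.0)   # most frequent
        assert w[0] == pytest.approx(2.0)   # set-specific

    def test_midpoint_values(self):
        assert self._weights([1, 2, 3], alpha=1.0)[1] == pytest.approx(1.5)
        assert self._weights([1, 2, 3], alpha=0.5)[1] == pytest.approx(
            1.0 + np.sqrt(0.5))

    def test_all_equal_frequencies_give_unit_weights(self):
        np.testing.assert_allclose(self._weights([4, 4, 4]), 1.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        f=st.lists(st.integers(min_value=1, max_value=60), min_size=2, max_size=40),
        alpha=st.floats(min_value=0.1, max_value=3.0),
    )
    def test_bounded_and_monotone(self, f, alpha):
        w = self._weights(f, alpha=alpha)
        assert np.all((w >= 1.0) & (w <= 2.0))
        order = np.argsort(f)
        assert np.all(np.diff(w[order]) <= 1e-12)  # non-increasing in frequency


class TestSetScore:
    def test_weighted_mean(self):
        assert set_score([1.0, 2.0], [2.0, 1.0]) == pytest.approx(2.0)

    def test_unit_weights_reduce_to_mean_abs(self):
        vals = np.array([0.5, 1.5, 2.5])
        assert set_score(vals, np.ones(3)) == pytest.approx(vals.mean())

    def test_zero_scores(self):
        assert set_score([0.0, 0.0], [1.5, 2.0]) == 0.0

    def test_empty_set_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            set_score(np.array([]), np.array([]))


class TestStandardize:
    def test_sqrt_size_scaling(self):
        # same raw score, sizes 25 and 100: the larger set's standardized
        # score has twice the magnitude
        rng = np.random.default_rng(0)
        aw = rng.uniform(0.5, 2.0, size=500)
        S0 = np.array([aw.mean() + 0.3, aw.mean() + 0.3])
        row, _ = standardize_scores(S0, aw, np.array([25, 100]))
        assert row[1] / row[0] == pytest.approx(2.0, rel=1e-12)

    def test_double_standardization_scale_invariance(self):
        rng = np.random.default_rng(1)
        aw = rng.uniform(0.1, 3.0, size=300)
        S0 = rng.uniform(0.5, 2.0, size=10)
        sizes = np.full(10, 30)
        _, star1 = standardize_scores(S0, aw, sizes)
        _, star2 = standardize_scores(2.0 * S0, 2.0 * aw, sizes)
        np.testing.assert_allclose(star1, star2, atol=1e-10)

    def test_degenerate_equal_scores_map_to_zero(self, caplog):
        aw = np.array([1.0, 2.0, 3.0, 4.0])
        S0 = np.full(3, aw.mean())
        with caplog.at_level("WARNING"):
            row, star = standardize_scores(S0, aw, np.array([2, 2, 2]))
        np.testing.assert_allclose(row, 0.0, atol=1e-12)
        np.testing.assert_allclose(star, 0.0)


class TestBhFdr:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_fdr(np.array([0.01, 0.02, 0.03])),
                                   [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr(np.array([0.2])), [0.2])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr(np.ones(5)), 1.0)

    def test_q_at_least_p_and_in_unit_interval(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=40)
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-12) and np.all((q >= 0) & (q <= 1))


class TestPermutationP:
    def test_boundary_literal_and_add_one(self):
        star = np.vstack([[5.0], np.zeros((10, 1))])
        assert permutation_p(star)[0] == 0.0
        assert permutation_p(star, add_one=True)[0] == pytest.approx(1.0 / 11.0)

    def test_ties_count_against_significance(self):
        star = np.vstack([[1.0], [[1.0]], [[0.5]]])
        assert permutation_p(star)[0] == pytest.approx(0.5)


def brute_force_mean_abs_t(dataset, collection):
    """Independent oracle: enumerate all label assignments, score sets by the
    mean |pooled t| (no weights, no moderation), standardize twice, count."""
    X = dataset.matrix
    n = X.shape[1]
    case_obs = tuple(np.flatnonzero(dataset.is_case))
    n1 = len(case_obs)
    all_assignments = list(itertools.combinations(range(n), n1))

    def stars(case_idx):
        case = np.array(case_idx)
        ctrl = np.array([j for j in range(n) if j not in case_idx])
        t = np.array([
            sps.ttest_ind(X[g, case], X[g, ctrl], equal_var=True).statistic
            for g in range(X.shape[0])
        ])
        a = np.abs(t)
        gidx = {g: i for i, g in enumerate(dataset.gene_ids)}
        s0, sizes = [], []
        for genes in collection.sets.values():
            rows = [gidx[g] for g in genes]
            s0.append(a[rows].mean())
            sizes.append(len(rows))
        s0, sizes = np.array(s0), np.array(sizes)
        rowstd = (s0 - a.mean()) / (a.std(ddof=1) / np.sqrt(sizes))
        return (rowstd - rowstd.mean()) / rowstd.std(ddof=1)

    obs = stars(case_obs)
    perm = np.array([stars(c) for c in all_assignments if c != case_obs])
    return (perm >= obs[None, :]).mean(axis=0)


class TestExhaustiveEnumerationOracle:
    def test_sampling_engine_matches_brute_force(self, toy_dataset, toy_collection):
        """3v3 design: 20 assignments; the engine must enumerate and agree
        exactly with an independent loop/scipy reimplementation."""
        cfg = PadogConfig(n_perm=100, seed=0, use_weights=False,
                          use_moderated=False)
        res = permutation_test(toy_dataset, toy_collection, cfg)
        expected = brute_force_mean_abs_t(toy_dataset, toy_collection)
        got = res.set_index("set_id").loc[list(toy_collection.sets), "p"].to_numpy()
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_relabeling_case_control_leaves_p_unchanged(self, toy_dataset,
                                                        toy_collection):
        cfg = PadogConfig(n_perm=100, seed=3)
        res1 = permutation_test(toy_dataset, toy_collection, cfg)
        flipped = make_dataset(toy_dataset.matrix,
                               group=np.where(toy_dataset.is_case, "control", "case"))
        res2 = permutation_test(flipped, toy_collection, cfg)
        a = res1.set_index("set_id")["p"]
        b = res2.set_index("set_id")["p"]
        np.testing.assert_allclose(a, b[a.index], atol=1e-12)


class TestAblationVariants:
    def test_noMnoW_equals_mean_abs_ordinary_t(self, toy_dataset, toy_collection):
        from padog.stats import ordinary_t

        cfg = PadogConfig(n_perm=50, seed=1, use_weights=False, use_moderated=False)
        res = permutation_test(toy_dataset, toy_collection, cfg)
        st = ordinary_t(toy_dataset)
        a = np.abs(st.t_ordinary)
        gidx = {g: i for i, g in enumerate(toy_dataset.gene_ids)}
        for sid, genes in toy_collection.sets.items():
            expected = a[[gidx[g] for g in genes]].mean()
            got = float(res.set_index("set_id").loc[sid, "S0"])
            assert got == pytest.approx(expected, rel=1e-10)

    def test_weights_shared_across_permutations(self):
        # weights depend only on the collection, never on the labels
        coll = GeneSetCollection({"A": ["g0", "g1"], "B": ["g1", "g2"]})
        fw1 = gene_weights(gene_frequencies(coll, cap_quantile=1.0))
        fw2 = gene_weights(gene_frequencies(coll, cap_quantile=1.0))
        np.testing.assert_array_equal(fw1.w, fw2.w)


class TestDownweightingContrast:
    def test_set_with_unique_de_genes_scores_no_worse_than_shared(self):
        """Two equal-size sets with identical injected shifts: the one whose
        shifted genes are shared with a third set gets down-weighted, so the
        set with unique shifts earns the smaller (or equal) median p."""
        import padog.simulate as sim

        ps_unique, ps_shared = [], []
        for rep in range(8):
            ds = sim.make_null_dataset(n_genes=200, n_per_group=15, seed=100 + rep)
            ids = ds.gene_ids
            sets = {
                "UNIQ": ids[0:20], "SHARED": ids[20:40],
                "OTHER": ids[40:60] + ids[20:30],   # absorbs SHARED's DE genes
                "REST1": ids[60:80], "REST2": ids[80:100],
                "REST3": ids[100:120], "REST4": ids[120:140],
                "REST5": ids[140:160], "REST6": ids[160:180],
            }
            coll = GeneSetCollection(sets)
            spec = sim.ScenarioSpec(10, 0, 0.6)
            ds = sim.inject_effect(ds, spec, ids[0:20])     # genes 0-9 up
            ds = sim.inject_effect(ds, spec, ids[20:40])    # genes 20-29 up
            cfg = PadogConfig(n_perm=300, seed=rep)
            res = permutation_test(ds, coll, cfg,
                                   WeightingConfig(cap_quantile=1.0)).set_index("set_id")
            ps_unique.append(float(res.loc["UNIQ", "p"]))
            ps_shared.append(float(res.loc["SHARED", "p"]))
        assert np.median(ps_unique) <= np.median(ps_shared)
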