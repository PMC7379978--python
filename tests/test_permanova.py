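import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dietrep import nested_ss, pseudo_f, rrpp_test, two_group_permanova
from dietrep.permanova import TERMS, cube_to_units


def balanced_labels(I, J, K):
    ind = np.repeat([f"b{i}" for i in range(I)], J * K)
    pel = np.tile(np.repeat([f"p{j}" for j in range(J)], K), I)
    pcr = np.tile([f"r{k}" for k in range(K)], I * J)
    return ind, pel, pcr


def gower_center(Y):
    """-0.5 J D^2 J from squared Euclidean distances (oracle path)."""
    D2 = ((Y[:, None, :] - Y[None, :, :]) ** 2).sum(axis=2)
    n = len(Y)
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ D2 @ J


def hat(dummies):
    X = np.asarray(dummies, dtype=float)
    return X @ np.linalg.pinv(X)


def dummy(codes):
    codes, _ = pd.factorize(codes)
    return np.eye(codes.max() + 1)[codes]


class TestNestedSS:
    def test_identical_rows_all_zero(self):
        ind, pel, pcr = balanced_labels(3, 2, 2)
        Y = np.ones((12, 4))
        t = nested_ss(Y, (ind, pel, pcr)).to_frame()
        assert t.loc[TERMS, "SS"].tolist() == pytest.approx([0, 0, 0], abs=1e-12)

    def test_hand_example_two_individuals(self):
        # 2 individuals x 2 pellets x 1 PCR, one taxon, values (1,1 | 0,0)
        ind = np.array(["a", "a", "b", "b"])
        pel = np.array(["p1", "p2", "p1", "p2"])
        Y = np.array([[1.0], [1.0], [0.0], [0.0]])
        t = nested_ss(Y, (ind, pel)).to_frame()
        assert t.loc["individual", "SS"] == pytest.approx(1.0)
        assert t.loc["individual:pellet", "SS"] == pytest.approx(0.0)
        assert t.loc["total", "SS"] == pytest.approx(1.0)
        assert t.loc["individual", "R2"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_additivity(self, seed):
        g = np.random.default_rng(seed)
        ind, pel, pcr = balanced_labels(4, 3, 2)
        Y = (g.random((24, 6)) < 0.5).astype(float)
        t = nested_ss(Y, (ind, pel, pcr)).to_frame()
        assert t.loc[TERMS, "SS"].sum() == pytest.approx(
            t.loc["total", "SS"], abs=1e-10
        )

    def test_additivity_ragged(self):
        g = np.random.default_rng(7)
        ind = np.array(["a"] * 5 + ["b"] * 3 + ["c"] * 4)
        pel = np.array(["p1", "p1", "p2", "p2", "p3", "p1", "p1", "p2",
                        "p1", "p2", "p2", "p2"])
        Y = (g.random((12, 5)) < 0.5).astype(float)
        t = nested_ss(Y, (ind, pel)).to_frame()
        assert t.loc[TERMS, "SS"].sum() == pytest.approx(
            t.loc["total", "SS"], abs=1e-10
        )
        assert t.loc[TERMS, "df"].sum() + t.loc["residual", "df"] == len(Y) - 1

    def test_df_bookkeeping_balanced(self):
        ind, pel, pcr = balanced_labels(5, 4, 3)
        Y = np.random.default_rng(0).random((60, 3))
        t = nested_ss(Y, (ind, pel, pcr)).to_frame()
        assert t.loc["individual", "df"] == 4
        assert t.loc["individual:pellet", "df"] == 5 * 3
        assert t.loc["individual:pellet:pcr", "df"] == 20 * 2
        assert t.loc["total", "df"] == 59

    def test_gower_distance_matrix_oracle(self):
        """Data-space SS equals the trace form on the Gower-centered
        squared-distance matrix (McArdle-Anderson identity)."""
        g = np.random.default_rng(42)
        for _ in range(3):
            ind, pel, pcr = balanced_labels(5, 3, 2)
            Y = (g.random((30, 8)) < 0.4).astype(float)
            t = nested_ss(Y, (ind, pel, pcr)).to_frame()
            G = gower_center(Y)
            h1 = hat(np.ones((30, 1)))
            h_ind = hat(dummy(ind))
            pel_keys = [f"{a}|{b}" for a, b in zip(ind, pel)]
            h_pel = hat(dummy(pel_keys))
            ss_ind = np.trace(h_ind @ G) - np.trace(h1 @ G)
            ss_pel = np.trace(h_pel @ G) - np.trace(h_ind @ G)
            ss_pcr = np.trace(G) - np.trace(h_pel @ G)
            assert t.loc["individual", "SS"] == pytest.approx(ss_ind, abs=1e-8)
            assert t.loc["individual:pellet", "SS"] == pytest.approx(ss_pel, abs=1e-8)
            assert t.loc["individual:pellet:pcr", "SS"] == pytest.approx(
                ss_pcr, abs=1e-8
            )
            assert t.loc["total", "SS"] == pytest.approx(np.trace(G), abs=1e-8)

    def test_relabelling_invariance(self):
        g = np.random.default_rng(3)
        ind, pel, pcr = balanced_labels(4, 3, 2)
        Y = (g.random((24, 5)) < 0.5).astype(float)
        t1 = pseudo_f(nested_ss(Y, (ind, pel, pcr))).to_frame()
        perm = g.permutation(24)
        t2 = pseudo_f(nested_ss(Y[perm], (ind[perm], pel[perm], pcr[perm]))).to_frame()
        pd.testing.assert_frame_equal(
            t1[["df", "SS", "MS", "R2", "F"]], t2[["df", "SS", "MS", "R2", "F"]]
        )


class TestPseudoF:
    def make_table(self, ms=(8.0, 2.0, 1.0)):
        ind, pel, pcr = balanced_labels(3, 3, 2)
        Y = np.random.default_rng(0).random((18, 4))
        t = nested_ss(Y, (ind, pel, pcr))
        dfs = t.table.loc[TERMS, "df"]
        t.table.loc[TERMS, "MS"] = ms
        t.table.loc[TERMS, "SS"] = np.asarray(ms) * dfs.to_numpy()
        return t

    def test_next_nested_ratios(self):
        t = pseudo_f(self.make_table()).to_frame()
        assert t.loc["individual", "F"] == pytest.approx(4.0)
        assert t.loc["individual:pellet", "F"] == pytest.approx(2.0)
        assert np.isnan(t.loc["individual:pellet:pcr", "F"])

    def test_equal_ms_gives_unit_f(self):
        t = pseudo_f(self.make_table(ms=(2.0, 2.0, 1.0))).to_frame()
        assert t.loc["individual", "F"] == pytest.approx(1.0)

    def test_residual_scheme_saturated_warns(self):
        t = self.make_table()
        with pytest.warns(UserWarning, match="residual df"):
            t = pseudo_f(t, f_scheme="residual")
        assert t.to_frame().loc[TERMS, "F"].isna().all()

    def test_zero_denominator_inf(self):
        t = self.make_table(ms=(3.0, 0.0, 0.0))
        with pytest.warns(UserWarning, match="zero denominator"):
            t = pseudo_f(t)
        assert np.isinf(t.to_frame().loc["individual", "F"])

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            pseudo_f(self.make_table(), f_scheme="marginal")


class TestRRPP:
    def test_null_p_uniform(self):
        """Individual-term RRPP p over 200 structureless datasets is
        approximately Uniform(0,1) (KS at alpha = 0.01)."""
        g = np.random.default_rng(2024)
        ind, pel, pcr = balanced_labels(5, 3, 2)
        pvals = []
        for _ in range(200):
            Y = (g.random((30, 8)) < 0.5).astype(float)
            t = rrpp_test(
                Y, (ind, pel, pcr), B=199, seed=int(g.integers(2**31))
            )
            pvals.append(t["individual"]["p"])
        stat, p = stats.kstest(pvals, "uniform")
        assert p > 0.01

    def test_injected_effect_saturates_p(self):
        g = np.random.default_rng(5)
        ind, pel, pcr = balanced_labels(4, 3, 2)
        Y = (g.random((24, 6)) < 0.5).astype(float)
        Y[:6] += 10.0  # huge individual effect
        t = rrpp_test(Y, (ind, pel, pcr), B=999, seed=1)
        assert t["individual"]["p"] == pytest.approx(1 / 1000)

    def test_seed_determinism(self):
        g = np.random.default_rng(6)
        ind, pel, pcr = balanced_labels(4, 3, 2)
        Y = (g.random((24, 6)) < 0.5).astype(float)
        a = rrpp_test(Y, (ind, pel, pcr), B=99, seed=3).to_frame()
        b = rrpp_test(Y, (ind, pel, pcr), B=99, seed=3).to_frame()
        pd.testing.assert_frame_equal(a, b)

    def test_default_synthetic_ms_ordering(self, default_dataset):
        cube, _, _ = default_dataset
        Y, ind, pel, pcr = cube_to_units(cube)
        t = rrpp_test(Y, (ind, pel, pcr), B=99, seed=8)
        ms = t.to_frame().loc[TERMS, "MS"]
        assert ms["individual"] > ms["individual:pellet"] > ms["individual:pellet:pcr"]

    def test_bad_b_rejected(self):
        ind, pel, pcr = balanced_labels(2, 2, 2)
        with pytest.raises(ValueError):
            rrpp_test(np.zeros((8, 2)), (ind, pel, pcr), B=0)


class TestTwoGroup:
    def test_disjoint_constant_profiles_r2_one(self):
        Y = np.array([[1, 0]] * 4 + [[0, 1]] * 4, dtype=float)
        grp = ["a"] * 4 + ["b"] * 4
        f, r2, p = two_group_permanova(Y, grp, B=99, seed=0)
        assert r2 == pytest.approx(1.0)
        assert np.isinf(f)

    def test_identical_rows_warns(self):
        Y = np.ones((6, 3))
        with pytest.warns(UserWarning, match="identical"):
            f, r2, p = two_group_permanova(Y, ["a"] * 3 + ["b"] * 3, B=9, seed=0)
        assert np.isnan(f)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            two_group_permanova(np.zeros((3, 2)), ["a", "b", "b"], B=9)

    def test_three_groups_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            two_group_permanova(np.zeros((6, 2)), ["a", "b", "c"] * 2, B=9)

    def test_distance_matrix_oracle(self):
        g = np.random.default_rng(9)
        Y = (g.random((12, 5)) < 0.5).astype(float)
        grp = np.array(["a"] * 5 + ["b"] * 7)
        f, r2, p = two_group_permanova(Y, grp, B=99, seed=1)
        G = gower_center(Y)
        h = hat(dummy(grp))
        h1 = hat(np.ones((12, 1)))
        ss_b = np.trace(h @ G) - np.trace(h1 @ G)
        ss_tot = np.trace(G)
        ss_w = ss_tot - ss_b
        f_oracle = (ss_b / 1) / (ss_w / 10)
        assert f == pytest.approx(f_oracle, abs=1e-8)
        assert r2 == pytest.approx(ss_b / ss_tot, abs=1e-8)

    def test_null_p_uniformish(self):
        g = np.random.default_rng(10)
        pvals = []
        for _ in range(100):
            Y = (g.random((10, 4)) < 0.5).astype(float)
            _, _, p = two_group_permanova(
                Y, ["a"] * 5 + ["b"] * 5, B=99, seed=int(g.integers(2**31))
            )
            pvals.append(p)
        assert 0.2 < np.mean(pvals) < 0.8
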