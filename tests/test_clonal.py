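"""Kinship estimation, clone detection, the clonal randomization test and
broad-sense heritability."""

import itertools

import numpy as np
import pandas as pd
import pytest

from volatilome import simulate
from volatilome.clonal import (
    CloneDistanceTest,
    CloneHeritability,
    clone_randomization_test,
    compare_h2_sets,
    estimate_h2,
    estimate_kinship,
    identify_clones,
)


def _geno(rows, ids=None):
    arr = np.asarray(rows, dtype=float)
    ids = ids or [f"s{i}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=ids, columns=[f"m{j}" for j in range(arr.shape[1])])


class TestKinship:
    def test_single_snp_hand_value(self):
        # dosages (0, 2): p = 0.5, numerator (0-1)(2-1) = -1, denominator
        # 2 * 2 * 0.5 * 0.5 = 1 -> phi = -1
        K = estimate_kinship(_geno([[0.0], [2.0]]))
        assert K.iloc[0, 1] == pytest.approx(-1.0)
        assert K.iloc[0, 0] == pytest.approx(1.0)

    def test_symmetric_and_snp_order_invariant(self, rng):
        p = rng.uniform(0.1, 0.5, 200)
        G = _geno(rng.binomial(2, p, size=(8, 200)))
        K = estimate_kinship(G)
        assert np.allclose(K, K.T)
        shuffled = G.sample(frac=1.0, axis=1, random_state=0)
        assert np.allclose(estimate_kinship(shuffled), K)

    def test_monomorphic_snps_excluded(self):
        G = _geno([[0.0, 1.0], [0.0, 2.0], [0.0, 0.0]])
        K_all = estimate_kinship(G)
        K_poly = estimate_kinship(G[["m1"]])
        assert np.allclose(K_all, K_poly)
        with pytest.raises(ValueError):
            estimate_kinship(_geno([[2.0], [2.0]]))

    def test_missing_calls_handled_pairwise(self, rng):
        p = rng.uniform(0.2, 0.5, 500)
        G = rng.binomial(2, p, size=(6, 500)).astype(float)
        G[0, :250] = np.nan
        K = estimate_kinship(_geno(G))
        assert np.isfinite(K.to_numpy()).all()

    def test_clone_pair_near_half_unrelated_near_zero(self):
        # 200 unrelated + 1 duplicated genotype at 10,000 HWE SNPs; the
        # plug-in allele frequencies attenuate the clone value by O(1/n)
        rng = np.random.default_rng(5)
        p = rng.uniform(0.05, 0.5, 10_000)
        G = rng.binomial(2, p, size=(200, 10_000)).astype(float)
        G = np.vstack([G, G[0]])
        K = estimate_kinship(_geno(G))
        assert K.iloc[0, 200] == pytest.approx(0.5, abs=0.02)
        assert K.iloc[1, 2] == pytest.approx(0.0, abs=0.02)


class TestIdentifyClones:
    def test_no_clones_empty(self):
        K = pd.DataFrame(np.eye(4) * 1.0, index=list("abcd"), columns=list("abcd"))
        assert identify_clones(K).groups == []

    def test_chain_transitive_closure(self):
        K = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        K.loc["a", "b"] = K.loc["b", "a"] = 0.5
        K.loc["b", "c"] = K.loc["c", "b"] = 0.45
        clones = identify_clones(K)
        assert clones.groups == [("a", "b", "c")]

    def test_planted_groups_recovered(self, small_panel):
        geno = simulate.simulate_genotypes(small_panel, n_snps=2000, seed=4)
        clones = identify_clones(estimate_kinship(geno))
        truth = sorted(tuple(m) for m in small_panel.clone_groups().values())
        assert sorted(clones.groups) == truth
        # partition: no sample in two groups
        members = list(itertools.chain.from_iterable(clones.groups))
        assert len(members) == len(set(members)) == clones.n_members

    def test_name_agreement_flags(self):
        K = pd.DataFrame(np.eye(4), index=list("abcd"), columns=list("abcd"))
        K.loc["a", "b"] = K.loc["b", "a"] = 0.5
        K.loc["c", "d"] = K.loc["d", "c"] = 0.5
        names = pd.Series(["X", "X", "Y", "Z"], index=list("abcd"))
        clones = identify_clones(K, names=names)
        assert clones.name_agreement == [True, False]

    def test_triple_decomposes_to_three_pairs(self):
        K = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        for i, j in (("a", "b"), ("b", "c"), ("a", "c")):
            K.loc[i, j] = K.loc[j, i] = 0.5
        clones = identify_clones(K)
        assert len(clones.pairs(decompose=True)) == 3
        assert clones.pairs(decompose=False) == []


class TestRandomizationTest:
    def test_identical_clone_rows_give_p_zero(self, rng):
        X = pd.DataFrame(rng.normal(size=(12, 5)), index=[f"s{i}" for i in range(12)])
        X.iloc[1] = X.iloc[0]
        X.iloc[3] = X.iloc[2]
        res = clone_randomization_test(X, [("s0", "s1"), ("s2", "s3")], n_replicates=500, seed=0)
        assert res.observed == 0.0
        assert res.pvalue == 0.0

    def test_brute_force_enumeration_oracle(self, rng):
        # 4 samples, 1 clone pair: a null replicate draws one of the 6
        # unordered sample pairs uniformly; compare MC P with exact P
        X = pd.DataFrame(rng.normal(size=(4, 3)), index=list("abcd"))
        from scipy.spatial.distance import pdist, squareform

        D = squareform(pdist(X.to_numpy()))
        observed = D[0, 1]
        pairs = list(itertools.combinations(range(4), 2))
        exact = np.mean([D[i, j] < observed for i, j in pairs])
        res = clone_randomization_test(X, [("a", "b")], n_replicates=20_000, seed=1)
        assert res.pvalue == pytest.approx(exact, abs=0.02)

    def test_seed_determinism_and_echo(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 4)), index=[f"s{i}" for i in range(20)])
        pairs = [("s0", "s1"), ("s2", "s3")]
        r1 = clone_randomization_test(X, pairs, n_replicates=100, seed=7)
        r2 = CloneDistanceTest(X, pairs).fit(n_replicates=100, seed=7)
        assert r1.pvalue == r2.pvalue and r1.null_mean == r2.null_mean
        assert r1.n_replicates == 100 and r1.seed == 7

    def test_scaling_clone_distances_down_decreases_p(self, rng):
        # monotonicity: moving clone-mates closer can only lower P
        X = pd.DataFrame(rng.normal(size=(20, 4)), index=[f"s{i}" for i in range(20)])
        pairs = [("s0", "s1"), ("s2", "s3")]
        base = clone_randomization_test(X, pairs, n_replicates=2000, seed=3).pvalue
        Y = X.copy()
        for a, b in pairs:
            mid = (X.loc[a] + X.loc[b]) / 2
            Y.loc[a] = mid + (X.loc[a] - mid) * 0.1
            Y.loc[b] = mid + (X.loc[b] - mid) * 0.1
        closer = clone_randomization_test(Y, pairs, n_replicates=2000, seed=3).pvalue
        assert closer <= base

    def test_invalid_inputs(self, rng):
        X = pd.DataFrame(rng.normal(size=(4, 2)), index=list("abcd"))
        with pytest.raises(ValueError):
            clone_randomization_test(X, [], n_replicates=10)
        with pytest.raises(ValueError):
            clone_randomization_test(
                X, [("a", "b"), ("c", "d"), ("a", "c")], n_replicates=10
            )
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError):
            clone_randomization_test(X, [("a", "b")], n_replicates=10)


class TestHeritability:
    def test_perfect_repeatability(self):
        m = pd.DataFrame({"v": [1.0, 1.0, 5.0, 5.0]}, index=list("abcd"))
        t = estimate_h2(m, [("a", "b"), ("c", "d")])
        assert t.loc["v", "h2"] == pytest.approx(1.0)

    def test_hand_anova(self):
        # pairs (0,1),(1,0),(2,3),(3,2): MSB = 8/3, MSW = 1/2
        m = pd.DataFrame({"v": [0.0, 1.0, 1.0, 0.0, 2.0, 3.0, 3.0, 2.0]}, index=list("abcdefgh"))
        t = estimate_h2(m, [("a", "b"), ("c", "d"), ("e", "f"), ("g", "h")])
        assert t.loc["v", "msb"] == pytest.approx(8 / 3)
        assert t.loc["v", "msw"] == pytest.approx(0.5)
        assert t.loc["v", "h2"] == pytest.approx((8 / 3 - 0.5) / (8 / 3 + 0.5))

    def test_negative_estimate_reported(self):
        # within-pair variance only: MSB = 0, MSW = 1/2 -> H2 = -1
        m = pd.DataFrame({"v": [0.0, 1.0, 1.0, 0.0]}, index=list("abcd"))
        t = estimate_h2(m, [("a", "b"), ("c", "d")])
        assert t.loc["v", "h2"] == pytest.approx(-1.0)

    def test_missing_members_and_zero_variance_flagged(self):
        m = pd.DataFrame(
            {"v": [0.0, np.nan, 1.0, 0.0, 2.0, 2.1], "w": [1.0] * 6}, index=list("abcdef")
        )
        t = estimate_h2(m, [("a", "b"), ("c", "d"), ("e", "f")])
        assert t.loc["v", "n_groups"] == 2
        assert t.loc["w", "note"] == "zero_variance"
        assert np.isnan(t.loc["w", "h2"])

    def test_estimates_never_exceed_one(self, rng):
        for _ in range(20):
            vals = rng.normal(size=(10, 2))
            m = pd.DataFrame({"v": vals.reshape(-1)}, index=[f"s{i}" for i in range(20)])
            pairs = [(f"s{2 * i}", f"s{2 * i + 1}") for i in range(10)]
            h2 = estimate_h2(m, pairs).loc["v", "h2"]
            assert h2 <= 1.0

    def test_model_wrapper_summary(self, small_matrix, small_panel):
        pairs = [tuple(m[:2]) for m in small_panel.clone_groups().values()]
        res = CloneHeritability(small_matrix, pairs).fit()
        assert "heritability" in res.summary()
        assert len(res.table) == small_matrix.shape[1]


class TestCompareH2Sets:
    def _table(self, values):
        return pd.DataFrame(
            {"h2": values}, index=[f"v{i}" for i in range(len(values))]
        )

    def test_identical_tables(self, rng):
        t = self._table(rng.uniform(-0.5, 1.0, 20))
        out = compare_h2_sets(t, t)
        assert out["rho"] == pytest.approx(1.0)
        assert out["outliers"] == []

    def test_noisy_tables_still_concordant(self, rng):
        base = rng.uniform(0.0, 1.0, 60)
        out = compare_h2_sets(
            self._table(base), self._table(base + rng.normal(0, 0.05, 60))
        )
        assert out["rho"] > 0.9

    def test_shifted_volatile_flagged(self, rng):
        base = rng.uniform(0.0, 1.0, 10)
        shifted = base.copy()
        shifted[4] += 1.0
        out = compare_h2_sets(self._table(base), self._table(shifted), outlier_threshold=0.5)
        assert out["outliers"] == ["v4"]

    def test_too_few_shared_volatiles(self):
        with pytest.raises(ValueError):
            compare_h2_sets(self._table([0.1, 0.2]), self._table([0.1, 0.2]))
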