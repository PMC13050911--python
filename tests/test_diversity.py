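import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pollenet.diversity import (
    bray_curtis,
    chao1,
    faith_pd,
    permanova,
    rarefy,
    shannon,
    two_way_anova,
    venn_partition,
    welch_games_howell,
)
from pollenet.io_model import CountTable, RelAbundanceTable
from pollenet.synthetic import generate_tree


def _rel(arr, samples=None):
    arr = np.asarray(arr, dtype=float)
    idx = [f"t{i}" for i in range(arr.shape[0])]
    cols = samples or [f"s{i}" for i in range(arr.shape[1])]
    return RelAbundanceTable(
        values=pd.DataFrame(arr, index=idx, columns=cols),
        taxonomy=pd.Series("u", index=idx),
        domain="bacteria",
    )


class TestChao1:
    @pytest.mark.parametrize(
        "counts, expected",
        [([5, 3, 2], 3.0), ([5, 1, 1, 2], 4.5), ([0, 0, 0], 0.0)],
    )
    def test_bias_corrected_formula(self, counts, expected):
        assert chao1(counts) == pytest.approx(expected)

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            chao1([1.5, 2.0])

    def test_never_below_observed_richness_and_matches_skbio(self, rng):
        from skbio.diversity.alpha import chao1 as skbio_chao1

        for _ in range(50):
            x = rng.poisson(1.2, size=30)
            est = chao1(x)
            assert est >= (x > 0).sum()
            if (x == 1).sum() == 0:
                assert est == (x > 0).sum()
            assert est == pytest.approx(skbio_chao1(x, bias_corrected=True))


class TestShannon:
    def test_uniform_is_log_richness(self):
        assert shannon([5, 5, 5, 5]) == pytest.approx(np.log(4), abs=1e-5)

    def test_single_taxon_is_zero(self):
        assert shannon([7]) == 0.0

    def test_hand_value(self):
        assert shannon([1, 1, 2]) == pytest.approx(1.03972, abs=1e-5)

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError, match="positive library"):
            shannon([0, 0])


class TestFaithPD:
    def test_star_tree_unit_branches(self):
        ids = list("ABCD")
        tree = generate_tree(ids, star=True, branch_length=1.0)
        assert faith_pd([1, 1, 1, 0], ids, tree) == pytest.approx(3.0)

    def test_all_tips_is_total_branch_length(self):
        ids = [f"t{i}" for i in range(6)]
        tree = generate_tree(ids, seed=2)
        total = sum(n.length or 0.0 for n in tree.tree.traverse())
        assert faith_pd([1] * 6, ids, tree) == pytest.approx(total)

    def test_missing_taxon_named(self):
        ids = list("AB")
        tree = generate_tree(ids, star=True)
        with pytest.raises(ValueError, match="ghost"):
            faith_pd([1, 1, 1], ["A", "B", "ghost"], tree)

    def test_monotone_in_observed_set_and_matches_skbio(self, rng):
        from skbio.diversity.alpha import faith_pd as skbio_faith_pd

        ids = [f"t{i}" for i in range(10)]
        for seed in range(20):
            tree = generate_tree(ids, seed=seed)
            counts = np.zeros(10, dtype=int)
            last = 0.0
            order = rng.permutation(10)
            for k in order:
                counts[k] = 1
                pd_now = faith_pd(counts, ids, tree)
                assert pd_now >= last - 1e-12
                last = pd_now
            assert last == pytest.approx(
                skbio_faith_pd(counts, taxa=ids, tree=tree.tree), abs=1e-6
            )


class TestRarefy:
    def _table(self, cols):
        arr = np.asarray(cols)
        return CountTable(
            counts=pd.DataFrame(arr, index=[f"t{i}" for i in range(arr.shape[0])],
                                columns=[f"s{i}" for i in range(arr.shape[1])]),
            taxonomy=pd.Series("u", index=[f"t{i}" for i in range(arr.shape[0])]),
            domain="bacteria",
        )

    def test_library_equal_depth_unchanged(self):
        t = self._table([[10], [0], [10]])
        out, excluded = rarefy(t, 20, seed=0)
        assert out.counts["s0"].tolist() == [10, 0, 10]
        assert excluded == []

    def test_hypergeometric_expectation(self):
        t = self._table([[10], [0], [10]])
        sums = np.zeros(3)
        for seed in range(400):
            out, _ = rarefy(t, 10, seed=seed)
            sums += out.counts["s0"].to_numpy()
        np.testing.assert_allclose(sums / 400, [5, 0, 5], atol=0.3)

    def test_low_depth_samples_excluded_and_listed(self):
        t = self._table([[10, 3], [10, 2]])
        out, excluded = rarefy(t, 10, seed=0)
        assert out.sample_ids == ["s0"]
        assert excluded == [("s1", "library 5 < depth 10")]

    def test_depth_above_all_libraries_is_error(self):
        t = self._table([[4], [4]])
        with pytest.raises(ValueError, match="exceeds every library"):
            rarefy(t, 100)

    def test_never_increases_observed_richness(self, rng):
        arr = rng.poisson(3.0, size=(12, 3)) * rng.integers(0, 2, size=(12, 3))
        arr[0] += 30
        t = self._table(arr)
        out, _ = rarefy(t, 25, seed=1)
        for s in out.sample_ids:
            assert (out.counts[s] > 0).sum() <= (t.counts[s] > 0).sum()
            assert out.counts[s].sum() == 25


class TestVenn:
    def _fixture(self):
        counts = pd.DataFrame(
            {"o1": [1, 1, 0], "b1": [0, 1, 1]},
            index=["A", "B", "C"],
        )
        t = CountTable(counts=counts, taxonomy=pd.Series("u", index=["A", "B", "C"]),
                       domain="bacteria")
        meta = pd.DataFrame({
            "sample_id": ["o1", "b1"],
            "species": ["CA", "CA"],
            "treatment": ["open", "bagging"],
            "pollination": ["self", "self"],
            "replicate": [1, 1],
        })
        return t, meta

    def test_shared_and_unique_enumeration(self):
        t, meta = self._fixture()
        v = venn_partition(t, meta, "CA")
        assert (v["n_shared"], v["n_unique_open"], v["n_unique_bagging"]) == (1, 1, 1)
        assert v["pct_unique_open"] == pytest.approx(50.0)

    def test_identical_and_disjoint_pools(self):
        t, meta = self._fixture()
        t.counts["b1"] = t.counts["o1"]
        assert venn_partition(t, meta, "CA")["pct_unique_open"] == 0.0
        t.counts["o1"] = [1, 0, 0]
        t.counts["b1"] = [0, 0, 1]
        v = venn_partition(t, meta, "CA")
        assert v["pct_unique_open"] == 100.0
        assert v["pct_unique_bagging"] == 100.0

    def test_absent_species_is_error(self):
        t, meta = self._fixture()
        with pytest.raises(ValueError, match="MC"):
            venn_partition(t, meta, "MC")


def _meta_2x2(reps=2):
    rows = []
    for sp, pol in (("CA", "self"), ("LA", "cross")):
        for tr in ("open", "bagging"):
            for r in range(reps):
                rows.append({"sample_id": f"{sp}_{tr}_{r}", "species": sp,
                             "treatment": tr, "pollination": pol, "replicate": r})
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_constant_response_gives_zero_f(self):
        meta = _meta_2x2()
        values = pd.Series(3.0, index=meta.sample_id)
        res = two_way_anova(values, meta)
        assert (res.effects["F"] == 0).all()
        assert (res.effects["p"] == 1).all()

    def test_matches_hand_computed_sums_of_squares(self):
        # 2x2 with 2 replicates; cell means 10, 12, 20, 26
        meta = _meta_2x2()
        data = {"CA_open_0": 9, "CA_open_1": 11, "CA_bagging_0": 11,
                "CA_bagging_1": 13, "LA_open_0": 19, "LA_open_1": 21,
                "LA_bagging_0": 25, "LA_bagging_1": 27}
        values = pd.Series(data, dtype=float)
        res = two_way_anova(values, meta)
        # hand ANOVA: SS_species = 8*(17-12.? ...) computed directly:
        y = values.to_numpy()
        grand = y.mean()
        means_sp = {"CA": 11.0, "LA": 23.0}
        means_tr = {"open": 15.0, "bagging": 19.0}
        ss_sp = 4 * sum((m - grand) ** 2 for m in means_sp.values())
        ss_tr = 4 * sum((m - grand) ** 2 for m in means_tr.values())
        cell = {("CA", "open"): 10, ("CA", "bagging"): 12,
                ("LA", "open"): 20, ("LA", "bagging"): 26}
        ss_int = 2 * sum(
            (cell[(s, t)] - means_sp[s] - means_tr[t] + grand) ** 2
            for s in means_sp for t in means_tr
        )
        ss_err = 8.0  # each obs deviates by 1 from its cell mean
        f_sp = (ss_sp / 1) / (ss_err / 4)
        f_tr = (ss_tr / 1) / (ss_err / 4)
        f_int = (ss_int / 1) / (ss_err / 4)
        assert res.effects.loc["species", "F"] == pytest.approx(f_sp)
        assert res.effects.loc["treatment", "F"] == pytest.approx(f_tr)
        assert res.effects.loc["treatment:species", "F"] == pytest.approx(f_int)

    def test_additive_shift_yields_small_interaction(self, rng):
        meta = _meta_2x2(reps=5)
        base = pd.Series(rng.normal(0, 0.1, len(meta)), index=meta.sample_id)
        base[meta.set_index("sample_id").species == "LA"] += 10.0
        res = two_way_anova(base, meta)
        assert res.effects.loc["species", "F"] > 100
        assert res.effects.loc["treatment:species", "F"] < 5

    def test_single_replicate_cell_flagged(self):
        meta = _meta_2x2(reps=1)
        values = pd.Series(range(len(meta)), index=meta.sample_id, dtype=float)
        res = two_way_anova(values, meta)
        assert any("interaction unavailable" in n for n in res.notes)
        assert "treatment:species" not in res.effects.index


class TestWelchGamesHowell:
    def test_identical_groups_zero_f(self):
        vals = [1.0, 2.0, 3.0] * 3
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = welch_games_howell(vals, labels)
        assert res.effects.loc["group", "F"] == pytest.approx(0.0, abs=1e-12)
        assert len(set(res.letters.values())) == 1

    def test_two_groups_equals_welch_t_test(self, rng):
        a = rng.normal(0, 1, 8)
        b = rng.normal(1, 3, 6)
        res = welch_games_howell(np.r_[a, b], ["a"] * 8 + ["b"] * 6)
        t_p = stats.ttest_ind(a, b, equal_var=False).pvalue
        assert res.effects.loc["group", "p"] == pytest.approx(t_p, rel=1e-6)

    def test_strongly_shifted_group_gets_own_letter(self, rng):
        a = rng.normal(0, 1, 6)
        b = rng.normal(0.2, 1, 6)
        c = rng.normal(10, 1, 6)
        res = welch_games_howell(np.r_[a, b, c], ["a"] * 6 + ["b"] * 6 + ["c"] * 6)
        assert res.letters["c"] not in (res.letters["a"], res.letters["b"])
        assert set(res.letters["a"]) & set(res.letters["b"])

    def test_zero_variance_group_suggests_tie_handling(self):
        with pytest.raises(ValueError, match="exact tie"):
            welch_games_howell([1, 1, 1, 2, 3, 4], ["a"] * 3 + ["b"] * 3)


class TestBrayCurtis:
    def test_identical_disjoint_and_hand_value(self):
        rel = _rel(np.array([[0.5, 0.5, 0.0, 1.0],
                             [0.5, 0.5, 0.5, 0.0],
                             [0.0, 0.0, 0.5, 0.0]]))
        d = bray_curtis(rel)
        assert d.iloc[0, 1] == pytest.approx(0.0)
        assert d.iloc[0, 3] == pytest.approx(0.5)  # overlapping support, hand value
        assert d.iloc[2, 3] == pytest.approx(1.0)  # disjoint supports

    def test_bounds_symmetry_zero_diagonal(self, rng):
        arr = rng.dirichlet(np.ones(6), size=5).T
        d = bray_curtis(_rel(arr)).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert ((d >= -1e-12) & (d <= 1 + 1e-12)).all()


class TestPermanova:
    def _distance(self, arr):
        return bray_curtis(_rel(arr))

    def test_duplicated_distinct_groups_r2_near_one(self):
        a = np.array([0.9, 0.1, 0.0])
        b = np.array([0.0, 0.1, 0.9])
        arr = np.c_[a, a, a, b, b, b] + 1e-6
        arr /= arr.sum(axis=0)
        res = permanova(self._distance(arr), ["g1"] * 3 + ["g2"] * 3,
                        n_permutations=99, seed=0)
        assert res.r2 > 0.99

    def test_r2_invariant_to_label_renaming(self, rng):
        arr = rng.dirichlet(np.ones(5), size=8).T
        d = self._distance(arr)
        r1 = permanova(d, ["x"] * 4 + ["y"] * 4, n_permutations=99, seed=1)
        r2 = permanova(d, ["y"] * 4 + ["x"] * 4, n_permutations=99, seed=1)
        assert r1.r2 == pytest.approx(r2.r2)
        assert r1.pseudo_f == pytest.approx(r2.pseudo_f)

    def test_p_resolution_and_floor(self, rng):
        arr = rng.dirichlet(np.ones(5), size=8).T
        res = permanova(self._distance(arr), ["x"] * 4 + ["y"] * 4,
                        n_permutations=99, seed=2)
        assert res.p_value >= 1 / 100
        assert (res.p_value * 100) == pytest.approx(round(res.p_value * 100))

    def test_pseudo_f_matches_skbio(self, rng):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova

        arr = rng.dirichlet(np.ones(6), size=9).T
        d = self._distance(arr)
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        ours = permanova(d, labels, n_permutations=99, seed=0)
        theirs = skbio_permanova(DistanceMatrix(d.to_numpy(), ids=d.index),
                                 grouping=labels, permutations=99)
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_single_group_is_error(self, rng):
        arr = rng.dirichlet(np.ones(4), size=4).T
        with pytest.raises(ValueError, match="2 groups"):
            permanova(self._distance(arr), ["g"] * 4)
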