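from itertools import combinations, product

import numpy as np
import pandas as pd
import pytest

import tissuedecoder as td
from tissuedecoder.phenostats import group_z_score


def exact_signed_rank_p(d: np.ndarray) -> float:
    """Enumerate all 2^n sign patterns of the |differences| ranks."""
    d = d[d != 0]
    ranks = pd.Series(np.abs(d)).rank().to_numpy()
    w_obs = ranks[d > 0].sum()
    n = len(d)
    stats = []
    for signs in product([0, 1], repeat=n):
        stats.append(sum(r for r, s in zip(ranks, signs) if s))
    stats = np.asarray(stats)
    mu = stats.mean()
    # two-sided: patterns at least as extreme as observed, by distance from mean
    p = np.mean(np.abs(stats - mu) >= abs(w_obs - mu) - 1e-12)
    return float(p)


def exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Enumerate all C(n1+n2, n1) group assignments of the pooled ranks."""
    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank().to_numpy()
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    stats = [
        sum(ranks[i] for i in comb)
        for comb in combinations(range(len(pooled)), n1)
    ]
    stats = np.asarray(stats)
    mu = stats.mean()
    return float(np.mean(np.abs(stats - mu) >= abs(w_obs - mu) - 1e-12))


class TestPairedTest:
    def test_identical_pairs_give_p_one(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        r = td.paired_test(x, x)
        assert r.p == 1.0
        assert r.effect == 0.0

    def test_all_positive_n5_exact(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = x - np.array([0.5, 0.6, 0.7, 0.8, 0.9])
        r = td.paired_test(x, y)
        assert r.p == pytest.approx(2 / 32)

    @pytest.mark.parametrize("n", [4, 6, 8])
    def test_matches_enumeration_oracle(self, n, rng):
        for _ in range(10):
            d = rng.normal(0.3, 1.0, size=n)
            while np.unique(np.abs(d)).size < n or (d == 0).any():
                d = rng.normal(0.3, 1.0, size=n)
            x = rng.uniform(0, 1, size=n)
            r = td.paired_test(x + d, x)
            assert r.p == pytest.approx(exact_signed_rank_p(d), abs=1e-12)

    def test_power_on_shifted_pairs(self, rng):
        hits = 0
        reps = 50
        for _ in range(reps):
            x = rng.normal(0, 1, size=50)
            y = x + rng.normal(1.0, 1.0, size=50)  # shift of one SD
            if td.paired_test(y, x).p < 0.05:
                hits += 1
        assert hits / reps > 0.8

    def test_monotone_transform_invariance(self, rng):
        # signed ranks depend only on difference ranks, so a common positive
        # rescaling of the differences leaves p unchanged
        x = rng.uniform(0, 1, size=12)
        d = rng.normal(0.2, 0.5, size=12)
        p1 = td.paired_test(x + d, x).p
        p2 = td.paired_test(x + 7 * d, x).p
        assert p1 == pytest.approx(p2)


class TestUnpairedTest:
    def test_identical_groups_give_p_one(self):
        x = np.array([0.1, 0.2, 0.3])
        r = td.unpaired_test(x, x)
        assert r.p == 1.0

    def test_complete_separation_exact(self):
        r = td.unpaired_test(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert r.p == pytest.approx(0.1)  # 2 / C(6,3)

    @pytest.mark.parametrize("n1,n2", [(3, 4), (4, 4), (5, 3)])
    def test_matches_enumeration_oracle(self, n1, n2, rng):
        for _ in range(10):
            x = rng.normal(0.5, 1.0, size=n1)
            y = rng.normal(0.0, 1.0, size=n2)
            r = td.unpaired_test(x, y)
            assert r.p == pytest.approx(exact_rank_sum_p(x, y), abs=1e-12)

    def test_tie_heavy_data_matches_permutation_oracle(self, rng):
        x = rng.integers(0, 4, size=12).astype(float)
        y = rng.integers(1, 5, size=10).astype(float)
        r = td.unpaired_test(x, y)
        # Monte-Carlo permutation of group assignment
        pooled = np.concatenate([x, y])
        ranks = pd.Series(pooled).rank().to_numpy()
        w_obs = ranks[:12].sum()
        mu = ranks.mean() * 12
        n_mc = 20000
        hits = 0
        for _ in range(n_mc):
            perm = rng.permutation(ranks)
            if abs(perm[:12].sum() - mu) >= abs(w_obs - mu) - 1e-12:
                hits += 1
        p_mc = hits / n_mc
        assert r.p == pytest.approx(p_mc, abs=0.02)

    def test_rank_invariance_under_monotone_transform(self, rng):
        x = rng.uniform(0.01, 0.99, size=8)
        y = rng.uniform(0.01, 0.99, size=9)
        p1 = td.unpaired_test(x, y).p
        p2 = td.unpaired_test(np.log(x), np.log(y)).p
        assert p1 == pytest.approx(p2)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            td.unpaired_test(np.array([1.0, 2.0]), np.array([1.0, 2, 3]))


class TestSpearmanPerm:
    def test_perfect_monotone_gives_floor_p(self):
        x = np.arange(10.0)
        r = td.spearman_perm(x, np.exp(x), n_perm=99, seed=0)
        assert r.statistic == pytest.approx(1.0)
        assert r.p == pytest.approx(1 / 100)

    def test_rho_matches_closed_form_on_untied_data(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        r = td.spearman_perm(x, y, n_perm=99, seed=0)
        rx = pd.Series(x).rank()
        ry = pd.Series(y).rank()
        d2 = ((rx - ry) ** 2).sum()
        n = 20
        rho_closed = 1 - 6 * d2 / (n * (n**2 - 1))
        assert r.statistic == pytest.approx(rho_closed, abs=1e-12)

    def test_null_type_one_error_calibrated(self, rng):
        n_reps, n = 300, 30
        rejections = 0
        for i in range(n_reps):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            if td.spearman_perm(x, y, n_perm=199, seed=i).p <= 0.05:
                rejections += 1
        assert 0.02 <= rejections / n_reps <= 0.08

    def test_degenerate_covariate_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            td.spearman_perm(np.ones(10), np.arange(10.0), n_perm=99)

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError, match="99"):
            td.spearman_perm(np.arange(5.0), np.arange(5.0), n_perm=10)


class TestAdjustBH:
    @staticmethod
    def _results(ps):
        return [
            td.AssociationResult(f"c{i}", "t", "rank_sum", 0.0, 0.0, p)
            for i, p in enumerate(ps)
        ]

    def test_single_p_unchanged(self):
        res = td.adjust_bh(self._results([0.012]))
        assert res[0].p_adj == pytest.approx(0.012)

    def test_hand_computed_example(self):
        res = td.adjust_bh(self._results([0.01, 0.02, 0.03, 0.04]))
        assert [r.p_adj for r in res] == pytest.approx([0.04] * 4)

    def test_all_ones_stay_one(self):
        res = td.adjust_bh(self._results([1.0, 1.0, 1.0]))
        assert all(r.p_adj == 1.0 for r in res)

    def test_never_decreases_and_order_preserved(self, rng):
        ps = rng.uniform(size=40)
        res = td.adjust_bh(self._results(list(ps)))
        for r in res:
            assert r.p_adj >= r.p
        order = np.argsort(ps)
        adj_sorted = np.array([res[i].p_adj for i in order])
        assert (np.diff(adj_sorted) >= -1e-12).all()


class TestZScoreAndAssociate:
    def test_z_score_is_mean_gap_over_pooled_sd(self, rng):
        x = rng.normal(1.0, 1.0, size=30)
        y = rng.normal(0.0, 1.0, size=25)
        z = group_z_score(x, y)
        pooled_sd = np.concatenate([x, y]).std(ddof=1)
        assert z == pytest.approx((x.mean() - y.mean()) / pooled_sd)

    def test_associate_grid_null_and_planted_effect(self, rng):
        k = 4
        fracs = pd.DataFrame(
            rng.dirichlet(np.ones(k) * 5, size=60),
            columns=[f"ct{i}" for i in range(k)],
            index=[f"s{i}" for i in range(60)],
        )
        pheno, shifted = td.simulate_phenotypes(
            fracs, td.EffectSpec(shifts={"ct0": 0.25}), seed=1
        )
        table = td.associate(shifted, pheno, group_trait="group")
        assert len(table) == k
        row = table.set_index("cell_type").loc["ct0"]
        assert row["p"] < 0.01
        assert row["z_score"] < 0  # group A lacks the shift planted into B
        assert (table["p_adj"] >= table["p"] - 1e-12).all()

    def test_associate_paired_design(self, rng):
        k = 3
        fracs = pd.DataFrame(
            rng.dirichlet(np.ones(k) * 5, size=20),
            columns=[f"ct{i}" for i in range(k)],
            index=[f"subj{i}" for i in range(20)],
        )
        pheno, shifted = td.simulate_phenotypes(
            fracs, td.EffectSpec(shifts={"ct1": 0.2}, paired=True), seed=2
        )
        table = td.associate(shifted, pheno, group_trait="group", paired=True)
        row = table.set_index("cell_type").loc["ct1"]
        assert row["test"] == "signed_rank"
        assert row["p"] < 0.01
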