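import itertools

import numpy as np
import pandas as pd
import pytest

from gradedcat import (
    dif_scan,
    generate_cohort,
    local_dependence_q3,
    lord_wingersky,
    modal_category_check,
    mokken_analysis,
    simulate_responses,
    sx2_item_fit,
)
from gradedcat.bank import GradedItem, ItemBank
from gradedcat.estimation import DEFAULT_GRID
from gradedcat.grm import category_probabilities


class TestMokken:
    def test_guttman_scale_is_perfect(self):
        """Items that are deterministic step functions of a common rank
        scale perfectly: H = H_i = 1, no monotonicity violations."""
        rank = np.repeat(np.arange(10), 12)
        data = pd.DataFrame(
            {
                "I1": 1 + (rank >= 3).astype(int),
                "I2": 1 + (rank >= 5).astype(int) + (rank >= 8).astype(int),
                "I3": 1 + (rank >= 2).astype(int) + (rank >= 6).astype(int),
            }
        )
        res = mokken_analysis(data, minsize=12)
        assert res.H == pytest.approx(1.0)
        assert np.allclose(res.H_i, 1.0)
        assert res.monotonicity_violations.sum() == 0

    def test_independent_items_scale_near_zero(self, rng):
        data = pd.DataFrame(
            {f"I{j}": rng.integers(1, 6, size=5000) for j in range(6)}
        )
        res = mokken_analysis(data)
        assert abs(res.H) < 0.05

    def test_pairwise_h_matches_permutation_oracle(self):
        """H_ij against brute force: max covariance over all couplings of
        the two margins, found by enumerating permutations."""
        x = np.array([1, 1, 2, 3, 3, 2])
        y = np.array([2, 1, 1, 2, 2, 1])
        data = pd.DataFrame({"A": x, "B": y})
        res = mokken_analysis(data, minsize=6)
        cov = np.mean(x * y) - x.mean() * y.mean()
        cov_max = max(
            np.mean(x * np.array(p)) - x.mean() * y.mean()
            for p in itertools.permutations(y)
        )
        assert res.H_ij.loc["A", "B"] == pytest.approx(cov / cov_max)
        assert res.H_ij.loc["B", "A"] == pytest.approx(cov / cov_max)

    def test_zero_variance_item_rejected(self):
        data = pd.DataFrame({"A": [1, 2, 3, 2], "B": [2, 2, 2, 2]})
        with pytest.raises(ValueError, match="zero-variance"):
            mokken_analysis(data)

    def test_model_consistent_data_meet_published_criterion(self, cohort):
        res = mokken_analysis(cohort.responses)
        assert res.H > 0.50


class TestLocalDependence:
    def test_unidimensional_data_mostly_clean(self, bank, cohort):
        res = local_dependence_q3(cohort.responses, bank)
        n_pairs = len(bank) * (len(bank) - 1) // 2
        assert 1 - len(res.flagged_pairs) / n_pairs >= 0.95
        # symmetric with empty diagonal
        mat = res.residual_correlations
        assert np.allclose(mat.values, mat.values.T, equal_nan=True)
        assert mat.isna().values.diagonal().all()

    def test_duplicate_item_pair_flagged(self, bank, cohort):
        resp = cohort.responses.copy()
        resp["AAQ_dup"] = resp["AAQ_06"]
        dup = GradedItem(id="AAQ_dup", a=bank["AAQ_06"].a, b=bank["AAQ_06"].b)
        bigger = ItemBank(tuple(bank) + (dup,))
        res = local_dependence_q3(resp, bigger)
        assert ("AAQ_06", "AAQ_dup", pytest.approx(res.residual_correlations.loc["AAQ_06", "AAQ_dup"])) in [
            (a, b, pytest.approx(r)) for a, b, r in res.flagged_pairs
        ]

    def test_degenerate_item_rejected(self, bank, cohort):
        resp = cohort.responses.copy()
        resp["AAQ_01"] = 1
        with pytest.raises(ValueError, match="categories"):
            local_dependence_q3(resp, bank)


class TestLordWingersky:
    def test_two_binary_items_closed_form(self):
        i1 = GradedItem(id="A", a=1.7, b=(0.3,))
        i2 = GradedItem(id="B", a=0.9, b=(-0.5,))
        th = 0.4
        p1 = category_probabilities(i1, th)[1]
        p2 = category_probabilities(i2, th)[1]
        dist = lord_wingersky([i1, i2], th)
        expected = [(1 - p1) * (1 - p2), p1 * (1 - p2) + (1 - p1) * p2, p1 * p2]
        np.testing.assert_allclose(dist, expected, atol=1e-14)

    def test_three_item_enumeration_oracle(self, toy_bank):
        """Marginal summed-score distribution equals exhaustive pattern
        enumeration integrated over the quadrature prior."""
        nodes, w = DEFAULT_GRID.nodes, DEFAULT_GRID.weights
        marg = w @ lord_wingersky(list(toy_bank), nodes)
        ms = [it.n_categories for it in toy_bank]
        enum = np.zeros(sum(ms) - len(ms) + 1)
        for pattern in itertools.product(*[range(1, m + 1) for m in ms]):
            pq = np.ones_like(nodes)
            for it, k in zip(toy_bank, pattern):
                pq = pq * category_probabilities(it, nodes)[:, k - 1]
            enum[sum(pattern) - len(ms)] += w @ pq
        np.testing.assert_allclose(marg, enum, atol=1e-10)

    def test_probability_conserved_at_every_node(self, bank):
        nodes = DEFAULT_GRID.nodes
        dist = lord_wingersky(list(bank), nodes)
        np.testing.assert_allclose(dist.sum(axis=-1), 1.0, atol=1e-12)


class TestSX2:
    def test_model_consistent_data_pass_published_criterion(self, bank, cohort):
        res = sx2_item_fit(cohort.responses, bank)
        assert res.table["df"].min() >= 1
        assert not res.table["flagged"].any()

    def test_type_one_rate_near_nominal(self, bank):
        """With the true generating parameters, rejection at alpha=0.05
        stays in a loose nominal band across seeded replicates."""
        rej = n = 0
        for rep in range(20):
            c = generate_cohort(bank, n=1408, seed=500 + rep)
            t = sx2_item_fit(c.responses, bank, params_estimated=False).table
            rej += int((t.p_value < 0.05).sum())
            n += len(t)
        assert 0.01 <= rej / n <= 0.10

    def test_misfitting_item_detected(self, bank, cohort):
        """Replacing one item's responses with noise produces gross
        misfit for that item."""
        rng = np.random.default_rng(77)
        resp = cohort.responses.copy()
        resp["AAQ_06"] = rng.integers(1, 6, size=len(resp))
        res = sx2_item_fit(resp, bank)
        assert res.table.loc["AAQ_06", "flagged"]


@pytest.fixture(scope="module")
def two_groups(bank):
    ga = generate_cohort(bank, n=700, seed=61)
    gb = generate_cohort(bank, n=700, seed=62)
    resp = pd.concat([ga.responses, gb.responses]).reset_index(drop=True)
    groups = pd.Series(["A"] * 700 + ["B"] * 700, index=resp.index)
    return resp, groups


class TestDIF:
    def test_no_dif_under_common_model(self, bank, two_groups):
        resp, groups = two_groups
        res = dif_scan(resp, groups, bank)
        assert (res.table["r2_change"].dropna() < 0.02).all()
        assert res.table["r2_change"].dropna().min() >= 0.0

    def test_injected_uniform_dif_flagged(self, bank):
        """Shifting one item's thresholds by +1 in group B produces a
        detectable pseudo-R2 change for that item only."""
        aaq06 = bank["AAQ_06"]
        shifted_item = GradedItem(
            id="AAQ_06", a=aaq06.a, b=tuple(t + 1.0 for t in aaq06.b)
        )
        shifted_bank = ItemBank(
            tuple(shifted_item if it.id == "AAQ_06" else it for it in bank)
        )
        ga = generate_cohort(bank, n=700, seed=63)
        gb = generate_cohort(shifted_bank, n=700, seed=64)
        resp = pd.concat([ga.responses, gb.responses]).reset_index(drop=True)
        groups = pd.Series(["A"] * 700 + ["B"] * 700, index=resp.index)
        res = dif_scan(resp, groups, bank)
        assert res.table.loc["AAQ_06", "r2_change"] >= 0.02

    def test_label_symmetry(self, bank, two_groups):
        resp, groups = two_groups
        idx = list(range(200)) + list(range(700, 900))  # 200 from each group
        sub = resp.iloc[idx]
        gsub = groups.iloc[idx]
        res1 = dif_scan(sub, gsub, bank)
        res2 = dif_scan(sub, gsub.map({"A": "B", "B": "A"}), bank)
        np.testing.assert_allclose(
            res1.table["r2_change"].to_numpy(dtype=float),
            res2.table["r2_change"].to_numpy(dtype=float),
            atol=1e-6,
        )

    def test_non_binary_groups_rejected(self, bank, cohort):
        groups = pd.Series(np.arange(len(cohort.responses)) % 3,
                           index=cohort.responses.index)
        with pytest.raises(ValueError, match="binary"):
            dif_scan(cohort.responses, groups, bank)


class TestModalCategories:
    def test_well_separated_item_unflagged(self):
        item = GradedItem(id="W", a=2.0, b=(-2.0, 0.0, 2.0))
        assert modal_category_check(ItemBank((item,)))["W"] == []

    def test_crowded_middle_category_flagged(self):
        item = GradedItem(id="C", a=2.0, b=(0.0, 0.1, 2.0))
        assert modal_category_check(ItemBank((item,)))["C"] == [2]

    def test_bundled_bank_flags_four_items(self, bank):
        """The never-modal scan reproduces the published count of four
        items with disordered-looking categories."""
        out = modal_category_check(bank)
        flagged = [k for k, v in out.items() if v]
        assert len(flagged) == 4
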