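import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from omicstack import (
    FeatureSetCollection,
    bh_adjust,
    hypergeometric_ora,
    lme_longitudinal,
    rank_test_early,
)
from omicstack.univariate import read_gmt
from tests.conftest import longitudinal_cohort


def bh_stepup_oracle(p):
    """Hand implementation of the step-up formula
    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestBHAdjust:
    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_stepup_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            m = int(rng.integers(1, 100))
            p = rng.random(m)
            np.testing.assert_allclose(bh_adjust(p), bh_stepup_oracle(p),
                                       atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])

    def test_false_discovery_proportion_controlled_under_the_null(self):
        """On fully null tables every rejection is false; the mean FDP at
        q < 0.05 must not exceed 0.05."""
        rng = np.random.default_rng(0)
        fdp = []
        for _ in range(500):
            q = bh_adjust(rng.random(100))
            fdp.append(float((q < 0.05).any()))
        mean = np.mean(fdp)
        se = np.std(fdp, ddof=1) / np.sqrt(len(fdp))
        assert mean <= 0.05 + 2 * se


def ranksum_enumeration_p(a, b):
    """Exact two-sided rank-sum p by enumerating all C(n1+n2, n1) label
    assignments of the pooled sample."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1 = len(a)
    obs = ranks[:n1].sum()
    mean = n1 * (len(pooled) + 1) / 2
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(ranks[list(idx)].sum() - mean) >= abs(obs - mean) - 1e-9:
            count += 1
    return count / total


class TestRankTestEarly:
    def _cohort(self, case_vals, ctrl_vals):
        n = len(case_vals) + len(ctrl_vals)
        y = np.r_[np.ones(len(case_vals), dtype=int),
                  np.zeros(len(ctrl_vals), dtype=int)]
        feats = {"f1": np.r_[case_vals, ctrl_vals]}
        return longitudinal_cohort(n_patients=n, n_visits=1,
                                   features=feats, outcome=y, seed=1)

    def test_separated_groups_worked_example(self):
        ds = self._cohort([5.0, 6, 7, 8], [1.0, 2, 3, 4])
        ds.samples["week"] = 10.0
        tab = rank_test_early(ds, "b")
        assert tab.table["p"].iloc[0] == pytest.approx(2 / 70)
        assert tab.table["direction"].iloc[0] == 1.0

    def test_matches_full_enumeration_for_small_groups(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            a = rng.standard_normal(4)
            b = rng.standard_normal(4)
            ds = self._cohort(a, b)
            ds.samples["week"] = 10.0
            got = rank_test_early(ds, "b").table["p"].iloc[0]
            assert got == pytest.approx(ranksum_enumeration_p(a, b), abs=1e-12)

    def test_shift_invariance(self):
        rng = np.random.default_rng(2)
        a, b = rng.standard_normal(5), rng.standard_normal(6)
        p1 = rank_test_early(self._cohort(a, b), "b").table["p"].iloc[0]
        p2 = rank_test_early(self._cohort(a + 7, b + 7), "b").table["p"].iloc[0]
        assert p1 == p2

    def test_takes_earliest_sample_within_window(self):
        y = np.array([1, 1, 0, 0])
        ds = longitudinal_cohort(n_patients=4, n_visits=3,
                                 features={"f1": np.arange(12.0)},
                                 outcome=y, seed=0)
        tab = rank_test_early(ds, "b", week_cutoff=40.0)
        assert tab.table["n"].iloc[0] == 4  # one sample per patient

    def test_too_small_group_rejected(self):
        ds = self._cohort([1.0], [2.0, 3, 4])
        ds.samples["week"] = 10.0
        with pytest.raises(ValueError, match="2 patients"):
            rank_test_early(ds, "b")

    def test_null_rejection_rate_is_calibrated(self):
        rng = np.random.default_rng(8)
        n_pat = 24
        y = np.array([i % 2 for i in range(n_pat)])
        feats = {f"f{j}": rng.standard_normal(n_pat) for j in range(300)}
        ds = longitudinal_cohort(n_patients=n_pat, n_visits=1,
                                 features=feats, outcome=y, seed=3)
        tab = rank_test_early(ds, "b", week_cutoff=40.0)
        frac = (tab.table["p"] < 0.05).mean()
        assert 0.02 <= frac <= 0.09


class TestLMELongitudinal:
    def test_recovers_exact_shift_without_noise(self):
        rng = np.random.default_rng(0)
        n_pat = 12
        y = np.array([i % 2 for i in range(n_pat)])
        ds = longitudinal_cohort(n_patients=n_pat, n_visits=3, outcome=y,
                                 seed=0)
        week = ds.samples["week"].to_numpy()
        y_s = ds.outcomes.loc[ds.samples["patient_id"]].to_numpy()
        vals = 1.0 + 0.7 * y_s + 0.05 * week + 1e-8 * rng.standard_normal(len(week))
        from omicstack.datasets import OmicsBlock
        ds.blocks["b"] = OmicsBlock("b", pd.DataFrame({"f1": vals},
                                                      index=ds.samples.index))
        tab = lme_longitudinal(ds, "b")
        assert tab.table["statistic"].iloc[0] == pytest.approx(0.7, abs=1e-5)

    def test_agrees_with_ols_when_patients_contribute_no_variance(self):
        """With zero between-patient variance the REML fit collapses to
        ordinary least squares."""
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        n_pat = 20
        y = np.array([i % 2 for i in range(n_pat)])
        ds = longitudinal_cohort(n_patients=n_pat, n_visits=3, outcome=y,
                                 seed=5)
        week = ds.samples["week"].to_numpy()
        y_s = ds.outcomes.loc[ds.samples["patient_id"]].to_numpy()
        # independent residuals only -> random-intercept estimate hits 0
        vals = 0.4 * y_s + 0.02 * week + rng.standard_normal(len(week))
        from omicstack.datasets import OmicsBlock
        ds.blocks["b"] = OmicsBlock("b", pd.DataFrame({"f1": vals},
                                                      index=ds.samples.index))
        tab = lme_longitudinal(ds, "b")
        X = np.column_stack([np.ones(len(week)), y_s, week])
        ols = sm.OLS(vals, X).fit()
        assert tab.table["statistic"].iloc[0] == pytest.approx(
            ols.params[1], abs=1e-4)

    def test_invariant_to_patient_relabeling(self):
        rng = np.random.default_rng(6)
        n_pat = 14
        y = np.array([i % 2 for i in range(n_pat)])
        feats = {"f1": rng.standard_normal(n_pat * 3)}
        ds = longitudinal_cohort(n_patients=n_pat, n_visits=3,
                                 features=feats, outcome=y, seed=6)
        p1 = lme_longitudinal(ds, "b").table["p"].iloc[0]

        mapping = {p: f"Z{i:02d}" for i, p in
                   enumerate(reversed(ds.patient_ids))}
        samples = ds.samples.copy()
        samples["patient_id"] = samples["patient_id"].map(mapping)
        from omicstack.datasets import CohortDataset
        ds2 = CohortDataset(
            samples=samples,
            outcomes=pd.Series(ds.outcomes.to_numpy(),
                               index=[mapping[p] for p in ds.outcomes.index]),
            blocks=ds.blocks)
        p2 = lme_longitudinal(ds2, "b").table["p"].iloc[0]
        assert p1 == pytest.approx(p2, rel=1e-9)


def ora_pmf_oracle(M, K, n, k):
    """Upper-tail hypergeometric by explicit pmf summation."""
    from math import comb

    return sum(comb(K, i) * comb(M - K, n - i) for i in range(k, min(K, n) + 1)
               ) / comb(M, n)


class TestHypergeometricORA:
    def test_worked_example(self):
        universe = [f"g{i}" for i in range(20)]
        sets = FeatureSetCollection(
            sets={"S": set(universe[:5])}, universe=universe)
        selected = universe[2:7]  # g2, g3, g4 fall in S -> overlap 3
        out = hypergeometric_ora(selected, sets)
        assert out.loc["S", "overlap"] == 3
        assert out.loc["S", "p"] == pytest.approx(1126 / 15504)

    def test_set_equal_to_universe_saturates(self):
        universe = [f"g{i}" for i in range(10)]
        sets = FeatureSetCollection(sets={"All": set(universe)},
                                    universe=universe)
        out = hypergeometric_ora(universe[:4], sets)
        assert out.loc["All", "overlap"] == 4
        assert out.loc["All", "p"] == pytest.approx(1.0)

    def test_zero_overlap_is_unenriched(self):
        universe = [f"g{i}" for i in range(12)]
        sets = FeatureSetCollection(sets={"S": set(universe[:4])},
                                    universe=universe)
        out = hypergeometric_ora(universe[8:12], sets)
        assert out.loc["S", "enrichment"] == 0.0
        assert out.loc["S", "p"] > 0.5

    def test_matches_pmf_summation_on_random_parameters(self):
        rng = np.random.default_rng(1)
        for _ in range(60):
            M = int(rng.integers(2, 30))
            K = int(rng.integers(1, M + 1))
            n = int(rng.integers(1, M + 1))
            universe = [f"g{i}" for i in range(M)]
            set_members = set(rng.choice(universe, size=K, replace=False))
            selected = list(rng.choice(universe, size=n, replace=False))
            out = hypergeometric_ora(
                selected, FeatureSetCollection(sets={"S": set_members},
                                               universe=universe))
            k = len(set_members & set(selected))
            assert out.loc["S", "p"] == pytest.approx(
                ora_pmf_oracle(M, K, n, k), rel=1e-10)

    def test_selection_outside_universe_rejected(self):
        sets = FeatureSetCollection(sets={"S": {"g1"}}, universe=["g1", "g2"])
        with pytest.raises(ValueError):
            hypergeometric_ora(["g3"], sets)


def test_read_gmt(tmp_path):
    p = tmp_path / "sets.gmt"
    p.write_text("pathA\tdesc\tg1\tg2\npathB\tdesc\tg3\n")
    sets = read_gmt(p)
    assert sets == {"pathA": {"g1", "g2"}, "pathB": {"g3"}}
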