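import numpy as np
import pandas as pd
import pytest

from omicstack import (
    StackedENModel,
    StackedModel,
    average_patient_scores,
    compute_auc,
    fit_final_model,
    fit_stacking_weights,
    generate_cohort,
    loo_base_predictions,
    nested_loo_stacked_cv,
)
from omicstack.datasets import CohortDataset, OmicsBlock
from omicstack.elasticnet import fit_en, predict_score
from omicstack.simulate import BlockSpec, SyntheticSpec
from omicstack.stacking import _derive_seed, _with_seed, stack_sample_scores


class TestLooBasePredictions:
    def test_matches_naive_loop_reimplementation(self, tiny_cohort, fast_cfg):
        ds, _ = tiny_cohort
        blk = ds.blocks["b0"]
        got = loo_base_predictions(blk, ds, fast_cfg)

        # naive reimplementation: explicit loop re-calling fit_en
        X = blk.matrix()
        pats = ds.samples.loc[blk.sample_ids, "patient_id"].to_numpy()
        y = ds.outcomes.loc[pats].to_numpy(dtype=float)
        expected = np.empty(len(y))
        for i, pat in enumerate(pd.unique(pats)):
            hold = pats == pat
            cfg_i = _with_seed(fast_cfg, _derive_seed(fast_cfg.seed, i))
            fit = fit_en(X[~hold], y[~hold], cfg_i,
                         feature_ids=blk.feature_ids, groups=pats[~hold])
            expected[hold] = predict_score(fit, X[hold])
        np.testing.assert_array_equal(got.to_numpy(), expected)

    def test_heldout_score_unaffected_by_own_label(self, tiny_cohort, fast_cfg):
        ds, _ = tiny_cohort
        pat = ds.patient_ids[0]
        flipped = pd.Series(ds.outcomes.copy())
        flipped[pat] = 1 - flipped[pat]
        ds_flip = CohortDataset(samples=ds.samples, outcomes=flipped,
                                blocks=ds.blocks)
        a = loo_base_predictions(ds.blocks["b0"], ds, fast_cfg)
        b = loo_base_predictions(ds_flip.blocks["b0"], ds_flip, fast_cfg)
        own = ds.samples.index[ds.samples["patient_id"] == pat]
        np.testing.assert_array_equal(a.loc[own], b.loc[own])

    def test_one_score_per_sample(self, tiny_cohort, fast_cfg):
        ds, _ = tiny_cohort
        out = loo_base_predictions(ds.blocks["b0"], ds, fast_cfg)
        assert list(out.index) == ds.blocks["b0"].sample_ids
        assert out.between(0, 1).all()


class TestStackingWeights:
    def test_perfect_column_gets_unit_weight(self):
        y = np.array([1.0, 0, 1, 0, 1, 0])
        gamma = fit_stacking_weights(y.reshape(-1, 1), y)
        np.testing.assert_allclose(gamma, [1.0], atol=1e-12)

    def test_antipredictive_column_clipped_at_zero(self):
        y = np.array([1.0, 0, 1, 0, 1, 0])
        C = np.column_stack([y, 1 - y])
        gamma = fit_stacking_weights(C, y)
        np.testing.assert_allclose(gamma, [1.0, 0.0], atol=1e-12)

    def test_matches_dense_grid_search_oracle(self):
        y = np.array([1.0, 0, 1, 0])
        C = np.array([[0.9, 0.2], [0.1, 0.9], [0.8, 0.4], [0.2, 0.6]])
        gamma = fit_stacking_weights(C, y)
        grid_best = _refining_grid_search(C, y, k=2)
        np.testing.assert_allclose(gamma, grid_best, atol=2e-3)

    def test_all_zero_column_gets_zero_weight(self):
        y = np.array([1.0, 0, 1, 0])
        C = np.column_stack([y, np.zeros(4)])
        gamma = fit_stacking_weights(C, y)
        assert gamma[1] == 0.0

    def test_non_negativity_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            C = rng.random((12, 3))
            y = rng.integers(0, 2, 12).astype(float)
            assert (fit_stacking_weights(C, y) >= 0).all()


def _refining_grid_search(C, y, k, lo=0.0, hi=3.0, rounds=4, n_pts=31):
    """Dense grid search refined around the incumbent, to ~1e-3."""
    import itertools

    centers = [(lo + hi) / 2] * k
    half = (hi - lo) / 2
    best = None
    for _ in range(rounds):
        axes = [np.clip(np.linspace(c - half, c + half, n_pts), 0, None)
                for c in centers]
        for g in itertools.product(*axes):
            g = np.asarray(g)
            loss = np.sum((y - C @ g) ** 2)
            if best is None or loss < best[0] - 1e-15:
                best = (loss, g)
        centers = best[1]
        half /= n_pts / 4
    return best[1]


class TestAveragePatientScores:
    def test_single_sample_unchanged(self):
        s = pd.Series([0.7], index=["s1"])
        out = average_patient_scores(s, pd.Series({"s1": "A"}))
        assert out["A"] == 0.7

    def test_arithmetic_mean(self):
        s = pd.Series([0.2, 0.4], index=["s1", "s2"])
        out = average_patient_scores(s, pd.Series({"s1": "A", "s2": "A"}))
        assert out["A"] == pytest.approx(0.3)

    def test_order_invariant(self):
        s = pd.Series([0.2, 0.9, 0.4], index=["s1", "s2", "s3"])
        m = pd.Series({"s1": "A", "s2": "B", "s3": "A"})
        a = average_patient_scores(s, m)
        b = average_patient_scores(s.iloc[::-1], m)
        pd.testing.assert_series_equal(a.sort_index(), b.sort_index())


def test_missing_block_renormalizes_with_warning():
    per_block = {
        "b1": pd.Series([0.8, 0.6], index=["s1", "s2"]),
        "b2": pd.Series([0.4], index=["s1"]),  # s2 lacks block b2
    }
    with pytest.warns(UserWarning, match="renormalized"):
        out = stack_sample_scores(per_block, ["b1", "b2"],
                                  np.array([1.0, 1.0]), ["s1", "s2"])
    assert out["s1"] == pytest.approx(0.8 + 0.4)
    assert out["s2"] == pytest.approx(0.6 * 2.0)  # weight mass rescaled


class TestNestedCV:
    def test_heldout_fold_model_ignores_heldout_features(self, fast_cfg):
        """The model that scores patient i must be identical whether or not
        patient i's feature values are perturbed (no leakage into its own
        fold); the perturbation may only pass through the scoring step."""
        from omicstack.stacking import _outer_fold

        spec = SyntheticSpec(
            n_patients=10,
            blocks=[BlockSpec(name="b0", p=8, n_latent=2, n_signal=2,
                              effect_size=1.0)],
            seed=3)
        ds, _ = generate_cohort(spec)
        idx = 4
        pat = ds.patient_ids[idx]
        own = ds.samples.index[ds.samples["patient_id"] == pat]
        vals = ds.blocks["b0"].values.copy()
        vals.loc[own] = 3.0
        ds2 = CohortDataset(samples=ds.samples, outcomes=ds.outcomes,
                            blocks={"b0": OmicsBlock("b0", vals)})
        _, gamma1, sup1 = _outer_fold(ds, fast_cfg, pat, idx)
        _, gamma2, sup2 = _outer_fold(ds2, fast_cfg, pat, idx)
        np.testing.assert_array_equal(gamma1, gamma2)
        assert sup1 == sup2

    def test_gamma_non_negative_in_every_fold(self, two_block_cohort, fast_cfg):
        ds, _ = two_block_cohort
        cv = nested_loo_stacked_cv(ds, fast_cfg)
        assert (cv.gamma_per_fold.to_numpy() >= 0).all()

    def test_patient_scores_average_sample_scores(self, two_block_cohort,
                                                  fast_cfg):
        ds, _ = two_block_cohort
        cv = nested_loo_stacked_cv(ds, fast_cfg)
        manual = average_patient_scores(cv.sample_scores.dropna(),
                                        ds.patient_of_sample)
        np.testing.assert_allclose(
            cv.patient_scores.sort_index(), manual.sort_index())

    def test_parallel_equals_serial(self, tiny_cohort, fast_cfg):
        ds, _ = tiny_cohort
        a = nested_loo_stacked_cv(ds, fast_cfg, n_jobs=1)
        b = nested_loo_stacked_cv(ds, fast_cfg, n_jobs=2)
        np.testing.assert_array_equal(a.patient_scores, b.patient_scores)
        assert a.auc.auc == b.auc.auc

    def test_strong_signal_cohort_is_well_classified(self, fast_cfg):
        spec = SyntheticSpec(
            n_patients=20,
            blocks=[BlockSpec(name=f"b{k}", p=30, n_latent=3, n_signal=4,
                              effect_size=2.0) for k in range(2)],
            seed=17)
        ds, _ = generate_cohort(spec)
        cv = nested_loo_stacked_cv(ds, fast_cfg)
        assert cv.auc.auc > 0.85

    def test_selection_frequencies_lie_in_unit_interval(self, tiny_cohort,
                                                        fast_cfg):
        ds, _ = tiny_cohort
        cv = nested_loo_stacked_cv(ds, fast_cfg)
        s = cv.selection_frequency["b0"]
        assert ((s >= 0) & (s <= 1)).all()
        assert len(s) == len(ds.blocks["b0"].feature_ids)


class TestFinalModel:
    def test_training_predictions_reproducible_after_serialization(
            self, tiny_cohort, fast_cfg, tmp_path):
        ds, _ = tiny_cohort
        model = fit_final_model(ds, fast_cfg)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = StackedModel.from_json(path)
        pd.testing.assert_series_equal(model.predict(ds), back.predict(ds))

    def test_single_block_stacked_scores_rank_like_block_scores(
            self, tiny_cohort, fast_cfg):
        ds, _ = tiny_cohort
        model = fit_final_model(ds, fast_cfg, debias=False)
        stacked = model.predict(ds)
        block_scores = average_patient_scores(
            pd.Series(
                predict_score(model.fits["b0"], ds.blocks["b0"].values),
                index=ds.blocks["b0"].sample_ids),
            ds.patient_of_sample)
        y = ds.outcomes.loc[stacked.index]
        assert compute_auc(stacked, y) == compute_auc(
            block_scores.loc[stacked.index], y)

    def test_prediction_never_mutates_the_model(self, tiny_cohort, fast_cfg):
        ds, _ = tiny_cohort
        model = fit_final_model(ds, fast_cfg)
        before = model.state_hash()
        model.predict(ds)
        assert model.state_hash() == before

    def test_generalizes_to_replicate_cohorts(self, fast_cfg):
        spec = SyntheticSpec(
            n_patients=24,
            blocks=[BlockSpec(name="b0", p=40, n_latent=4, n_signal=5,
                              effect_size=1.5)],
            seed=31)
        gaps = []
        for r in range(3):
            ds, _ = generate_cohort(spec, replicate=2 * r)
            ds_val, _ = generate_cohort(spec, replicate=2 * r + 1)
            cv = nested_loo_stacked_cv(ds, fast_cfg)
            model = fit_final_model(ds, fast_cfg)
            scores = model.predict(ds_val)
            ext = compute_auc(scores, ds_val.outcomes.loc[scores.index])
            gaps.append(abs(ext - cv.auc.auc))
        assert np.mean(gaps) < 0.15


def test_model_results_wrappers_summarize(tiny_cohort, fast_cfg):
    ds, _ = tiny_cohort
    model = StackedENModel(ds, config=fast_cfg)
    res = model.fit()
    assert "stacking weights" in res.summary()
    cv = model.cross_validate()
    assert "AUC" in cv.summary()
    assert 0 <= cv.auc.auc <= 1
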