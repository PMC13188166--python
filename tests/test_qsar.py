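import numpy as np
import pandas as pd
import pytest

from ttraop import qsar
from ttraop.curation import CompoundRecord
from ttraop.descriptors import MODEL1_DESCRIPTORS, MODEL2_DESCRIPTORS
from ttraop.synth import GeneratorSpec, gen_binding_dataset

from conftest import records_from_frame


def _records(classes):
    out = []
    for i, c in enumerate(classes):
        pec50 = {"weak": -1.5, "medium": -0.3, "strong": 0.5}[c] + 0.01 * i
        out.append(CompoundRecord(f"c{i}", f"c{i}", "C", 10.0**-pec50,
                                  pec50, c))
    return out


class TestStratifiedSplit:
    def test_single_stratum_fraction_arithmetic(self):
        recs = _records(["medium"] * 10)
        train, test = qsar.stratified_split(recs, test_fraction=0.2, seed=1)
        assert (len(train), len(test)) == (8, 2)

    def test_explicit_test_size_recovers_62_10_partition(self, curated_actives):
        train, test = qsar.stratified_split(curated_actives, test_size=10, seed=3)
        assert (len(train), len(test)) == (62, 10)

    def test_same_seed_gives_identical_partition(self, curated_actives):
        a = qsar.stratified_split(curated_actives, test_size=10, seed=9)
        b = qsar.stratified_split(curated_actives, test_size=10, seed=9)
        assert [r.compound_id for r in a[1]] == [r.compound_id for r in b[1]]

    def test_union_is_input_and_intersection_empty(self, curated_actives):
        train, test = qsar.stratified_split(curated_actives, test_size=10, seed=4)
        ids = {r.compound_id for r in train} | {r.compound_id for r in test}
        assert ids == {r.compound_id for r in curated_actives}
        assert not ({r.compound_id for r in train} & {r.compound_id for r in test})

    def test_tiny_stratum_goes_to_train(self):
        recs = _records(["medium"] * 8 + ["strong"])
        train, test = qsar.stratified_split(recs, test_fraction=0.25, seed=0)
        assert all(r.binder_class == "medium" for r in test)

    def test_extreme_values_pinned_to_train(self, curated_actives):
        vals = [r.pec50 for r in curated_actives]
        for seed in range(5):
            train, _ = qsar.stratified_split(curated_actives, test_size=10,
                                             seed=seed, keep_extremes_in_train=True)
            tvals = [r.pec50 for r in train]
            assert max(tvals) == max(vals) and min(tvals) == min(vals)


class TestPLS:
    def test_exact_linear_response_gives_unit_r2_with_one_component(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(20, 1))
        y = 2.0 + 3.0 * x[:, 0]
        m = qsar.fit_pls(x, y, 1, compute_loo=False)
        assert m.training_metrics["r2"] == pytest.approx(1.0, abs=1e-12)

    def test_full_rank_pls_equals_ols(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 5))
        y = rng.normal(size=40)
        m = qsar.fit_pls(X, y, 5, compute_loo=False)
        beta = np.linalg.lstsq(np.column_stack([np.ones(40), X]), y, rcond=None)[0]
        assert np.abs(np.r_[m.intercept, m.coefficients] - beta).max() < 1e-6

    def test_zero_variance_column_dropped(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(15, 3))
        X[:, 1] = 7.0
        y = rng.normal(size=15)
        m = qsar.fit_pls(X, y, 2, ["a", "b", "c"], compute_loo=False)
        assert m.descriptor_names == ["a", "c"]

    def test_training_r2_tracks_generator_signal_to_noise(self):
        spec = GeneratorSpec(seed=4, noise_sd=0.3, plant_salts=False,
                             plant_duplicate=False)
        df, truth = gen_binding_dataset(spec)
        recs = [r for r in records_from_frame(df) if r.ec50 is not None]
        from ttraop.descriptors import descriptor_table
        desc = descriptor_table([(r.compound_id, r.smiles) for r in recs],
                                three_d=False)
        X = desc[list(MODEL1_DESCRIPTORS)]
        y = np.array([r.pec50 for r in recs])
        # analytic R2 from the planted signal and the (rescaled) noise SD
        Z = (X - X.mean()) / X.std(ddof=1)
        beta = np.array([truth["beta_std"][d] for d in MODEL1_DESCRIPTORS])
        signal_var = float(np.var(Z.to_numpy() @ beta))
        analytic = signal_var / (signal_var + truth["noise_sd"] ** 2)
        m = qsar.fit_pls(X, y, 5, compute_loo=False)
        assert m.training_metrics["r2"] == pytest.approx(analytic, abs=0.1)


class TestEvaluateAndLOO:
    @pytest.fixture(scope="class")
    def small_fit(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + rng.normal(0, 0.4, 10)
        return X, y, qsar.fit_pls(X, y, 2, compute_loo=False)

    def test_evaluate_on_training_data_equals_training_metrics(self, small_fit):
        X, y, m = small_fit
        ev = qsar.evaluate(m, X, y)
        assert ev["r2"] == pytest.approx(m.training_metrics["r2"], abs=1e-12)
        assert ev["rmse"] == pytest.approx(m.training_metrics["rmse"], abs=1e-12)

    def test_single_test_point_flags_undefined_r2(self, small_fit):
        X, y, m = small_fit
        ev = qsar.evaluate(m, X[:1], y[:1])
        assert ev["r2"] is None and ev["r2_undefined"]

    def test_perfect_predictions_trivial_metrics(self):
        X = np.arange(12, dtype=float).reshape(-1, 1)
        y = 3.0 * X[:, 0] - 1.0
        m = qsar.fit_pls(X, y, 1, compute_loo=False)
        ev = qsar.evaluate(m, X, y)
        assert ev["rmse"] == pytest.approx(0.0, abs=1e-9)
        assert ev["r2"] == pytest.approx(1.0, abs=1e-12)

    def test_noiseless_linear_data_has_q2_near_one(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(15, 2))
        y = X @ np.array([1.0, 2.0])
        assert qsar.loo_cv(X, y, 2) > 0.999

    def test_q2_not_above_training_r2(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(16, 3))
            y = X[:, 0] + rng.normal(0, 0.7, 16)
            m = qsar.fit_pls(X, y, 2, compute_loo=True)
            assert m.training_metrics["q2_loo"] <= m.training_metrics["r2"] + 1e-12

    def test_pure_noise_q2_non_positive_in_expectation(self):
        q2s = []
        for seed in range(50):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(15, 3))
            y = rng.normal(size=15)
            q2s.append(qsar.loo_cv(X, y, 2))
        assert np.mean(q2s) < 0.1

    def test_evaluate_and_loo_match_brute_force_loops(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 3))
        y = X[:, 0] - 0.5 * X[:, 2] + rng.normal(0, 0.3, 10)
        k = 2
        m = qsar.fit_pls(X, y, k, compute_loo=False)
        # brute-force metrics with explicit loops
        pred = np.array([m.predict(X[i:i + 1])[0] for i in range(10)])
        rmse_bf, ss_res, ss_tot = 0.0, 0.0, 0.0
        for i in range(10):
            ss_res += (y[i] - pred[i]) ** 2
            ss_tot += (y[i] - y.mean()) ** 2
        ev = qsar.evaluate(m, X, y)
        assert ev["r2"] == pytest.approx(1 - ss_res / ss_tot, abs=1e-9)
        assert ev["rmse"] == pytest.approx(np.sqrt(ss_res / 10), abs=1e-9)
        press = 0.0
        for i in range(10):
            keep = [j for j in range(10) if j != i]
            mi = qsar.fit_pls(X[keep], y[keep], k, compute_loo=False)
            press += (y[i] - mi.predict(X[i:i + 1])[0]) ** 2
        assert qsar.loo_cv(X, y, k) == pytest.approx(1 - press / ss_tot, abs=1e-9)


class TestDoA:
    @pytest.fixture(scope="class")
    def doa(self, active_descriptors):
        return qsar.fit_doa(active_descriptors[list(MODEL1_DESCRIPTORS)])

    def test_every_training_compound_in_domain_at_zero_margin(self, doa, active_descriptors):
        X = active_descriptors[list(MODEL1_DESCRIPTORS)]
        for i in range(len(X)):
            inside, _ = qsar.in_domain(doa, X.iloc[i:i + 1])
            assert inside

    def test_query_far_outside_training_space_flagged(self, doa, active_descriptors):
        x = active_descriptors[list(MODEL1_DESCRIPTORS)].iloc[:1].copy()
        x["a_count"] = 10.0 * active_descriptors["a_count"].max()
        x["b_single"] = 10.0 * active_descriptors["b_single"].max()
        inside, scores = qsar.in_domain(doa, x)
        assert not inside
        assert np.isfinite(scores).all()

    def test_explained_variances_are_fractions_summing_below_one(self, doa):
        assert 0 <= doa.pca2_variance <= doa.pca1_variance <= 1
        assert doa.pca1_variance + doa.pca2_variance <= 1 + 1e-12

    def test_degenerate_descriptor_variance_names_the_axis(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [5.0] * 4})
        with pytest.raises(ValueError, match="'b'"):
            qsar.fit_doa(X)


class TestTiered:
    @pytest.fixture(scope="class")
    def tiered(self, curated_actives, active_descriptors):
        return qsar.fit_tiered(
            active_descriptors,
            [r.pec50 for r in curated_actives],
            [r.binder_class for r in curated_actives],
        )

    def test_tier2_trained_on_medium_strong_subset_only(self, tiered, curated_actives):
        n_sub = sum(r.binder_class in ("medium", "strong") for r in curated_actives)
        assert tiered.tier2 is not None
        assert tiered.tier2.scores.shape[0] == n_sub < len(curated_actives)

    def test_all_weak_dataset_has_no_tier2(self, active_descriptors):
        n = len(active_descriptors)
        model = qsar.fit_tiered(active_descriptors,
                                [-2.0 + 0.001 * i for i in range(n)],
                                ["weak"] * n)
        assert model.tier2 is None and model.tier1 is not None

    def test_tier2_no_worse_than_tier1_on_medium_strong_subset(self):
        from ttraop.descriptors import descriptor_table
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            df, _ = gen_binding_dataset(GeneratorSpec(
                seed=seed, plant_salts=False, plant_duplicate=False))
            recs = [r for r in records_from_frame(df) if r.ec50 is not None]
            desc = descriptor_table([(r.compound_id, r.smiles) for r in recs])
            model = qsar.fit_tiered(desc, [r.pec50 for r in recs],
                                    [r.binder_class for r in recs])
            sub = [r for r in recs if r.binder_class in ("medium", "strong")]
            sub_desc = desc.loc[[r.compound_id for r in sub]]
            sub_y = [r.pec50 for r in sub]
            t1 = qsar.evaluate(model.tier1, sub_desc, sub_y)["rmse"]
            t2 = qsar.evaluate(model.tier2, sub_desc, sub_y)["rmse"]
            wins += t2 <= t1 + 1e-9
        assert wins >= n_seeds - 1

    def test_weak_tier1_prediction_suppresses_tier2_value(self, tiered, active_descriptors,
                                                          curated_actives):
        weakest = min(curated_actives, key=lambda r: r.pec50)
        d = active_descriptors.loc[weakest.compound_id].to_dict()
        out = qsar.predict_tiered(tiered, d)
        if out["binder_class"] == "weak":
            assert out["pec50_tier2"] is None

    def test_training_compound_reproduces_fitted_value(self, tiered, active_descriptors):
        d = active_descriptors.iloc[0]
        out = qsar.predict_tiered(tiered, d.to_dict())
        fitted = tiered.tier1.predict(active_descriptors.iloc[:1])[0]
        assert out["pec50_tier1"] == pytest.approx(fitted, abs=1e-12)

    def test_out_of_domain_prediction_still_reported(self, tiered, active_descriptors):
        d = active_descriptors.iloc[0].to_dict()
        d["a_count"] = 1000.0
        d["b_single"] = 1000.0
        out = qsar.predict_tiered(tiered, d)
        assert out["pec50_tier1"] is not None
        assert out["in_doa1"] is False

    def test_serialization_round_trips_schema(self, tiered, tmp_path):
        import json
        path = tmp_path / "model.json"
        tiered.to_json(path)
        payload = json.loads(path.read_text())
        assert payload["schema"].startswith("ttraop.tiered_qsar")
        assert payload["tier1"]["descriptor_names"] == list(MODEL1_DESCRIPTORS)
        assert payload["tier2"]["descriptor_names"] == list(MODEL2_DESCRIPTORS)

    def test_reloaded_model_reproduces_predictions(self, tiered, tmp_path,
                                                   active_descriptors):
        path = tmp_path / "model.json"
        tiered.to_json(path)
        reloaded = qsar.TieredQSAR.from_json(path)
        for i in (0, 5, 20):
            d = active_descriptors.iloc[i].to_dict()
            a = qsar.predict_tiered(tiered, d)
            b = qsar.predict_tiered(reloaded, d)
            assert b["pec50_tier1"] == pytest.approx(a["pec50_tier1"], abs=1e-12)
            assert b["binder_class"] == a["binder_class"]
            assert b["in_doa1"] == a["in_doa1"]
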