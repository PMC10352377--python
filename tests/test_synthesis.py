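import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency, norm

from synthpool.schema import HarmonizedSurveyTable, VariableSchema
from synthpool.simulate import canada_like, simulate_country
from synthpool.synthesis import (
    DegenerateVariableError, NormalScoreTransform, SynthesisError,
    SynthesisModel, SynthesisOrder, TuningConfig, fit_conditional,
    fit_sequential, generate_replicates, normal_score_forward, suggest_order,
)

NO_TUNE = TuningConfig(n_trials=0)


def _binary_table(n, seed, dep=None, p=0.3):
    """x ~ Bernoulli(0.5); y ~ Bernoulli(p) independent, or y = x if dep."""
    rng = np.random.default_rng(seed)
    x = np.where(rng.random(n) < 0.5, "a", "b")
    if dep == "copy":
        y = x.copy()
        y_levels = ("a", "b")
    else:
        y = np.where(rng.random(n) < p, "yes", "no")
        y_levels = ("no", "yes")
    schema = [VariableSchema("x", "categorical", ("a", "b")),
              VariableSchema("y", "categorical", y_levels)]
    return HarmonizedSurveyTable(schema, pd.DataFrame({"x": x, "y": y}))


def cramers_v(a, b):
    tab = pd.crosstab(a, b)
    chi2 = chi2_contingency(tab, correction=False)[0]
    n = tab.to_numpy().sum()
    k = min(tab.shape) - 1
    return np.sqrt(chi2 / (n * k)) if k > 0 else 0.0


class TestNormalScoreTransform:
    def test_three_point_sample_matches_quantile_table(self):
        out = normal_score_forward([1.0, 2.0, 3.0])
        expected = norm.ppf([0.25, 0.5, 0.75])  # -0.6745, 0, 0.6745
        assert np.allclose(out, expected, atol=5e-5)
        assert np.allclose(expected, [-0.6745, 0.0, 0.6745], atol=5e-5)

    def test_median_of_odd_sample_maps_to_zero(self):
        vals = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
        t = NormalScoreTransform.fit(vals)
        assert t.forward([np.median(vals)])[0] == pytest.approx(0.0, abs=1e-12)

    def test_forward_is_monotone(self):
        rng = np.random.default_rng(0)
        vals = rng.gamma(2, 1, 500)
        t = NormalScoreTransform.fit(vals)
        x = np.sort(rng.gamma(2, 1, 200))
        z = t.forward(x)
        assert np.all(np.diff(z) >= 0)

    def test_round_trip_is_identity_on_support(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(5, 2, 1000)
        t = NormalScoreTransform.fit(vals)
        back = t.inverse(t.forward(vals))
        assert np.max(np.abs(back - vals)) < 1e-9

    def test_round_trip_with_ties(self):
        vals = np.array([1.0, 2.0, 2.0, 2.0, 3.0, 3.0, 7.0])
        t = NormalScoreTransform.fit(vals)
        assert np.allclose(t.inverse(t.forward(vals)), vals, atol=1e-9)

    def test_symmetric_sample_median_round_trip(self):
        vals = np.array([3.0, 4.0, 5.0, 6.0, 7.0])
        t = NormalScoreTransform.fit(vals)
        assert t.inverse([0.0])[0] == pytest.approx(5.0)

    def test_far_tail_clips_to_training_range(self):
        t = NormalScoreTransform.fit(np.array([1.0, 2.0, 3.0]))
        assert t.inverse([10.0])[0] == pytest.approx(3.0)
        assert t.inverse([-10.0])[0] == pytest.approx(1.0)

    def test_degenerate_sample_refused(self):
        with pytest.raises(DegenerateVariableError):
            NormalScoreTransform.fit([2.0, 2.0, 2.0])


class TestFitConditional:
    def test_independent_target_calibrated_to_prevalence(self):
        table = _binary_table(5000, seed=21, p=0.3)
        cm = fit_conditional("y", ["x"], table, NO_TUNE, seed=1)
        X = pd.DataFrame({"x": pd.Categorical(["a", "b"], categories=["a", "b"])})
        probs = cm.predict_proba(X)
        p_yes = probs[:, list(cm.present_levels).index("yes")]
        assert np.all(np.abs(p_yes - 0.3) < 0.05)

    def test_deterministic_relation_learned_exactly(self):
        table = _binary_table(2000, seed=22, dep="copy")
        cm = fit_conditional("y", ["x"], table, NO_TUNE, seed=1)
        X = pd.DataFrame({"x": pd.Categorical(["a", "b"], categories=["a", "b"])})
        probs = cm.predict_proba(X)
        pred = [cm.present_levels[i] for i in probs.argmax(axis=1)]
        assert pred == ["a", "b"]  # y copies x

    def test_tuning_is_seed_deterministic(self):
        table = _binary_table(400, seed=23, p=0.4)
        cfg = TuningConfig(n_trials=4, n_initial=2, n_candidates=16)
        cm1 = fit_conditional("y", ["x"], table, cfg, seed=5)
        cm2 = fit_conditional("y", ["x"], table, cfg, seed=5)
        assert cm1.hyperparams == cm2.hyperparams
        assert cm1.cv_score == cm2.cv_score

    def test_single_class_target_becomes_constant(self):
        schema = [VariableSchema("x", "categorical", ("a", "b")),
                  VariableSchema("y", "categorical", ("no", "yes"))]
        df = pd.DataFrame({"x": ["a", "b"] * 50, "y": ["no"] * 100})
        cm = fit_conditional("y", ["x"], HarmonizedSurveyTable(schema, df),
                             NO_TUNE, seed=1)
        assert cm.kind == "constant_cat" and cm.constant == "no"

    def test_insufficient_rows_error_names_variable(self):
        table = _binary_table(20, seed=24)
        with pytest.raises(SynthesisError, match="y"):
            fit_conditional("y", ["x"], table, NO_TUNE, seed=1)


class TestFitSequential:
    def test_independent_variables_stay_independent(self):
        table = _binary_table(5000, seed=31, p=0.4)
        model = fit_sequential(table, config=NO_TUNE, seed=2)
        cm = model.models[1]
        X = pd.DataFrame({"x": pd.Categorical(["a", "b"], categories=["a", "b"])})
        p_yes = cm.predict_proba(X)[:, list(cm.present_levels).index("yes")]
        assert abs(p_yes[0] - p_yes[1]) < 0.05
        assert np.all(np.abs(p_yes - 0.4) < 0.05)

    def test_single_variable_order_is_marginal_only(self):
        schema = [VariableSchema("x", "categorical", ("a", "b"))]
        df = pd.DataFrame({"x": ["a", "b", "a", "a"] * 30})
        model = fit_sequential(HarmonizedSurveyTable(schema, df),
                               config=NO_TUNE, seed=3)
        assert len(model.models) == 1
        assert model.models[0].kind == "marginal_cat"
        assert model.models[0].marginal_probs == pytest.approx([0.75, 0.25])

    def test_deterministic_chain_preserved_in_synthesis(self):
        rng = np.random.default_rng(41)
        x = np.where(rng.random(3000) < 0.5, "a", "b")
        schema = [VariableSchema("x", "categorical", ("a", "b")),
                  VariableSchema("y", "categorical", ("a", "b")),
                  VariableSchema("z", "categorical", ("a", "b"))]
        df = pd.DataFrame({"x": x, "y": x.copy(), "z": x.copy()})
        model = fit_sequential(HarmonizedSurveyTable(schema, df),
                               config=NO_TUNE, seed=4)
        syn = generate_replicates(model, n=3000, m=1, seed=5).tables[0].data
        assert (syn.z == syn.x).mean() >= 0.99

    def test_invalid_order_rejected(self, canada_small):
        with pytest.raises(SynthesisError):
            SynthesisOrder.for_table(canada_small, ["sex", "income"])

    def test_greedy_order_heuristic_is_a_permutation(self, canada_small):
        order = suggest_order(canada_small, seed=6, max_rows=1000)
        assert sorted(order) == sorted(canada_small.variable_names)


class TestGeneration:
    def test_constant_column_synthesized_as_constant(self):
        schema = [VariableSchema("x", "categorical", ("a", "b")),
                  VariableSchema("c", "continuous")]
        df = pd.DataFrame({"x": ["a", "b"] * 100, "c": 3.25})
        model = fit_sequential(HarmonizedSurveyTable(schema, df),
                               config=NO_TUNE, seed=7)
        syn = generate_replicates(model, n=50, m=2, seed=8)
        for t in syn.tables:
            assert (t.data["c"] == 3.25).all()

    def test_replicate_shapes(self, model_20k):
        reps = generate_replicates(model_20k, n=100, m=10, seed=9)
        assert reps.m == 10 and len(reps.tables) == 10
        assert all(t.n == 100 for t in reps.tables)

    def test_binary_marginal_within_sampling_error(self, canada_20k, replicates_20k):
        p = (canada_20k.data["diabetes"] == "yes").mean()
        se = np.sqrt(p * (1 - p) / 20_000)
        for t in replicates_20k.tables:
            q = (t.data["diabetes"] == "yes").mean()
            assert abs(q - p) < 3 * se

    def test_marginal_fidelity_across_all_levels(self, canada_20k, replicates_20k):
        # >= 95% of (variable, level) pairs within 3 SE of the training share
        syn = replicates_20k.tables[0].data
        train = canada_20k.data
        ok = total = 0
        for v in canada_20k.schema:
            if v.name == "country" or v.kind == "continuous":
                continue
            pt = train[v.name].value_counts(normalize=True, dropna=False)
            ps = syn[v.name].value_counts(normalize=True, dropna=False)
            for level, p in pt.items():
                if p < 0.002:
                    continue
                tol = 3 * np.sqrt(p * (1 - p) / len(train))
                total += 1
                ok += abs(ps.get(level, 0.0) - p) < tol
        assert ok / total >= 0.95

    def test_bivariate_association_preserved(self, canada_20k, replicates_20k):
        syn = replicates_20k.tables[0].data
        train = canada_20k.data
        names = [v.name for v in canada_20k.schema if v.kind != "continuous"]
        for a, b in zip(names[1:-1], names[2:]):
            v_train = cramers_v(train[a].fillna("NA"), train[b].fillna("NA"))
            v_syn = cramers_v(syn[a].fillna("NA"), syn[b].fillna("NA"))
            assert abs(v_train - v_syn) < 0.05, (a, b)

    def test_missingness_rate_preserved(self, canada_20k, replicates_20k):
        train_rate = canada_20k.data["bmi_lt25"].isna().mean()
        syn_rate = replicates_20k.tables[0].data["bmi_lt25"].isna().mean()
        se = np.sqrt(train_rate * (1 - train_rate) / 20_000)
        assert abs(syn_rate - train_rate) < 4 * se

    def test_no_excess_row_copying(self, canada_20k, replicates_20k):
        cols = [v.name for v in canada_20k.schema]
        train_keys = canada_20k.data[cols].fillna("NA").apply(tuple, axis=1)
        dup_baseline = train_keys.duplicated(keep=False).mean()
        syn_keys = replicates_20k.tables[0].data[cols].fillna("NA").apply(tuple, axis=1)
        match_rate = syn_keys.isin(set(train_keys)).mean()
        assert match_rate <= dup_baseline + 0.01

    def test_full_determinism_and_replicate_independence(self, model_20k):
        r1 = generate_replicates(model_20k, n=500, m=2, seed=77)
        r2 = generate_replicates(model_20k, n=500, m=2, seed=77)
        for t1, t2 in zip(r1.tables, r2.tables):
            pd.testing.assert_frame_equal(t1.data, t2.data)
        assert not r1.tables[0].data.fillna("").equals(r1.tables[1].data.fillna(""))

    def test_invalid_sizes_rejected(self, model_20k):
        with pytest.raises(SynthesisError):
            generate_replicates(model_20k, n=0, m=1, seed=0)
        with pytest.raises(SynthesisError):
            generate_replicates(model_20k, n=10, m=0, seed=0)


class TestContinuousPath:
    @pytest.fixture(scope="class")
    def bmi_model(self):
        table = simulate_country(canada_like(3000, continuous_bmi=True), seed=55)
        return table, fit_sequential(table, config=NO_TUNE, seed=56)

    def test_continuous_values_within_training_range(self, bmi_model):
        table, model = bmi_model
        syn = generate_replicates(model, n=2000, m=1, seed=57).tables[0]
        vals = syn.data["bmi"].dropna()
        train = table.data["bmi"].dropna()
        assert vals.min() >= train.min() - 1e-9
        assert vals.max() <= train.max() + 1e-9

    def test_continuous_distribution_matches(self, bmi_model):
        table, model = bmi_model
        syn = generate_replicates(model, n=3000, m=1, seed=58).tables[0]
        a = table.data["bmi"].dropna()
        b = syn.data["bmi"].dropna()
        assert abs(a.mean() - b.mean()) < 0.3
        assert abs(a.std() - b.std()) < 0.4
        # missingness indicator restored to empty cells
        assert abs(syn.data["bmi"].isna().mean()
                   - table.data["bmi"].isna().mean()) < 0.03


class TestSerialization:
    def test_archive_round_trip_bit_identical_sampling(self, tmp_path):
        table = simulate_country(canada_like(2000), seed=61)
        model = fit_sequential(table, config=NO_TUNE, seed=62)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = SynthesisModel.load(path)
        a = generate_replicates(model, n=500, m=2, seed=63)
        b = generate_replicates(loaded, n=500, m=2, seed=63)
        for t1, t2 in zip(a.tables, b.tables):
            pd.testing.assert_frame_equal(t1.data, t2.data)
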