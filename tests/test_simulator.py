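import itertools

import numpy as np
import pandas as pd
import pytest

from synthpool.schema import SchemaError
from synthpool.simulate import (
    DEMOGRAPHICS, CanheartIndex, CountrySpec, canada_like, canheart_scores,
    compute_canheart, simulate_country, split_members_holdout,
)


def _degenerate_spec(n=1):
    """Every marginal concentrated on a single level, zero effect logits."""
    spec = canada_like(n)
    marg = {}
    for var, probs in spec.marginals.items():
        if var in ("bmi_lt25", "hypertension", "diabetes", "smoking"):
            marg[var] = {"male": 0.0, "female": 0.0}
        else:
            levels = list(probs)
            marg[var] = {l: (1.0 if i == 0 else 0.0) for i, l in enumerate(levels)}
    return CountrySpec("CA", n, marg,
                       effect_logits={v: {} for v in ("bmi_lt25", "hypertension",
                                                      "diabetes", "smoking")},
                       missing_rates={})


class TestSimulateCountry:
    def test_published_diabetes_prevalence_recovered(self):
        # male 10.3%, female 8.5%: empirical prevalence within 3 SE at n=50,000
        table = simulate_country(canada_like(50_000), seed=1)
        df = table.data
        for sex, p in (("male", 0.103), ("female", 0.085)):
            sub = df[(df.sex == sex) & df.diabetes.notna()]
            se = np.sqrt(p * (1 - p) / len(sub))
            assert abs((sub.diabetes == "yes").mean() - p) < 3 * se

    def test_degenerate_spec_forces_single_row(self):
        table = simulate_country(_degenerate_spec(1), seed=0)
        row = table.data.iloc[0]
        assert row["sex"] == "male"
        assert row["age_group"] == "<20"
        assert row["bmi_lt25"] == "no"  # prevalence target 0

    def test_seed_determinism(self):
        spec = canada_like(200)
        a = simulate_country(spec, seed=7).data
        b = simulate_country(spec, seed=7).data
        pd.testing.assert_frame_equal(a, b)
        c = simulate_country(spec, seed=8).data
        assert (a.fillna("") != c.fillna("")).any().any()

    def test_invalid_marginal_names_variable(self):
        spec = canada_like(100)
        spec.marginals["income"] = {"low": 0.5, "medium": 0.2, "high": 0.2}
        with pytest.raises(SchemaError, match="income"):
            simulate_country(spec, seed=0)
        spec = canada_like(100)
        spec.marginals["sex"] = {"male": -0.1, "female": 1.1}
        with pytest.raises(SchemaError, match="sex"):
            simulate_country(spec, seed=0)

    def test_marginals_converge_at_scale(self):
        spec = canada_like(50_000)
        table = simulate_country(spec, seed=202)
        for var in DEMOGRAPHICS:
            col = table.data[var].dropna()
            for level, p in spec.marginals[var].items():
                if p in (0.0, 1.0):
                    continue
                tol = 3 * np.sqrt(p * (1 - p) / len(col))
                assert abs((col == level).mean() - p) < tol, (var, level)

    def test_sex_gap_monotone_in_marginal_targets(self):
        # widening the published male/female targets widens the realized gap
        base = canada_like(50_000)
        wide = canada_like(50_000)
        wide.marginals["smoking"] = {"male": 0.30, "female": 0.10}
        gaps = []
        for spec in (base, wide):
            df = simulate_country(spec, seed=303).data
            male = df[(df.sex == "male") & df.smoking.notna()]
            female = df[(df.sex == "female") & df.smoking.notna()]
            gaps.append((male.smoking == "yes").mean() - (female.smoking == "yes").mean())
        assert gaps[1] > gaps[0]

    def test_risk_factor_age_gradient_follows_logit(self):
        spec = canada_like(50_000)
        df = simulate_country(spec, seed=404).data
        young = df[df.age_group.isin(["<20", "20-29"]) & df.hypertension.notna()]
        old = df[df.age_group.isin(["60-69", ">=70"]) & df.hypertension.notna()]
        assert (old.hypertension == "yes").mean() > (young.hypertension == "yes").mean() + 0.1

    def test_continuous_bmi_consistent_with_indicator(self):
        table = simulate_country(canada_like(5000, continuous_bmi=True), seed=9)
        df = table.data.dropna(subset=["bmi", "bmi_lt25"])
        assert ((df.bmi < 25) == (df.bmi_lt25 == "yes")).all()


class TestCanheart:
    def test_enumeration_of_all_indicator_combinations(self):
        values = []
        for smoking, bmi, diab, hyp in itertools.product(["yes", "no"], repeat=4):
            row = {"smoking": smoking, "bmi_lt25": bmi,
                   "diabetes": diab, "hypertension": hyp}
            idx = compute_canheart(row)
            values.append(idx.value)
        assert min(values) == 0 and max(values) == 4
        assert set(values) <= {0, 1, 2, 3, 4}

    def test_ideal_and_worst_and_single_adverse(self):
        ideal = {"smoking": "no", "bmi_lt25": "yes", "diabetes": "no",
                 "hypertension": "no"}
        assert compute_canheart(ideal).value == 4
        worst = {"smoking": "yes", "bmi_lt25": "no", "diabetes": "yes",
                 "hypertension": "yes"}
        assert compute_canheart(worst).value == 0
        smoker = dict(ideal, smoking="yes")
        assert compute_canheart(smoker).value == 3

    def test_missing_component_flags_missing_outcome(self):
        row = {"smoking": np.nan, "bmi_lt25": "yes", "diabetes": "no",
               "hypertension": "no"}
        assert compute_canheart(row) is None

    def test_continuous_bmi_fallback(self):
        row = {"smoking": "no", "bmi": 23.4, "diabetes": "no", "hypertension": "no"}
        assert compute_canheart(row).value == 4

    def test_vectorized_scores_match_rowwise(self, canada_small):
        scores = canheart_scores(canada_small)
        sample = canada_small.data.head(200)
        for i, row in sample.iterrows():
            idx = compute_canheart(row)
            if idx is None:
                assert np.isnan(scores[i])
            else:
                assert scores[i] == idx.value

    def test_out_of_range_value_rejected(self):
        with pytest.raises(ValueError):
            CanheartIndex(5)


class TestSplit:
    def test_partition_arithmetic(self, canada_small):
        members, holdout = split_members_holdout(canada_small, 0.5, seed=1)
        assert members.n == holdout.n == canada_small.n // 2
        merged = pd.concat([members.data, holdout.data]).sort_values(
            list(members.data.columns)).reset_index(drop=True)
        original = canada_small.data.sort_values(
            list(members.data.columns)).reset_index(drop=True)
        pd.testing.assert_frame_equal(merged, original)

    def test_extreme_fraction_keeps_both_parts_nonempty(self, canada_small):
        small = canada_small.subset(canada_small.data.index < 10)
        members, holdout = split_members_holdout(small, 0.999, seed=2)
        assert members.n == 9 and holdout.n == 1
        members, holdout = split_members_holdout(small, 0.001, seed=2)
        assert members.n == 1 and holdout.n == 9

    def test_seed_determinism_and_validation(self, canada_small):
        a1, _ = split_members_holdout(canada_small, 0.3, seed=3)
        a2, _ = split_members_holdout(canada_small, 0.3, seed=3)
        pd.testing.assert_frame_equal(a1.data, a2.data)
        with pytest.raises(ValueError):
            split_members_holdout(canada_small, 1.0, seed=0)
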