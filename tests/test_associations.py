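import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from assocmap.associations import (
    FIT_FAILED,
    OK,
    SKIPPED_CONSTANT,
    AliasedDesignError,
    Design,
    ModelSpec,
    bh_adjust,
    build_design,
    fit_feature,
    results_to_frame,
    run_model,
)
from assocmap.schema import CATEGORICAL, CONTINUOUS, VariableSchema


def brute_force_bh(p):
    """Independent step-up oracle: raw_i = p_(i) m / i, cummin from the top."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    raw = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _design_from(metadata, schema, spec):
    return build_design(metadata, schema, spec)


@pytest.fixture
def cohort_schema_small():
    return VariableSchema(
        sample_id_col="sid",
        fixed_vars={"disease": CATEGORICAL, "diet": CATEGORICAL, "age": CONTINUOUS},
        level_order={"disease": ["case", "control"],
                     "diet": ["breastfed", "formula", "mixed"]},
        reference={"disease": "control", "diet": "breastfed"},
    )


class TestBuildDesign:
    def test_treatment_coding_binary_plus_continuous(self, cohort_schema_small):
        meta = pd.DataFrame(
            {"disease": ["case", "control", "case", "control"],
             "age": [1.0, 2.0, 3.0, 4.0]},
            index=pd.Index(list("abcd"), name="sid"),
        )
        spec = ModelSpec(name="m", fixed=("disease", "age"))
        design = _design_from(meta, cohort_schema_small, spec)
        assert list(design.exog.columns) == ["Intercept", "disease[case]", "age"]
        assert design.terms == [("disease", "case", "control"), ("age", "", "")]
        np.testing.assert_array_equal(design.exog["disease[case]"], [1, 0, 1, 0])

    def test_three_level_variable_gets_two_indicators(self, cohort_schema_small):
        meta = pd.DataFrame(
            {"diet": ["breastfed", "formula", "mixed", "formula"]},
            index=pd.Index(list("abcd"), name="sid"),
        )
        spec = ModelSpec(name="m", fixed=("diet",))
        design = _design_from(meta, cohort_schema_small, spec)
        assert list(design.exog.columns) == ["Intercept", "diet[formula]", "diet[mixed]"]

    def test_identical_binary_columns_are_aliased(self):
        schema = VariableSchema(
            sample_id_col="sid",
            fixed_vars={"g1": CATEGORICAL, "g2": CATEGORICAL},
            level_order={"g1": ["a", "b"], "g2": ["a", "b"]},
            reference={"g1": "a", "g2": "a"},
        )
        meta = pd.DataFrame(
            {"g1": ["a", "b", "a", "b"], "g2": ["a", "b", "a", "b"]},
            index=pd.Index(list("abcd"), name="sid"),
        )
        with pytest.raises(AliasedDesignError) as err:
            _design_from(meta, schema, ModelSpec(name="m", fixed=("g1", "g2")))
        assert err.value.column == "g2[b]"
        assert err.value.aliased_with == "g1[b]"

    def test_reference_level_must_have_samples(self, cohort_schema_small):
        meta = pd.DataFrame(
            {"diet": ["formula", "mixed", "formula", "mixed"]},
            index=pd.Index(list("abcd"), name="sid"),
        )
        with pytest.raises(Exception, match="reference"):
            _design_from(meta, cohort_schema_small, ModelSpec(name="m", fixed=("diet",)))


class TestFitFeature:
    @pytest.fixture
    def two_group_design(self):
        exog = pd.DataFrame(
            {"Intercept": [1.0, 1, 1, 1], "g[B]": [0.0, 0, 1, 1]},
            index=pd.Index(list("abcd"), name="sid"),
        )
        return Design(exog=exog, terms=[("g", "B", "A")], groups=pd.DataFrame(index=exog.index))

    def test_binary_coefficient_is_group_mean_difference(self, two_group_design):
        status, stats = fit_feature([0.10, 0.20, 0.40, 0.50], two_group_design)
        assert status == OK
        coef, _, _ = stats[0]
        assert coef == pytest.approx(0.30, abs=1e-12)

    def test_binary_p_equals_pooled_two_sample_t(self, two_group_design):
        y = [0.10, 0.20, 0.40, 0.50]
        _, stats = fit_feature(y, two_group_design)
        _, _, p = stats[0]
        expected = sps.ttest_ind(y[2:], y[:2], equal_var=True).pvalue
        assert p == pytest.approx(expected, abs=1e-10)

    def test_constant_feature_skipped(self, two_group_design):
        status, stats = fit_feature([0.3, 0.3, 0.3, 0.3], two_group_design)
        assert status == SKIPPED_CONSTANT and stats == []

    def test_underdetermined_fit_fails_gracefully(self):
        exog = pd.DataFrame({"Intercept": [1.0, 1], "x": [0.0, 1]},
                            index=pd.Index(list("ab"), name="sid"))
        design = Design(exog=exog, terms=[("x", "", "")],
                        groups=pd.DataFrame(index=exog.index))
        status, _ = fit_feature([0.1, 0.4], design)
        assert status == FIT_FAILED

    def test_mixed_model_matches_ols_when_no_subject_variance(self):
        rng = np.random.default_rng(3)
        n_subj, visits = 40, 4
        n = n_subj * visits
        idx = pd.Index([f"s{i}" for i in range(n)], name="sid")
        group = np.repeat(rng.integers(0, 2, n_subj), visits).astype(float)
        exog = pd.DataFrame({"Intercept": np.ones(n), "g[B]": group}, index=idx)
        y = 0.2 + 0.1 * group + rng.normal(0, 0.05, n)  # zero between-subject variance
        subjects = pd.DataFrame({"subj": np.repeat(np.arange(n_subj), visits).astype(str)},
                                index=idx)
        terms = [("g", "B", "A")]
        _, ols = fit_feature(y, Design(exog=exog, terms=terms,
                                       groups=pd.DataFrame(index=idx)))
        status, mixed = fit_feature(y, Design(exog=exog, terms=terms, groups=subjects))
        assert status == OK
        assert mixed[0][0] == pytest.approx(ols[0][0], abs=1e-3)


class TestBHAdjust:
    def test_hand_enumerated_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.04, 0.03, 0.005]), [0.02, 0.04, 0.04, 0.02]
        )

    def test_single_p_is_identity(self):
        np.testing.assert_allclose(bh_adjust([0.5]), [0.5])

    def test_all_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.07] * 5), [0.07] * 5)

    def test_missing_entries_pass_through(self):
        q = bh_adjust([0.01, np.nan, 0.02])
        assert np.isnan(q[1])
        # family size excludes the missing entry
        np.testing.assert_allclose(q[[0, 2]], brute_force_bh([0.01, 0.02]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_agrees_with_brute_force_step_up(self, ps):
        np.testing.assert_allclose(bh_adjust(ps), brute_force_bh(ps), atol=1e-12)

    def test_q_never_below_p(self):
        rng = np.random.default_rng(0)
        p = rng.random(100)
        assert (bh_adjust(p) >= p - 1e-12).all()


class TestRunModel:
    def test_association_count_and_family(self, two_group_table, two_group_schema):
        spec = ModelSpec(name="m", fixed=("group", "cov"))
        results = run_model(two_group_table, two_group_schema, spec)
        # 3 features x (group=case vs ctrl, cov) = 6 rows
        assert len(results) == 6
        frame = results_to_frame(results)
        assert set(frame["feature"]) == {"feat_a", "feat_b", "feat_c"}
        ok = frame[frame["status"] == OK]
        np.testing.assert_allclose(
            np.sort(ok["q"]), np.sort(brute_force_bh(ok["p"].to_numpy()))
        )

    def test_constant_feature_reported_not_fitted(self, two_group_table, two_group_schema):
        spec = ModelSpec(name="m", fixed=("group",))
        frame = results_to_frame(run_model(two_group_table, two_group_schema, spec))
        const = frame[frame["feature"] == "feat_c"]
        assert (const["status"] == SKIPPED_CONSTANT).all()
        assert const["p"].isna().all() and const["q"].isna().all()

    def test_q_values_invariant_to_feature_order(self, two_group_schema):
        from assocmap.tables import SampleTable

        rng = np.random.default_rng(11)
        idx = pd.Index([f"s{i}" for i in range(12)], name="sid")
        metadata = pd.DataFrame(
            {"group": ["case"] * 6 + ["ctrl"] * 6, "cov": rng.normal(10, 2, 12)},
            index=idx,
        )
        features = pd.DataFrame(rng.uniform(0.5, 3, (12, 4)), index=idx,
                                columns=["f0", "f1", "f2", "f3"])
        spec = ModelSpec(name="m", fixed=("group", "cov"))
        table = SampleTable(metadata=metadata, features=features, sample_id_col="sid")
        shuffled = SampleTable(
            metadata=metadata,
            features=features[["f2", "f0", "f3", "f1"]],
            sample_id_col="sid",
        )
        a = results_to_frame(run_model(table, two_group_schema, spec))
        b = results_to_frame(run_model(shuffled, two_group_schema, spec))
        key = ["feature", "variable", "level"]
        merged = a.merge(b, on=key, suffixes=("_a", "_b"))
        assert len(merged) == len(a)
        np.testing.assert_allclose(merged["q_a"], merged["q_b"])

    def test_missing_metadata_shrinks_fit_not_results(self, two_group_table, two_group_schema):
        table = two_group_table
        table.metadata.loc[table.metadata.index[0], "group"] = np.nan
        spec = ModelSpec(name="m", fixed=("group",))
        frame = results_to_frame(run_model(table, two_group_schema, spec))
        assert (frame["n_used"] == table.n_samples - 1).all()

    def test_spec_validation(self):
        with pytest.raises(ValueError, match="fixed"):
            ModelSpec(name="m", fixed=())
        with pytest.raises(ValueError, match="q_threshold"):
            ModelSpec(name="m", fixed=("x",), q_threshold=1.2)
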