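import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rpclust as rp
from rpclust.data import DataError
from rpclust.preprocessing import ConfigurationError


class TestAverageRecalls:
    @pytest.mark.parametrize("day1, day2, expected", [
        ([2.0], [0.0], [1.0]),
        ([1, 0, 2], [3, 4, 0], [2, 2, 1]),
    ])
    def test_two_day_mean(self, day1, day2, expected):
        cols = [f"f{i}" for i in range(len(day1))]
        rec = pd.DataFrame(
            [{"person_id": 1, "day_index": 1,
              **dict(zip(cols, day1))},
             {"person_id": 1, "day_index": 2,
              **dict(zip(cols, day2))}])
        out = rp.average_recalls(rec)
        assert np.allclose(out.loc[1].to_numpy(), expected)

    def test_single_day_kept_unchanged(self):
        rec = pd.DataFrame([{"person_id": 9, "day_index": 1, "f0": 3.5}])
        out = rp.average_recalls(rec)
        assert out.loc[9, "f0"] == 3.5

    def test_person_without_recalls_logged_not_raised(self, caplog):
        rec = pd.DataFrame([{"person_id": 1, "day_index": 1, "f0": 1.0}])
        with caplog.at_level("WARNING"):
            out = rp.average_recalls(rec, expected_ids=[1, 2])
        assert 2 not in out.index
        assert "no complete dietary recall" in caplog.text


class TestFitCategorization:
    def test_uniform_1_to_9_gives_3_and_6(self):
        # sort-based oracle: with nine equally weighted positive values the
        # 1/3 and 2/3 inverse-CDF quantiles are the 3rd and 6th order stats
        amounts = pd.DataFrame({"f": np.arange(1.0, 10.0)})
        rule = rp.fit_categorization(amounts)
        assert rule.cutpoints["f"] == (3.0, 6.0)

    def test_zeros_ignored_when_fitting(self):
        amounts = pd.DataFrame({"f": [0, 0, 0] + list(range(1, 10))})
        rule = rp.fit_categorization(amounts)
        assert rule.cutpoints["f"] == (3.0, 6.0)

    def test_all_zero_column_degenerate(self):
        rule = rp.fit_categorization(pd.DataFrame({"f": [0.0, 0.0]}))
        assert "f" in rule.degenerate

    def test_constant_positive_column_degenerate(self):
        rule = rp.fit_categorization(pd.DataFrame({"f": [5.0, 5.0, 5.0]}))
        assert "f" in rule.degenerate

    def test_rule_roundtrip(self, tmp_path):
        amounts = pd.DataFrame({"a": np.arange(1.0, 10.0),
                                "b": np.zeros(9)})
        rule = rp.fit_categorization(amounts)
        rule.to_json(tmp_path / "rule.json")
        back = rp.CategorizationRule.from_json(tmp_path / "rule.json")
        assert back.cutpoints["a"] == (3.0, 6.0)
        assert "b" in back.degenerate


class TestCategorize:
    @pytest.fixture
    def rule(self):
        return rp.fit_categorization(
            pd.DataFrame({"f": np.arange(1.0, 10.0)}))

    @pytest.mark.parametrize("amount, level", [
        (0.0, 1),    # zero is no-consumption by definition
        (3.0, 2),    # tie at the cutpoint goes to the lower level
        (3.0001, 3),
        (6.0, 3),
        (6.5, 4),
    ])
    def test_boundary_mapping(self, rule, amount, level):
        out = rp.categorize(pd.DataFrame({"f": [amount]}), rule)
        assert out.y[0, 0] == level

    def test_negative_amount_names_position(self, rule):
        with pytest.raises(DataError, match="row 1.*'f'"):
            rp.categorize(pd.DataFrame({"f": [1.0, -0.5]}), rule)

    def test_degenerate_column_collapses_to_consumed(self):
        amounts = pd.DataFrame({"f": [0.0, 5.0, 5.0]})
        rule = rp.fit_categorization(amounts)
        out = rp.categorize(amounts, rule)
        assert out.y[:, 0].tolist() == [1, 2, 2]

    @given(st.lists(st.floats(min_value=0, max_value=100,
                              allow_nan=False), min_size=8, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_amount(self, values):
        amounts = pd.DataFrame({"f": values})
        rule = rp.fit_categorization(amounts)
        levels = rp.categorize(amounts, rule).y[:, 0]
        order = np.argsort(values, kind="stable")
        assert (np.diff(levels[order]) >= 0).all()

    def test_tertile_balance_among_consumers(self):
        # with distinct positive values the consumed levels split within one
        # person of n_pos / 3 each
        rng = np.random.default_rng(0)
        vals = np.concatenate([np.zeros(20), rng.permutation(90) + 1.0])
        amounts = pd.DataFrame({"f": vals})
        rule = rp.fit_categorization(amounts)
        levels = rp.categorize(amounts, rule).y[:, 0]
        counts = np.bincount(levels, minlength=5)[2:5]
        assert (np.abs(counts - 30) <= 1).all()


class TestEligibility:
    @pytest.fixture
    def table(self):
        return pd.DataFrame({
            "sex": ["female"] * 10,
            "age": [25] * 10,
            "race": [1] * 10,
            "income_ratio": [1.0] * 5 + [2.0, 1.4, 1.31] + [1.0] * 2,
            "pregnant": [True, True] + [False] * 8,
            "n_recalls": [1] * 10,
        })

    def test_tally_counts_in_fixed_order(self, table):
        kept, tally = rp.apply_eligibility(table, rp.EligibilityCriteria())
        # income is applied before pregnancy: 3 above-ceiling persons fall
        # under income; the 2 pregnant persons are below ceiling
        assert tally["income"] == 3
        assert tally["pregnancy"] == 2
        assert len(kept) == 5

    def test_boundary_person_retained(self):
        tab = pd.DataFrame({"sex": ["female"], "age": [20], "race": [1],
                            "income_ratio": [1.30], "pregnant": [False],
                            "n_recalls": [1]})
        kept, _ = rp.apply_eligibility(tab, rp.EligibilityCriteria())
        assert kept == [0]

    def test_ratio_just_above_ceiling_excluded(self):
        tab = pd.DataFrame({"sex": ["female"], "age": [30], "race": [1],
                            "income_ratio": [1.31], "pregnant": [False],
                            "n_recalls": [1]})
        kept, tally = rp.apply_eligibility(tab, rp.EligibilityCriteria())
        assert kept == [] and tally["income"] == 1

    def test_idempotent(self, table):
        crit = rp.EligibilityCriteria()
        kept, _ = rp.apply_eligibility(table, crit)
        kept2, tally2 = rp.apply_eligibility(table.loc[kept], crit)
        assert kept2 == kept
        assert all(v == 0 for v in tally2.values())

    def test_missing_column_is_configuration_error(self, table):
        with pytest.raises(ConfigurationError, match="income_ratio"):
            rp.apply_eligibility(table.drop(columns="income_ratio"),
                                 rp.EligibilityCriteria())


class TestRiskFlags:
    def test_threshold_boundaries(self):
        tab = pd.DataFrame({
            "bmi": [30.0, 29.9],
            "total_chol": [200.0, 201.0],
            "glucose": [126.0, 127.0],
        })
        flags = rp.derive_risk_flags(tab)
        assert flags["obesity"].tolist() == [1, 0]          # >= inclusive
        # strict >: values above the cutoff set the flag regardless of the
        # other (missing) disjuncts
        assert flags["high_cholesterol"][1] == 1
        assert flags["diabetes"][1] == 1

    def test_strict_cholesterol_boundary_with_full_inputs(self):
        tab = pd.DataFrame({"total_chol": [200.0], "ldl": [100.0],
                            "chol_meds": [0]})
        assert rp.derive_risk_flags(tab)["high_cholesterol"].tolist() == [0]

    def test_missing_disjunct_with_known_true_is_true(self):
        tab = pd.DataFrame({"glucose": [np.nan], "diabetes_meds": [1]})
        assert rp.derive_risk_flags(tab)["diabetes"].tolist() == [1]

    def test_all_missing_gives_missing_flag(self):
        tab = pd.DataFrame({"bmi": [np.nan]})
        flags = rp.derive_risk_flags(tab)
        assert flags["obesity"].isna().all()

    def test_hypertension_or(self):
        tab = pd.DataFrame({"sbp": [150, 120, 120], "dbp": [80, 95, 80],
                            "bp_meds": [0, 0, 1]})
        assert rp.derive_risk_flags(tab)["hypertension"].tolist() == [1, 1, 1]
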