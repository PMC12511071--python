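import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gabapbpk.validation import (
    PredObsPair,
    fold_fraction,
    gmfe,
    gmfe_signed,
    load_reference_table,
    mfe,
    mfe_mean,
    pairs_from_table,
    summarize,
    validate_engine,
)


def make_pairs(values, param="auc_0_inf"):
    return [PredObsPair(param, p, o) for p, o in values]


class TestMfe:
    def test_reported_pair(self):
        assert round(mfe(33.99, 26.18), 2) == 1.30

    def test_identity(self):
        assert mfe(7.3, 7.3) == 1.0

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            mfe(0.0, 1.0)
        with pytest.raises(ValueError):
            PredObsPair("cmax", 1.0, -2.0)

    def test_adult_development_mean(self):
        pairs = pairs_from_table(cohort="adult_dev", parameter="auc_0_inf")
        assert round(mfe_mean(pairs), 2) == 1.05


class TestGmfe:
    def test_symmetry_of_absolute_logs(self):
        assert gmfe(make_pairs([(2, 1), (1, 2)])) == pytest.approx(2.0, rel=1e-12)

    def test_pediatric_cmax_from_raw_values(self):
        pairs = make_pairs([(4.05, 4.52), (3.63, 2.6), (4.34, 3.74)], "cmax")
        assert round(gmfe(pairs), 2) == 1.22

    def test_printed_pediatric_cmax_mfe_is_a_typo(self):
        # the table prints 1.60 for this pair; the raw ratio is 1.16 and the
        # cohort GMFE (1.22) is only consistent with the raw value
        assert round(mfe(4.34, 3.74), 2) == 1.16

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gmfe([])

    @settings(derandomize=True, max_examples=50)
    @given(
        vals=st.lists(
            st.tuples(st.floats(0.1, 100), st.floats(0.1, 100)), min_size=2, max_size=8
        ),
        c=st.floats(0.01, 100),
    )
    def test_permutation_and_scale_invariance(self, vals, c):
        pairs = make_pairs(vals)
        g = gmfe(pairs)
        assert g >= 1.0
        assert gmfe(list(reversed(pairs))) == pytest.approx(g, rel=1e-9)
        scaled = make_pairs([(p * c, o * c) for p, o in vals])
        assert gmfe(scaled) == pytest.approx(g, rel=1e-9)
        worst = max(max(p / o, o / p) for p, o in vals)
        assert g <= worst * (1 + 1e-9)


class TestFoldFraction:
    def test_identical_pairs(self):
        assert fold_fraction(make_pairs([(1, 1), (2, 2)]), 1.25) == 1.0

    def test_direct_count(self):
        assert fold_fraction(make_pairs([(1, 1), (3, 1)]), 2.0) == 0.5

    def test_constructed_24_of_25(self):
        vals = [(1.0, 1.0)] * 24 + [(5.0, 1.0)]
        assert fold_fraction(make_pairs(vals), 2.0) == pytest.approx(0.96)

    def test_non_increasing_in_stricter_factor(self):
        pairs = pairs_from_table(cohort="adult_eval", parameter="auc_0_inf")
        fr = [fold_fraction(pairs, f) for f in (2.0, 1.5, 1.25)]
        assert fr[0] >= fr[1] >= fr[2]

    def test_invalid_factor(self):
        with pytest.raises(ValueError):
            fold_fraction(make_pairs([(1, 1)]), 0.9)


class TestReferenceTableAggregates:
    """The packaged predicted/observed table reproduces the reported metrics."""

    @pytest.mark.parametrize(
        "cohort,expected",
        [
            ("adult_dev", {"auc_0_inf": 1.18, "cmax": 1.11, "tmax": 1.31}),
            ("ri_adult", {"auc_0_inf": 1.48, "cmax": 1.40, "tmax": 1.67}),
            ("pediatric", {"auc_0_inf": 1.51, "cmax": 1.22, "tmax": 1.11}),
        ],
    )
    def test_cohort_gmfe_exact_to_two_decimals(self, cohort, expected):
        for param, val in expected.items():
            pairs = pairs_from_table(cohort=cohort, parameter=param)
            assert round(gmfe(pairs), 2) == val

    def test_adult_eval_aggregates_within_rounding_band(self):
        # the printed evaluation aggregate (1.34) disagrees at the 2nd
        # decimal with recomputation from its own printed rows (~1.36)
        for param, printed in [("auc_0_inf", 1.34), ("cmax", 1.15), ("tmax", 1.28)]:
            pairs = pairs_from_table(cohort="adult_eval", parameter=param)
            assert gmfe(pairs) == pytest.approx(printed, abs=0.05)

    def test_signed_variant_does_not_reproduce_reported_value(self):
        pairs = pairs_from_table(cohort="adult_dev", parameter="auc_0_inf")
        assert round(gmfe_signed(pairs), 2) == 1.03
        assert round(gmfe(pairs), 2) == 1.18


class TestValidateEngine:
    def test_perfect_predictions(self):
        table = load_reference_table()
        sub = table[table["cohort"] == "adult_dev"].copy()
        # one row-set per study so "predicted == observed" is well defined
        sub["regimen"] = sub["regimen"] + "|" + sub["study_label"]
        preds = {}
        for r in sub.itertuples():
            preds.setdefault(r.regimen, {})[r.parameter] = r.observed
        out = validate_engine(preds, "adult_dev", table=sub)
        for param, summary in out.items():
            assert summary.gmfe == pytest.approx(1.0)
            assert summary.pass_2fold
            assert all(v == 1.0 for v in summary.fold_fractions.values())

    def test_reference_predictions_reproduce_reported_gmfe(self):
        table = load_reference_table()
        sub = table[table["cohort"] == "adult_dev"]
        preds = {}
        for r in sub.itertuples():
            # one prediction per regimen label is not enough here: studies
            # sharing a regimen have distinct predictions, so pair directly
            preds.setdefault(f"{r.regimen}|{r.study_label}", {})[r.parameter] = r.predicted
        sub = sub.assign(regimen=sub["regimen"] + "|" + sub["study_label"])
        out = validate_engine(preds, "adult_dev", table=sub)
        assert round(out["auc_0_inf"].gmfe, 2) == 1.18
        assert round(out["cmax"].gmfe, 2) == 1.11
        assert round(out["tmax"].gmfe, 2) == 1.31

    def test_missing_regimen_listed_as_gap(self):
        preds = {"single_400": {"auc_0_inf": 30.0, "cmax": 3.0, "tmax": 2.5}}
        out = validate_engine(preds, "adult_dev")
        assert out["auc_0_inf"].gaps  # 300/600 mg studies unmatched
        assert len(out["auc_0_inf"].mfe_per_pair) == 5
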