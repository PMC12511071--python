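import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gabapbpk import calibration
from gabapbpk.physiology import (
    Demographics,
    RENAL_CLASSES,
    bsa,
    build_individual,
    gfr_maturation,
    representative_individual,
    sample_population,
)


class TestBSA:
    def test_du_bois_reference_adult(self):
        # 0.007184 * 70^0.425 * 170^0.725, hand-evaluated
        assert bsa(Demographics(30, 70, 170)) == pytest.approx(1.8097, abs=1e-3)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            Demographics(30, 0.0, 170)
        with pytest.raises(ValueError):
            Demographics(30, 70, -1.0)

    @settings(derandomize=True, max_examples=50)
    @given(w=st.floats(3, 150), h=st.floats(40, 210))
    def test_power_law_scaling(self, w, h):
        # doubling both W and H multiplies BSA by 2^(0.425+0.725)
        r = bsa(Demographics(30, 2 * w, 2 * h)) / bsa(Demographics(30, w, h))
        assert r == pytest.approx(2 ** 1.15, rel=1e-9)


class TestGfrMaturation:
    def test_anchors(self):
        assert gfr_maturation(0.0) == pytest.approx(0.30, abs=0.02)
        assert gfr_maturation(2.0) >= 0.95
        assert gfr_maturation(30.0) == 1.0

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            gfr_maturation(-0.1)

    @settings(derandomize=True, max_examples=100)
    @given(a=st.floats(0, 90), da=st.floats(0.001, 10))
    def test_monotone_and_bounded(self, a, da):
        m1, m2 = gfr_maturation(a), gfr_maturation(a + da)
        assert 0 < m1 <= 1.0
        assert m2 >= m1


class TestBuildIndividual:
    def test_adult_normal_gfr_normalization(self, adult):
        # 100 mL/min/1.73 m2 scaled by BSA 1.81 m2
        assert adult.physiology.gfr_absolute == pytest.approx(104.6, abs=0.2)
        assert adult.physiology.ts_scale == 1.0

    def test_severe_ri_gfr(self):
        ind = representative_individual("adult", "severe")
        expected = 5.0 * ind.physiology.bsa / 1.73
        assert ind.physiology.gfr_absolute == pytest.approx(expected, rel=1e-12)

    def test_unknown_renal_class_rejected(self):
        with pytest.raises(ValueError):
            build_individual(Demographics(30, 70, 170), "dialysis")

    def test_class_ordering_of_gfr_ts_kidney(self):
        order = ["normal", "mild", "moderate", "severe"]
        inds = [representative_individual("adult", c) for c in order]
        for a, b in zip(inds, inds[1:]):
            assert a.physiology.gfr_absolute > b.physiology.gfr_absolute
            assert a.physiology.ts_scale > b.physiology.ts_scale
            assert a.physiology.kidney_volume > b.physiology.kidney_volume

    def test_pediatric_ts_ordering(self):
        vals = [calibration.TS_SCALE_PEDIATRIC[c] for c in ("normal", "mild", "moderate", "severe")]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert all(0 < v <= 1 for v in vals)

    @pytest.mark.parametrize("band", ["1m-3y", "3-12y", "12-17y", "adult"])
    def test_volumes_within_body_weight(self, band):
        ind = representative_individual(band)
        assert ind.physiology.total_volume() <= ind.demographics.weight
        assert all(v > 0 and q > 0 for v, q in ind.physiology.organs.values())

    def test_gfr_increases_with_bsa(self):
        small = build_individual(Demographics(30, 60, 160))
        large = build_individual(Demographics(30, 90, 185))
        assert large.physiology.gfr_absolute > small.physiology.gfr_absolute


class TestSamplePopulation:
    def test_empty(self):
        assert sample_population(0, (3, 12)) == []

    def test_seed_reproducibility(self):
        a = sample_population(50, (3, 12), "mild", seed=7)
        b = sample_population(50, (3, 12), "mild", seed=7)
        assert [(x.demographics.age, x.demographics.weight) for x in a] == [
            (x.demographics.age, x.demographics.weight) for x in b
        ]

    def test_age_range_containment(self):
        pop = sample_population(200, (3, 12), seed=1)
        ages = np.array([p.demographics.age for p in pop])
        assert ages.min() >= 3 and ages.max() < 12

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            sample_population(5, (12, 3))
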