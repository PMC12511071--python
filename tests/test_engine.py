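import math
from dataclasses import replace

import numpy as np
import pytest

from gabapbpk.engine import (
    GABAPENTIN,
    DoseEvent,
    ORGAN_ORDER,
    Regimen,
    apply_release,
    build_ode,
    mass_balance_error,
    partition_coefficients,
    renal_clearance,
    simulate,
    vss_plasma,
)
from gabapbpk.nca import auc_trapezoid, nca_single_dose, nca_steady_state
from gabapbpk.physiology import representative_individual


class TestRenalClearance:
    def test_pure_filtration(self, adult):
        drug = replace(GABAPENTIN, fup=1.0, ts_spec=0.0)
        phys = replace(adult.physiology, gfr_absolute=100.0)
        assert renal_clearance(drug, phys) == pytest.approx(6.0, rel=1e-12)

    def test_reference_adult_matches_identified_value(self, adult):
        cl = renal_clearance(GABAPENTIN, adult.physiology)
        assert cl / 0.06 / 70.0 == pytest.approx(3.2, rel=1e-9)  # mL/min/kg

    def test_strictly_decreasing_with_severity(self):
        cls = ["normal", "mild", "moderate", "severe"]
        cl = [
            renal_clearance(GABAPENTIN, representative_individual("adult", c).physiology)
            for c in cls
        ]
        assert all(a > b for a, b in zip(cl, cl[1:]))

    def test_severe_with_no_secretion_is_filtration_only(self, adult):
        ind = representative_individual("adult", "severe")
        drug = replace(GABAPENTIN, ts_spec=0.0)
        expected = 0.73 * 5.0 * ind.physiology.bsa / 1.73 * 0.06  # L/h
        assert renal_clearance(drug, ind.physiology) == pytest.approx(expected, rel=1e-9)


class TestPartitionCoefficients:
    def test_positive_and_dose_independent(self):
        kp = partition_coefficients(GABAPENTIN)
        assert set(kp) == set(ORGAN_ORDER)
        assert all(v > 0 for v in kp.values())

    def test_vss_in_hydrophilic_range(self, adult):
        vss = vss_plasma(adult, GABAPENTIN) / adult.demographics.weight
        assert 0.5 <= vss <= 1.0

    def test_identity_partitioning_gives_body_water_like_volume(self, adult):
        drug = replace(GABAPENTIN, kp_set={o: 1.0 for o in ORGAN_ORDER}, b2p=1.0)
        vss = vss_plasma(adult, drug)
        assert vss == pytest.approx(adult.physiology.total_volume(), rel=1e-9)


class TestRelease:
    def test_immediate_bolus(self):
        bolus, rate = apply_release(DoseEvent(0.0, 300.0), GABAPENTIN.mw)
        assert bolus == pytest.approx(300.0 / GABAPENTIN.mw * 1000.0)
        assert rate(0.5) == 0.0

    def test_zero_order_rate(self):
        bolus, rate = apply_release(
            DoseEvent(2.0, 600.0, "zero_order", 6.0), GABAPENTIN.mw
        )
        expected = 600.0 / GABAPENTIN.mw * 1000.0 / 6.0  # umol/h == 100 mg/h
        assert bolus == 0.0
        assert rate(3.0) == pytest.approx(expected)
        assert rate(1.9) == 0.0 and rate(8.1) == 0.0

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            DoseEvent(0.0, 600.0, "zero_order", -1.0)

    def test_extended_release_tmax_in_window(self, adult):
        reg = Regimen.single(600.0, 48.0, release="zero_order", release_duration=6.0)
        pk = nca_single_dose(simulate(adult, GABAPENTIN, reg))
        assert 5.0 <= pk.tmax <= 8.0


class TestSimulate:
    def test_zero_at_time_zero_and_nonnegative(self, adult_400mg_profile):
        ts = adult_400mg_profile
        assert ts.conc[0] == 0.0
        assert np.all(ts.conc >= 0)

    def test_mass_conservation(self, adult, adult_400mg_profile):
        assert mass_balance_error(adult_400mg_profile, GABAPENTIN) < 1e-3

    def test_mass_conservation_multidose(self, adult):
        reg = Regimen.repeated("tid", 400.0, 2.0)
        ts = simulate(adult, GABAPENTIN, reg, dt=0.1)
        assert mass_balance_error(ts, GABAPENTIN) < 1e-3

    def test_zero_dose_gives_zero_profile(self, adult):
        ts = simulate(adult, GABAPENTIN, Regimen.single(0.0, 24.0), dt=0.1)
        assert np.allclose(ts.conc, 0.0)

    def test_dose_linearity(self, adult, adult_400mg_profile):
        ts2 = simulate(adult, GABAPENTIN, Regimen.single(800.0, 48.0))
        mask = adult_400mg_profile.conc > 1e-6
        ratio = ts2.conc[mask] / adult_400mg_profile.conc[mask]
        assert np.allclose(ratio, 2.0, rtol=1e-5)

    def test_auc_matches_dose_over_clearance(self, adult, adult_400mg_profile):
        cl = renal_clearance(GABAPENTIN, adult.physiology)
        pk = nca_single_dose(adult_400mg_profile)
        assert pk.auc_0_inf == pytest.approx(400.0 * GABAPENTIN.fabs / cl, rel=1e-3)

    def test_no_elimination_reaches_plateau(self, adult):
        drug = replace(GABAPENTIN, ts_spec=0.0)
        ind = representative_individual("adult")
        phys = replace(ind.physiology, gfr_absolute=0.0)
        ind = replace(ind, physiology=phys)
        ts = simulate(ind, drug, Regimen.single(400.0, 96.0), dt=0.1)
        tail = ts.conc[ts.times > 72]
        assert tail.min() > 0
        assert tail.std() / tail.mean() < 1e-3

    def test_auc_increases_with_ri_severity(self):
        aucs = []
        for c in ("normal", "mild", "moderate", "severe"):
            ind = representative_individual("adult", c)
            ts = simulate(ind, GABAPENTIN, Regimen.single(400.0, 240.0), dt=0.1)
            aucs.append(nca_single_dose(ts).auc_0_inf)
        assert all(a < b for a, b in zip(aucs, aucs[1:]))

    def test_one_compartment_limit(self, adult):
        # lumped limit: flows -> infinity, all Kp = 1, B/P = 1
        phys = adult.physiology
        organs = {k: (v, q * 1e4) for k, (v, q) in phys.organs.items()}
        ind = replace(adult, physiology=replace(phys, organs=organs))
        drug = replace(GABAPENTIN, kp_set={o: 1.0 for o in ORGAN_ORDER}, b2p=1.0)
        cl = renal_clearance(drug, ind.physiology)
        ts = simulate(ind, drug, Regimen.single(400.0, 96.0), dt=0.1, rtol=1e-9)
        pk = nca_single_dose(ts)
        assert pk.auc_0_inf == pytest.approx(400.0 * drug.fabs / cl, rel=0.01)

    def test_multidose_periodic_steady_state(self, adult):
        reg = Regimen.repeated("tid", 600.0, 7.0)
        ts = simulate(adult, GABAPENTIN, reg, dt=0.1)
        per = int(round(8.0 / 0.1))

        def day_auc(day):
            m = (ts.times >= day * 24.0) & (ts.times <= (day + 1) * 24.0)
            return auc_trapezoid(ts.times[m], ts.conc[m])

        assert day_auc(6) == pytest.approx(day_auc(5), rel=0.01)

    def test_event_beyond_duration_rejected(self, adult):
        reg = Regimen((DoseEvent(30.0, 100.0),), 24.0)
        with pytest.raises(ValueError):
            simulate(adult, GABAPENTIN, reg)
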