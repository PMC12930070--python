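import numpy as np
import pytest

from flotcea.cohort_engine import CYCLE_LENGTH_MONTHS, CohortTrace, DiscountSpec
from flotcea.econ_model import (
    AES,
    EconOptions,
    EconResult,
    K_AE_COST,
    K_AE_DIS,
    K_AE_INC,
    accumulate,
    ae_burden,
    drug_cost_per_cycle,
    followup_cost,
    icer,
    load_parameters,
    mosteller_bsa,
    treatment_calendar,
)


class TestParameters:
    def test_published_values_loaded(self, params):
        assert params.value("Drug cost per cycle/Durvalumab") == 12787.50
        assert params.value("Utility/EFS") == 0.797
        assert params.value("Administration cost per/Hospice care") == 4563.28
        assert params.discount_rate == pytest.approx(0.03)

    def test_bsc_range_repaired(self, params):
        p = params["Administration cost per/Best supportive care"]
        assert p.min == pytest.approx(0.75 * 16632.03)
        assert p.max == pytest.approx(1.25 * 16632.03)

    def test_with_value_is_pure(self, params):
        changed = params.with_value("Utility/EFS", 0.5)
        assert changed.value("Utility/EFS") == 0.5
        assert params.value("Utility/EFS") == 0.797

    def test_invalid_utility_rejected(self, params):
        with pytest.raises(ValueError):
            params.with_value("Utility/PD", 1.4).validate()


class TestMostellerBsa:
    def test_unit_square(self):
        assert mosteller_bsa(60.0, 60.0) == pytest.approx(1.0)

    def test_reference_patient(self):
        # the published BSA 1.99 for the 84.7 kg reference adult
        assert mosteller_bsa(168.3, 84.7) == pytest.approx(1.99, abs=0.005)

    def test_monotone_in_each_argument(self):
        assert mosteller_bsa(170, 85) > mosteller_bsa(160, 85)
        assert mosteller_bsa(170, 85) > mosteller_bsa(170, 75)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            mosteller_bsa(0.0, 70.0)


class TestDrugCosts:
    def test_durvalumab_monotherapy_drug_component(self, params):
        cost = drug_cost_per_cycle("DFLOT", "monotherapy", params)
        iv = params.value("Administration cost per/IV infusion 1h")
        assert cost - iv == pytest.approx(12787.50)

    def test_flot_drug_component_per_model_cycle(self, params):
        # 35.40 + 62.68 + 61.42 + 75.23
        flot = drug_cost_per_cycle("FLOT", "neoadjuvant", params)
        iv_long = params.value("Administration cost per/IV infusion over 1h")
        assert flot - 2 * iv_long == pytest.approx(234.73)

    def test_chemo_cycle_reading_doubles_flot_drugs(self, params):
        opt = EconOptions(flot_cycle_reading="chemo")
        a = drug_cost_per_cycle("FLOT", "adjuvant", params)
        b = drug_cost_per_cycle("FLOT", "adjuvant", params, opt)
        assert b - a == pytest.approx(234.73)

    def test_second_line_drug_component(self, params):
        cost = drug_cost_per_cycle("FLOT", "second_line", params)
        admin = (2 * params.value("Administration cost per/IV infusion over 1h")
                 + params.value("Administration cost per/IV infusion 1h"))
        assert cost - admin == pytest.approx(20179.74 + 50.50)

    def test_unknown_phase_rejected(self, params):
        with pytest.raises(KeyError):
            drug_cost_per_cycle("FLOT", "maintenance", params)
        with pytest.raises(KeyError):
            drug_cost_per_cycle("FLOT", "monotherapy", params)


class TestCalendar:
    def test_dflot_has_fourteen_durvalumab_cycles(self):
        cal = treatment_calendar("DFLOT")
        durva = [u for u, ph in cal.items()
                 if ph in ("neoadjuvant", "adjuvant", "monotherapy")]
        assert len(durva) == 14

    def test_flot_stops_after_adjuvant(self):
        cal = treatment_calendar("FLOT")
        assert max(cal) == 4
        assert "monotherapy" not in cal.values()

    def test_single_surgery_cycle(self):
        cal = treatment_calendar("DFLOT")
        assert sum(ph == "surgery" for ph in cal.values()) == 1


class TestAeBurden:
    def test_zero_incidence(self):
        assert ae_burden([0, 0], [10, 20], [0.1, 0.2]) == (0.0, 0.0)

    def test_dflot_expected_cost(self, params):
        p = [params.value(K_AE_INC["DFLOT"][ae]) for ae in AES]
        c = [params.value(K_AE_COST[ae]) for ae in AES]
        d = [params.value(K_AE_DIS[ae]) for ae in AES]
        cost, dis = ae_burden(p, c, d)
        expect = 0.063 * 3928 + 0.051 * 528 + 0.409 * 18987 + 0.053 * 96238
        assert cost == pytest.approx(expect)
        assert dis == pytest.approx(0.063 * 0.247 + 0.051 * 0.200
                                    + 0.409 * 0.159 + 0.053 * 0.149)

    def test_mismatched_vectors_rejected(self):
        with pytest.raises(ValueError):
            ae_burden([0.1], [1, 2], [0.1, 0.2])


class TestFollowup:
    def test_cycle_without_encounter_is_free(self, params):
        assert followup_cost(1, params) == 0.0

    def test_first_visit_priced_initial_plus_cbc(self, params):
        # month 3 falls in cycle 3 with the 28-day cycle
        assert followup_cost(3, params) == pytest.approx(165.44 + 19.00)

    def test_year_one_ct_charges(self, params):
        total = sum(followup_cost(u, params) for u in range(14))
        ct_part = 2 * 171.10  # CTs at months 6 and 12
        visits = 4  # months 3, 6, 9, 12
        expect = ct_part + 165.44 + (visits - 1) * 130.15 + visits * 19.00
        assert total == pytest.approx(expect)


def _toy_trace(n=5):
    occ = np.tile([1.0, 0, 0, 0], (n + 1, 1))
    return CohortTrace(occ)


class TestAccumulate:
    def test_constant_efs_closed_form_qaly(self, params):
        n = 13  # inside the neoadjuvant..monotherapy window
        trace = _toy_trace(n)
        p0 = params.with_value("Patient/Discount rate, %", 0.0)
        res = accumulate(trace, p0, "FLOT")
        u_efs, u_g = 0.797, 0.773
        g = 13 - 2  # gastrectomy utility from cycle 2 for the rest of horizon
        expect = (2 * u_efs + g * u_g) * (28 / 365.25)
        dis = (0.06 * 0.247 + 0.051 * 0.200 + 0.446 * 0.159
               + 0.06 * 0.149) * 28 / 365.25
        assert res.qalys == pytest.approx(expect - dis, rel=1e-9)
        assert res.life_years == pytest.approx(n * 28 / 365.25)

    def test_zero_prices_zero_cost_same_qalys(self, ce_model, params):
        zero = params.with_values({k: 0.0 for k in params.keys()
                                   if "cost" in k.lower() or "Drug" in k
                                   or "Administration" in k})
        trace = ce_model.trace("DFLOT")
        res0 = accumulate(trace, zero, "DFLOT")
        res1 = accumulate(trace, params, "DFLOT")
        assert res0.total_cost == 0.0
        assert res0.qalys == pytest.approx(res1.qalys)

    def test_category_additivity(self, ce_model):
        res = ce_model.evaluate()
        for arm in ("DFLOT", "FLOT"):
            r = res[arm]
            assert r.total_cost == pytest.approx(sum(r.categories().values()),
                                                 abs=0.01)
            assert r.qalys <= r.life_years

    def test_utility_and_price_monotonicity(self, ce_model, params):
        trace = ce_model.trace("DFLOT")
        base = accumulate(trace, params, "DFLOT")
        up_u = accumulate(trace, params.with_value("Utility/PD", 0.7),
                          "DFLOT")
        assert up_u.qalys >= base.qalys
        up_c = accumulate(
            trace, params.with_value("Drug cost per cycle/Durvalumab", 15000.0),
            "DFLOT")
        assert up_c.total_cost >= base.total_cost

    def test_bsc_per_episode_cheaper_than_per_cycle(self, ce_model, params):
        trace = ce_model.trace("FLOT")
        per_cycle = accumulate(trace, params, "FLOT",
                               options=EconOptions(bsc_mode="per_cycle"))
        per_episode = accumulate(trace, params, "FLOT",
                                 options=EconOptions(bsc_mode="per_episode"))
        assert per_episode.cost_drug < per_cycle.cost_drug

    def test_mono_cycle_scaling_reduces_dflot_drug_cost(self, ce_model, params):
        trace = ce_model.trace("DFLOT")
        full = accumulate(trace, params, "DFLOT")
        short = accumulate(trace, params, "DFLOT",
                           options=EconOptions(expected_mono_cycles=5.0))
        assert short.cost_drug < full.cost_drug
        assert short.qalys == pytest.approx(full.qalys)


class TestIcer:
    def _res(self, cost, qaly, name="x"):
        return EconResult(name, cost, 0.0, 0.0, 0.0, qaly, qaly)

    def test_published_increments_divide(self):
        r = icer(self._res(259010.78, 3.89), self._res(154754.66, 3.05))
        assert r.delta_cost == pytest.approx(104256.12)
        assert r.icer == pytest.approx(104256.12 / 0.84)

    def test_identical_results_undefined(self):
        a = self._res(10.0, 1.0)
        assert icer(a, a).label == "undefined"

    def test_dominance_labels(self):
        assert icer(self._res(5.0, 2.0), self._res(10.0, 1.0)).label == "a dominant"
        assert icer(self._res(10.0, 1.0), self._res(5.0, 2.0)).label == "a dominated"
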