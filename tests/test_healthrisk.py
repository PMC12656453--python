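import numpy as np
import pandas as pd
import pytest

import soilrisk as sr
from soilrisk.registry import ExposureProfile


def unit_profile(**overrides):
    """A profile in which every dose factor is 1 (ef=at=365), so the
    ingestion/dermal ADD reduce to conc * 1e-6 and inhalation to conc."""
    params = dict(
        cohort="unit", ing_rate=1.0, inh_rate=1.0, ef=365.0, ed=1.0, bw=1.0,
        at_nc=365.0, at_ca=365.0, sa=1.0, af=1.0, abs=1.0, pef=1.0,
    )
    params.update(overrides)
    return ExposureProfile(**params)


class TestDoseEquations:
    def test_ingestion_factors_cancel(self):
        assert sr.add_ingestion(1.0, unit_profile()) == pytest.approx(1e-6)

    def test_ingestion_linearity(self):
        p = unit_profile()
        assert sr.add_ingestion(2.0, p) == pytest.approx(2 * sr.add_ingestion(1.0, p))

    def test_ingestion_adult_defaults_spreadsheet_value(self, registry):
        # 13.4 * 100 * 250 * 24 / (70 * 8760) * 1e-6, evaluated by hand
        add = sr.add_ingestion(13.4, registry.cohorts["adult"])
        assert add == pytest.approx(1.31115e-5, rel=1e-4)

    def test_dermal_unit_profile(self):
        assert sr.add_dermal(3.0, unit_profile()) == pytest.approx(3e-6)

    def test_dermal_vanishes_with_absorption(self):
        assert sr.add_dermal(1.0, unit_profile(abs=1e-9)) == pytest.approx(
            1e-15, rel=1e-6
        )

    def test_dermal_adult_defaults_spreadsheet_value(self, registry):
        # 61.4 * 5075 * 0.2 * 0.05 * 250 * 24 / (70 * 8760) * 1e-6
        add = sr.add_dermal(61.4, registry.cohorts["adult"])
        assert add == pytest.approx(3.04897e-5, rel=1e-4)

    def test_inhalation_no_mass_factor(self):
        # inh_rate = pef and all else canceling leaves ADD = conc exactly
        assert sr.add_inhalation(1.0, unit_profile()) == pytest.approx(1.0)

    def test_inhalation_vanishes_as_pef_grows(self):
        assert sr.add_inhalation(1.0, unit_profile(pef=1e12)) == pytest.approx(
            1e-12, rel=1e-9
        )

    def test_inhalation_adult_defaults_spreadsheet_value(self, registry):
        # 0.05 * 20 * 250 * 24 / (1.36e9 * 70 * 8760)
        add = sr.add_inhalation(0.05, registry.cohorts["adult"])
        assert add == pytest.approx(7.19466e-12, rel=1e-4)

    def test_carcinogenic_switch_uses_at_ca(self, registry):
        p = registry.cohorts["adult"]
        ratio = sr.add_ingestion(1.0, p, carcinogenic=True) / sr.add_ingestion(1.0, p)
        assert ratio == pytest.approx(p.at_nc / p.at_ca)

    def test_non_positive_concentration_rejected(self):
        with pytest.raises(sr.ValidationError):
            sr.add_ingestion(-1.0, unit_profile())


class TestQuotients:
    def test_hazard_quotient(self):
        assert sr.hazard_quotient(2e-6, 2e-6) == pytest.approx(1.0)
        assert sr.hazard_quotient(0.0, 1.0) == 0.0
        with pytest.raises(sr.ValidationError):
            sr.hazard_quotient(1.0, 0.0)

    def test_cancer_risk(self):
        assert sr.cancer_risk(1e-6, 1.5) == pytest.approx(1.5e-6)
        with pytest.raises(sr.ValidationError):
            sr.cancer_risk(1e-6, 0.0)

    def test_totals_are_plain_sums(self):
        values = [1.0, 2.5, 0.5]
        assert sr.hazard_index(values) == pytest.approx(4.0)
        assert sr.total_cancer_risk(values) == pytest.approx(4.0)
        with pytest.raises(sr.ValidationError):
            sr.hazard_index([])


def flat_loop_oracle(means, registry, cohorts=("adult", "child")):
    """Independent re-evaluation of HI/TCR with explicit loops and the raw
    dose formulas, bypassing the table machinery."""
    hi, tcr = {}, {}
    for cohort in cohorts:
        p = registry.cohorts[cohort]
        hi_total, tcr_total = 0.0, 0.0
        for metal, conc in means.items():
            el = registry.elements[metal]
            doses_nc = {
                "ingestion": conc * p.ing_rate * p.ef * p.ed / (p.bw * p.at_nc) * 1e-6,
                "dermal": conc * p.sa * p.af * p.abs * p.ef * p.ed
                / (p.bw * p.at_nc) * 1e-6,
                "inhalation": conc * p.inh_rate * p.ef * p.ed
                / (p.pef * p.bw * p.at_nc),
            }
            doses_ca = {
                k: v * p.at_nc / p.at_ca for k, v in doses_nc.items()
            }
            for pathway, dose in doses_nc.items():
                rfd = el.rfd.get(pathway)
                if rfd is not None:
                    hi_total += dose / rfd
            for pathway, dose in doses_ca.items():
                sf = el.sf.get(pathway)
                if sf is not None:
                    tcr_total += dose * sf
        hi[cohort], tcr[cohort] = hi_total, tcr_total
    return hi, tcr


class TestAggregate:
    def test_matches_flat_loop_oracle(self, registry):
        means = {"Cd": 0.29, "As": 13.4, "Cr": 61.4}
        table = sr.aggregate_health_risk(means, registry)
        hi, tcr = flat_loop_oracle(means, registry)
        for cohort in ("adult", "child"):
            assert table.hi[cohort] == pytest.approx(hi[cohort], abs=1e-12)
            assert table.tcr[cohort] == pytest.approx(tcr[cohort], abs=1e-15)

    def test_carcinogen_rows_are_cd_as_cr(self, survey48, registry):
        table = sr.aggregate_health_risk(survey48, registry)
        assert list(table.cr.index) == ["Cd", "As", "Cr"]

    def test_cr_dermal_absent_for_cr_metal(self, registry):
        table = sr.aggregate_health_risk({"Cr": 61.4}, registry)
        assert pd.isna(table.cr.loc["Cr", ("adult", "dermal")])
        assert table.formatted("cr").loc["Cr", ("adult", "dermal")] == "—"

    def test_hi_tcr_linear_in_concentrations(self, registry):
        means = {el: registry.elements[el].background for el in sr.CANONICAL_ELEMENTS}
        base = sr.aggregate_health_risk(means, registry)
        double = sr.aggregate_health_risk(
            {k: 2 * v for k, v in means.items()}, registry
        )
        for cohort in ("adult", "child"):
            assert double.hi[cohort] == pytest.approx(2 * base.hi[cohort], rel=1e-12)
            assert double.tcr[cohort] == pytest.approx(2 * base.tcr[cohort], rel=1e-12)

    def test_child_exceeds_adult_on_identical_concentrations(self, survey48, registry):
        table = sr.aggregate_health_risk(survey48, registry)
        assert table.hi["child"] > table.hi["adult"]
        assert table.tcr["child"] > table.tcr["adult"]

    def test_inhalation_contribution_below_one_percent(self, survey48, registry):
        table = sr.aggregate_health_risk(survey48, registry)
        assert (table.hq_contribution.loc["inhalation"] < 1.0).all()

    def test_contributions_sum_to_100(self, survey48, registry):
        table = sr.aggregate_health_risk(survey48, registry)
        assert table.hq_contribution.sum().to_dict() == pytest.approx(
            {"adult": 100.0, "child": 100.0}, abs=1e-9
        )
        assert table.cr_contribution.sum().to_dict() == pytest.approx(
            {"adult": 100.0, "child": 100.0}, abs=1e-9
        )

    def test_sampleset_input_uses_mean_concentrations(self, survey48, registry):
        from_set = sr.aggregate_health_risk(survey48, registry)
        from_means = sr.aggregate_health_risk(
            survey48.mean_concentrations().to_dict(), registry
        )
        assert from_set.hi["adult"] == pytest.approx(from_means.hi["adult"], rel=1e-12)

    def test_no_carcinogen_gives_zero_tcr(self, registry, caplog):
        table = sr.aggregate_health_risk({"Pb": 26.11, "Zn": 72.94}, registry)
        assert table.tcr["adult"] == 0.0


class TestPerSampleMode:
    def test_mean_of_per_sample_hi_equals_hi_of_mean(self, survey48, registry):
        per_sample = sr.per_sample_hazard_index(survey48, registry, "adult")
        aggregate = sr.aggregate_health_risk(survey48, registry)
        assert per_sample.mean() == pytest.approx(aggregate.hi["adult"], rel=1e-12)
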