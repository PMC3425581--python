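"""Prescribing ratios, normalized rates, ranked risks, and stratifications."""

from __future__ import annotations

from datetime import date

import pytest

from aerspipe.categories import make_category
from aerspipe.datasets import myalgia_counts, statin_nrx
from aerspipe.io import CaseReport, DrugMention, DrugRole, Outcome, ReporterOccupation
from aerspipe.metrics import (
    ROLE_SCOPE_ALL,
    ROLE_SCOPE_PRIMARY,
    combined_risk,
    count_reports,
    normalized_rate,
    prescribing_ratios,
    ranked_risk,
    risk_table_from_counts,
    sensitivity_peak_rx,
    stratify,
    yearly_trend,
)
from aerspipe.util import round_half_up

#: Published prescribing ratios for the six statins (simvastatin = reference).
PUBLISHED_PR = {
    "simvastatin": 1.0,
    "atorvastatin": 0.8604,
    "rosuvastatin": 0.2901,
    "lovastatin": 0.2153,
    "pravastatin": 0.2275,
    "fluvastatin": 0.0265,
}


class TestPrescribingRatios:
    def test_six_statin_nrx_reproduce_published_ratios(self):
        table = prescribing_ratios(statin_nrx())
        assert table.pr == PUBLISHED_PR
        assert table.reference_drug == "simvastatin"

    def test_single_drug_gets_ratio_one(self):
        assert prescribing_ratios({"x": 123}).pr == {"x": 1.0}

    def test_equal_nrx_both_ratio_one(self):
        assert prescribing_ratios({"a": 10, "b": 10}).pr == {"a": 1.0, "b": 1.0}

    def test_empty_or_nonpositive_fatal(self):
        with pytest.raises(ValueError):
            prescribing_ratios({})
        with pytest.raises(ValueError):
            prescribing_ratios({"a": 0})

    def test_scale_invariance(self):
        nrx = statin_nrx()
        scaled = {d: v * 7 for d, v in nrx.items()}
        assert prescribing_ratios(scaled).pr == prescribing_ratios(nrx).pr


class TestNormalizedRate:
    @pytest.mark.parametrize(
        "count,pr,displayed",
        [(2751, 0.8604, 3197), (103, 0.0265, 3887), (1641, 0.2901, 5657), (42, 1.0, 42)],
    )
    def test_displayed_rate_examples(self, count, pr, displayed):
        assert round_half_up(normalized_rate(count, pr)) == displayed

    def test_nonpositive_ratio_fatal(self):
        with pytest.raises(ValueError):
            normalized_rate(5, 0.0)


class TestRankedRisk:
    def test_published_myalgia_primary_ranks(self):
        counts = dict(zip(myalgia_counts().drug, myalgia_counts().primary_count))
        rates = {d: normalized_rate(c, PUBLISHED_PR[d]) for d, c in counts.items()}
        ranks = ranked_risk(rates)
        assert ranks["rosuvastatin"] == 100
        assert ranks["atorvastatin"] == 57
        assert ranks["fluvastatin"] == 69
        assert ranks["pravastatin"] == 20
        assert ranks["simvastatin"] == 18

    def test_single_drug_is_100(self):
        assert ranked_risk({"x": 3.2}) == {"x": 100}

    def test_scale_invariant(self):
        rates = {"a": 5.0, "b": 2.0, "c": 0.5}
        assert ranked_risk(rates) == ranked_risk({d: 2 * r for d, r in rates.items()})

    def test_all_zero_rates_rank_zero(self):
        assert ranked_risk({"a": 0.0, "b": 0.0}) == {"a": 0, "b": 0}


def mk_case(isr, drug_roles, reactions=("myalgia",), d=date(2006, 6, 1),
            outcomes=(), occ=ReporterOccupation.PHYSICIAN):
    return CaseReport(
        isr_id=str(isr), case_id=f"C{isr}", receipt_date=d, age=60.0, sex="F",
        reporter_occupation=occ,
        drugs=[DrugMention(c.upper(), role, canonical_drug=c) for c, role in drug_roles],
        reactions=list(reactions), outcomes=frozenset(outcomes),
    )


PS, SS, CON = DrugRole.PRIMARY_SUSPECT, DrugRole.SECONDARY_SUSPECT, DrugRole.CONCOMITANT


class TestCountReports:
    def test_role_scoping(self, myalgia_category):
        cases = [
            mk_case(1, [("atorvastatin", PS)]),
            mk_case(2, [("atorvastatin", SS), ("simvastatin", PS)]),
            mk_case(3, [("atorvastatin", CON)]),
            mk_case(4, [("atorvastatin", PS)], reactions=("nausea",)),
        ]
        assert count_reports(cases, "atorvastatin", myalgia_category, ROLE_SCOPE_PRIMARY) == 1
        assert count_reports(cases, "atorvastatin", myalgia_category, ROLE_SCOPE_ALL) == 2
        assert (
            count_reports(cases, "atorvastatin", myalgia_category, ROLE_SCOPE_ALL,
                          include_concomitant=True)
            == 3
        )

    def test_unknown_drug_counts_zero(self, myalgia_category):
        cases = [mk_case(1, [("atorvastatin", PS)])]
        assert count_reports(cases, "cerivastatin", myalgia_category) == 0

    def test_all_scope_never_below_primary(self, myalgia_category):
        import random

        rng = random.Random(0)
        cases = [
            mk_case(i, [("atorvastatin", rng.choice([PS, SS, CON]))],
                    reactions=(rng.choice(["myalgia", "nausea"]),))
            for i in range(100)
        ]
        p = count_reports(cases, "atorvastatin", myalgia_category, ROLE_SCOPE_PRIMARY)
        a = count_reports(cases, "atorvastatin", myalgia_category, ROLE_SCOPE_ALL)
        assert a >= p


class TestRiskTable:
    def test_from_counts_orders_by_primary_rank(self):
        mc = myalgia_counts()
        table = risk_table_from_counts(
            dict(zip(mc.drug, mc.primary_count)),
            dict(zip(mc.drug, mc.all_count)),
            prescribing_ratios(statin_nrx()),
        )
        assert list(table.drug)[:2] == ["rosuvastatin", "fluvastatin"]
        assert table.ranked_primary.max() == 100 and table.ranked_all.max() == 100
        assert (table.all_count >= table.primary_count).all()

    def test_all_below_primary_is_fatal(self):
        with pytest.raises(ValueError):
            risk_table_from_counts({"a": 5}, {"a": 3}, prescribing_ratios({"a": 1}))


class TestCombinedRisk:
    def test_single_category_reduces_to_ranked_risk(self, myalgia_category):
        cases = [mk_case(i, [("atorvastatin", PS)]) for i in range(8)]
        cases += [mk_case(i + 10, [("simvastatin", PS)]) for i in range(4)]
        pr = prescribing_ratios({"atorvastatin": 100, "simvastatin": 100})
        combined = combined_risk(cases, ["atorvastatin", "simvastatin"], [myalgia_category], pr)
        assert combined == {"atorvastatin": 100.0, "simvastatin": 50.0}

    def test_disjoint_categories_are_additive(self):
        rhab = make_category("Rhabdomyolysis", ["rhabdomyolysis"])
        mya = make_category("Myalgia", ["myalgia"])
        cases = [mk_case(1, [("a", PS)], reactions=("myalgia",)),
                 mk_case(2, [("a", PS)], reactions=("rhabdomyolysis",)),
                 mk_case(3, [("b", PS)], reactions=("myalgia",))]
        pr = prescribing_ratios({"a": 10, "b": 10})
        combined = combined_risk(cases, ["a", "b"], [mya, rhab], pr)
        assert combined == {"a": 100.0, "b": 50.0}

    def test_multi_category_case_counts_once_per_category_by_default(self):
        rhab = make_category("Rhabdomyolysis", ["rhabdomyolysis"])
        mya = make_category("Myalgia", ["myalgia"])
        both = mk_case(1, [("a", PS)], reactions=("myalgia", "rhabdomyolysis"))
        single = mk_case(2, [("b", PS)], reactions=("myalgia",))
        pr = prescribing_ratios({"a": 10, "b": 10})
        per_category = combined_risk([both, single], ["a", "b"], [mya, rhab], pr)
        assert per_category == {"a": 100.0, "b": 50.0}  # a contributes 2
        unique = combined_risk([both, single], ["a", "b"], [mya, rhab], pr, unique_cases=True)
        assert unique == {"a": 100.0, "b": 100.0}


class TestYearlyTrend:
    def test_single_year_bucket(self, myalgia_category):
        cases = [mk_case(i, [("a", PS)], d=date(2007, 3, 1)) for i in range(5)]
        assert yearly_trend(cases, "a", myalgia_category) == {2007: 5}

    def test_years_partition_primary_count(self, myalgia_category):
        import random

        rng = random.Random(2)
        cases = [
            mk_case(i, [("a", PS)], d=date(rng.choice([2006, 2007, 2008]), 6, 1))
            for i in range(60)
        ]
        import dataclasses

        cases.append(dataclasses.replace(mk_case(99, [("a", PS)]), receipt_date=None))
        trend = yearly_trend(cases, "a", myalgia_category)
        assert sum(trend.values()) == count_reports(cases, "a", myalgia_category)
        assert trend["UNKNOWN"] == 1


class TestStratify:
    def test_outcome_strata_are_not_exclusive(self, myalgia_category):
        c = mk_case(1, [("a", PS)], outcomes=(Outcome.DEATH, Outcome.HOSPITALIZATION))
        df = stratify([c], "a", myalgia_category, "OUTCOME")
        assert dict(zip(df.stratum, df["count"])) == {"DEATH": 1, "HOSPITALIZATION": 1}

    def test_reporter_percentages_sum_to_100(self, myalgia_category):
        cases = [mk_case(i, [("a", PS)], occ=ReporterOccupation.PHYSICIAN) for i in range(7)]
        cases += [mk_case(i + 10, [("a", PS)], occ=ReporterOccupation.CONSUMER) for i in range(3)]
        df = stratify(cases, "a", myalgia_category, "REPORTER")
        assert df["count"].sum() == 10
        assert df.percent.sum() == pytest.approx(100.0)

    def test_unknown_axis_rejected(self, myalgia_category):
        with pytest.raises(ValueError):
            stratify([], "a", myalgia_category, "SEVERITY")


class TestSensitivityPeakRx:
    def test_peak_table_matching_summed_proportions_is_identity(self, myalgia_category):
        cases = [mk_case(1, [("a", PS)]), mk_case(2, [("b", PS)])]
        main_pr = prescribing_ratios({"a": 200, "b": 100})
        yearly = {("a", 2006): 200, ("a", 2007): 150, ("b", 2006): 100}
        pr_peak, table = sensitivity_peak_rx(yearly, cases, ["a", "b"], myalgia_category)
        assert pr_peak.pr == main_pr.pr
        assert table.attrs["variant"] == "peak_annual_rx"

    def test_doubling_peak_denominator_halves_rate(self, myalgia_category):
        cases = [mk_case(1, [("a", PS)]), mk_case(2, [("b", PS)])]
        # doubling a non-reference drug's peak denominator halves its rate
        # (doubling the reference drug would instead renormalize every PR)
        y1 = {("a", 2006): 400, ("b", 2006): 100}
        y2 = {("a", 2006): 400, ("b", 2006): 200}
        _, t1 = sensitivity_peak_rx(y1, cases, ["a", "b"], myalgia_category)
        _, t2 = sensitivity_peak_rx(y2, cases, ["a", "b"], myalgia_category)
        rate1 = float(t1[t1.drug == "b"].primary_rate.iloc[0])
        rate2 = float(t2[t2.drug == "b"].primary_rate.iloc[0])
        assert rate2 == pytest.approx(rate1 / 2)

    def test_missing_drug_in_yearly_table_fatal(self, myalgia_category):
        with pytest.raises(ValueError):
            sensitivity_peak_rx({("a", 2006): 1}, [], ["a", "b"], myalgia_category)
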