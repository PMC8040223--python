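import math

import pytest
from statsmodels.stats.proportion import proportion_confint

from refcorrect import (
    ContingencyTable,
    DegenerateInputError,
    DegenerateMarginError,
    DegenerateReferenceError,
    ReferenceAccuracy,
    UninformativeReferenceError,
    attach_wilson_ci,
    brenner_correct,
    classical_estimate,
    gart_buck_correct,
    staquet_correct,
    staquet_prevalence,
    wilson_interval,
)


class TestClassical:
    def test_mathews(self, mathews_table):
        result = classical_estimate(mathews_table)
        assert result.sensitivity.value == pytest.approx(40 / 62)
        assert round(result.sensitivity.value, 2) == 0.65
        assert round(result.specificity.value, 2) == 0.89
        assert result.sample_prevalence == pytest.approx(62 / 261)
        assert not result.sensitivity.illogical and not result.specificity.illogical

    def test_matos_d3_fc(self):
        result = classical_estimate(ContingencyTable(21, 38, 0, 348))
        assert result.sensitivity.value == pytest.approx(1.0)
        assert round(result.specificity.value, 2) == 0.90

    def test_perfect_diagonal(self):
        result = classical_estimate(ContingencyTable(10, 0, 0, 10))
        assert result.sensitivity.value == 1.0
        assert result.specificity.value == 1.0

    @pytest.mark.parametrize(
        "cells,margin", [((0, 5, 0, 5), "e"), ((5, 0, 5, 0), "f")]
    )
    def test_zero_margin_identified(self, cells, margin):
        with pytest.raises(DegenerateMarginError) as excinfo:
            classical_estimate(ContingencyTable(*cells))
        assert excinfo.value.margin == margin


class TestStaquet:
    def test_mathews(self, mathews_table, mathews_ref):
        result = staquet_correct(mathews_table, mathews_ref)
        assert round(result.sensitivity.value, 2) == 0.89
        assert round(result.specificity.value, 2) == 0.96
        assert not result.sensitivity.illogical

    def test_illogical_sensitivity_flagged(self):
        # dentine-lesion LFpen table: corrected sensitivity exceeds one
        result = staquet_correct(ContingencyTable(20, 45, 1, 341), ReferenceAccuracy(0.786, 0.995))
        assert round(result.sensitivity.value, 2) == 1.04
        assert result.sensitivity.illogical
        assert result.sensitivity.ci is None

    def test_perfect_reference_collapses_to_classical(self, mathews_table, perfect_ref):
        staquet = staquet_correct(mathews_table, perfect_ref)
        classical = classical_estimate(mathews_table)
        assert staquet.sensitivity.value == pytest.approx(classical.sensitivity.value)
        assert staquet.specificity.value == pytest.approx(classical.specificity.value)

    def test_uninformative_reference(self, mathews_table):
        with pytest.raises(UninformativeReferenceError):
            staquet_correct(mathews_table, ReferenceAccuracy(0.3, 0.7))

    def test_degenerate_sn_denominator(self):
        # e/N = 1 - Sp_RS makes N(Sp_RS - 1) + e vanish
        with pytest.raises(DegenerateReferenceError) as excinfo:
            staquet_correct(ContingencyTable(1, 4, 0, 5), ReferenceAccuracy(0.8, 0.9))
        assert "Sp_RS" in excinfo.value.quantity

    def test_degenerate_sp_denominator(self):
        # e/N = Sn_RS makes N Sn_RS - e vanish
        with pytest.raises(DegenerateReferenceError) as excinfo:
            staquet_correct(ContingencyTable(8, 1, 0, 1), ReferenceAccuracy(0.8, 0.9))
        assert "Sn_RS" in excinfo.value.quantity


class TestStaquetPrevalence:
    def test_illogical_high_prevalence(self):
        # non-cavitated caries margins: e=351, N=383
        est = staquet_prevalence(ContingencyTable(241, 6, 110, 26), ReferenceAccuracy(0.796, 0.799))
        assert round(est.value, 1) == 1.2
        assert est.illogical

    def test_low_prevalence(self):
        # dentine-lesion margins: e=21, N=407
        est = staquet_prevalence(ContingencyTable(20, 45, 1, 341), ReferenceAccuracy(0.786, 0.995))
        assert round(est.value, 2) == 0.06
        assert not est.illogical

    def test_perfect_reference_gives_sample_prevalence(self, mathews_table, perfect_ref):
        est = staquet_prevalence(mathews_table, perfect_ref)
        assert est.value == pytest.approx(62 / 261)

    def test_uninformative_reference(self, mathews_table):
        with pytest.raises(UninformativeReferenceError):
            staquet_prevalence(mathews_table, ReferenceAccuracy(0.5, 0.5))


class TestGartBuck:
    def test_mathews_equals_staquet(self, mathews_table, mathews_ref):
        gb = gart_buck_correct(mathews_table, mathews_ref)
        sq = staquet_correct(mathews_table, mathews_ref)
        # exact rational oracle: (62*0.91 - 22)/(261*(0.91-1) + 62) = 3442/3851
        assert gb.sensitivity.value == pytest.approx(3442 / 3851, abs=1e-12)
        assert abs(gb.sensitivity.value - sq.sensitivity.value) < 1e-9
        assert abs(gb.specificity.value - sq.specificity.value) < 1e-9

    def test_matos_nc_lfpen_specificity(self):
        gb = gart_buck_correct(ContingencyTable(241, 6, 110, 26), ReferenceAccuracy(0.796, 0.799))
        assert round(gb.specificity.value, 2) == 0.04

    def test_perfect_reference_collapses_to_classical(self, mathews_table, perfect_ref):
        gb = gart_buck_correct(mathews_table, perfect_ref)
        classical = classical_estimate(mathews_table)
        assert gb.sensitivity.value == pytest.approx(classical.sensitivity.value)
        assert gb.specificity.value == pytest.approx(classical.specificity.value)

    def test_inherits_margin_errors(self, mathews_ref):
        with pytest.raises(DegenerateMarginError):
            gart_buck_correct(ContingencyTable(0, 5, 0, 5), mathews_ref)


class TestBrenner:
    def test_mathews(self, mathews_table, mathews_ref):
        result = brenner_correct(mathews_table, mathews_ref)
        assert round(result.sensitivity.value, 2) == 0.50
        assert round(result.specificity.value, 2) == 0.85

    def test_matos_d3_fc_sensitivity(self):
        result = brenner_correct(ContingencyTable(21, 38, 0, 348), ReferenceAccuracy(0.786, 0.995))
        assert round(result.sensitivity.value, 2) == 0.91

    def test_perfect_reference_collapses_to_classical(self, mathews_table, perfect_ref):
        result = brenner_correct(mathews_table, perfect_ref)
        classical = classical_estimate(mathews_table)
        assert result.sensitivity.value == pytest.approx(classical.sensitivity.value)
        assert result.specificity.value == pytest.approx(classical.specificity.value)

    def test_closed_form_at_expected_counts(self):
        # expected-count table of the RS-better scenario:
        # cells 1000 * (0.237, 0.213, 0.103, 0.447)
        table = ContingencyTable(237, 213, 103, 447)
        result = brenner_correct(table, ReferenceAccuracy(0.9, 0.9))
        assert result.sensitivity.value == pytest.approx(0.2346 / 0.372, abs=1e-12)
        assert result.specificity.value == pytest.approx(0.4126 / 0.628, abs=1e-12)

    def test_degenerate_denominator(self):
        with pytest.raises(DegenerateInputError):
            brenner_correct(ContingencyTable(0, 5, 0, 5), ReferenceAccuracy(1.0, 1.0))


class TestWilsonInterval:
    def test_mathews_classical_sensitivity(self):
        lo, hi = wilson_interval(40 / 62, 62)
        assert (round(lo, 2), round(hi, 2)) == (0.52, 0.75)

    def test_mathews_classical_specificity(self):
        lo, hi = wilson_interval(177 / 199, 199)
        assert (round(lo, 2), round(hi, 2)) == (0.84, 0.93)

    def test_boundary_point_zero(self):
        lo, hi = wilson_interval(0.0, 25)
        assert lo == 0.0
        assert 0.0 < hi < 1.0

    def test_boundary_point_one(self):
        lo, hi = wilson_interval(1.0, 21)
        assert hi == 1.0
        assert (round(lo, 2), round(hi, 2)) == (0.85, 1.00)

    @pytest.mark.parametrize("count,nobs", [(40, 62), (177, 199), (1, 32), (0, 10), (21, 21)])
    def test_matches_statsmodels(self, count, nobs):
        lo, hi = wilson_interval(count / nobs, nobs)
        sm_lo, sm_hi = proportion_confint(count, nobs, alpha=0.05, method="wilson")
        assert lo == pytest.approx(sm_lo, abs=1e-10)
        assert hi == pytest.approx(sm_hi, abs=1e-10)

    @pytest.mark.parametrize("point,n", [(-0.1, 10), (1.1, 10), (0.5, 0)])
    def test_invalid_inputs(self, point, n):
        with pytest.raises(ValueError):
            wilson_interval(point, n)


class TestAttachWilsonCI:
    def test_uses_e_and_f(self, mathews_table, mathews_ref):
        result = attach_wilson_ci(staquet_correct(mathews_table, mathews_ref), mathews_table)
        sn_ci = wilson_interval(result.sensitivity.value, 62)
        sp_ci = wilson_interval(result.specificity.value, 199)
        assert result.sensitivity.ci == pytest.approx(sn_ci)
        assert result.specificity.ci == pytest.approx(sp_ci)

    def test_illogical_estimate_keeps_no_ci(self):
        table = ContingencyTable(20, 45, 1, 341)
        result = attach_wilson_ci(
            staquet_correct(table, ReferenceAccuracy(0.786, 0.995)), table
        )
        assert result.sensitivity.illogical
        assert result.sensitivity.ci is None
        assert result.specificity.ci is not None

    def test_point_rounding_convention(self, mathews_table, mathews_ref):
        result = attach_wilson_ci(
            brenner_correct(mathews_table, mathews_ref), mathews_table, point_dp=2
        )
        assert result.sensitivity.ci == pytest.approx(wilson_interval(0.50, 62))
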