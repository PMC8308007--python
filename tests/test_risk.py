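"""Exposure/risk arithmetic: EDI, HQ, HI, slope-factor risk, classification.

The hazard-index oracle here recomputes each sample's HI term by term from
the raw concentration cells and reference constants, independently of the
pipeline's exposure-row machinery.
"""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metalrisk import (
    AssessmentConfig,
    CensorPolicy,
    ConcentrationValue,
    CRConvention,
    RiskAssessment,
    SampleRecord,
    classify_cr,
    classify_hi,
    compute_cr,
    compute_edi,
    compute_hi,
    compute_hq,
    count_exceedances,
    percent_of_reference,
    risk_table,
)
from metalrisk.core import EXCLUDED, apply_censor_policy


def hi_oracle(record, refs, policy, body_weight=70.0, servings=1):
    """Brute-force HI: resolve each cell, divide by RfD, sum over the list."""
    total = 0.0
    for el, conc in record.concentrations.items():
        ref = refs.get(el)
        if ref is None or not ref.in_hi_list:
            continue
        resolved = apply_censor_policy(conc, policy)
        if resolved is EXCLUDED:
            continue
        total += (resolved * record.serving_mass / 1000 * servings / body_weight) / ref.rfd
    return total


class TestEDI:
    def test_be_p1_spot_value(self):
        assert compute_edi(5.6, 60) == pytest.approx(4.8e-3, rel=1e-2)

    def test_cd_p1_spot_value(self):
        assert compute_edi(58.1, 60) == pytest.approx(0.0498, rel=1e-3)

    def test_zero_concentration(self):
        assert compute_edi(0.0, 60, 3, 70) == 0.0

    def test_servings_linearity(self):
        assert compute_edi(100, 30, 3) == pytest.approx(3 * compute_edi(100, 30, 1))


class TestHQ:
    def test_tl_p1_largest_term(self):
        edi = compute_edi(3.1, 60)
        assert compute_hq(edi, 0.01) == pytest.approx(0.2657, rel=1e-3)

    def test_threshold_identity(self):
        assert compute_hq(0.5, 0.5) == 1.0
        assert compute_hq(0.0, 2.0) == 0.0

    def test_missing_rfd_rejected(self):
        with pytest.raises(ValueError):
            compute_hq(1.0, 0.0)


class TestHI:
    def test_p1_golden_row(self, study_records, study_refs):
        by_id = {r.sample_id: r for r in study_records}
        cfg1 = AssessmentConfig(servings_per_day=1)
        cfg3 = AssessmentConfig(servings_per_day=3)
        assert compute_hi(by_id["P1"], study_refs, cfg1) == pytest.approx(0.956, rel=0.01)
        assert compute_hi(by_id["P1"], study_refs, cfg3) == pytest.approx(2.868, rel=0.01)

    @pytest.mark.parametrize("policy", list(CensorPolicy))
    def test_matches_term_by_term_oracle(self, study_records, study_refs, policy):
        for record in study_records:
            cfg = AssessmentConfig(censor_policy=policy)
            assert compute_hi(record, study_refs, cfg) == pytest.approx(
                hi_oracle(record, study_refs, policy), rel=1e-12
            )

    def test_censor_policy_ordering(self, study_records, study_refs):
        """HI(zero) <= HI(half_limit) <= HI(at_limit) for every sample."""
        for record in study_records:
            his = [
                compute_hi(record, study_refs, AssessmentConfig(censor_policy=p))
                for p in (CensorPolicy.ZERO, CensorPolicy.HALF_LIMIT, CensorPolicy.AT_LIMIT)
            ]
            assert his[0] <= his[1] <= his[2]

    def test_monotone_in_any_concentration(self, study_records, study_refs):
        """Raising one quantified concentration never decreases HI."""
        record = study_records[0]
        cfg = AssessmentConfig()
        base = compute_hi(record, study_refs, cfg)
        for el, c in record.concentrations.items():
            if c.value is None or not study_refs[el].in_hi_list:
                continue
            bumped = dict(record.concentrations)
            bumped[el] = ConcentrationValue.quantified(c.value * 2)
            rec2 = SampleRecord(
                record.sample_id, record.protein_type, record.serving_mass,
                record.weighed_mass, bumped,
            )
            assert compute_hi(rec2, study_refs, cfg) >= base

    def test_all_zero_panel(self, study_refs):
        rec = SampleRecord(
            "Z", "whey", 30, 0.45,
            {"Pb": ConcentrationValue.quantified(0.0)},
        )
        assert compute_hi(rec, study_refs, AssessmentConfig()) == 0.0


class TestCR:
    @pytest.mark.parametrize(
        "edi, csf, expected",
        [
            (4.8e-3, 4300, 1.1e-6),
            (0.0498, 380, 1.3e-4),
            (0.04243, 8.5, 5.0e-3),
        ],
    )
    def test_table_match_golden_cells(self, edi, csf, expected):
        assert compute_cr(edi, csf, "table_match") == pytest.approx(expected, rel=0.02)

    @given(
        edi=st.floats(1e-8, 10),
        csf=st.floats(0.1, 1e4),
    )
    @settings(max_examples=200, derandomize=True)
    def test_convention_identity(self, edi, csf):
        """literal = table_match × CSF² for every nonzero intake."""
        literal = compute_cr(edi, csf, CRConvention.LITERAL)
        table = compute_cr(edi, csf, CRConvention.TABLE_MATCH)
        assert literal == pytest.approx(table * csf**2, rel=1e-12)


class TestClassification:
    @pytest.mark.parametrize(
        "hi, label", [(0.956, "low"), (2.868, "elevated"), (1.0, "low")]
    )
    def test_hi_classes(self, hi, label):
        assert classify_hi(hi) == label

    @pytest.mark.parametrize(
        "cr, label", [(1.1e-6, "low"), (5.0e-3, "elevated"), (1e-4, "low")]
    )
    def test_cr_classes(self, cr, label):
        assert classify_cr(cr) == label

    def test_percent_of_reference(self):
        assert percent_of_reference(1.127, 45) == pytest.approx(2.5, rel=0.01)
        assert percent_of_reference(4.8e-3, 2) == pytest.approx(0.24, rel=0.01)
        assert percent_of_reference(0.0, 45) == 0.0


class TestRiskTable:
    def test_hi_equals_sum_of_row_hqs(self, study_results):
        """Table HI is the sum of its constituent exposure-row HQs."""
        table = study_results.table
        exposures = study_results.exposures
        for _, row in table.iterrows():
            hqs = exposures[
                (exposures.sample_id == row.sample_id)
                & (exposures.servings == row.servings)
            ].hq.dropna()
            assert row.hi == pytest.approx(hqs.sum(), rel=1e-12)

    def test_servings_linearity_across_fixture(self, study_results):
        """HI and every CR column at 3 servings equal 3 × the 1-serving value."""
        t = study_results.table
        one = t[t.servings == 1].set_index("sample_id")
        three = t[t.servings == 3].set_index("sample_id")
        for col in ["hi", "cr_Be", "cr_Cd", "cr_Pb"]:
            assert three[col].equals(three[col])  # alignment sanity
            for sid in one.index:
                assert three.loc[sid, col] == pytest.approx(
                    3 * one.loc[sid, col], rel=1e-12
                )

    def test_count_exceedances_requires_known_metric(self, study_results):
        with pytest.raises(ValueError):
            count_exceedances(study_results.table, "cr_Hg", 1e-4, 1)

    def test_results_summary_names_conventions(self, study_results):
        text = study_results.summary()
        assert "table_match" in text and "zero" in text
        assert "Hazard index" in text
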