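"""Unit and property tests of the rule engine.

The property tests compare the pipeline against an independent brute-force
re-implementation of the suspicion and organ criteria written as literal
condition lists, and check rule monotonicity and blindness of the suspicion
index to histopathology.
"""

import pytest
from hypothesis import given, settings

from sarcphen.phenotyping import (
    CaseGroup,
    ICDVersion,
    InconsistentRecordError,
    Organ,
    PFTPattern,
    ScaddingStage,
    Suspicion,
    assess_organ_involvement,
    assign_phenotype_groups,
    classify_case,
    classify_record,
    index_of_suspicion,
    is_multi_organ,
    low_dlco,
    match_icd_codes,
    pft_pattern,
    scadding_stage,
)
from sarcphen.records import (
    BiopsyRecord,
    ClinicalCourse,
    ClinicalFeature,
    ICDClaim,
    ImagingFindings,
    PatientRecord,
    PFTMeasurements,
    RadiologicFeature,
)

from conftest import record_st


def make_record(**kwargs) -> PatientRecord:
    base = dict(
        patient_id="T-1", site="SF", sex="male", race="african_american", age_years=60.0
    )
    base.update(kwargs)
    return PatientRecord(**base)


# ---------------------------------------------------------------------------
# ICD capture
# ---------------------------------------------------------------------------

class TestICDCapture:
    @pytest.mark.parametrize(
        "codes, expected",
        [
            ([("D86.0", "outpatient")], (True, ICDVersion.icd10)),
            ([("J44.9", "inpatient")], (False, ICDVersion.none)),
            ([("135.1", "inpatient"), ("D86", "outpatient")], (True, ICDVersion.icd9)),
            ([("135", "outpatient")], (True, ICDVersion.icd9)),
            ([("d86.2", "outpatient")], (True, ICDVersion.icd10)),
            ([("1350", "outpatient")], (False, ICDVersion.none)),  # not a 135 subcode
            ([], (False, ICDVersion.none)),
        ],
    )
    def test_capture_and_version(self, codes, expected):
        rec = make_record(claims=[ICDClaim(code=c, setting=s) for c, s in codes])
        assert match_icd_codes(rec) == expected

    def test_earliest_dated_claim_wins(self):
        rec = make_record(claims=[
            ICDClaim(code="135", setting="outpatient", date="2015-06-01"),
            ICDClaim(code="D86.0", setting="outpatient", date="2014-01-01"),
        ])
        assert match_icd_codes(rec) == (True, ICDVersion.icd10)

    def test_inpatient_and_outpatient_both_count(self):
        for setting in ("inpatient", "outpatient"):
            rec = make_record(claims=[ICDClaim(code="135", setting=setting)])
            assert match_icd_codes(rec)[0]


# ---------------------------------------------------------------------------
# index of suspicion and case group
# ---------------------------------------------------------------------------

GRANULOMA = BiopsyRecord(site="lung", result="nonnecrotizing_granuloma")


class TestSuspicionAndCaseGroup:
    def test_single_radiologic_feature_is_high(self):
        rec = make_record(
            radiologic_flags={RadiologicFeature.bilateral_hilar_lymphadenopathy}
        )
        assert index_of_suspicion(rec) == Suspicion.high

    def test_granuloma_without_features_stays_low_and_unlikely(self):
        rec = make_record(biopsies=[GRANULOMA])
        assert index_of_suspicion(rec) == Suspicion.low
        assert classify_case(rec) == CaseGroup.unlikely

    def test_no_features_is_low(self):
        assert index_of_suspicion(make_record()) == Suspicion.low

    def test_high_plus_granuloma_is_confirmed(self):
        rec = make_record(
            clinical_flags={ClinicalFeature.respiratory_symptoms}, biopsies=[GRANULOMA]
        )
        assert classify_case(rec) == CaseGroup.confirmed_biopsy

    def test_high_without_biopsy_is_probable(self):
        rec = make_record(clinical_flags={ClinicalFeature.respiratory_symptoms})
        assert classify_case(rec) == CaseGroup.probable_no_biopsy

    def test_nondiagnostic_biopsy_is_probable(self):
        rec = make_record(
            clinical_flags={ClinicalFeature.respiratory_symptoms},
            biopsies=[BiopsyRecord(site="lung", result="other_finding")],
        )
        assert classify_case(rec) == CaseGroup.probable_no_biopsy


# ---------------------------------------------------------------------------
# organ involvement
# ---------------------------------------------------------------------------

class TestOrganInvolvement:
    def test_abnormal_pft_implies_lung(self):
        rec = make_record(clinical_flags={ClinicalFeature.pft_abnormal})
        assert assess_organ_involvement(rec) == {Organ.lung}

    def test_three_feature_organs(self):
        rec = make_record(
            clinical_flags={
                ClinicalFeature.lupus_pernio_or_erythema_nodosum,
                ClinicalFeature.ocular_inflammation,
            },
            radiologic_flags={RadiologicFeature.cardiac_mri_or_pet_consistent},
        )
        assert assess_organ_involvement(rec) == {Organ.skin, Organ.eye, Organ.cardiac}

    def test_no_evidence_no_organs(self):
        assert assess_organ_involvement(make_record()) == frozenset()

    def test_granuloma_biopsy_confers_organ(self):
        rec = make_record(biopsies=[BiopsyRecord(site="mediastinal_hilar_node",
                                                 result="nonnecrotizing_granuloma")])
        assert assess_organ_involvement(rec) == {Organ.lung}

    def test_nondiagnostic_biopsy_confers_nothing(self):
        rec = make_record(biopsies=[BiopsyRecord(site="skin", result="other_finding")])
        assert assess_organ_involvement(rec) == frozenset()

    @pytest.mark.parametrize(
        "organs, expected",
        [
            (set(), False),
            ({Organ.lung, Organ.skin}, False),
            ({Organ.lung, Organ.skin, Organ.eye}, True),
        ],
    )
    def test_multi_organ_threshold(self, organs, expected):
        assert is_multi_organ(organs) is expected


# ---------------------------------------------------------------------------
# Scadding stage and PFT pattern
# ---------------------------------------------------------------------------

class TestScadding:
    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            (dict(report_available=False), ScaddingStage.missing),
            (dict(report_available=True, cxr_normal=True), ScaddingStage.stage0),
            (dict(report_available=True, hilar_mediastinal_nodal_enlargement=True),
             ScaddingStage.stage1),
            (dict(report_available=True, hilar_mediastinal_nodal_enlargement=True,
                  parenchymal_disease=True), ScaddingStage.stage2),
            (dict(report_available=True, parenchymal_disease=True), ScaddingStage.stage3),
            (dict(report_available=True, parenchymal_disease=True, fibrosis_end_stage=True),
             ScaddingStage.stage4),
            # fibrosis dominates coexisting nodal enlargement
            (dict(report_available=True, hilar_mediastinal_nodal_enlargement=True,
                  fibrosis_end_stage=True), ScaddingStage.stage4),
        ],
    )
    def test_staging(self, kwargs, expected):
        assert scadding_stage(ImagingFindings(**kwargs)) == expected

    def test_available_but_empty_report_is_inconsistent(self):
        with pytest.raises(InconsistentRecordError):
            scadding_stage(ImagingFindings(report_available=True))


class TestPFTPattern:
    @pytest.mark.parametrize(
        "ratio, tlc, expected",
        [
            (0.60, 6.0, PFTPattern.obstructive),
            (0.78, 3.9, PFTPattern.restrictive),
            (0.60, 3.9, PFTPattern.mixed),
            (0.78, 6.0, PFTPattern.normal),
        ],
    )
    def test_patterns_from_tlc(self, ratio, tlc, expected):
        pft = PFTMeasurements(
            available=True, fev1_fvc_ratio=ratio, fev1_fvc_lln=0.70,
            tlc=tlc, tlc_lln=5.0, fvc=3.5, fvc_lln=3.0,
        )
        assert pft_pattern(pft) == expected

    def test_fvc_fallback_when_no_lung_volumes(self):
        pft = PFTMeasurements(
            available=True, fev1_fvc_ratio=0.78, fev1_fvc_lln=0.70, fvc=2.5, fvc_lln=3.0
        )
        assert pft_pattern(pft) == PFTPattern.restrictive

    def test_unavailable_is_missing(self):
        assert pft_pattern(PFTMeasurements(available=False)) == PFTPattern.missing

    def test_available_without_fields_is_inconsistent(self):
        with pytest.raises(InconsistentRecordError):
            pft_pattern(PFTMeasurements(available=True))

    def test_isolated_low_dlco_reports_normal_pattern_plus_flag(self):
        pft = PFTMeasurements(
            available=True, fev1_fvc_ratio=0.78, fev1_fvc_lln=0.70,
            tlc=6.0, tlc_lln=5.0, fvc=3.5, fvc_lln=3.0,
            dlco_pct_predicted=60.0, dlco_lln_pct=75.0,
        )
        assert pft_pattern(pft) == PFTPattern.normal
        assert low_dlco(pft)


# ---------------------------------------------------------------------------
# phenotype groups
# ---------------------------------------------------------------------------

def course(**kw) -> ClinicalCourse:
    return ClinicalCourse(**kw)


class TestPhenotypeGroups:
    def test_stage2_treated_single_organ(self):
        got = assign_phenotype_groups(
            course(ever_treated=True), ScaddingStage.stage2, False,
            CaseGroup.confirmed_biopsy,
        )
        assert got == {3}

    def test_stage1_untreated_multi_organ_overlaps(self):
        got = assign_phenotype_groups(
            course(), ScaddingStage.stage1, True, CaseGroup.probable_no_biopsy
        )
        assert got == {1, 2}

    def test_acute_lofgren_contains_group7(self):
        got = assign_phenotype_groups(
            course(acute_lofgren=True), ScaddingStage.stage2, False,
            CaseGroup.confirmed_biopsy,
        )
        assert 7 in got
        # acute excludes the nonacute stage-based groups
        assert not got & {2, 3, 4, 5, 6}

    def test_remitting_untreated_is_group8(self):
        got = assign_phenotype_groups(
            course(remitting_no_active_disease_gt_1yr=True), ScaddingStage.stage0,
            False, CaseGroup.confirmed_biopsy,
        )
        assert got == {8}

    def test_recent_treatment_blocks_group8(self):
        got = assign_phenotype_groups(
            course(ever_treated=True, treated_within_3_months=True,
                   remitting_no_active_disease_gt_1yr=True),
            ScaddingStage.stage0, False, CaseGroup.confirmed_biopsy,
        )
        assert 8 not in got

    def test_cardiac_treated_is_group9(self):
        got = assign_phenotype_groups(
            course(ever_treated=True, cardiac_manifestations=True),
            ScaddingStage.stage4, True, CaseGroup.confirmed_biopsy,
        )
        assert got == {1, 5, 9}

    def test_unlikely_cases_rejected(self):
        with pytest.raises(ValueError):
            assign_phenotype_groups(course(), ScaddingStage.stage0, False, CaseGroup.unlikely)


# ---------------------------------------------------------------------------
# properties: monotonicity, biopsy-blindness, partition, oracle equivalence
# ---------------------------------------------------------------------------

ORACLE_ORGAN_CRITERIA = {
    # organ -> (biopsy sites, clinical features, radiologic features)
    "lung": ({"lung", "mediastinal_hilar_node"}, {"pft_abnormal"},
             {"bilateral_hilar_lymphadenopathy", "perilymphatic_nodules",
              "diffuse_infiltrates_or_fibrosis"}),
    "skin": ({"skin"}, {"lupus_pernio_or_erythema_nodosum"}, set()),
    "eye": ({"conjunctiva_sclera"}, {"ocular_inflammation"}, set()),
    "cardiac": ({"heart_pericardium"}, {"cardiac_manifestation"},
                {"cardiac_mri_or_pet_consistent"}),
    "liver_spleen": ({"liver", "spleen"}, {"hepatosplenomegaly"}, {"liver_spleen_lesions"}),
    "neuro": ({"brain_dura_nerve"}, set(), {"brain_mri_inflammation"}),
    "ent": ({"ear_nose_throat"}, {"laryngoscopy_granulomatous"}, set()),
}


def oracle_classify(rec: PatientRecord):
    """Literal re-statement of the suspicion/case/organ rules."""
    high = len(rec.clinical_flags) + len(rec.radiologic_flags) >= 1
    granuloma = any(b.result.value == "nonnecrotizing_granuloma" for b in rec.biopsies)
    if not high:
        group = "unlikely"
    elif granuloma:
        group = "confirmed_biopsy"
    else:
        group = "probable_no_biopsy"
    gran_sites = {b.site.value for b in rec.biopsies
                  if b.result.value == "nonnecrotizing_granuloma"}
    cf = {f.value for f in rec.clinical_flags}
    rf = {f.value for f in rec.radiologic_flags}
    organs = {
        organ
        for organ, (sites, clin, rad) in ORACLE_ORGAN_CRITERIA.items()
        if gran_sites & sites or cf & clin or rf & rad
    }
    return "high" if high else "low", group, organs


class TestRuleProperties:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(rec=record_st, extra=__import__("hypothesis").strategies.sampled_from(
        list(ClinicalFeature)))
    def test_adding_a_feature_never_lowers_suspicion(self, rec, extra):
        before = index_of_suspicion(rec)
        more = rec.model_copy(update={"clinical_flags": rec.clinical_flags | {extra}})
        after = index_of_suspicion(more)
        assert not (before == Suspicion.high and after == Suspicion.low)
        assert after == Suspicion.high

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(rec=record_st)
    def test_removing_all_features_forces_low(self, rec):
        bare = rec.model_copy(update={"clinical_flags": set(), "radiologic_flags": set()})
        assert index_of_suspicion(bare) == Suspicion.low

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(rec=record_st)
    def test_suspicion_is_blind_to_biopsies(self, rec):
        stripped = rec.model_copy(update={"biopsies": []})
        augmented = rec.model_copy(update={"biopsies": [GRANULOMA]})
        assert index_of_suspicion(stripped) == index_of_suspicion(rec)
        assert index_of_suspicion(augmented) == index_of_suspicion(rec)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(rec=record_st)
    def test_case_groups_partition_suspicion_classes(self, rec):
        group = classify_case(rec)
        if index_of_suspicion(rec) == Suspicion.high:
            assert group in (CaseGroup.confirmed_biopsy, CaseGroup.probable_no_biopsy)
        else:
            assert group == CaseGroup.unlikely

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(recs=__import__("hypothesis").strategies.lists(record_st, max_size=6))
    def test_pipeline_agrees_with_brute_force_oracle(self, recs):
        recs = [r.model_copy(update={"patient_id": f"P{i}"}) for i, r in enumerate(recs)]
        for rec in recs:
            cl = classify_record(rec)
            susp, group, organs = oracle_classify(rec)
            assert cl.index_of_suspicion.value == susp
            assert cl.case_group.value == group
            assert {o.value for o in cl.organs} == organs
            assert cl.multi_organ == (len(organs) >= 3)
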