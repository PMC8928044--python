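import datetime

import pytest
from hypothesis import strategies as st

from sarcphen.cohort import build_fixture_cohort
from sarcphen.phenotyping import classify_cohort
from sarcphen.records import (
    BiopsyRecord,
    BiopsyResult,
    BiopsySite,
    ClinicalCourse,
    ClinicalFeature,
    ICDClaim,
    ImagingFindings,
    PatientRecord,
    PFTMeasurements,
    Provenance,
    Race,
    RadiologicFeature,
    Setting,
    Sex,
    Site,
)


@pytest.fixture(scope="session")
def fixture_cohort():
    return build_fixture_cohort()


@pytest.fixture(scope="session")
def fixture_classifications(fixture_cohort):
    return classify_cohort(fixture_cohort)


# ---------------------------------------------------------------------------
# hypothesis strategies for arbitrary valid records
# ---------------------------------------------------------------------------

_codes = st.sampled_from(["135", "135.1", "D86.0", "D86.9", "d86.2", "J44.9", "486", "1350"])

claims_st = st.lists(
    st.builds(
        ICDClaim,
        code=_codes,
        setting=st.sampled_from(list(Setting)),
        date=st.one_of(
            st.none(),
            st.dates(min_value=datetime.date(1989, 1, 1), max_value=datetime.date(2019, 12, 31)),
        ),
    ),
    max_size=4,
)

biopsies_st = st.lists(
    st.builds(
        BiopsyRecord,
        site=st.sampled_from(list(BiopsySite)),
        result=st.sampled_from(list(BiopsyResult)),
        provenance=st.sampled_from(list(Provenance)),
    ),
    max_size=3,
)

_lln = st.floats(min_value=0.1, max_value=8.0, allow_nan=False)

pft_st = st.one_of(
    st.just(PFTMeasurements(available=False)),
    st.builds(
        PFTMeasurements,
        available=st.just(True),
        fev1_fvc_ratio=st.floats(min_value=0.2, max_value=1.0),
        fev1_fvc_lln=st.floats(min_value=0.5, max_value=0.8),
        tlc=st.one_of(st.none(), st.floats(min_value=2.0, max_value=9.0)),
        tlc_lln=_lln,
        fvc=st.floats(min_value=1.0, max_value=7.0),
        fvc_lln=_lln,
        dlco_pct_predicted=st.one_of(st.none(), st.floats(min_value=20.0, max_value=140.0)),
        dlco_lln_pct=st.floats(min_value=50.0, max_value=90.0),
    ),
)

imaging_st = st.one_of(
    st.just(ImagingFindings(report_available=False)),
    st.just(ImagingFindings(report_available=True, cxr_normal=True)),
    st.builds(
        ImagingFindings,
        report_available=st.just(True),
        cxr_normal=st.just(False),
        hilar_mediastinal_nodal_enlargement=st.booleans(),
        parenchymal_disease=st.booleans(),
        fibrosis_end_stage=st.booleans(),
    ).filter(
        lambda im: im.hilar_mediastinal_nodal_enlargement
        or im.parenchymal_disease
        or im.fibrosis_end_stage
    ),
)

course_st = st.builds(
    lambda ever, within3, acute, remit, cardiac: ClinicalCourse(
        ever_treated=ever or within3,
        treated_within_3_months=within3,
        acute_lofgren=acute,
        remitting_no_active_disease_gt_1yr=remit,
        cardiac_manifestations=cardiac,
    ),
    ever=st.booleans(),
    within3=st.booleans(),
    acute=st.booleans(),
    remit=st.booleans(),
    cardiac=st.booleans(),
)

record_st = st.builds(
    PatientRecord,
    patient_id=st.text(alphabet="ABCDEF0123456789-", min_size=1, max_size=12),
    site=st.sampled_from(list(Site)),
    sex=st.sampled_from(list(Sex)),
    race=st.sampled_from(list(Race)),
    age_years=st.floats(min_value=0.0, max_value=120.0, allow_nan=False),
    claims=claims_st,
    clinical_flags=st.sets(st.sampled_from(list(ClinicalFeature)), max_size=6),
    radiologic_flags=st.sets(st.sampled_from(list(RadiologicFeature)), max_size=4),
    biopsies=biopsies_st,
    pft=pft_st,
    imaging=imaging_st,
    course=course_st,
)
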