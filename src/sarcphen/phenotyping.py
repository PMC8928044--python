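"""Rule-based sarcoidosis case classification.

The pipeline derives, per patient and purely from raw record fields:

* **ICD capture** — at least one inpatient or outpatient claim carrying the
  sarcoidosis codes (ICD-9 ``135`` incl. subcodes, ICD-10 ``D86.x``).
* **Index of suspicion** — *high* if any supportive clinical or radiological
  feature is documented, *low* otherwise.  Biopsies are never consulted at
  this step: the index is built from clinical and radiographic information
  regardless of the availability of biopsy data.
* **Case group** — high index + documented nonnecrotizing granuloma on any
  biopsy (primary or secondary report) -> *confirmed biopsy*; high index
  without such histopathology -> *probable (no confirmed biopsy)*; low
  index -> *unlikely*, even when a granuloma biopsy exists.
* **Organ involvement** — per-organ criteria (qualifying granuloma biopsy
  site, or the organ's clinical/radiological features); *multi-organ* means
  involvement of >= 3 organs.
* **Scadding stage** from chest-imaging findings, the 4-level **PFT
  pattern** against lower-limit-of-normal thresholds, and the nine
  (non-exclusive) clinical phenotype groups.
"""

from __future__ import annotations

import datetime
import enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, model_validator

from .records import (
    BiopsyResult,
    BiopsySite,
    ClinicalCourse,
    ClinicalFeature,
    ICDClaim,
    ImagingFindings,
    PatientRecord,
    PFTMeasurements,
    RadiologicFeature,
)

__all__ = [
    "ICDVersion",
    "Suspicion",
    "CaseGroup",
    "Organ",
    "ScaddingStage",
    "PFTPattern",
    "CaseClassification",
    "InconsistentRecordError",
    "match_icd_codes",
    "index_of_suspicion",
    "classify_case",
    "assess_organ_involvement",
    "is_multi_organ",
    "scadding_stage",
    "pft_pattern",
    "low_dlco",
    "assign_phenotype_groups",
    "classify_record",
    "classify_cohort",
]


class ICDVersion(str, enum.Enum):
    icd9 = "icd9"
    icd10 = "icd10"
    none = "none"


class Suspicion(str, enum.Enum):
    high = "high"
    low = "low"


class CaseGroup(str, enum.Enum):
    confirmed_biopsy = "confirmed_biopsy"
    probable_no_biopsy = "probable_no_biopsy"
    unlikely = "unlikely"


class Organ(str, enum.Enum):
    lung = "lung"
    skin = "skin"
    eye = "eye"
    cardiac = "cardiac"
    liver_spleen = "liver_spleen"
    neuro = "neuro"
    ent = "ent"


class ScaddingStage(str, enum.Enum):
    stage0 = "stage0"
    stage1 = "stage1"
    stage2 = "stage2"
    stage3 = "stage3"
    stage4 = "stage4"
    missing = "missing"


class PFTPattern(str, enum.Enum):
    obstructive = "obstructive"
    restrictive = "restrictive"
    mixed = "mixed"
    normal = "normal"
    missing = "missing"


class InconsistentRecordError(ValueError):
    """An internally inconsistent record reached a derivation rule."""


class CaseClassification(BaseModel):
    """Derived labels for one patient.  Never stored on records; always the
    output of :func:`classify_record`."""

    model_config = ConfigDict(frozen=True)

    patient_id: str
    icd_captured: bool
    icd_version_first: ICDVersion
    index_of_suspicion: Suspicion
    case_group: CaseGroup
    granuloma_documented: bool
    organs: frozenset[Organ]
    multi_organ: bool
    scadding: ScaddingStage
    pft_pattern: PFTPattern
    low_dlco: bool
    phenotype_groups: frozenset[int]

    @model_validator(mode="after")
    def _invariants(self) -> "CaseClassification":
        if (self.case_group == CaseGroup.unlikely) != (self.index_of_suspicion == Suspicion.low):
            raise ValueError("case_group 'unlikely' must coincide with low index of suspicion")
        if self.multi_organ != (len(self.organs) >= 3):
            raise ValueError("multi_organ must equal |organs| >= 3")
        if self.case_group == CaseGroup.unlikely:
            if self.phenotype_groups:
                raise ValueError("unlikely cases carry no phenotype groups")
        elif (1 in self.phenotype_groups) != self.multi_organ:
            raise ValueError("phenotype group 1 must coincide with multi-organ involvement")
        if not self.phenotype_groups <= set(range(1, 10)):
            raise ValueError("phenotype groups must lie in 1..9")
        return self


# ---------------------------------------------------------------------------
# ICD capture
# ---------------------------------------------------------------------------

def _sarcoid_code_version(code: str) -> Optional[ICDVersion]:
    """ICD-9 135 (whole code or '135.' subcode) or ICD-10 D86 prefix.

    '135' must match exactly or as a '135.' prefix so unrelated codes that
    merely begin with the digits 135 are not captured.
    """
    c = code.upper()
    if c == "135" or c.startswith("135."):
        return ICDVersion.icd9
    if c.startswith("D86"):
        return ICDVersion.icd10
    return None


def match_icd_codes(record: PatientRecord) -> tuple[bool, ICDVersion]:
    """Return (captured, version of the earliest qualifying claim).

    Dated claims are ordered by date; undated claims sort before dated ones,
    and ICD-9 is preferred at ties (the only ordering consistent with a study
    era that predates ICD-10 adoption).
    """
    qualifying: list[tuple[ICDClaim, ICDVersion]] = []
    for claim in record.claims:
        v = _sarcoid_code_version(claim.code)
        if v is not None:
            qualifying.append((claim, v))
    if not qualifying:
        return False, ICDVersion.none
    first = min(
        qualifying,
        key=lambda cv: (
            cv[0].date is not None,
            cv[0].date or datetime.date.min,
            cv[1] != ICDVersion.icd9,
        ),
    )
    return True, first[1]


# ---------------------------------------------------------------------------
# index of suspicion and case group
# ---------------------------------------------------------------------------

def index_of_suspicion(record: PatientRecord) -> Suspicion:
    """High iff at least one supportive clinical or radiological feature is
    present.  Deliberately blind to biopsies."""
    if record.clinical_flags or record.radiologic_flags:
        return Suspicion.high
    return Suspicion.low


def _has_granuloma(record: PatientRecord) -> bool:
    return any(b.result == BiopsyResult.nonnecrotizing_granuloma for b in record.biopsies)


def classify_case(record: PatientRecord) -> CaseGroup:
    """Three-way case grouping.

    A granuloma-positive biopsy without supportive clinical/radiological
    features still classifies as *unlikely*: histopathology alone does not
    establish the case.
    """
    if index_of_suspicion(record) == Suspicion.low:
        return CaseGroup.unlikely
    if _has_granuloma(record):
        return CaseGroup.confirmed_biopsy
    return CaseGroup.probable_no_biopsy


# ---------------------------------------------------------------------------
# organ involvement
# ---------------------------------------------------------------------------

ORGAN_BIOPSY_SITES: dict[Organ, frozenset[BiopsySite]] = {
    Organ.lung: frozenset({BiopsySite.lung, BiopsySite.mediastinal_hilar_node}),
    Organ.skin: frozenset({BiopsySite.skin}),
    Organ.eye: frozenset({BiopsySite.conjunctiva_sclera}),
    Organ.cardiac: frozenset({BiopsySite.heart_pericardium}),
    Organ.liver_spleen: frozenset({BiopsySite.liver, BiopsySite.spleen}),
    Organ.neuro: frozenset({BiopsySite.brain_dura_nerve}),
    Organ.ent: frozenset({BiopsySite.ear_nose_throat}),
}

ORGAN_CLINICAL_FEATURES: dict[Organ, frozenset[ClinicalFeature]] = {
    Organ.lung: frozenset({ClinicalFeature.pft_abnormal}),
    Organ.skin: frozenset({ClinicalFeature.lupus_pernio_or_erythema_nodosum}),
    Organ.eye: frozenset({ClinicalFeature.ocular_inflammation}),
    Organ.cardiac: frozenset({ClinicalFeature.cardiac_manifestation}),
    Organ.liver_spleen: frozenset({ClinicalFeature.hepatosplenomegaly}),
    Organ.ent: frozenset({ClinicalFeature.laryngoscopy_granulomatous}),
}

ORGAN_RADIOLOGIC_FEATURES: dict[Organ, frozenset[RadiologicFeature]] = {
    Organ.lung: frozenset({
        RadiologicFeature.bilateral_hilar_lymphadenopathy,
        RadiologicFeature.perilymphatic_nodules,
        RadiologicFeature.diffuse_infiltrates_or_fibrosis,
    }),
    Organ.cardiac: frozenset({RadiologicFeature.cardiac_mri_or_pet_consistent}),
    Organ.liver_spleen: frozenset({RadiologicFeature.liver_spleen_lesions}),
    Organ.neuro: frozenset({RadiologicFeature.brain_mri_inflammation}),
}


def assess_organ_involvement(record: PatientRecord) -> frozenset[Organ]:
    """Per-organ involvement: a qualifying granuloma-positive biopsy site, or
    any of the organ's clinical/radiological criteria."""
    granuloma_sites = {
        b.site for b in record.biopsies if b.result == BiopsyResult.nonnecrotizing_granuloma
    }
    involved: set[Organ] = set()
    for organ in Organ:
        if granuloma_sites & ORGAN_BIOPSY_SITES[organ]:
            involved.add(organ)
        elif record.clinical_flags & ORGAN_CLINICAL_FEATURES.get(organ, frozenset()):
            involved.add(organ)
        elif record.radiologic_flags & ORGAN_RADIOLOGIC_FEATURES.get(organ, frozenset()):
            involved.add(organ)
    return frozenset(involved)


def is_multi_organ(organs: frozenset[Organ] | set[Organ]) -> bool:
    """Multi-organ phenotype: involvement of at least 3 organs."""
    return len(organs) >= 3


# ---------------------------------------------------------------------------
# Scadding stage and PFT pattern
# ---------------------------------------------------------------------------

def scadding_stage(imaging: ImagingFindings) -> ScaddingStage:
    """Chest-radiograph staging: 0 normal; I nodal enlargement only; II nodal
    enlargement and parenchymal disease; III parenchymal disease only; IV
    end-stage fibrosis (dominant when it coexists with other findings)."""
    if not imaging.report_available:
        return ScaddingStage.missing
    if imaging.fibrosis_end_stage:
        return ScaddingStage.stage4
    if imaging.hilar_mediastinal_nodal_enlargement and imaging.parenchymal_disease:
        return ScaddingStage.stage2
    if imaging.parenchymal_disease:
        return ScaddingStage.stage3
    if imaging.hilar_mediastinal_nodal_enlargement:
        return ScaddingStage.stage1
    if imaging.cxr_normal:
        return ScaddingStage.stage0
    raise InconsistentRecordError(
        "imaging report available but neither normal nor any finding recorded"
    )


def pft_pattern(pft: PFTMeasurements) -> PFTPattern:
    """Obstruction: FEV1/FVC below its LLN.  Restriction: TLC below its LLN
    (FVC against its LLN when lung volumes are absent).  Both -> mixed;
    neither -> normal.  Isolated low DLCO is reported separately
    (:func:`low_dlco`) and classifies as normal here."""
    if not pft.available:
        return PFTPattern.missing
    if pft.fev1_fvc_ratio is None or pft.fev1_fvc_lln is None:
        raise InconsistentRecordError("PFT available but FEV1/FVC ratio or its LLN missing")
    obstruction = pft.fev1_fvc_ratio < pft.fev1_fvc_lln
    if pft.tlc is not None and pft.tlc_lln is not None:
        restriction = pft.tlc < pft.tlc_lln
    elif pft.fvc is not None and pft.fvc_lln is not None:
        restriction = pft.fvc < pft.fvc_lln
    else:
        raise InconsistentRecordError("PFT available but neither TLC nor FVC with LLN present")
    if obstruction and restriction:
        return PFTPattern.mixed
    if obstruction:
        return PFTPattern.obstructive
    if restriction:
        return PFTPattern.restrictive
    return PFTPattern.normal


def low_dlco(pft: PFTMeasurements) -> bool:
    """Diffusing capacity below its LLN (false when unavailable)."""
    if not pft.available or pft.dlco_pct_predicted is None or pft.dlco_lln_pct is None:
        return False
    return pft.dlco_pct_predicted < pft.dlco_lln_pct


# ---------------------------------------------------------------------------
# clinical phenotype groups
# ---------------------------------------------------------------------------

def assign_phenotype_groups(
    course: ClinicalCourse,
    scadding: ScaddingStage,
    multi_organ: bool,
    case_group: CaseGroup,
) -> frozenset[int]:
    """Nine non-exclusive clinical phenotype groups (patients may overlap):

    1 multi-organ (>=3 organs); 2 nonacute stage I never treated;
    3 nonacute stage II–III treated (formerly or within 3 months, i.e. ever);
    4 nonacute stage II–III never treated; 5 nonacute stage IV treated;
    6 nonacute stage IV never treated; 7 acute (Lofgren); 8 remitting (>1 yr
    without active disease) and not recently treated; 9 cardiac
    manifestations, treated.

    Only defined for sarcoidosis cases (confirmed or probable).
    """
    if case_group == CaseGroup.unlikely:
        raise ValueError("phenotype groups are not defined for unlikely cases")
    groups: set[int] = set()
    nonacute = not course.acute_lofgren
    treated = course.ever_treated
    if multi_organ:
        groups.add(1)
    if nonacute and scadding == ScaddingStage.stage1 and not treated:
        groups.add(2)
    if nonacute and scadding in (ScaddingStage.stage2, ScaddingStage.stage3):
        groups.add(3 if treated else 4)
    if nonacute and scadding == ScaddingStage.stage4:
        groups.add(5 if treated else 6)
    if course.acute_lofgren:
        groups.add(7)
    if course.remitting_no_active_disease_gt_1yr and not course.treated_within_3_months:
        groups.add(8)
    if course.cardiac_manifestations and treated:
        groups.add(9)
    return frozenset(groups)


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def classify_record(record: PatientRecord) -> CaseClassification:
    """Derive the full classification for one patient."""
    captured, version = match_icd_codes(record)
    suspicion = index_of_suspicion(record)
    group = classify_case(record)
    organs = assess_organ_involvement(record)
    multi = is_multi_organ(organs)
    stage = scadding_stage(record.imaging)
    pattern = pft_pattern(record.pft)
    if group == CaseGroup.unlikely:
        groups: frozenset[int] = frozenset()
    else:
        groups = assign_phenotype_groups(record.course, stage, multi, group)
    return CaseClassification(
        patient_id=record.patient_id,
        icd_captured=captured,
        icd_version_first=version,
        index_of_suspicion=suspicion,
        case_group=group,
        granuloma_documented=_has_granuloma(record),
        organs=organs,
        multi_organ=multi,
        scadding=stage,
        pft_pattern=pattern,
        low_dlco=low_dlco(record.pft),
        phenotype_groups=groups,
    )


def classify_cohort(records: list[PatientRecord]) -> list[CaseClassification]:
    """Classify every record; deterministic, order-preserving."""
    return [classify_record(r) for r in records]
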