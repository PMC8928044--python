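"""Structured EMR-extract records for sarcoidosis phenotyping.

One :class:`PatientRecord` holds everything the rule engine consumes for a
single patient: ICD claims, the supportive clinical and radiological feature
flags, biopsy records, pulmonary function measurements with their
lower-limit-of-normal (LLN) reference values, chest-imaging findings used for
Scadding staging, treatment/disease-course history, and demographics.

Records are validated on construction (pydantic) and can be serialized to
JSON or to a flat one-row-per-patient CSV dialect.  Both formats round-trip
exactly.  Derived labels (index of suspicion, case group, organ sets, ...)
are never stored on a record: they are functions of the raw fields, computed
by :mod:`sarcphen.phenotyping`.
"""

from __future__ import annotations

import csv
import datetime
import enum
import io
import json
from pathlib import Path
from typing import Optional, Union

from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator, model_validator

__all__ = [
    "Setting",
    "Site",
    "Sex",
    "Race",
    "ClinicalFeature",
    "RadiologicFeature",
    "BiopsySite",
    "BiopsyResult",
    "Provenance",
    "ICDClaim",
    "BiopsyRecord",
    "PFTMeasurements",
    "ImagingFindings",
    "ClinicalCourse",
    "PatientRecord",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "cohort_to_json_bytes",
    "cohort_json_schema",
]


class Setting(str, enum.Enum):
    """Claim setting; both inpatient and outpatient claims count for capture."""

    inpatient = "inpatient"
    outpatient = "outpatient"


class Site(str, enum.Enum):
    SF = "SF"
    PA = "PA"


class Sex(str, enum.Enum):
    male = "male"
    female = "female"


class Race(str, enum.Enum):
    african_american = "african_american"
    non_hispanic_white = "non_hispanic_white"
    hispanic_white = "hispanic_white"
    unknown = "unknown"
    other = "other"


class ClinicalFeature(str, enum.Enum):
    """Clinical features supportive of sarcoidosis (high-index-of-suspicion list).

    Items listed with "or" alternatives are merged into a single flag, since
    the rule is presence-of-any (e.g. optic neuritis / scleritis / uveitis /
    retinitis -> ``ocular_inflammation``).
    """

    lofgren_syndrome = "lofgren_syndrome"
    heerfordt_syndrome = "heerfordt_syndrome"
    lupus_pernio_or_erythema_nodosum = "lupus_pernio_or_erythema_nodosum"
    maculopapular_lesions = "maculopapular_lesions"
    facial_nerve_palsy = "facial_nerve_palsy"
    parotid_enlargement = "parotid_enlargement"
    ocular_inflammation = "ocular_inflammation"
    lacrimal_swelling = "lacrimal_swelling"
    laryngoscopy_granulomatous = "laryngoscopy_granulomatous"
    hepatosplenomegaly = "hepatosplenomegaly"
    respiratory_symptoms = "respiratory_symptoms"
    pft_abnormal = "pft_abnormal"
    cardiac_manifestation = "cardiac_manifestation"
    calcium_vitd_abnormal = "calcium_vitd_abnormal"
    ace_or_sil2r_elevated = "ace_or_sil2r_elevated"
    bal_lymphocytosis = "bal_lymphocytosis"


class RadiologicFeature(str, enum.Enum):
    """Radiological features supportive of sarcoidosis."""

    bilateral_hilar_lymphadenopathy = "bilateral_hilar_lymphadenopathy"
    perilymphatic_nodules = "perilymphatic_nodules"
    diffuse_infiltrates_or_fibrosis = "diffuse_infiltrates_or_fibrosis"
    cardiac_mri_or_pet_consistent = "cardiac_mri_or_pet_consistent"
    liver_spleen_lesions = "liver_spleen_lesions"
    brain_mri_inflammation = "brain_mri_inflammation"
    extrathoracic_lymphadenopathy = "extrathoracic_lymphadenopathy"


class BiopsySite(str, enum.Enum):
    lung = "lung"
    mediastinal_hilar_node = "mediastinal_hilar_node"
    skin = "skin"
    conjunctiva_sclera = "conjunctiva_sclera"
    heart_pericardium = "heart_pericardium"
    liver = "liver"
    spleen = "spleen"
    brain_dura_nerve = "brain_dura_nerve"
    ear_nose_throat = "ear_nose_throat"
    other = "other"


class BiopsyResult(str, enum.Enum):
    nonnecrotizing_granuloma = "nonnecrotizing_granuloma"
    other_finding = "other_finding"


class Provenance(str, enum.Enum):
    """Primary: read from an actual pathology report; secondary: re-documented
    in clinical notes (remote or outside biopsy)."""

    primary = "primary"
    secondary = "secondary"


class ICDClaim(BaseModel):
    """A single diagnostic claim.  Codes are stored verbatim (uppercased); a
    record may carry non-sarcoidosis codes."""

    model_config = ConfigDict(frozen=True)

    code: str
    setting: Setting
    date: Optional[datetime.date] = None

    @field_validator("code")
    @classmethod
    def _code_ok(cls, v: str) -> str:
        if not v:
            raise ValueError("ICD code must be non-empty")
        if any(ch.isspace() for ch in v):
            raise ValueError(f"ICD code {v!r} contains whitespace")
        return v.upper()


class BiopsyRecord(BaseModel):
    model_config = ConfigDict(frozen=True)

    site: BiopsySite
    result: BiopsyResult
    provenance: Provenance = Provenance.primary


class PFTMeasurements(BaseModel):
    """Pulmonary function measurements with LLN reference values.

    ``fev1_fvc_ratio`` / ``fev1_fvc_lln`` are fractions; ``tlc`` / ``fvc`` and
    their LLNs are liters; DLCO is percent-predicted.  When ``available`` is
    false the measurement fields are ignored by the pattern rule.
    """

    available: bool = False
    fev1_fvc_ratio: Optional[float] = None
    fev1_fvc_lln: Optional[float] = None
    tlc: Optional[float] = None
    tlc_lln: Optional[float] = None
    fvc: Optional[float] = None
    fvc_lln: Optional[float] = None
    dlco_pct_predicted: Optional[float] = None
    dlco_lln_pct: Optional[float] = None

    @model_validator(mode="after")
    def _lln_positive(self) -> "PFTMeasurements":
        for name in ("fev1_fvc_lln", "tlc_lln", "fvc_lln", "dlco_lln_pct"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
        return self


class ImagingFindings(BaseModel):
    """Chest-imaging findings abstracted from radiology reports, the inputs to
    Scadding staging."""

    report_available: bool = False
    cxr_normal: bool = False
    hilar_mediastinal_nodal_enlargement: bool = False
    parenchymal_disease: bool = False
    fibrosis_end_stage: bool = False

    @model_validator(mode="after")
    def _normal_excludes_findings(self) -> "ImagingFindings":
        if self.cxr_normal and (
            self.hilar_mediastinal_nodal_enlargement
            or self.parenchymal_disease
            or self.fibrosis_end_stage
        ):
            raise ValueError("cxr_normal is incompatible with positive imaging findings")
        return self


class ClinicalCourse(BaseModel):
    """Treatment and disease-activity history used for phenotype grouping."""

    ever_treated: bool = False
    treated_within_3_months: bool = False
    acute_lofgren: bool = False
    remitting_no_active_disease_gt_1yr: bool = False
    cardiac_manifestations: bool = False

    @model_validator(mode="after")
    def _treatment_consistent(self) -> "ClinicalCourse":
        if self.treated_within_3_months and not self.ever_treated:
            raise ValueError("treated_within_3_months implies ever_treated")
        return self


class PatientRecord(BaseModel):
    """One patient's structured EMR extract."""

    patient_id: str
    site: Site
    sex: Sex
    race: Race
    age_years: float = Field(ge=0, le=120)
    claims: list[ICDClaim] = Field(default_factory=list)
    clinical_flags: set[ClinicalFeature] = Field(default_factory=set)
    radiologic_flags: set[RadiologicFeature] = Field(default_factory=set)
    biopsies: list[BiopsyRecord] = Field(default_factory=list)
    pft: PFTMeasurements = Field(default_factory=PFTMeasurements)
    imaging: ImagingFindings = Field(default_factory=ImagingFindings)
    course: ClinicalCourse = Field(default_factory=ClinicalCourse)

    @field_validator("patient_id")
    @classmethod
    def _id_ok(cls, v: str) -> str:
        if not v:
            raise ValueError("patient_id must be non-empty")
        return v


class CohortValidationError(ValueError):
    """Raised when a cohort file violates the schema; carries the offending
    patient_id (when known) and field."""

    def __init__(self, message: str, patient_id: Optional[str] = None, field: Optional[str] = None):
        self.patient_id = patient_id
        self.field = field
        super().__init__(message)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "patient_id", "site", "sex", "race", "age_years",
    "claims", "clinical_flags", "radiologic_flags", "biopsies",
    "pft_available", "fev1_fvc_ratio", "fev1_fvc_lln", "tlc", "tlc_lln",
    "fvc", "fvc_lln", "dlco_pct_predicted", "dlco_lln_pct",
    "cxr_report_available", "cxr_normal", "hilar_mediastinal_nodal_enlargement",
    "parenchymal_disease", "fibrosis_end_stage",
    "ever_treated", "treated_within_3_months", "acute_lofgren",
    "remitting_no_active_disease_gt_1yr", "cardiac_manifestations",
]


def _record_to_dict(rec: PatientRecord) -> dict:
    d = rec.model_dump(mode="json")
    # sets dump in arbitrary order; sort for byte-stable output
    d["clinical_flags"] = sorted(d["clinical_flags"])
    d["radiologic_flags"] = sorted(d["radiologic_flags"])
    return d


def _opt_float(s: str) -> Optional[float]:
    return None if s == "" else float(s)


def _fmt_opt(v: Optional[float]) -> str:
    return "" if v is None else repr(v)


def _bool(s: str) -> bool:
    if s in ("true", "True", "1"):
        return True
    if s in ("false", "False", "0", ""):
        return False
    raise ValueError(f"not a boolean token: {s!r}")


def _record_to_row(rec: PatientRecord) -> dict:
    claims = ";".join(
        "|".join([c.code, c.setting.value, c.date.isoformat() if c.date else ""])
        for c in rec.claims
    )
    biopsies = ";".join(
        "|".join([b.site.value, b.result.value, b.provenance.value]) for b in rec.biopsies
    )
    p, im, co = rec.pft, rec.imaging, rec.course
    return {
        "patient_id": rec.patient_id,
        "site": rec.site.value,
        "sex": rec.sex.value,
        "race": rec.race.value,
        "age_years": repr(rec.age_years),
        "claims": claims,
        "clinical_flags": ";".join(sorted(f.value for f in rec.clinical_flags)),
        "radiologic_flags": ";".join(sorted(f.value for f in rec.radiologic_flags)),
        "biopsies": biopsies,
        "pft_available": str(p.available).lower(),
        "fev1_fvc_ratio": _fmt_opt(p.fev1_fvc_ratio),
        "fev1_fvc_lln": _fmt_opt(p.fev1_fvc_lln),
        "tlc": _fmt_opt(p.tlc),
        "tlc_lln": _fmt_opt(p.tlc_lln),
        "fvc": _fmt_opt(p.fvc),
        "fvc_lln": _fmt_opt(p.fvc_lln),
        "dlco_pct_predicted": _fmt_opt(p.dlco_pct_predicted),
        "dlco_lln_pct": _fmt_opt(p.dlco_lln_pct),
        "cxr_report_available": str(im.report_available).lower(),
        "cxr_normal": str(im.cxr_normal).lower(),
        "hilar_mediastinal_nodal_enlargement": str(im.hilar_mediastinal_nodal_enlargement).lower(),
        "parenchymal_disease": str(im.parenchymal_disease).lower(),
        "fibrosis_end_stage": str(im.fibrosis_end_stage).lower(),
        "ever_treated": str(co.ever_treated).lower(),
        "treated_within_3_months": str(co.treated_within_3_months).lower(),
        "acute_lofgren": str(co.acute_lofgren).lower(),
        "remitting_no_active_disease_gt_1yr": str(co.remitting_no_active_disease_gt_1yr).lower(),
        "cardiac_manifestations": str(co.cardiac_manifestations).lower(),
    }


def _row_to_record(row: dict) -> PatientRecord:
    claims = []
    if row["claims"]:
        for tok in row["claims"].split(";"):
            code, setting, date = tok.split("|")
            claims.append(ICDClaim(code=code, setting=setting, date=date or None))
    biopsies = []
    if row["biopsies"]:
        for tok in row["biopsies"].split(";"):
            site, result, prov = tok.split("|")
            biopsies.append(BiopsyRecord(site=site, result=result, provenance=prov))
    return PatientRecord(
        patient_id=row["patient_id"],
        site=row["site"],
        sex=row["sex"],
        race=row["race"],
        age_years=float(row["age_years"]),
        claims=claims,
        clinical_flags={ClinicalFeature(t) for t in row["clinical_flags"].split(";") if t},
        radiologic_flags={RadiologicFeature(t) for t in row["radiologic_flags"].split(";") if t},
        biopsies=biopsies,
        pft=PFTMeasurements(
            available=_bool(row["pft_available"]),
            fev1_fvc_ratio=_opt_float(row["fev1_fvc_ratio"]),
            fev1_fvc_lln=_opt_float(row["fev1_fvc_lln"]),
            tlc=_opt_float(row["tlc"]),
            tlc_lln=_opt_float(row["tlc_lln"]),
            fvc=_opt_float(row["fvc"]),
            fvc_lln=_opt_float(row["fvc_lln"]),
            dlco_pct_predicted=_opt_float(row["dlco_pct_predicted"]),
            dlco_lln_pct=_opt_float(row["dlco_lln_pct"]),
        ),
        imaging=ImagingFindings(
            report_available=_bool(row["cxr_report_available"]),
            cxr_normal=_bool(row["cxr_normal"]),
            hilar_mediastinal_nodal_enlargement=_bool(row["hilar_mediastinal_nodal_enlargement"]),
            parenchymal_disease=_bool(row["parenchymal_disease"]),
            fibrosis_end_stage=_bool(row["fibrosis_end_stage"]),
        ),
        course=ClinicalCourse(
            ever_treated=_bool(row["ever_treated"]),
            treated_within_3_months=_bool(row["treated_within_3_months"]),
            acute_lofgren=_bool(row["acute_lofgren"]),
            remitting_no_active_disease_gt_1yr=_bool(row["remitting_no_active_disease_gt_1yr"]),
            cardiac_manifestations=_bool(row["cardiac_manifestations"]),
        ),
    )


def _check_unique_ids(records: list[PatientRecord]) -> None:
    seen: set[str] = set()
    for r in records:
        if r.patient_id in seen:
            raise CohortValidationError(
                f"duplicate patient_id {r.patient_id!r}", patient_id=r.patient_id, field="patient_id"
            )
        seen.add(r.patient_id)


def cohort_to_json_bytes(records: list[PatientRecord]) -> bytes:
    """Canonical UTF-8 JSON serialization (used for checksums and files)."""
    payload = [_record_to_dict(r) for r in records]
    return (json.dumps(payload, indent=1, ensure_ascii=False) + "\n").encode("utf-8")


def _cohort_to_csv_text(records: list[PatientRecord]) -> str:
    buf = io.StringIO()
    writer = csv.DictWriter(buf, fieldnames=_CSV_COLUMNS, lineterminator="\n")
    writer.writeheader()
    for r in records:
        writer.writerow(_record_to_row(r))
    return buf.getvalue()


def write_cohort(records: list[PatientRecord], path: Union[str, Path], format: str = "json") -> None:
    """Write a validated cohort to ``path`` in the given format ("json"/"csv").

    Output is deterministic: serializing the same records twice yields
    byte-identical files, and ``read_cohort`` reproduces the records exactly.
    """
    _check_unique_ids(records)
    path = Path(path)
    if format == "json":
        path.write_bytes(cohort_to_json_bytes(records))
    elif format == "csv":
        path.write_text(_cohort_to_csv_text(records), encoding="utf-8")
    else:
        raise ValueError(f"unknown format {format!r}")


def _validation_error_message(err: ValidationError, patient_id: Optional[str]) -> CohortValidationError:
    first = err.errors()[0]
    field = ".".join(str(p) for p in first["loc"])
    return CohortValidationError(
        f"invalid record (patient_id={patient_id!r}): {field}: {first['msg']}",
        patient_id=patient_id,
        field=field,
    )


def read_cohort(path: Union[str, Path], format: Optional[str] = None) -> list[PatientRecord]:
    """Read and validate a cohort file; row order is preserved.

    ``format`` defaults from the file suffix.  Schema violations raise
    :class:`CohortValidationError` naming the offending patient and field.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "json"
    records: list[PatientRecord] = []
    if format == "json":
        try:
            payload = json.loads(path.read_text(encoding="utf-8"))
        except json.JSONDecodeError as e:
            raise CohortValidationError(f"not valid JSON: {e}") from e
        if not isinstance(payload, list):
            raise CohortValidationError("cohort JSON must be a top-level array of records")
        for item in payload:
            pid = item.get("patient_id") if isinstance(item, dict) else None
            try:
                records.append(PatientRecord.model_validate(item))
            except ValidationError as e:
                raise _validation_error_message(e, pid) from e
    elif format == "csv":
        with path.open(newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                pid = row.get("patient_id")
                try:
                    records.append(_row_to_record(row))
                except ValidationError as e:
                    raise _validation_error_message(e, pid) from e
                except (KeyError, ValueError) as e:
                    raise CohortValidationError(
                        f"malformed CSV row (patient_id={pid!r}): {e}", patient_id=pid
                    ) from e
    else:
        raise ValueError(f"unknown format {format!r}")
    _check_unique_ids(records)
    return records


def cohort_json_schema() -> dict:
    """JSON schema of the cohort interchange format (array of PatientRecord)."""
    return {
        "$schema": "https://json-schema.org/draft/2020-12/schema",
        "title": "sarcphen cohort",
        "type": "array",
        "items": PatientRecord.model_json_schema(),
    }
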