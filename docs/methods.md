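# Methods

## Case definition

The pipeline operates on code-captured patients: anyone with at least one
inpatient or outpatient claim carrying a sarcoidosis diagnostic code.
Matching is deliberately conservative for ICD-9: a claim qualifies only if
the code is exactly `135` or begins with `135.`, so unrelated ICD-10 codes
that merely start with the digits 135 are never captured; ICD-10 matching is
a case-insensitive `D86` prefix (all subcodes). The *version of first
capture* orders qualifying claims by date; undated claims sort first, and
ICD-9 wins ties — the only ordering consistent with a records era that
begins before ICD-10 adoption. In the fixture each patient carries a single
claim, so the attribute is effectively patient-level.

The **index of suspicion** is high iff at least one supportive clinical or
radiological feature is present. The feature vocabulary merges list items
joined by "or" into single flags (e.g. optic neuritis/scleritis/uveitis/
retinitis → `ocular_inflammation`), because the rule is presence-of-any and
finer granularity changes no downstream decision. The index never reads
biopsies: a granuloma-positive biopsy without supportive features leaves
the patient *low index* and therefore *unlikely* — the histopathology axis
and the chart-review axis of the validation table stay independent by
construction.

**Organ involvement** is assessed per organ as: a granuloma-positive biopsy
at a qualifying site (lung/mediastinal node → lung; skin → skin;
conjunctiva/sclera → eye; heart/pericardium → cardiac; liver/spleen →
liver-spleen; brain/dura/nerve → neuro; ear-nose-throat → ENT), OR any of
the organ's clinical/radiological criteria. Respiratory symptoms raise
suspicion but are not an organ criterion. Two simplifications are
deliberate: an "abnormal liver enzymes"-only presentation must be encoded
through the liver/spleen imaging or exam flags to count toward that organ
(no laboratory-only flag exists in the vocabulary), and cardiomyopathy
response to treatment is not modelled as a separate attribute from the
cardiac-manifestation flag. *Multi-organ* means ≥3 involved organs (the
≥5-organ convention used elsewhere would leave such a cohort empty).

**Scadding staging** from imaging findings: no report → missing; end-stage
fibrosis → IV (dominant over coexisting findings, since stage IV denotes
end-stage disease); nodal enlargement + parenchymal disease → II;
parenchymal only → III; nodal only → I; normal film → 0. A report that is
available but records neither a finding nor a normal film is an
inconsistent record and raises an error rather than guessing.

**PFT pattern**: obstruction iff FEV1/FVC < its lower limit of normal
(LLN); restriction iff TLC < LLN, falling back to FVC < LLN when lung
volumes were not measured; both → mixed, neither → normal. LLNs are inputs
on each record (as produced by the reference equations of the originating
lab); the package does not compute reference values. An isolated low DLCO
classifies as *normal* for the four-level pattern — the reported pattern
taxonomy has no DLCO-only category — and is surfaced as a separate
`low_dlco` boolean.

**Phenotype groups** (non-exclusive; a patient may belong to several):
1 multi-organ; 2 nonacute stage I never treated; 3 nonacute stage II–III
treated; 4 nonacute stage II–III never treated; 5 nonacute stage IV
treated; 6 nonacute stage IV never treated; 7 acute (Löfgren); 8 remitting
(>1 year without active disease); 9 cardiac manifestations, treated.
"Treated" for groups 3/5/9 is implemented as *ever treated* (a superset of
"treated within 3 months of review"). The remitting group's "untreated" is
implemented as *not treated within the last 3 months*: a formerly treated
patient whose disease has been quiescent for over a year is still
remitting, whereas recent treatment contradicts quiescence. Groups are
undefined for unlikely cases.

## Validation statistics

PPV and sensitivity are binomial proportions (verified/flagged and
detected/condition) with exact Clopper–Pearson intervals via the
beta-quantile formulation; at x = n the lower bound is `(α/2)^(1/n)`.
The intervals reported are always the exact ones recomputed from the
counts. Specificity and likelihood ratios raise `NotEstimableError`: a
design that reviews only code-positive patients observes no true
negatives.

The chi-square test is Pearson's without continuity correction by default
(`yates=True` available). The Fisher exact test handles r×c tables by full
enumeration of margin-preserving tables, summing multivariate
hypergeometric probabilities of tables no more probable than the observed
one (point-probability rule, the dominant two-sided convention);
probabilities are compared in log space with a 1e-7 relative tie tolerance.
Enumeration is limited to totals ≤500 and dimensions ≤6×6; beyond that a
seeded Monte-Carlo mode samples margin-preserving tables (add-one
corrected, so p > 0). Welch's t with Satterthwaite df is provided for
summary-statistic comparisons of means.

## The fixture cohort

The fixture encodes the adjudicated structure of a 200-patient two-center
validation cohort: 42 low-index patients (no flags, no biopsies), 16
high-index patients without any biopsy, and 142 high-index patients each
carrying one granuloma-positive biopsy. Only raw fields are stored;
every count below is re-derived by the pipeline at run time, and the
builder hard-fails if a contractual marginal is violated.

The published marginals constrain but do not determine the joint
distribution of attributes; the builder fixes one concrete joint assignment
chosen to satisfy all of them simultaneously:

* all 129 confirmed and 14 probable patients with pulmonary involvement
  carry the PFT and Scadding distributions; the 15 non-pulmonary sarcoid
  patients have no PFT and no imaging report (their stage and pattern are
  *missing*), which reconciles the per-column missing counts exactly;
* the four pulmonary-and-cardiac patients sit in the stage-II treated
  stratum and, with the two cardiac-without-pulmonary patients, are exactly
  the treated cardiac group (group 9 = 6);
* remitting patients are the 22 confirmed stage-0 + 8 non-pulmonary
  untreated patients (group 8 = 30) and the 5 probable stage-0 patients;
* ages are a deterministic two-point construction `mean ± sd·√((n−1)/n)`,
  giving exact sample mean and SD (65.5 ± 10.8 for confirmed,
  69.3 ± 10.3 for probable);
* the 100/100 site split is enforced but carries no classification
  consequence.

One documented inconsistency exists in the published table the fixture
emulates: the stage II–III column counts (62 confirmed) exceed the sum of
the treated/untreated stage II–III groups (42+14), and the stage IV
probable column (0) contradicts a nonzero stage-IV-untreated probable
count. Because groups 3/4 (and 5/6) partition the nonacute stage II–III
(stage IV) patients by treatment, no assignment can satisfy both rows and
the stage column. The fixture matches the stage distribution and groups 3
and 5 exactly; the derived group-4 and group-6 counts (20/3 and 5/0) are
pinned in the manifest as determinism checks, separate from the contractual
marginals. The shipped manifest also records a sha256 of the canonical
JSON serialization; two builds are byte-identical.

## The simulator

`simulate_cohort` draws records i.i.d.: each feature is Bernoulli at its
specified prevalence, biopsy availability is Bernoulli conditional on a
high index, and the biopsy result is granulomatous with probability
`granuloma_given_biopsy`. Defaults mirror the fixture cohort's observed
rates (biopsy in ~90% of high-index patients, granuloma in ~95% of
biopsies, ICD-9 fraction 0.68, 90% male, majority African American).
Ancillary fields (PFT, imaging, course, age) are filled with simple
consistent values so that simulated records exercise the full pipeline.
The generator is seeded (`numpy.random.default_rng`) and byte-reproducible.

What the simulator does **not** emulate: feature correlation (real
supportive features co-occur strongly), longitudinal claim structure,
missing-not-at-random documentation, inter-site differences, or free-text
provenance. Tests that pass on simulated cohorts therefore validate the
rule engine's logic and the estimators' calibration, not the real-world
accuracy of code capture, which can only come from chart review.

## Numerical and design notes

* Proportions are exact rationals of integer counts; CIs use scipy's beta
  quantiles (absolute agreement to 1e-9 with tail-bisection inversion is
  tested for all n ≤ 50).
* Fisher p-values are compared against an exact rational-arithmetic
  enumeration oracle to 1e-12 in tests (every 2×2 with total ≤14 plus
  seeded larger tables; the space of all 3×3 tables with total ≤20 is too
  large to sweep exhaustively in routine test runs).
* CSV serialization encodes set fields as semicolon-joined, lexically
  sorted tokens and floats via `repr`, making output byte-stable and
  round-trip exact; dates are optional everywhere and no rule consumes
  them beyond first-claim ordering.
* Report percentages use round-half-even at one decimal; report floats are
  fixed to four decimals for cross-platform byte stability.

## Limitations

The rule set operationalizes only the structured-data portion of guideline
diagnosis: it cannot perform the exclusion-of-alternatives step, which
requires clinical judgment over free text, and it treats documented
features as true (no documentation-error model). The fixture reproduces
published *marginals*; joint associations between its attributes beyond
those listed above are one admissible choice, not data.
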