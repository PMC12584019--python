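"""Published cutoff-performance tables from the derivation cohort.

The staging defaults in this package were derived on an inpatient
rehabilitation cohort of 270 adults (tertiary unit, admissions 2021–2024)
whose patient-level data are not deposited; what is public are the
cutoff-performance tables — for each stepwise comparison the selected cutoff
and its TP/FP/TN/FN cells — overall and stratified by sex, age band and
diagnosis. Those cells are reproduced here as plain tuples
``(cutoff, tp, fp, tn, fn)``, highest comparison first, so that

* metric arithmetic (Se/Sp/Acc/Youden) can be recomputed from the raw cells,
* :func:`clinstage.simulate.cohort_from_confusion_fixture` can rebuild exact
  fixture cohorts reproducing every cell.

Note the ``other`` diagnosis table: its two rows do not satisfy the
remaining-sample identity (the second step's cells total 36, not the 41 that
excluding the first step's predicted positives would leave). That table came
from a manually substituted pair of thresholds rather than the plain
sequential procedure, so the fixture builder rejects it by design; its cells
remain usable for per-row metric arithmetic.
"""

from __future__ import annotations

from .simulate import ConfusionFixtureSpec

#: Overall cohort (n = 270): high-vs-moderate at 192, moderate-vs-light at 135.
OVERALL_STEPS = ((192, 12, 93, 162, 3), (135, 19, 63, 79, 4))

#: Retained cutoffs and the resulting stage counts in the derivation cohort.
OVERALL_CUTOFFS = (135, 192)
OVERALL_STAGE_COUNTS = {"light": 83, "moderate": 82, "high": 105}

#: Sex strata (male n = 146, female n = 124).
SEX_STEPS = {
    "male": ((232, 4, 12, 126, 4), (156, 18, 48, 59, 5)),
    "female": ((175, 7, 55, 62, 0), (134, 6, 22, 34, 0)),
}

#: Age strata at the 65-year boundary (< 65 n = 136, >= 65 n = 134).
AGE_STEPS = {
    "<65": ((232, 4, 13, 119, 0), (173, 16, 27, 69, 7)),
    ">=65": ((175, 9, 60, 63, 2), (157, 5, 9, 48, 3)),
}

#: Diagnosis strata. "other" reflects a manual threshold substitution and is
#: internally inconsistent as a sequential table (see module docstring).
DIAGNOSIS_STEPS = {
    "stroke": ((175, 9, 42, 38, 0), (162, 2, 3, 33, 0)),
    "msk": ((261, 1, 0, 55, 1), (173, 13, 11, 27, 5)),
    "cancer": ((241, 2, 4, 57, 0), (134, 5, 33, 19, 0)),
    "other": ((193, 1, 19, 40, 1), (128, 12, 10, 10, 4)),
}


def overall_fixture_spec() -> ConfusionFixtureSpec:
    """Fixture spec for the overall derivation table (builds a 270-patient cohort)."""
    return ConfusionFixtureSpec.from_rows(OVERALL_STEPS)


def sex_fixture_spec(sex: str) -> ConfusionFixtureSpec:
    return ConfusionFixtureSpec.from_rows(SEX_STEPS[sex])


def age_fixture_spec(band: str) -> ConfusionFixtureSpec:
    return ConfusionFixtureSpec.from_rows(AGE_STEPS[band])


def diagnosis_fixture_spec(diagnosis: str) -> ConfusionFixtureSpec:
    """Raises FixtureError for ``other`` (inconsistent sequential table)."""
    return ConfusionFixtureSpec.from_rows(DIAGNOSIS_STEPS[diagnosis])
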