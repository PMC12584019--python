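"""Synthetic cohorts with the statistical structure the staging analysis assumes.

Two generators live here:

* :func:`simulate_cohort` draws cohorts whose marginals match the derivation
  study's inpatient rehabilitation population (n = 270, admission ClinFIT
  165.3 ± 59.4, discharge 97.5 ± 57.8, 54.1% male, age 62.9 ± 14.3, diagnosis
  mix stroke/MSK/cancer/other = 33.0/21.1/23.3/22.6%) and whose TD level is a
  noisy step function of the admission score with *plantable* thresholds —
  so cutoff-recovery experiments have a known ground truth.
* :func:`cohort_from_confusion_fixture` builds an exact cohort that, when the
  stepwise procedure is run with the given cutoffs forced, reproduces every
  TP/FP/TN/FN cell of a published cutoff-performance table cell-for-cell.

The latent-band + symmetric-noise model for the score → TD link is one
admissible choice; the within-level score distributions of real referral data
are unknown, and docs/methods.md discusses what this does and does not
emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import DIAGNOSES, SCORE_MAX, SCORE_MIN, Cohort
from .errors import FixtureError, ParameterError

__all__ = [
    "SimulationParams",
    "simulate_cohort",
    "FixtureStep",
    "ConfusionFixtureSpec",
    "cohort_from_confusion_fixture",
]


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the cohort generator; defaults are the study conditions.

    ``td_thresholds`` are the planted ascending score thresholds
    ``t1 < t2 < t3``: a patient's latent TD level is the number of thresholds
    at or below their admission score. The defaults (141, 198, 260) are the
    quantiles of the admission-score normal at the study's cumulative TD
    proportions (34.4 / 70.7 / 94.4%), so the simulated TD marginals land on
    the study's 34.4/36.3/23.7/5.6% split. ``td_noise`` is the probability
    the observed level is perturbed by ±1 (direction equiprobable, clipped to
    0–3).
    """

    n: int = 270
    admission_mean: float = 165.3
    admission_sd: float = 59.4
    discharge_mean_improvement: float = 67.8
    improvement_sd: float = 57.5
    td_thresholds: tuple[int, int, int] = (141, 198, 260)
    td_noise: float = 0.1
    sex_male_prop: float = 0.541
    age_mean: float = 62.9
    age_sd: float = 14.3
    diagnosis_props: Mapping[str, float] = field(
        default_factory=lambda: {
            "stroke": 0.330,
            "msk": 0.211,
            "cancer": 0.233,
            "other": 0.226,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        t = self.td_thresholds
        if len(t) != 3 or not (SCORE_MIN <= t[0] < t[1] < t[2] <= SCORE_MAX):
            raise ParameterError(
                f"td_thresholds must be ascending within [{SCORE_MIN}, {SCORE_MAX}], got {t}"
            )
        if not 0.0 <= self.td_noise <= 0.5:
            raise ParameterError("td_noise must lie in [0, 0.5]")
        if self.n < 1:
            raise ParameterError("n must be >= 1")
        if not 0.0 <= self.sex_male_prop <= 1.0:
            raise ParameterError("sex_male_prop must lie in [0, 1]")
        if set(self.diagnosis_props) != set(DIAGNOSES):
            raise ParameterError(f"diagnosis_props must cover exactly {DIAGNOSES}")
        if abs(sum(self.diagnosis_props.values()) - 1.0) > 1e-9:
            raise ParameterError("diagnosis_props must sum to 1")
        if self.admission_sd <= 0 or self.improvement_sd < 0 or self.age_sd <= 0:
            raise ParameterError("scale parameters must be positive")


def latent_td_level(scores, thresholds: Sequence[int]) -> np.ndarray:
    """Number of planted thresholds at or below each score (0–3)."""
    s = np.asarray(scores)
    t = np.asarray(thresholds)
    return (s[:, None] >= t[None, :]).sum(axis=1)


def simulate_cohort(params: SimulationParams | None = None, **overrides) -> Cohort:
    """Draw a fully reproducible synthetic cohort.

    Admission scores are a rounded, clipped normal; the observed TD level is
    the latent band of the score perturbed by ±1 with probability
    ``td_noise``; discharge = admission − improvement draw, clipped to the
    scale; demographics are drawn independently of scores.
    """
    if params is None:
        params = SimulationParams(**overrides)
    elif overrides:
        raise ParameterError("pass either a SimulationParams or keyword overrides, not both")
    rng = np.random.default_rng(params.seed)
    n = params.n

    adm = np.clip(
        np.rint(rng.normal(params.admission_mean, params.admission_sd, n)),
        SCORE_MIN,
        SCORE_MAX,
    ).astype(np.int64)

    td = latent_td_level(adm, params.td_thresholds)
    flip = rng.random(n) < params.td_noise
    direction = rng.choice([-1, 1], size=n)
    td = np.clip(td + flip * direction, 0, 3).astype(np.int64)

    improvement = rng.normal(params.discharge_mean_improvement, params.improvement_sd, n)
    dis = np.clip(np.rint(adm - improvement), SCORE_MIN, SCORE_MAX).astype(np.int64)

    sex = np.where(rng.random(n) < params.sex_male_prop, "male", "female")
    age = np.clip(rng.normal(params.age_mean, params.age_sd, n), 18.0, 105.0)
    diags = list(params.diagnosis_props)
    diagnosis = rng.choice(diags, size=n, p=[params.diagnosis_props[d] for d in diags])

    df = pd.DataFrame(
        {
            "patient_id": [f"S{i:05d}" for i in range(n)],
            "age_years": np.round(age, 1),
            "sex": sex,
            "diagnosis": diagnosis,
            "clinfit_admission": adm,
            "clinfit_discharge": dis,
            "td_level": td,
        }
    )
    return Cohort(df, provenance=f"synthetic seed={params.seed}")


@dataclass(frozen=True)
class FixtureStep:
    """One row of a cutoff-performance table: cutoff plus its four cells."""

    cutoff: int
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ConfusionFixtureSpec:
    """Ordered steps of a stepwise derivation, highest comparison first.

    Invariants: cutoffs strictly decrease across steps, and each step's total
    equals the previous total minus the previous predicted positives
    (tp + fp) — the published tables note that the cells therefore do not sum
    to the full study population. ``top_level`` anchors the dichotomies: step
    k compares ``td >= top_level - k + 1`` against the rest.
    """

    steps: tuple[FixtureStep, ...]
    top_level: int = 3

    def __post_init__(self) -> None:
        if not self.steps:
            raise FixtureError("fixture needs at least one step")
        if len(self.steps) > self.top_level:
            raise FixtureError(
                f"{len(self.steps)} steps need top_level >= {len(self.steps)}"
            )
        for st in self.steps:
            if min(st.tp, st.fp, st.tn, st.fn) < 0:
                raise FixtureError(f"negative cell in step at cutoff {st.cutoff}")
            if not SCORE_MIN < st.cutoff <= SCORE_MAX:
                raise FixtureError(f"cutoff {st.cutoff} outside ({SCORE_MIN}, {SCORE_MAX}]")
        for a, b in zip(self.steps, self.steps[1:]):
            if b.cutoff >= a.cutoff:
                raise FixtureError(
                    f"cutoffs must strictly decrease: {a.cutoff} then {b.cutoff}"
                )
            expected = a.total - (a.tp + a.fp)
            if b.total != expected:
                raise FixtureError(
                    f"remaining-sample identity violated at cutoff {b.cutoff}: "
                    f"step total {b.total} != previous total {a.total} - "
                    f"previous predicted positives {a.tp + a.fp} = {expected}"
                )
            if a.fn > b.tp + b.fn:
                raise FixtureError(
                    f"carried false negatives ({a.fn}) exceed the next step's "
                    f"positives ({b.tp + b.fn}) at cutoff {b.cutoff}"
                )

    @classmethod
    def from_rows(
        cls, rows: Sequence[Sequence[int]], top_level: int = 3
    ) -> "ConfusionFixtureSpec":
        """Rows of ``(cutoff, tp, fp, tn, fn)``, highest comparison first."""
        return cls(tuple(FixtureStep(*map(int, r)) for r in rows), top_level=top_level)


def cohort_from_confusion_fixture(
    spec: ConfusionFixtureSpec,
    sex: str = "male",
    age_years: float = 60.0,
    diagnosis: str = "other",
    id_prefix: str = "F",
) -> Cohort:
    """Build a cohort reproducing every cell of ``spec`` exactly.

    Construction: step k's predicted positives get scores mid-band between
    the step's cutoff and the previous one; predicted negatives materialize
    at the step where they are finally resolved. TD labels are minimal —
    positives at the dichotomy's upper level, negatives one level below —
    except for false negatives carried from earlier steps, which keep their
    higher level so each step's cells come out exactly. Demographics are
    constant fill values (overridable) so subgroup fixtures can be stacked.
    """
    steps = spec.steps
    K = len(steps)
    upper = [spec.top_level - k for k in range(K)]  # dichotomy level per step

    rows: list[tuple[int, int]] = []  # (score, td)
    carried: list[int] = []  # td labels of false negatives carried forward
    for k, st in enumerate(steps):
        band_hi = steps[k - 1].cutoff if k > 0 else SCORE_MAX + 1
        pos_score = st.cutoff + (band_hi - st.cutoff) // 2
        # predicted positives, resolved (excluded) at this step
        tp_carried = carried[: st.tp]
        n_fresh_tp = st.tp - len(tp_carried)
        carried = carried[st.tp :]
        rows += [(pos_score, td) for td in tp_carried]
        rows += [(pos_score, upper[k])] * n_fresh_tp
        rows += [(pos_score, upper[k] - 1)] * st.fp
        # false negatives: carried ones keep their level, fresh ones get this
        # step's upper level; all carry forward as positives of later steps
        n_fresh_fn = st.fn - len(carried)
        if n_fresh_fn < 0:  # cannot happen for a valid spec
            raise FixtureError(f"inconsistent carry at cutoff {st.cutoff}")
        carried = carried + [upper[k]] * n_fresh_fn
    # final remainder: last step's TN and FN, scores below the last cutoff
    last = steps[-1]
    neg_score = last.cutoff // 2
    rows += [(neg_score, td) for td in carried]  # the FN of the last step
    rows += [(neg_score, upper[-1] - 1)] * last.tn

    df = pd.DataFrame(
        {
            "patient_id": [f"{id_prefix}{i:05d}" for i in range(len(rows))],
            "age_years": float(age_years),
            "sex": sex,
            "diagnosis": diagnosis,
            "clinfit_admission": [r[0] for r in rows],
            "clinfit_discharge": pd.array([pd.NA] * len(rows), dtype="Int64"),
            "td_level": [r[1] for r in rows],
        }
    )
    return Cohort(df, provenance=f"confusion fixture ({K} steps)")
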