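"""Stratified re-derivation of staging models and cross-stratum collation.

Subgroups are analysed marginally, one factor at a time (sex; age below /
at-or-above a boundary, default 65; diagnosis group), each stratum running
the identical stepwise procedure with the same retention criteria. Strata
too sparse for any comparison yield 1-stage models with warnings rather than
failures. Crossed strata (e.g. older male stroke) are deliberately not
supported: crossing explodes sparsity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import DIAGNOSES, SEXES, Cohort
from .errors import PlanError
from .staging import RetentionCriteria, StagingResults, run_stepwise

__all__ = [
    "StratificationPlan",
    "SubgroupResult",
    "run_subgroups",
    "collate_cutoffs",
]

SUPPORTED_FACTORS = ("sex", "age", "diagnosis")


@dataclass(frozen=True)
class StratificationPlan:
    """Which factors to stratify by, and where the age boundary sits."""

    factors: tuple[str, ...] = SUPPORTED_FACTORS
    age_boundary: float = 65.0

    def __post_init__(self) -> None:
        if not self.factors:
            raise PlanError("factors must be non-empty")
        unknown = set(self.factors) - set(SUPPORTED_FACTORS)
        if unknown:
            raise PlanError(
                f"unsupported factors {sorted(unknown)}; choose from {SUPPORTED_FACTORS}"
            )

    def strata(self, cohort: Cohort) -> dict[str, np.ndarray]:
        """Boolean masks keyed by ``factor:level`` labels."""
        df = cohort.df
        out: dict[str, np.ndarray] = {}
        for factor in self.factors:
            if factor == "sex":
                for lv in SEXES:
                    out[f"sex:{lv}"] = (df["sex"] == lv).to_numpy()
            elif factor == "age":
                b = self.age_boundary
                out[f"age:<{b:g}"] = (df["age_years"] < b).to_numpy()
                out[f"age:>={b:g}"] = (df["age_years"] >= b).to_numpy()
            elif factor == "diagnosis":
                for lv in DIAGNOSES:
                    out[f"diagnosis:{lv}"] = (df["diagnosis"] == lv).to_numpy()
        return out


@dataclass(frozen=True)
class SubgroupResult:
    """One stratum's staging model plus its audit."""

    label: str
    n: int
    results: StagingResults | None  # None when the stratum is empty

    @property
    def warnings(self) -> tuple[str, ...]:
        return self.results.warnings if self.results else ("empty stratum",)


def run_subgroups(
    cohort: Cohort,
    plan: StratificationPlan | None = None,
    criteria: RetentionCriteria | None = None,
    include_overall: bool = False,
    overrides: Mapping[str, Mapping[int, int]] | None = None,
    **fit_kwargs,
) -> dict[str, SubgroupResult]:
    """Apply the stepwise procedure independently within each stratum.

    ``overrides`` maps stratum labels to ``{upper_level: forced_cutoff}``
    manual overrides (e.g. reproducing a hand-substituted threshold); they
    are passed to the fit and flagged in each audit, never applied silently.
    """
    plan = plan or StratificationPlan()
    overrides = overrides or {}
    results: dict[str, SubgroupResult] = {}
    masks = plan.strata(cohort)
    if include_overall:
        masks = {"overall": np.ones(len(cohort), dtype=bool), **masks}
    for label, mask in masks.items():
        n = int(mask.sum())
        if n == 0:
            results[label] = SubgroupResult(label, 0, None)
            continue
        sub = cohort.subset(mask, provenance=f"{cohort.provenance} [{label}]")
        forced = overrides.get(label)
        try:
            res = run_stepwise(
                sub, criteria=criteria, forced_cutoffs=forced, **fit_kwargs
            )
        except Exception as exc:  # degenerate stratum (e.g. single TD level)
            results[label] = SubgroupResult(label, n, _one_stage(sub, criteria, str(exc)))
            continue
        results[label] = SubgroupResult(label, n, res)
    return results


def _one_stage(cohort, criteria, reason: str) -> StagingResults:
    from .staging import FunctionalStaging

    model = FunctionalStaging.from_cohort(cohort)
    return StagingResults(
        model=model,
        cutoffs=(),
        stage_names=("all",),
        audit=(),
        criteria=criteria or RetentionCriteria(),
        n=len(cohort),
        warnings=(f"no staging possible: {reason}",),
    )


def collate_cutoffs(results: Mapping[str, SubgroupResult]) -> pd.DataFrame:
    """Cross-stratum comparison table: one row per stratum × retained cutoff.

    Strata with no retained cutoff appear once with missing cutoff columns
    and a warning marker, so the table always covers every stratum. Dropped
    or skipped candidates are available via :func:`audit_table`.
    """
    if not results:
        raise PlanError("no subgroup results to collate")
    rows = []
    for label, sr in results.items():
        if sr.results is None or not sr.results.cutoffs:
            rows.append(
                {
                    "stratum": label,
                    "n": sr.n,
                    "cutoff": pd.NA,
                    "auc": pd.NA,
                    "sensitivity": pd.NA,
                    "specificity": pd.NA,
                    "warning": "; ".join(sr.warnings) or "no retained cutoffs",
                }
            )
            continue
        retained = sorted(
            (r for r in sr.results.audit if r.retained and r.metrics),
            key=lambda r: r.metrics.cutoff,
        )
        for r in retained:
            rows.append(
                {
                    "stratum": label,
                    "n": sr.n,
                    "cutoff": r.metrics.cutoff,
                    "auc": r.metrics.auc,
                    "sensitivity": r.metrics.sensitivity,
                    "specificity": r.metrics.specificity,
                    "warning": "exploratory" if r.exploratory else "",
                }
            )
    return pd.DataFrame(rows)


def audit_table(results: Mapping[str, SubgroupResult]) -> pd.DataFrame:
    """Long-format audit of every comparison in every stratum."""
    rows = []
    for label, sr in results.items():
        if sr.results is None:
            continue
        for step in sr.results.to_dict()["steps"]:
            rows.append({"stratum": label, **step})
    return pd.DataFrame(rows)
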