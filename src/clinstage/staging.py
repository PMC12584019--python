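"""Stepwise ROC-based functional staging.

The procedure derives ordered score cutoffs that partition the ClinFIT scale
into rehabilitation-intensity stages, using the ordinal Therapy Disciplines
(TD) level as the reference:

1. Starting from the highest TD level ``L`` present, dichotomize the current
   sample cumulatively (positives = ``td >= L``) and find the Youden-optimal
   integer cutoff for predicting the positive class from the admission score.
2. Exclude the predicted positives (``score >= cutoff``) and repeat for the
   next level down, until the comparison against ``L = 1`` has run.
3. Apply retention rules: drop candidates with AUC below ``min_auc`` or a
   Youden index below ``min_youden``; then, while any adjacent pair of
   surviving cutoffs is closer than ``min_separation`` score points, drop the
   member with the lower Youden index and re-check.

The retained cutoffs ``c1 < c2 < ... < cK`` define ``K + 1`` stages, bands
``[0, c1), [c1, c2), ..., [cK, 300]`` — a score belongs to the stage indexed
by the number of cutoffs at or below it.

API shape follows the model/results idiom: :class:`FunctionalStaging` holds
the data, its :meth:`~FunctionalStaging.fit` returns a
:class:`StagingResults` carrying retained cutoffs, the full per-step audit
(including dropped and skipped comparisons), stage assignment and a
``summary()`` table. ``run_stepwise`` is the one-call convenience wrapper.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._round import round_half_up
from .cohort import SCORE_MAX, SCORE_MIN, Cohort
from .errors import ParameterError, StagingError
from .roc import (
    ConfusionMatrix,
    CutoffMetrics,
    auc,
    confusion_at_cutoff,
    metrics_from_confusion,
    optimal_cutoff_youden,
)

__all__ = [
    "RetentionCriteria",
    "CutoffResult",
    "FunctionalStaging",
    "StagingResults",
    "run_stepwise",
    "assign_stage",
    "stage_distribution",
]

#: Names for the cumulative dichotomies, keyed by the upper TD level.
_COMPARISON_NAMES = {
    3: "high vs moderate",
    2: "moderate vs light",
    1: "light vs none",
}

#: Canonical stage-name sets by number of stages.
_STAGE_NAMES = {
    1: ("all",),
    2: ("light", "high"),
    3: ("light", "moderate", "high"),
    4: ("light", "moderate", "high", "very-high"),
}

#: Steps whose positive class is smaller than this are flagged exploratory
#: in reports (they still run; small high-intensity groups are expected).
EXPLORATORY_POSITIVE_MIN = 10


@dataclass(frozen=True)
class RetentionCriteria:
    """Rules deciding which candidate cutoffs survive.

    Defaults: adjacent cutoffs must be at least 5% of the 0–300 scale apart
    (15 points), and a candidate needs AUC >= 0.6 and Youden >= 0.3.
    """

    min_separation: int = 15
    min_auc: float = 0.6
    min_youden: float = 0.3

    def __post_init__(self) -> None:
        if self.min_separation < 0:
            raise ParameterError("min_separation must be >= 0")
        if not 0.5 <= self.min_auc <= 1.0:
            raise ParameterError("min_auc must lie in [0.5, 1]")
        if not 0.0 <= self.min_youden <= 1.0:
            raise ParameterError("min_youden must lie in [0, 1]")


@dataclass(frozen=True)
class CutoffResult:
    """Audit entry for one executed (or skipped) comparison step."""

    comparison_label: str
    upper_level: int
    n_remaining: int
    metrics: CutoffMetrics | None = None
    confusion: ConfusionMatrix | None = None
    retained: bool = False
    reason: str = ""
    forced: bool = False
    exploratory: bool = False

    @property
    def skipped(self) -> bool:
        return self.metrics is None


def _stage_names(n_stages: int) -> tuple[str, ...]:
    if n_stages in _STAGE_NAMES:
        return _STAGE_NAMES[n_stages]
    return tuple(f"stage-{i}" for i in range(n_stages))


class FunctionalStaging:
    """Model object: admission scores paired with ordinal TD levels."""

    def __init__(self, scores, td_levels) -> None:
        s = np.asarray(scores, dtype=np.int64)
        td = np.asarray(td_levels, dtype=np.int64)
        if s.shape != td.shape or s.ndim != 1:
            raise StagingError("scores and td_levels must be 1-d and equal length")
        if s.size == 0:
            raise StagingError("empty cohort")
        if s.min() < SCORE_MIN or s.max() > SCORE_MAX:
            raise StagingError(f"scores outside [{SCORE_MIN}, {SCORE_MAX}]")
        self.scores = s
        self.td = td

    @classmethod
    def from_cohort(cls, cohort: Cohort) -> "FunctionalStaging":
        return cls(cohort.admission_scores, cohort.td_levels)

    def fit(
        self,
        criteria: RetentionCriteria | None = None,
        min_class_size: int = 2,
        forced_cutoffs: Mapping[int, int] | None = None,
        excluded_candidates: Mapping[int, Sequence[int]] | None = None,
        refit_after_drop: bool = False,
    ) -> "StagingResults":
        """Run the stepwise derivation and retention rules.

        Parameters
        ----------
        criteria
            Retention/merge thresholds; defaults to
            ``RetentionCriteria(15, 0.6, 0.3)``.
        min_class_size
            A comparison is skipped (with a warning in the audit) when either
            class has fewer members. Default 2: subgroup steps with as few as
            2 positives must still run.
        forced_cutoffs
            Optional ``{upper_level: cutoff}`` manual overrides; the forced
            value replaces the Youden search at that step and is flagged in
            the audit. Never applied silently.
        excluded_candidates
            Optional ``{upper_level: [cutoff, ...]}`` values removed from the
            search at that step (audited manual exclusions).
        refit_after_drop
            Off by default: a provisionally retained cutoff still causes
            exclusion for subsequent steps even if the retention filter later
            drops it, mirroring the strictly sequential derivation. When on,
            the sequential pass is re-run with dropped comparisons disabled
            until the retained set is stable.
        """
        criteria = criteria or RetentionCriteria()
        if min_class_size < 1:
            raise ParameterError("min_class_size must be >= 1")
        forced_cutoffs = dict(forced_cutoffs or {})
        excluded = {k: frozenset(v) for k, v in (excluded_candidates or {}).items()}
        if len(np.unique(self.td)) < 2:
            raise StagingError("need at least 2 distinct TD levels to derive cutoffs")

        disabled: set[int] = set()
        while True:
            audit = self._sequential_pass(
                criteria, min_class_size, forced_cutoffs, excluded, disabled
            )
            audit, newly_dropped = self._apply_retention(audit, criteria)
            if not refit_after_drop or not newly_dropped:
                break
            disabled |= newly_dropped

        cutoffs = tuple(
            sorted(r.metrics.cutoff for r in audit if r.retained and r.metrics)
        )
        warnings_list: list[str] = [
            f"{r.comparison_label}: {r.reason}" for r in audit if r.reason
        ]
        if not cutoffs:
            msg = "no cutoff survived the retention rules; returning a 1-stage model"
            warnings.warn(msg, UserWarning, stacklevel=2)
            warnings_list.append(msg)
        return StagingResults(
            model=self,
            cutoffs=cutoffs,
            stage_names=_stage_names(len(cutoffs) + 1),
            audit=tuple(audit),
            criteria=criteria,
            n=int(self.scores.size),
            warnings=tuple(warnings_list),
        )

    # -- internals ---------------------------------------------------------
    def _sequential_pass(
        self, criteria, min_class_size, forced_cutoffs, excluded, disabled
    ) -> list[CutoffResult]:
        remaining = np.ones(self.scores.size, dtype=bool)
        audit: list[CutoffResult] = []
        top = int(self.td.max())
        for level in range(top, 0, -1):
            label = _COMPARISON_NAMES.get(level, f"level {level} vs below")
            if level in disabled:
                audit.append(
                    CutoffResult(label, level, int(remaining.sum()), reason="disabled after drop (refit)")
                )
                continue
            s = self.scores[remaining]
            pos = self.td[remaining] >= level
            n_pos, n_neg = int(pos.sum()), int((~pos).sum())
            if n_pos < min_class_size or n_neg < min_class_size:
                audit.append(
                    CutoffResult(
                        label,
                        level,
                        int(remaining.sum()),
                        reason=(
                            f"skipped: class sizes {n_pos} positive / {n_neg} negative "
                            f"below minimum {min_class_size}"
                        ),
                    )
                )
                continue
            if level in forced_cutoffs:
                c = int(forced_cutoffs[level])
                cm = confusion_at_cutoff(s, pos, c)
                m = metrics_from_confusion(cm)
                metrics = CutoffMetrics(
                    cutoff=c,
                    auc=auc(s, pos),
                    n=int(s.size),
                    **m,
                )
                forced = True
            else:
                metrics = optimal_cutoff_youden(s, pos, excluded.get(level))
                cm = confusion_at_cutoff(s, pos, metrics.cutoff)
                forced = False
            audit.append(
                CutoffResult(
                    label,
                    level,
                    int(remaining.sum()),
                    metrics=metrics,
                    confusion=cm,
                    retained=True,  # provisional; retention filter runs later
                    reason="forced cutoff (manual override)" if forced else "",
                    forced=forced,
                    exploratory=n_pos < EXPLORATORY_POSITIVE_MIN,
                )
            )
            # Exclude predicted positives before the next comparison.
            remaining &= self.scores < metrics.cutoff
        return audit

    @staticmethod
    def _apply_retention(
        audit: list[CutoffResult], criteria: RetentionCriteria
    ) -> tuple[list[CutoffResult], set[int]]:
        dropped_levels: set[int] = set()

        def drop(i: int, reason: str) -> None:
            dropped_levels.add(audit[i].upper_level)
            audit[i] = replace(audit[i], retained=False, reason=reason)

        for i, r in enumerate(audit):
            if not r.retained or r.metrics is None:
                continue
            if r.metrics.auc < criteria.min_auc:
                drop(i, f"dropped: AUC {r.metrics.auc:.3f} < {criteria.min_auc}")
            elif r.metrics.youden < criteria.min_youden:
                drop(i, f"dropped: Youden {r.metrics.youden:.3f} < {criteria.min_youden}")

        # Merge loop: terminates because each iteration removes one cutoff.
        while True:
            kept = sorted(
                (i for i, r in enumerate(audit) if r.retained and r.metrics),
                key=lambda i: audit[i].metrics.cutoff,
            )
            for a, b in zip(kept, kept[1:]):
                gap = audit[b].metrics.cutoff - audit[a].metrics.cutoff
                if gap < criteria.min_separation:
                    weaker = min(a, b, key=lambda i: audit[i].metrics.youden)
                    other = b if weaker == a else a
                    drop(
                        weaker,
                        f"merged: {gap} points from cutoff "
                        f"{audit[other].metrics.cutoff} (< {criteria.min_separation}); "
                        "lower Youden dropped",
                    )
                    break
            else:
                break
        return audit, dropped_levels


@dataclass(frozen=True)
class StagingResults:
    """Fitted staging model: retained cutoffs, stages and the full audit."""

    model: FunctionalStaging
    cutoffs: tuple[int, ...]
    stage_names: tuple[str, ...]
    audit: tuple[CutoffResult, ...]
    criteria: RetentionCriteria
    n: int
    warnings: tuple[str, ...] = ()

    @property
    def n_stages(self) -> int:
        return len(self.cutoffs) + 1

    def assign_stage(self, score: int) -> str:
        """Stage name for one score; bands are ``[0,c1), [c1,c2), ..., [cK,300]``."""
        return self.stage_names[self.stage_index(score)]

    def stage_index(self, score) -> np.ndarray | int:
        s = np.asarray(score, dtype=np.int64)
        if np.any(s < SCORE_MIN) or np.any(s > SCORE_MAX):
            raise StagingError(f"score outside [{SCORE_MIN}, {SCORE_MAX}]")
        idx = np.searchsorted(np.asarray(self.cutoffs), s, side="right")
        return idx if idx.ndim else int(idx)

    def stage_distribution(self, cohort: Cohort | None = None) -> pd.DataFrame:
        """Counts and percentages (1 decimal) per stage; a full partition.

        Defaults to the scores the model was fitted on.
        """
        scores = self.model.scores if cohort is None else cohort.admission_scores
        idx = np.searchsorted(np.asarray(self.cutoffs), scores, side="right")
        counts = np.bincount(idx, minlength=self.n_stages)
        n = scores.size
        return pd.DataFrame(
            {
                "stage": list(self.stage_names),
                "count": counts.astype(int),
                "pct": [round_half_up(100.0 * c / n, 1) for c in counts],
            }
        )

    def to_dict(self) -> dict:
        """JSON-ready audit mirroring the cutoff-performance table layout."""
        steps = []
        for r in self.audit:
            row: dict = {
                "comparison": r.comparison_label,
                "upper_level": r.upper_level,
                "n_remaining": r.n_remaining,
                "retained": r.retained,
                "reason": r.reason,
                "forced": r.forced,
                "exploratory": r.exploratory,
            }
            if r.metrics is not None and r.confusion is not None:
                row.update(
                    cutoff=r.metrics.cutoff,
                    tp=r.confusion.tp,
                    fp=r.confusion.fp,
                    tn=r.confusion.tn,
                    fn=r.confusion.fn,
                    sensitivity=round_half_up(r.metrics.sensitivity, 3),
                    specificity=round_half_up(r.metrics.specificity, 3),
                    accuracy=round_half_up(r.metrics.accuracy, 3),
                    auc=round_half_up(r.metrics.auc, 3),
                    youden=round_half_up(r.metrics.youden, 3),
                )
            steps.append(row)
        dist = self.stage_distribution()
        return {
            "n": self.n,
            "criteria": {
                "min_separation": self.criteria.min_separation,
                "min_auc": self.criteria.min_auc,
                "min_youden": self.criteria.min_youden,
            },
            "cutoffs": list(self.cutoffs),
            "stage_names": list(self.stage_names),
            "steps": steps,
            "stage_distribution": dist.to_dict(orient="records"),
            "warnings": list(self.warnings),
        }

    def summary(self) -> str:
        """Human-readable cutoff-performance and stage-distribution tables."""
        d = self.to_dict()
        lines = [
            f"Stepwise ROC staging (n = {self.n})",
            f"criteria: separation >= {self.criteria.min_separation}, "
            f"AUC >= {self.criteria.min_auc}, Youden >= {self.criteria.min_youden}",
            "",
            f"{'comparison':<22}{'cutoff':>7}{'TP':>5}{'FP':>5}{'TN':>5}{'FN':>5}"
            f"{'Se':>8}{'Sp':>8}{'Acc':>8}{'AUC':>8}{'Youden':>8}  status",
        ]
        for s in d["steps"]:
            if "cutoff" not in s:
                lines.append(f"{s['comparison']:<22}{'—':>7}  {s['reason']}")
                continue
            status = "retained" if s["retained"] else s["reason"]
            if s["forced"]:
                status += " [forced]"
            if s["exploratory"]:
                status += " [exploratory]"
            lines.append(
                f"{s['comparison']:<22}{s['cutoff']:>7}{s['tp']:>5}{s['fp']:>5}"
                f"{s['tn']:>5}{s['fn']:>5}{s['sensitivity']:>8.3f}{s['specificity']:>8.3f}"
                f"{s['accuracy']:>8.3f}{s['auc']:>8.3f}{s['youden']:>8.3f}  {status}"
            )
        lines += ["", "stage distribution:"]
        for row in d["stage_distribution"]:
            lines.append(f"  {row['stage']:<10}{row['count']:>6}  ({row['pct']}%)")
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)

    def plot_stages(self, ax=None):
        """Horizontal score-scale bar segmented at the retained cutoffs."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 1.6))
        bounds = [SCORE_MIN, *self.cutoffs, SCORE_MAX + 1]
        cmap = plt.get_cmap("YlOrRd")
        for i, (lo, hi) in enumerate(zip(bounds, bounds[1:])):
            ax.barh(0, hi - lo, left=lo, color=cmap(0.25 + 0.5 * i / max(1, self.n_stages - 1)))
            ax.text((lo + hi) / 2, 0, self.stage_names[i], ha="center", va="center")
        for c in self.cutoffs:
            ax.axvline(c, color="k", lw=0.8)
        ax.set_xlim(SCORE_MIN, SCORE_MAX + 1)
        ax.set_yticks([])
        ax.set_xlabel("ClinFIT total score at admission")
        return ax


def run_stepwise(
    cohort: Cohort,
    criteria: RetentionCriteria | None = None,
    **fit_kwargs,
) -> StagingResults:
    """Derive a staging model from a cohort in one call."""
    return FunctionalStaging.from_cohort(cohort).fit(criteria=criteria, **fit_kwargs)


def assign_stage(score: int, model: StagingResults) -> str:
    """Stage name for ``score`` under a fitted model."""
    return model.assign_stage(score)


def stage_distribution(cohort: Cohort, model: StagingResults) -> pd.DataFrame:
    """Stage counts/percentages of ``cohort`` under ``model``."""
    return model.stage_distribution(cohort)
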