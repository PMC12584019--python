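"""Pre/post descriptive inference on ClinFIT totals.

A paired t-test on admission vs discharge scores and the paired-design
Cohen's d (``d_z``: mean of the paired differences over the SD of the
differences) with a 95% confidence interval, interpreted against Cohen's
0.2 / 0.5 / 0.8 bands. Differences are oriented admission − discharge, so a
positive value means improvement (higher ClinFIT = worse functioning).

The normal-approximation CI uses ``SE = sqrt(1/n + d^2 / (2n))``; a
noncentral-t interval is available behind ``ci_method="nct"``. Which variant
the field's software uses varies, and both are reported as explicit choices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .cohort import Cohort
from .errors import UndefinedMetricError

__all__ = ["PairedChangeResult", "paired_change", "effect_band"]


def effect_band(d: float) -> str:
    """Cohen's qualitative band for |d|: 0.2 small, 0.5 medium, 0.8 large."""
    a = abs(d)
    if a >= 0.8:
        return "large"
    if a >= 0.5:
        return "medium"
    if a >= 0.2:
        return "small"
    return "negligible"


@dataclass(frozen=True)
class PairedChangeResult:
    n_pairs: int
    n_missing_discharge: int
    mean_admission: float
    mean_discharge: float
    mean_difference: float  # admission - discharge; positive = improvement
    sd_difference: float
    t_statistic: float
    p_value: float
    cohens_d: float
    d_ci_low: float
    d_ci_high: float
    effect_band: str

    def summary(self) -> str:
        p = "< 0.001" if self.p_value < 0.001 else f"= {self.p_value:.3f}"
        return (
            f"Paired change, n = {self.n_pairs} complete pairs "
            f"({self.n_missing_discharge} missing discharge excluded)\n"
            f"admission {self.mean_admission:.1f} -> discharge {self.mean_discharge:.1f}; "
            f"mean improvement {self.mean_difference:.1f} (SD {self.sd_difference:.1f})\n"
            f"paired t = {self.t_statistic:.2f}, p {p}; "
            f"Cohen's d = {self.cohens_d:.2f} "
            f"(95% CI {self.d_ci_low:.2f}-{self.d_ci_high:.2f}), {self.effect_band} effect"
        )


def _nct_ci(t: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Noncentral-t CI for d: invert the noncentrality parameter, divide by sqrt(n)."""
    df = n - 1
    alpha = (1 - level) / 2

    def solve(target: float) -> float:
        f = lambda nc: stats.nct.cdf(t, df, nc) - target
        lo, hi = t - 10 - 10 * abs(t), t + 10 + 10 * abs(t)
        return optimize.brentq(f, lo, hi)

    return solve(1 - alpha) / np.sqrt(n), solve(alpha) / np.sqrt(n)


def paired_change(cohort: Cohort, ci_method: str = "normal") -> PairedChangeResult:
    """Paired t-test and Cohen's d for admission vs discharge scores.

    Patients missing the discharge score are excluded and counted in the
    result. Raises when fewer than 2 complete pairs exist or when the
    differences have zero variance (t undefined).
    """
    df = cohort.df
    complete = df["clinfit_discharge"].notna()
    n_missing = int((~complete).sum())
    adm = df.loc[complete, "clinfit_admission"].to_numpy(dtype=float)
    dis = df.loc[complete, "clinfit_discharge"].to_numpy(dtype=float)
    n = adm.size
    if n < 2:
        raise UndefinedMetricError(f"need >= 2 complete pairs, have {n}")
    diff = adm - dis
    sd = float(np.std(diff, ddof=1))
    if sd == 0.0:
        raise UndefinedMetricError(
            "paired t undefined: all differences identical (SD of differences is 0)"
        )
    t, p = stats.ttest_rel(adm, dis)
    d = float(np.mean(diff)) / sd
    # identity check target: t == d * sqrt(n) for the paired design
    if ci_method == "normal":
        se = np.sqrt(1.0 / n + d * d / (2.0 * n))
        lo, hi = d - 1.96 * se, d + 1.96 * se
    elif ci_method == "nct":
        lo, hi = _nct_ci(float(t), n)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return PairedChangeResult(
        n_pairs=n,
        n_missing_discharge=n_missing,
        mean_admission=float(np.mean(adm)),
        mean_discharge=float(np.mean(dis)),
        mean_difference=float(np.mean(diff)),
        sd_difference=sd,
        t_statistic=float(t),
        p_value=float(p),
        cohens_d=d,
        d_ci_low=float(lo),
        d_ci_high=float(hi),
        effect_band=effect_band(d),
    )
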