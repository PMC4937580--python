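"""Deposition fractions, replicate summaries and group comparisons.

Turns corrected region activities into the headline quantities of a
regional-deposition experiment:

* ET/TH split — extrathoracic vs thoracic percentages of the total
  deposited activity (they sum to 100 by construction),
* exhaled fraction — expiratory-filter activity as a percentage of the
  nebulizer *emitted* activity (note the different denominator; both
  denominators are carried explicitly in reports so the two conventions
  cannot be conflated),
* mass balance — the share of emitted activity unaccounted for after
  summing ET, TH and filter, a QC quantity,
* mean ± SD replicate summaries and a two-sided Welch unequal-variance
  comparison between groups given only summary statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import t as t_dist

from .errors import ValidationError

#: |unaccounted| above this % of emitted is flagged in reports.
MASS_BALANCE_TOLERANCE_PCT = 5.0

__all__ = [
    "DepositionResult",
    "GroupSummary",
    "et_th_split",
    "exhaled_fraction",
    "mass_balance",
    "replicate_summary",
    "compare_groups",
    "MASS_BALANCE_TOLERANCE_PCT",
]


@dataclass(frozen=True)
class DepositionResult:
    """Regional deposition outcome of one run.

    ``et_pct``/``th_pct`` are percentages of the total *deposited*
    activity; ``exhaled_pct_of_emitted`` and ``unaccounted_pct`` are
    percentages of the *emitted* activity.
    """

    et_pct: float
    th_pct: float
    exhaled_pct_of_emitted: float
    emitted_activity: float
    loaded_activity: float
    unaccounted_pct: float = 0.0

    def __post_init__(self):
        if abs(self.et_pct + self.th_pct - 100.0) > 1e-9:
            raise ValidationError("ET% + TH% must equal 100")
        if self.et_pct < 0 or self.th_pct < 0 or self.exhaled_pct_of_emitted < 0:
            raise ValidationError("percentages must be non-negative")

    @property
    def balance_flagged(self) -> bool:
        return abs(self.unaccounted_pct) > MASS_BALANCE_TOLERANCE_PCT

    def to_dict(self) -> dict:
        return {
            "et_pct_of_deposited": self.et_pct,
            "th_pct_of_deposited": self.th_pct,
            "exhaled_pct_of_emitted": self.exhaled_pct_of_emitted,
            "emitted_activity": self.emitted_activity,
            "loaded_activity": self.loaded_activity,
            "unaccounted_pct_of_emitted": self.unaccounted_pct,
            "mass_balance_flagged": self.balance_flagged,
        }


@dataclass(frozen=True)
class GroupSummary:
    """mean ± SD over n replicates of one reported percentage."""

    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        if self.sd < 0:
            raise ValidationError("sd must be >= 0")


def et_th_split(et_activity: float, th_activity: float) -> tuple[float, float]:
    """Extrathoracic and thoracic percentages of total deposited activity."""
    if et_activity < 0 or th_activity < 0:
        raise ValidationError("activities must be non-negative")
    total = et_activity + th_activity
    if total <= 0:
        raise ValidationError("zero total deposition: ET + TH is zero")
    et = 100.0 * et_activity / total
    return et, 100.0 - et


def exhaled_fraction(filter_activity: float, emitted_activity: float) -> float:
    """Expiratory-filter activity as a percentage of the emitted activity."""
    if emitted_activity <= 0:
        raise ValidationError("emitted activity must be positive")
    if filter_activity < 0:
        raise ValidationError("filter activity must be non-negative")
    return 100.0 * filter_activity / emitted_activity


def mass_balance(loaded: float, residual: float, et: float, th: float,
                 filter_activity: float) -> float:
    """Unaccounted share of the emitted activity, in % (signed).

    ``100 · (emitted - ET - TH - filter) / emitted`` with
    ``emitted = loaded - residual``; all terms must be decay-corrected to
    the same reference.  Positive values are circuit losses; small
    negative values are counting noise.
    """
    if loaded <= residual:
        raise ValidationError("loaded activity must exceed the residual")
    emitted = loaded - residual
    return 100.0 * (emitted - et - th - filter_activity) / emitted


def replicate_summary(values: list[float]) -> GroupSummary:
    """Arithmetic mean and sample SD (n-1 denominator) of replicate values."""
    if len(values) == 0:
        raise ValidationError("cannot summarize an empty replicate list")
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size >= 2 else 0.0
    return GroupSummary(mean=float(arr.mean()), sd=sd, n=arr.size)


def compare_groups(a: GroupSummary, b: GroupSummary) -> float:
    """Two-sided Welch unequal-variance p-value from summary statistics.

    Welch's t with Welch–Satterthwaite degrees of freedom, computed from
    (mean, sd, n) alone.  Identical means give p = 1 regardless of SD.
    """
    if a.n < 2 or b.n < 2:
        raise ValidationError("group comparison requires n >= 2 in both groups")
    if a.mean == b.mean:
        return 1.0
    se2_a, se2_b = a.sd ** 2 / a.n, b.sd ** 2 / b.n
    se2 = se2_a + se2_b
    if se2 == 0:
        return 0.0  # different means, zero variance
    t_stat = (a.mean - b.mean) / math.sqrt(se2)
    df = se2 ** 2 / (se2_a ** 2 / (a.n - 1) + se2_b ** 2 / (b.n - 1))
    return float(2.0 * t_dist.sf(abs(t_stat), df))
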