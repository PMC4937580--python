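"""Cascade-impactor data reduction.

Reduces per-stage radioactivity measurements from a low-pressure cascade
impactor (ELPI operated in DLPI mode, 12 stages covering 30 nm - 10 μm)
to the standard activity-weighted size metrics of inhalation dosimetry:

* AMAD — activity median aerodynamic diameter (the 50 % point of the
  cumulative activity-vs-size distribution),
* GSD — geometric standard deviation, ``sqrt(d84 / d16)``,
* d16 / d84 — diameters at the 16 % and 84 % cumulative cut-offs,
* fine-particle (< 2.5 μm), ultrafine (< 0.1 μm), sub-micron (< 1 μm)
  and < 0.5 μm activity fractions,
* emitted fraction (aerosol output) — activity leaving the nebulizer as a
  percentage of the activity loaded into it.

Quantiles are read off the empirical cumulative curve by interpolating
linearly in (ln d, probit F) — the classical log-probability plot, exact
for log-normal aerosols.  No parametric distribution is fitted here; the
log-normal generative model lives in :mod:`aerodepo.synthetic`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import EmptyRunError, ExtrapolationError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "StageTable",
    "ImpactorRun",
    "SizeMetrics",
    "cumulative_activity_distribution",
    "quantile_diameter",
    "gsd_from_quantiles",
    "fraction_below",
    "size_metrics",
    "hatch_choate_range",
]


@dataclass(frozen=True)
class StageTable:
    """Stage boundary (cut) diameters of a cascade impactor, in μm.

    ``cut_diameters`` holds the n_stages + 1 bin edges in strictly
    ascending order; stage k collects particles with aerodynamic diameter
    between edges k and k+1.  Real instrument cut-offs are calibration
    data, so the table is fully overridable from CSV; the default spans
    the 30 nm - 10 μm range with 12 geometrically spaced stages.
    """

    cut_diameters: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.cut_diameters, dtype=float)
        if d.ndim != 1 or d.size < 2:
            raise ValidationError("stage table needs at least two cut diameters")
        if not np.all(d > 0):
            raise ValidationError("cut diameters must be positive")
        if not np.all(np.diff(d) > 0):
            raise ValidationError("cut diameters must be strictly ascending")
        object.__setattr__(self, "cut_diameters", d)

    @property
    def n_stages(self) -> int:
        return self.cut_diameters.size - 1

    @classmethod
    def default(cls) -> "StageTable":
        """12 stages geometrically spaced over 30 nm - 10 μm."""
        return cls(np.geomspace(0.030, 10.0, 13))

    @classmethod
    def geometric(cls, d_min: float, d_max: float, n_stages: int) -> "StageTable":
        return cls(np.geomspace(d_min, d_max, n_stages + 1))

    @classmethod
    def from_csv(cls, path) -> "StageTable":
        """Read a ``stage_index, cut_diameter_um`` CSV."""
        df = pd.read_csv(path)
        required = {"stage_index", "cut_diameter_um"}
        if not required.issubset(df.columns):
            raise ValidationError(
                f"stage table CSV must have columns {sorted(required)}"
            )
        df = df.sort_values("stage_index")
        return cls(df["cut_diameter_um"].to_numpy(dtype=float))


@dataclass
class ImpactorRun:
    """Per-stage activities from one impactor measurement.

    ``stage_activities[k]`` is the activity (counts or MBq) collected on
    stage k, bounded by consecutive cut diameters of the associated
    :class:`StageTable`.  ``below_min`` / ``above_max`` are optional catch
    bins for activity outside the instrument's size range.  ``loaded_activity``
    and ``residual_activity`` (MBq) enable the emitted-fraction metric.
    """

    stage_activities: np.ndarray
    loaded_activity: float | None = None
    residual_activity: float | None = None
    below_min: float = 0.0
    above_max: float = 0.0
    label: str = ""

    def __post_init__(self):
        a = np.asarray(self.stage_activities, dtype=float)
        if a.ndim != 1:
            raise ValidationError("stage activities must be a 1-D vector")
        if np.any(a < 0) or self.below_min < 0 or self.above_max < 0:
            raise ValidationError("stage activities must be non-negative")
        if not np.all(np.isfinite(a)):
            raise ValidationError("stage activities must be finite")
        self.stage_activities = a

    @property
    def total_activity(self) -> float:
        return float(self.stage_activities.sum() + self.below_min + self.above_max)


@dataclass(frozen=True)
class SizeMetrics:
    """Aerosol size-distribution metrics derived from one impactor run."""

    amad: float
    gsd: float
    d16: float
    d84: float
    fp_fraction: float
    ufp_fraction: float
    sub1_fraction: float
    sub05_fraction: float
    emitted_fraction: float | None = None

    def __post_init__(self):
        if not (self.d16 <= self.amad <= self.d84):
            raise ValidationError("d16 <= amad <= d84 violated")
        if self.gsd < 1:
            raise ValidationError("gsd must be >= 1")
        fr = (self.ufp_fraction, self.sub05_fraction, self.sub1_fraction,
              self.fp_fraction)
        if any(not (0 <= f <= 1) for f in fr):
            raise ValidationError("fractions must lie in [0, 1]")
        if not (fr[0] <= fr[1] <= fr[2] <= fr[3]):
            raise ValidationError("size fractions must be monotone in diameter")

    def to_dict(self) -> dict:
        return {
            "amad_um": self.amad,
            "gsd": self.gsd,
            "d16_um": self.d16,
            "d84_um": self.d84,
            "fp_fraction": self.fp_fraction,
            "ufp_fraction": self.ufp_fraction,
            "sub1_fraction": self.sub1_fraction,
            "sub05_fraction": self.sub05_fraction,
            "emitted_fraction_pct": self.emitted_fraction,
        }


def cumulative_activity_distribution(
    run: ImpactorRun, table: StageTable
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative activity fraction at each stage boundary.

    Returns ``(diameters, fractions)`` with one point per boundary:
    ``fractions[i]`` is the activity fraction carried by particles with
    aerodynamic diameter <= ``diameters[i]``.  Catch-bin activity below
    the lowest boundary is attributed to the first point; activity above
    the highest boundary keeps the last point below 1.
    """
    if run.stage_activities.size != table.n_stages:
        raise ValidationError(
            f"run has {run.stage_activities.size} stages, table defines "
            f"{table.n_stages}"
        )
    total = run.total_activity
    if total <= 0:
        raise EmptyRunError("empty run: total stage activity is zero")
    cum = np.concatenate(([run.below_min],
                          run.below_min + np.cumsum(run.stage_activities)))
    # pin the final point so it is exactly (total - above_max) / total
    # (exactly 1 without a top catch bin), then restore monotonicity
    # against cumsum rounding
    cum[-1] = total - run.above_max
    frac = np.maximum.accumulate(np.minimum(cum / total, cum[-1] / total))
    return table.cut_diameters.copy(), frac


def _probit_ok(f: float) -> bool:
    return 0.0 < f < 1.0


def quantile_diameter(
    cdf: tuple[np.ndarray, np.ndarray], q: float
) -> float:
    """Diameter at cumulative activity fraction ``q``.

    Interpolates linearly in (ln d, probit F) between the bracketing
    boundaries; a segment whose endpoint fraction is 0 or 1 (probit
    undefined) falls back to linear interpolation in the fraction itself.
    ``q = 0.5`` yields the AMAD, ``q = 0.16`` / ``0.84`` the d16 / d84.
    """
    d, f = np.asarray(cdf[0], float), np.asarray(cdf[1], float)
    if not 0.0 < q < 1.0:
        raise ValidationError("q must lie strictly inside (0, 1)")
    if q < f[0] or q > f[-1]:
        nearest = f[0] if q < f[0] else f[-1]
        raise ExtrapolationError(q, float(nearest))
    # exact hits (incl. plateau edges) resolve without interpolation
    hits = np.nonzero(np.isclose(f, q, rtol=0.0, atol=1e-15))[0]
    if hits.size:
        return float(np.exp(np.mean(np.log(d[hits]))))
    i = int(np.searchsorted(f, q, side="left")) - 1
    while f[i + 1] <= f[i]:  # skip zero-activity plateau
        i += 1
    f0, f1 = f[i], f[i + 1]
    x0, x1 = np.log(d[i]), np.log(d[i + 1])
    if _probit_ok(f0) and _probit_ok(f1):
        t = (norm.ppf(q) - norm.ppf(f0)) / (norm.ppf(f1) - norm.ppf(f0))
    else:
        t = (q - f0) / (f1 - f0)
    return float(np.exp(x0 + t * (x1 - x0)))


def gsd_from_quantiles(d16: float, d84: float) -> float:
    """Geometric standard deviation, ``sqrt(d84 / d16)``."""
    if not 0 < d16 <= d84:
        raise ValidationError("require 0 < d16 <= d84")
    return float(np.sqrt(d84 / d16))


def fraction_below(cdf: tuple[np.ndarray, np.ndarray], diameter: float) -> float:
    """Activity fraction carried by particles smaller than ``diameter`` (μm).

    Log-probit interpolation of the cumulative curve, clamped to the
    attained range outside the boundary grid (with a logged warning).
    """
    d, f = np.asarray(cdf[0], float), np.asarray(cdf[1], float)
    if diameter <= 0:
        raise ValidationError("diameter must be positive")
    if diameter <= d[0]:
        if diameter < d[0]:
            logger.warning(
                "diameter %.4g below the smallest boundary %.4g; clamping",
                diameter, d[0])
        return float(f[0])
    if diameter >= d[-1]:
        if diameter > d[-1]:
            logger.warning(
                "diameter %.4g above the largest boundary %.4g; clamping",
                diameter, d[-1])
        return float(f[-1])
    i = int(np.searchsorted(d, diameter, side="right")) - 1
    x0, x1 = np.log(d[i]), np.log(d[i + 1])
    t = (np.log(diameter) - x0) / (x1 - x0)
    f0, f1 = f[i], f[i + 1]
    if _probit_ok(f0) and _probit_ok(f1):
        val = norm.cdf(norm.ppf(f0) + t * (norm.ppf(f1) - norm.ppf(f0)))
    else:
        val = f0 + t * (f1 - f0)
    return float(min(max(val, 0.0), 1.0))


def size_metrics(run: ImpactorRun, table: StageTable) -> SizeMetrics:
    """Full reduction of one impactor run to :class:`SizeMetrics`."""
    emitted = None
    if run.loaded_activity is not None and run.residual_activity is not None:
        if run.loaded_activity <= 0:
            raise ValidationError("loaded activity must be positive")
        emitted = 100.0 * (run.loaded_activity - run.residual_activity) \
            / run.loaded_activity

    positive = np.nonzero(run.stage_activities > 0)[0]
    if positive.size == 1 and run.below_min == 0 and run.above_max == 0:
        # monodisperse degenerate case: one loaded stage
        k = positive[0]
        mid = float(np.sqrt(table.cut_diameters[k] * table.cut_diameters[k + 1]))
        cdf = cumulative_activity_distribution(run, table)
        return SizeMetrics(
            amad=mid, gsd=1.0, d16=mid, d84=mid,
            fp_fraction=fraction_below(cdf, 2.5),
            ufp_fraction=fraction_below(cdf, 0.1),
            sub1_fraction=fraction_below(cdf, 1.0),
            sub05_fraction=fraction_below(cdf, 0.5),
            emitted_fraction=emitted,
        )

    cdf = cumulative_activity_distribution(run, table)
    d16 = quantile_diameter(cdf, 0.16)
    d84 = quantile_diameter(cdf, 0.84)
    return SizeMetrics(
        amad=quantile_diameter(cdf, 0.5),
        gsd=gsd_from_quantiles(d16, d84),
        d16=d16,
        d84=d84,
        fp_fraction=fraction_below(cdf, 2.5),
        ufp_fraction=fraction_below(cdf, 0.1),
        sub1_fraction=fraction_below(cdf, 1.0),
        sub05_fraction=fraction_below(cdf, 0.5),
        emitted_fraction=emitted,
    )


def hatch_choate_range(amad: float, gsd: float) -> tuple[float, float]:
    """Log-normal (d16, d84) implied by (AMAD, GSD): ``(amad/gsd, amad*gsd)``.

    Diagnostic cross-check only — empirical distributions need not obey it.
    """
    if amad <= 0:
        raise ValidationError("amad must be positive")
    if gsd < 1:
        raise ValidationError("gsd must be >= 1")
    return amad / gsd, amad * gsd
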