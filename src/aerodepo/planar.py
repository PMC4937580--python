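"""Planar gamma-scintigraphy region quantification.

Anterior/posterior count rasters of each imaged element (nebulizer,
plastinated head with artificial larynx = extrathoracic region, lungs with
tracheobronchial tree = thoracic region, expiratory filter) are reduced to
region activities through the standard correction chain of quantitative
planar imaging:

1. ROI gross counts on each view,
2. background subtraction using the mean per-pixel rate of three external
   background ROIs,
3. conversion to count rates (÷ acquisition duration),
4. conjugate-view combination: geometric mean of the opposed views divided
   by the square root of a per-region transmission (attenuation) factor,
5. physical decay correction of the radionuclide (Tc-99m) to a common
   reference time.

Masks are co-registered rasters on the anterior image grid; the posterior
image is mirrored left-right before pairing (the usual camera convention,
configurable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DataInconsistencyError, ValidationError

logger = logging.getLogger(__name__)

#: Tc-99m physical half-life, seconds (6.0113 h).
TC99M_HALF_LIFE_S = 6.0113 * 3600.0

BACKGROUND_LABELS = ("background_1", "background_2", "background_3")

__all__ = [
    "TC99M_HALF_LIFE_S",
    "BACKGROUND_LABELS",
    "PlanarPair",
    "RoiSet",
    "CorrectionSpec",
    "RegionActivity",
    "roi_gross_counts",
    "background_correct",
    "decay_correct",
    "conjugate_view_activity",
    "region_activities",
    "nebulizer_emitted",
]


@dataclass
class PlanarPair:
    """One anterior/posterior acquisition of a single element.

    ``start_time`` is in seconds on the experiment clock (the same clock
    as :attr:`CorrectionSpec.reference_time`); ``pixel_size`` in mm.
    """

    anterior: np.ndarray
    posterior: np.ndarray
    duration: float
    start_time: float = 0.0
    pixel_size: float = 2.4

    def __post_init__(self):
        ant = np.asarray(self.anterior, dtype=float)
        post = np.asarray(self.posterior, dtype=float)
        if ant.ndim != 2 or post.shape != ant.shape:
            raise ValidationError("anterior/posterior must be equal-shape 2-D rasters")
        if np.any(ant < 0) or np.any(post < 0):
            raise ValidationError("count rasters must be non-negative")
        if self.duration <= 0:
            raise ValidationError("acquisition duration must be positive")
        self.anterior, self.posterior = ant, post


@dataclass
class RoiSet:
    """Labeled boolean masks over the image grid (anterior frame)."""

    masks: dict[str, np.ndarray]

    def __post_init__(self):
        shapes = set()
        clean = {}
        for label, m in self.masks.items():
            m = np.asarray(m, dtype=bool)
            if not m.any():
                raise ValidationError(f"ROI mask '{label}' is empty")
            shapes.add(m.shape)
            clean[label] = m
        if len(shapes) > 1:
            raise ValidationError("all ROI masks must share the image grid shape")
        self.masks = clean

    @property
    def background_labels(self) -> list[str]:
        return [l for l in self.masks if l in BACKGROUND_LABELS]

    @property
    def region_labels(self) -> list[str]:
        return [l for l in self.masks if l not in BACKGROUND_LABELS]


@dataclass
class CorrectionSpec:
    """Background/decay/attenuation correction configuration.

    ``attenuation`` maps region labels to transmission factors in (0, 1]
    (1.0 = no attenuation); ``None`` means unit transmission everywhere.
    """

    half_life: float = TC99M_HALF_LIFE_S
    reference_time: float = 0.0
    attenuation: dict[str, float] | None = None
    posterior_mirroring: bool = True
    background_correction: bool = True

    def __post_init__(self):
        if self.half_life <= 0:
            raise ValidationError("half-life must be positive")
        if self.attenuation is not None:
            for label, f in self.attenuation.items():
                if not 0 < f <= 1:
                    raise ValidationError(
                        f"attenuation factor for '{label}' must be in (0, 1]")

    def factor_for(self, label: str) -> float:
        if self.attenuation is None:
            return 1.0
        try:
            return self.attenuation[label]
        except KeyError:
            raise ConfigurationError(
                f"no attenuation factor configured for region '{label}'"
            ) from None


@dataclass(frozen=True)
class RegionActivity:
    """Background-, attenuation- and decay-corrected activity of one region."""

    label: str
    net_count_rate: float
    corrected_activity: float


def roi_gross_counts(image: np.ndarray, mask: np.ndarray) -> float:
    """Sum of counts over the mask pixels."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValidationError("mask shape does not match the image")
    if not mask.any():
        raise ValidationError("ROI mask is empty")
    return float(image[mask].sum())


def background_correct(
    gross: float,
    roi_pixel_count: int,
    background_rois: list[tuple[float, int]],
) -> float:
    """Subtract the mean per-pixel background of three external ROIs.

    ``net = gross - b̄ · n`` where b̄ is the mean over the three background
    ROIs of counts/pixel and n the target ROI pixel count.  Negative nets
    clamp to zero with a warning (expected for low-count ROIs).
    """
    if len(background_rois) != 3:
        raise ValidationError("background correction requires exactly three ROIs")
    rates = []
    for counts, npx in background_rois:
        if npx <= 0:
            raise ValidationError("background ROI must be non-empty")
        rates.append(counts / npx)
    net = gross - float(np.mean(rates)) * roi_pixel_count
    if net < 0:
        logger.warning("negative net counts (%.1f) clamped to zero", net)
        net = 0.0
    return net


def decay_correct(value: float, elapsed: float, half_life: float) -> float:
    """Correct a measurement made ``elapsed`` s after the reference time.

    Multiplies by ``2 ** (elapsed / half_life)`` — a measurement taken
    later than the reference is scaled up; negative ``elapsed`` decays the
    value forward.
    """
    if half_life <= 0:
        raise ValidationError("half-life must be positive")
    return value * 2.0 ** (elapsed / half_life)


def conjugate_view_activity(
    ant_net: float, post_net: float, attenuation_factor: float = 1.0
) -> float:
    """Geometric-mean conjugate-view estimate with transmission correction.

    ``sqrt(ant · post) / sqrt(f)`` where f in (0, 1] is the transmission
    factor of the tissue between the source plane and either detector.
    """
    if not 0 < attenuation_factor <= 1:
        raise ValidationError("attenuation factor must be in (0, 1]")
    if ant_net < 0 or post_net < 0:
        raise ValidationError("net rates must be non-negative")
    return float(np.sqrt(ant_net * post_net) / np.sqrt(attenuation_factor))


def _view_net_counts(image: np.ndarray, rois: RoiSet, label: str,
                     spec: CorrectionSpec) -> float:
    gross = roi_gross_counts(image, rois.masks[label])
    if not spec.background_correction:
        return gross
    bg_labels = rois.background_labels
    if len(bg_labels) != 3:
        raise ValidationError(
            f"background correction requires the three labels "
            f"{BACKGROUND_LABELS}; found {bg_labels}")
    backgrounds = [
        (roi_gross_counts(image, rois.masks[l]), int(rois.masks[l].sum()))
        for l in sorted(bg_labels)
    ]
    return background_correct(gross, int(rois.masks[label].sum()), backgrounds)


def region_activities(
    pair: PlanarPair, rois: RoiSet, spec: CorrectionSpec
) -> list[RegionActivity]:
    """Corrected activity of every non-background region in the ROI set.

    Per region: gross counts on each view → background subtraction →
    count rate → conjugate-view combination with the region's attenuation
    factor → decay correction to ``spec.reference_time``.
    """
    some_mask = next(iter(rois.masks.values()))
    if some_mask.shape != pair.anterior.shape:
        raise ValidationError("ROI grid does not match the image grid")
    posterior = np.fliplr(pair.posterior) if spec.posterior_mirroring \
        else pair.posterior
    out = []
    for label in rois.region_labels:
        factor = spec.factor_for(label)  # raises before any arithmetic
        ant_net = _view_net_counts(pair.anterior, rois, label, spec)
        post_net = _view_net_counts(posterior, rois, label, spec)
        rate = conjugate_view_activity(
            ant_net / pair.duration, post_net / pair.duration, factor)
        activity = decay_correct(
            rate, pair.start_time - spec.reference_time, spec.half_life)
        out.append(RegionActivity(label, net_count_rate=rate,
                                  corrected_activity=activity))
    return out


def nebulizer_emitted(
    full: RegionActivity, empty: RegionActivity
) -> tuple[float, float]:
    """Emitted activity and aerosol output (% of loaded).

    Both inputs must already be decay-corrected to a common reference.
    """
    if full.corrected_activity <= 0:
        raise ValidationError("full-nebulizer activity must be positive")
    if empty.corrected_activity > full.corrected_activity:
        raise DataInconsistencyError(
            "empty-nebulizer activity exceeds the full-nebulizer activity "
            "after decay correction")
    emitted = full.corrected_activity - empty.corrected_activity
    return emitted, 100.0 * emitted / full.corrected_activity
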