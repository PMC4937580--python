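"""Central vs peripheral partition of in-lung SPECT activity.

Consumes a reconstructed activity volume and a label volume delimiting the
proximal tracheobronchial region (trachea + two principal bronchi,
label 1, "central") from the lung periphery (label 2, "peripheral");
label 0 is outside the lung.  The in-lung activity is normalized to 100 %
so the two compartments can be compared across aerosols; activity falling
outside both labels is excluded from the normalization and reported
separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

LABEL_OUTSIDE, LABEL_CENTRAL, LABEL_PERIPHERAL = 0, 1, 2

__all__ = [
    "ActivityVolume",
    "RegionLabelVolume",
    "PartitionResult",
    "partition_fractions",
    "central_share_flag",
]


@dataclass
class ActivityVolume:
    """Reconstructed 3-D activity distribution; ``voxel_size`` in mm."""

    voxels: np.ndarray
    voxel_size: tuple[float, float, float] = (3.9, 3.9, 3.9)

    def __post_init__(self):
        v = np.asarray(self.voxels, dtype=float)
        if v.ndim != 3:
            raise ValidationError("activity volume must be 3-D")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValidationError("voxel activities must be finite and >= 0")
        self.voxels = v


@dataclass
class RegionLabelVolume:
    """Integer labels {0 outside, 1 central, 2 peripheral} on the same grid."""

    labels: np.ndarray

    def __post_init__(self):
        l = np.asarray(self.labels)
        if l.ndim != 3:
            raise ValidationError("label volume must be 3-D")
        if not np.isin(l, (LABEL_OUTSIDE, LABEL_CENTRAL, LABEL_PERIPHERAL)).all():
            raise ValidationError("labels must be 0 (outside), 1 (central) or 2 (peripheral)")
        if not (l == LABEL_CENTRAL).any() or not (l == LABEL_PERIPHERAL).any():
            raise ValidationError("need at least one central and one peripheral voxel")
        self.labels = l.astype(np.int8)


@dataclass(frozen=True)
class PartitionResult:
    """Central/peripheral percentages (summing to 100) and the excluded share."""

    central_pct: float
    peripheral_pct: float
    outside_pct: float  # % of total volume activity outside both labels


def partition_fractions(
    vol: ActivityVolume, labels: RegionLabelVolume
) -> PartitionResult:
    """Central and peripheral percentages of in-lung activity.

    The two percentages are normalized to the in-lung total, so they sum
    to exactly 100; the activity share outside both labels is reported
    but excluded from the normalization.
    """
    if vol.voxels.shape != labels.labels.shape:
        raise ValidationError("activity and label volumes differ in shape")
    central = float(vol.voxels[labels.labels == LABEL_CENTRAL].sum())
    peripheral = float(vol.voxels[labels.labels == LABEL_PERIPHERAL].sum())
    in_lung = central + peripheral
    if in_lung <= 0:
        raise ValidationError("no in-lung activity: central + peripheral is zero")
    total = float(vol.voxels.sum())
    outside_pct = 100.0 * (total - in_lung) / total if total > 0 else 0.0
    central_pct = 100.0 * central / in_lung
    return PartitionResult(
        central_pct=central_pct,
        peripheral_pct=100.0 - central_pct,
        outside_pct=outside_pct,
    )


def central_share_flag(central_pct: float) -> bool:
    """True when central deposition is below the 5 % peripheral-dominance mark."""
    if not 0 <= central_pct <= 100:
        raise ValidationError("central percentage must lie in [0, 100]")
    return central_pct < 5.0
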