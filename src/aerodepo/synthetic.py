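"""Ground-truth-known synthetic data with the statistical structure the
analysis pipeline assumes.

Three generators, all seed-reproducible:

* :func:`sample_impactor_run` — stage activities of a log-normal
  polydisperse aerosol (expected bin content = log-normal CDF increment,
  realized counts Poisson),
* :func:`render_planar_scene` — the full planar acquisition set of one
  nebulization experiment (full/empty nebulizer, expiratory filter, head
  = extrathoracic region, lungs = thoracic region), each element painted
  into its footprint, Gaussian-blurred by the collimator PSF, attenuated
  per view, over a uniform background, Poisson-sampled and physically
  decayed to its acquisition time,
* :func:`render_activity_volume` — a lung volume with a central
  (tracheobronchial) cylinder and two peripheral lobes at a configured
  activity split.

``STUDY_CONDITIONS`` collects the nebulizer-level ground truths used
throughout the test and reproduction harnesses: AMAD/GSD of the three jet
nebulizers (Atomisor NL11, modified Sidestream, Nanoneb), their aerosol
output, and the regional deposition and exhaled fractions measured for
each size range in the ex vivo chimeric head-lung model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.stats import norm

from .errors import GeometryError, ValidationError
from .planar import BACKGROUND_LABELS, TC99M_HALF_LIFE_S, CorrectionSpec, PlanarPair, RoiSet
from .report import DepositionResult
from .spect import LABEL_CENTRAL, LABEL_PERIPHERAL, ActivityVolume, RegionLabelVolume
from .impactor import ImpactorRun, StageTable

__all__ = [
    "AerosolSpec",
    "ScenarioSpec",
    "SceneGeometry",
    "PlanarScene",
    "STUDY_CONDITIONS",
    "scenario_from_condition",
    "sample_impactor_run",
    "render_planar_scene",
    "render_activity_volume",
]

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class AerosolSpec:
    """Log-normal aerosol: activity median aerodynamic diameter (μm),
    geometric standard deviation, and total activity (counts or MBq)."""

    amad: float
    gsd: float
    total_activity: float = 1.0

    def __post_init__(self):
        if self.amad <= 0:
            raise ValidationError("amad must be positive")
        if self.gsd < 1:
            raise ValidationError("gsd must be >= 1")


@dataclass(frozen=True)
class ScenarioSpec:
    """Ground-truth configuration of one nebulization experiment.

    Fractions are percentages: ``emitted_fraction`` of loaded,
    ``exhaled_fraction_of_emitted`` and ``circuit_loss_pct`` of emitted,
    ``et_pct``/``th_pct`` of the deposited total (must sum to 100),
    ``central_fraction`` of in-lung activity.  Breathing parameters are
    carried as annotation only (adult at rest: 15 breaths/min, I/E 1/2).
    """

    loaded_activity: float = 740.0  # MBq
    emitted_fraction: float = 44.5
    exhaled_fraction_of_emitted: float = 27.0
    et_pct: float = 65.0
    th_pct: float = 35.0
    circuit_loss_pct: float = 0.0
    central_fraction: float = 4.0
    nebulization_duration: float = 600.0  # s, standardized 10 min
    breathing_rate_per_min: float = 15.0
    ie_ratio: str = "1/2"
    label: str = ""

    def __post_init__(self):
        pcts = (self.emitted_fraction, self.exhaled_fraction_of_emitted,
                self.et_pct, self.th_pct, self.circuit_loss_pct,
                self.central_fraction)
        if any(not 0 <= p <= 100 for p in pcts):
            raise ValidationError("all fractions must lie in [0, 100]")
        if abs(self.et_pct + self.th_pct - 100.0) > 1e-9:
            raise ValidationError("et_pct + th_pct must equal 100")
        if self.exhaled_fraction_of_emitted + self.circuit_loss_pct > 100.0 + 1e-9:
            raise ValidationError("exhaled + loss cannot exceed 100 % of emitted")
        if self.loaded_activity <= 0:
            raise ValidationError("loaded activity must be positive")

    # activity bookkeeping (all in the loaded-activity unit, at t = 0)
    @property
    def emitted_activity(self) -> float:
        return self.loaded_activity * self.emitted_fraction / 100.0

    @property
    def residual_activity(self) -> float:
        return self.loaded_activity - self.emitted_activity

    @property
    def exhaled_activity(self) -> float:
        return self.emitted_activity * self.exhaled_fraction_of_emitted / 100.0

    @property
    def deposited_activity(self) -> float:
        return self.emitted_activity * (
            100.0 - self.exhaled_fraction_of_emitted - self.circuit_loss_pct
        ) / 100.0

    @property
    def et_activity(self) -> float:
        return self.deposited_activity * self.et_pct / 100.0

    @property
    def th_activity(self) -> float:
        return self.deposited_activity * self.th_pct / 100.0

    def truth(self) -> DepositionResult:
        return DepositionResult(
            et_pct=self.et_pct,
            th_pct=self.th_pct,
            exhaled_pct_of_emitted=self.exhaled_fraction_of_emitted,
            emitted_activity=self.emitted_activity,
            loaded_activity=self.loaded_activity,
            unaccounted_pct=self.circuit_loss_pct,
        )


#: Study conditions of the ex vivo chimeric-model experiments, keyed by
#: the [d16–d84] size range of each nebulizer's aerosol.
STUDY_CONDITIONS: dict[str, dict] = {
    "0.15-0.5um": dict(nebulizer="Nanoneb", amad=0.23, gsd=1.6,
                       emitted_fraction=4.2, et_pct=11.0, th_pct=89.0,
                       exhaled_pct=68.0),
    "0.25-1um": dict(nebulizer="Sidestream", amad=0.55, gsd=2.1,
                     emitted_fraction=9.3, et_pct=22.0, th_pct=78.0,
                     exhaled_pct=34.0),
    "1-9um": dict(nebulizer="Atomisor NL11", amad=2.80, gsd=3.2,
                  emitted_fraction=44.5, et_pct=65.0, th_pct=35.0,
                  exhaled_pct=27.0),
}


def scenario_from_condition(size_range: str, **overrides) -> ScenarioSpec:
    """Build the :class:`ScenarioSpec` of one study condition by size range."""
    cond = STUDY_CONDITIONS[size_range]
    spec = ScenarioSpec(
        emitted_fraction=cond["emitted_fraction"],
        exhaled_fraction_of_emitted=cond["exhaled_pct"],
        et_pct=cond["et_pct"],
        th_pct=cond["th_pct"],
        label=f"{cond['nebulizer']} [{size_range}]",
    )
    return replace(spec, **overrides) if overrides else spec


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# impactor stage sampling


def _lognormal_bin_fractions(aerosol: AerosolSpec,
                             edges: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Expected activity fractions per stage plus below/above catch shares."""
    if aerosol.gsd == 1.0:
        # monodisperse limit: everything in the bin containing the AMAD
        cdf = (edges >= aerosol.amad).astype(float)
    else:
        cdf = norm.cdf(np.log(edges / aerosol.amad) / np.log(aerosol.gsd))
    return np.diff(cdf), float(cdf[0]), float(1.0 - cdf[-1])


def sample_impactor_run(
    aerosol: AerosolSpec,
    table: StageTable,
    count_scale: float = 1e5,
    seed=None,
    noiseless: bool = False,
) -> ImpactorRun:
    """Draw one impactor measurement of a log-normal aerosol.

    Expected stage content is the log-normal CDF increment over the stage
    edges times ``count_scale``; realized stage activities are Poisson
    unless ``noiseless``.  Activity outside the instrument range lands in
    the catch bins.
    """
    fracs, below, above = _lognormal_bin_fractions(aerosol, table.cut_diameters)
    expected = np.concatenate(([below], fracs, [above])) * count_scale
    if noiseless:
        realized = expected
    else:
        realized = _rng(seed).poisson(expected).astype(float)
    return ImpactorRun(
        stage_activities=realized[1:-1],
        below_min=float(realized[0]),
        above_max=float(realized[-1]),
        label=f"synthetic lognormal amad={aerosol.amad} gsd={aerosol.gsd}",
    )


# ---------------------------------------------------------------------------
# planar scenes


#: Element label -> (acquisition start s, duration s).  The nebulizer is
#: imaged full before nebulization (60 s, the decay reference); after the
#: standardized 10-min nebulization the empty nebulizer, expiratory
#: filter, head and lungs are imaged in turn (180 s each).
ACQUISITION_SCHEDULE: dict[str, tuple[float, float]] = {
    "nebulizer_full": (0.0, 60.0),
    "nebulizer_empty": (900.0, 180.0),
    "filter": (1200.0, 180.0),
    "head_ET": (1500.0, 180.0),
    "lungs_TH": (1800.0, 180.0),
}

#: ROI label used inside each element's acquisition.
ELEMENT_REGION = {
    "nebulizer_full": "nebulizer",
    "nebulizer_empty": "nebulizer",
    "filter": "filter",
    "head_ET": "head_ET",
    "lungs_TH": "lungs_TH",
}


@dataclass(frozen=True)
class SceneGeometry:
    """Camera and scene layout for synthetic planar acquisitions.

    Defaults mimic the acquisition hardware: 256x256 matrix, 2.4 mm
    pixels, low-energy high-resolution collimator PSF of 8.3 mm FWHM.
    ``sensitivity`` converts activity to expected counts (counts per
    activity-unit·s); ``background_rate`` is counts/pixel/s.  Footprints
    are axis-aligned ellipses ``(row, col, r_row, r_col)`` in pixels and
    must be pairwise disjoint.  ``attenuation`` holds the per-region
    transmission factor in (0, 1], applied symmetrically to both views so
    the conjugate-view estimator is exactly unbiased; ``asymmetric_attenuation``
    unbalances the two views (anterior gets f**0.75, posterior f**0.25)
    to probe estimator bias.
    """

    shape: tuple[int, int] = (256, 256)
    pixel_size: float = 2.4  # mm
    psf_fwhm: float = 8.3  # mm
    background_rate: float = 0.05  # counts / pixel / s
    sensitivity: float = 1.0  # counts per (activity unit · s)
    footprints: dict[str, tuple[int, int, int, int]] = field(
        default_factory=lambda: {
            "nebulizer": (128, 50, 18, 14),
            "head_ET": (70, 128, 26, 22),
            "lungs_TH": (160, 128, 36, 30),
            "filter": (128, 206, 14, 14),
        })
    attenuation: dict[str, float] = field(
        default_factory=lambda: {
            "nebulizer": 0.85, "head_ET": 0.65, "lungs_TH": 0.55,
            "filter": 0.95,
        })
    asymmetric_attenuation: bool = False
    mask_margin_px: int = 8

    def __post_init__(self):
        if self.psf_fwhm < 0:
            raise ValidationError("psf_fwhm must be >= 0")
        if self.background_rate < 0 or self.sensitivity <= 0:
            raise ValidationError("background_rate >= 0 and sensitivity > 0 required")
        masks = {l: self.footprint_mask(l) for l in self.footprints}
        labels = list(masks)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                if np.any(masks[a] & masks[b]):
                    raise GeometryError(f"footprints '{a}' and '{b}' overlap")

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_fwhm / FWHM_TO_SIGMA / self.pixel_size

    def _ellipse(self, row, col, r_row, r_col, margin=0) -> np.ndarray:
        rr, cc = np.ogrid[: self.shape[0], : self.shape[1]]
        return ((rr - row) / (r_row + margin)) ** 2 \
            + ((cc - col) / (r_col + margin)) ** 2 <= 1.0

    def footprint_mask(self, label: str, margin: int = 0) -> np.ndarray:
        return self._ellipse(*self.footprints[label], margin=margin)

    def roi_mask(self, label: str) -> np.ndarray:
        """Footprint dilated to recover the blur-spread counts."""
        return self.footprint_mask(label, margin=self.mask_margin_px)

    def background_masks(self) -> dict[str, np.ndarray]:
        n0, n1 = self.shape
        side = 12
        spots = {
            "background_1": (8, 8),
            "background_2": (8, n1 - side - 8),
            "background_3": (n0 - side - 8, 8),
        }
        out = {}
        for label, (r, c) in spots.items():
            m = np.zeros(self.shape, dtype=bool)
            m[r:r + side, c:c + side] = True
            out[label] = m
        return out

    def correction_spec(self, reference_time: float = 0.0) -> CorrectionSpec:
        """Correction configuration matched to this geometry."""
        att = dict(self.attenuation)
        return CorrectionSpec(reference_time=reference_time,
                              attenuation=att, posterior_mirroring=True)


@dataclass
class PlanarScene:
    """One complete synthetic experiment: per-element planar pairs with
    their ROI sets, the generating scenario and its ground truth."""

    elements: dict[str, tuple[PlanarPair, RoiSet]]
    scenario: ScenarioSpec
    geometry: SceneGeometry
    truth: DepositionResult
    correction: CorrectionSpec


def _element_activities(scenario: ScenarioSpec) -> dict[str, float]:
    return {
        "nebulizer_full": scenario.loaded_activity,
        "nebulizer_empty": scenario.residual_activity,
        "filter": scenario.exhaled_activity,
        "head_ET": scenario.et_activity,
        "lungs_TH": scenario.th_activity,
    }


def _render_pair(
    activity: float, region: str, geometry: SceneGeometry,
    start: float, duration: float, half_life: float,
    rng: np.random.Generator, noiseless: bool,
) -> PlanarPair:
    scene = np.zeros(geometry.shape, dtype=float)
    fp = geometry.footprint_mask(region)
    decayed = activity * 0.5 ** (start / half_life)
    scene[fp] = decayed * geometry.sensitivity * duration / fp.sum()
    if geometry.psf_sigma_px > 0:
        scene = gaussian_filter(scene, geometry.psf_sigma_px)
    f = geometry.attenuation.get(region, 1.0)
    if geometry.asymmetric_attenuation:
        t_ant, t_post = f ** 0.75, f ** 0.25
    else:
        t_ant = t_post = np.sqrt(f)
    bg = geometry.background_rate * duration
    ant = scene * t_ant + bg
    post = np.fliplr(scene) * t_post + bg  # posterior stored mirrored
    if not noiseless:
        ant = rng.poisson(ant).astype(float)
        post = rng.poisson(post).astype(float)
    return PlanarPair(anterior=ant, posterior=post, duration=duration,
                      start_time=start, pixel_size=geometry.pixel_size)


def render_planar_scene(
    scenario: ScenarioSpec,
    geometry: SceneGeometry | None = None,
    seed=None,
    noiseless: bool = False,
    half_life: float = TC99M_HALF_LIFE_S,
) -> PlanarScene:
    """Render the full acquisition set of one nebulization experiment.

    Activity is apportioned per the scenario, painted into each element's
    footprint, blurred, attenuated (view-symmetrically by default), laid
    over a uniform background, Poisson-sampled (unless ``noiseless``) and
    decayed to each acquisition's start time.  The ground truth travels
    with the scene.  ``noiseless`` with ``background_rate=0``,
    ``psf_fwhm=0`` and unit attenuation reproduces the truth identically.
    """
    geometry = geometry or SceneGeometry()
    rng = _rng(seed)
    bg_masks = geometry.background_masks()
    elements: dict[str, tuple[PlanarPair, RoiSet]] = {}
    for element, (start, duration) in ACQUISITION_SCHEDULE.items():
        region = ELEMENT_REGION[element]
        pair = _render_pair(
            _element_activities(scenario)[element], region, geometry,
            start, duration, half_life, rng, noiseless)
        rois = RoiSet({region: geometry.roi_mask(region), **bg_masks})
        elements[element] = (pair, rois)
    return PlanarScene(
        elements=elements,
        scenario=scenario,
        geometry=geometry,
        truth=scenario.truth(),
        correction=geometry.correction_spec(
            reference_time=ACQUISITION_SCHEDULE["nebulizer_full"][0]),
    )


# ---------------------------------------------------------------------------
# SPECT volumes


def render_activity_volume(
    scenario: ScenarioSpec,
    shape: tuple[int, int, int] = (32, 64, 64),
    total_counts: float = 1e5,
    seed=None,
    noiseless: bool = False,
) -> tuple[ActivityVolume, RegionLabelVolume]:
    """Lung volume with a central airway cylinder and two peripheral lobes.

    The central (proximal tracheobronchial) compartment is a vertical
    cylinder between two ellipsoidal peripheral lobes; in-lung activity is
    split ``central_fraction : (100 - central_fraction)`` and scaled to
    ``total_counts``, with optional Poisson noise.
    """
    nz, ny, nx = shape
    zz, yy, xx = np.ogrid[:nz, :ny, :nx]
    zc, yc, xc = nz / 2, ny / 2, nx / 2

    central = (
        ((yy - yc) ** 2 + (xx - xc) ** 2 <= (min(ny, nx) * 0.045) ** 2)
        & (zz >= nz * 0.12) & (zz <= nz * 0.88)
    )
    rz, ry, rx = nz * 0.38, ny * 0.38, nx * 0.19
    lobes = np.zeros(shape, dtype=bool)
    for x_off in (-nx * 0.25, nx * 0.25):
        lobes |= (
            ((zz - zc) / rz) ** 2 + ((yy - yc) / ry) ** 2
            + ((xx - (xc + x_off)) / rx) ** 2 <= 1.0
        )
    lobes &= ~central
    labels = np.zeros(shape, dtype=np.int8)
    labels[central] = LABEL_CENTRAL
    labels[lobes] = LABEL_PERIPHERAL

    c = scenario.central_fraction / 100.0
    vol = np.zeros(shape, dtype=float)
    vol[central] = total_counts * c / central.sum()
    vol[lobes] = total_counts * (1.0 - c) / lobes.sum()
    if not noiseless:
        vol = _rng(seed).poisson(vol).astype(float)
    return ActivityVolume(voxels=vol), RegionLabelVolume(labels=labels)
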