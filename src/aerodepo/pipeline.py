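"""End-to-end orchestration: wiring the correction chain, the deposition
report and the reproduction harness over whole acquisition sets.

The functions here are what the command-line layer and the examples call;
they contain no science of their own beyond composing the modules.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigurationError, ValidationError
from .impactor import ImpactorRun, SizeMetrics, StageTable, \
    cumulative_activity_distribution, hatch_choate_range, size_metrics
from .planar import CorrectionSpec, PlanarPair, RegionActivity, RoiSet, \
    nebulizer_emitted, region_activities
from .report import DepositionResult, GroupSummary, et_th_split, \
    exhaled_fraction, mass_balance, replicate_summary
from .synthetic import ACQUISITION_SCHEDULE, ELEMENT_REGION, STUDY_CONDITIONS, \
    AerosolSpec, PlanarScene, SceneGeometry, sample_impactor_run, \
    scenario_from_condition, render_planar_scene

__all__ = [
    "analyze_planar_elements",
    "analyze_scene",
    "provenance",
    "reduce_impactor_run",
    "reproduce_tables",
]


def provenance(seed=None, config_text: str | None = None) -> dict:
    """Version/seed/config-hash stamp embedded in every report."""
    stamp = {"software": "aerodepo", "version": __version__}
    if seed is not None:
        stamp["seed"] = seed
    if config_text is not None:
        stamp["config_sha256"] = hashlib.sha256(
            config_text.encode()).hexdigest()
    return stamp


def reduce_impactor_run(run: ImpactorRun, table: StageTable) -> dict:
    """Size metrics plus the tidy cumulative curve for one impactor run."""
    metrics = size_metrics(run, table)
    d, f = cumulative_activity_distribution(run, table)
    lo, hi = hatch_choate_range(metrics.amad, metrics.gsd)
    return {
        "metrics": metrics.to_dict(),
        "hatch_choate_d16_um": lo,
        "hatch_choate_d84_um": hi,
        "cumulative_curve": [
            {"diameter_um": float(dd), "cumulative_fraction": float(ff)}
            for dd, ff in zip(d, f)
        ],
    }


def _single_region(pair: PlanarPair, rois: RoiSet, spec: CorrectionSpec,
                   label: str) -> RegionActivity:
    acts = {a.label: a for a in region_activities(pair, rois, spec)}
    if label not in acts:
        raise ConfigurationError(f"ROI set lacks the region label '{label}'")
    return acts[label]


def analyze_planar_elements(
    elements: dict[str, tuple[PlanarPair, RoiSet]],
    correction: CorrectionSpec,
) -> DepositionResult:
    """Reduce a full acquisition set to a :class:`DepositionResult`.

    ``elements`` maps the five element names (``nebulizer_full``,
    ``nebulizer_empty``, ``filter``, ``head_ET``, ``lungs_TH``) to their
    planar pair and ROI set; missing elements raise a configuration
    error naming them.
    """
    missing = [e for e in ACQUISITION_SCHEDULE if e not in elements]
    if missing:
        raise ConfigurationError(f"acquisition set lacks elements: {missing}")
    acts = {
        element: _single_region(pair, rois, correction,
                                ELEMENT_REGION[element])
        for element, (pair, rois) in elements.items()
    }
    emitted, _ = nebulizer_emitted(acts["nebulizer_full"],
                                   acts["nebulizer_empty"])
    et = acts["head_ET"].corrected_activity
    th = acts["lungs_TH"].corrected_activity
    filt = acts["filter"].corrected_activity
    et_pct, th_pct = et_th_split(et, th)
    return DepositionResult(
        et_pct=et_pct,
        th_pct=th_pct,
        exhaled_pct_of_emitted=exhaled_fraction(filt, emitted),
        emitted_activity=emitted,
        loaded_activity=acts["nebulizer_full"].corrected_activity,
        unaccounted_pct=mass_balance(
            acts["nebulizer_full"].corrected_activity,
            acts["nebulizer_empty"].corrected_activity, et, th, filt),
    )


def analyze_scene(scene: PlanarScene,
                  correction: CorrectionSpec | None = None) -> DepositionResult:
    """Run the planar pipeline on a synthetic scene (matched corrections
    by default)."""
    return analyze_planar_elements(scene.elements,
                                   correction or scene.correction)


# ---------------------------------------------------------------------------
# reproduction harness


def _recover_impactor(cond: dict, table: StageTable, count_scale: float,
                      replicates: int, rng: np.random.Generator) -> dict:
    amads, gsds = [], []
    aerosol = AerosolSpec(amad=cond["amad"], gsd=cond["gsd"])
    for _ in range(replicates):
        run = sample_impactor_run(aerosol, table, count_scale=count_scale,
                                  seed=rng)
        m = size_metrics(run, table)
        amads.append(m.amad)
        gsds.append(m.gsd)
    return {"amad_um": float(np.median(amads)), "gsd": float(np.median(gsds))}


def reproduce_tables(
    seed: int,
    replicates: int = 50,
    out_dir: str | Path | None = None,
    count_scale: float = 1e5,
    sensitivity: float = 10.0,
) -> dict[str, pd.DataFrame]:
    """Regenerate the study's headline tables from synthetic scenarios.

    For each nebulizer condition: (1) impactor stage data are sampled from
    the configured log-normal and reduced back to AMAD/GSD; (2) planar
    scenes are rendered at the configured deposition partition and pushed
    through the correction chain.  Each table carries configured-truth,
    recovered and recovery-error columns; medians over ``replicates``
    seeds.
    """
    rng = np.random.default_rng(seed)
    table = StageTable.geometric(0.03, 10.0, 50)
    geometry = SceneGeometry(sensitivity=sensitivity)

    rows_t1, rows_t2, rows_f3 = [], [], []
    for size_range, cond in STUDY_CONDITIONS.items():
        rec = _recover_impactor(cond, table, count_scale, replicates, rng)
        rows_t1.append({
            "size_range": size_range, "nebulizer": cond["nebulizer"],
            "amad_configured_um": cond["amad"],
            "amad_recovered_um": rec["amad_um"],
            "amad_error_pct": 100 * (rec["amad_um"] / cond["amad"] - 1),
            "gsd_configured": cond["gsd"], "gsd_recovered": rec["gsd"],
            "gsd_error_pct": 100 * (rec["gsd"] / cond["gsd"] - 1),
        })

        scenario = scenario_from_condition(size_range)
        et, th, ex = [], [], []
        for _ in range(replicates):
            scene = render_planar_scene(scenario, geometry, seed=rng)
            res = analyze_scene(scene)
            et.append(res.et_pct)
            th.append(res.th_pct)
            ex.append(res.exhaled_pct_of_emitted)
        et_s, th_s = replicate_summary(et), replicate_summary(th)
        rows_t2.append({
            "size_range": size_range,
            "et_configured_pct": cond["et_pct"],
            "et_recovered_pct": float(np.median(et)),
            "et_sd_pct": et_s.sd if replicates > 1 else float("nan"),
            "th_configured_pct": cond["th_pct"],
            "th_recovered_pct": float(np.median(th)),
            "th_sd_pct": th_s.sd if replicates > 1 else float("nan"),
            "n": replicates,
        })
        rows_f3.append({
            "size_range": size_range,
            "exhaled_configured_pct": cond["exhaled_pct"],
            "exhaled_recovered_pct": float(np.median(ex)),
            "exhaled_error_points": float(np.median(ex)) - cond["exhaled_pct"],
            "n": replicates,
        })

    tables = {
        "aerosol_metrics": pd.DataFrame(rows_t1),
        "regional_deposition": pd.DataFrame(rows_t2),
        "exhaled_fractions": pd.DataFrame(rows_f3),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out_dir / f"{name}.csv", index=False)
        (out_dir / "provenance.json").write_text(json.dumps(
            provenance(seed=seed) | {"replicates": replicates}, indent=2))
    return tables
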