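"""Staged mechanical re-calibration of an electrically calibrated population.

An electrically calibrated model population is put through mechanical tests
in a fixed order, and models failing a stage are rejected with the stage
recorded:

1. **force_biomarkers** — isometric twitch features (FTTP, FTTr, FTD) at the
   reference preload must fall inside the experimental re-calibration
   ranges.
2. **preload** — steady-state isometric runs at reduced initial lengths
   (0.90, 0.85, 0.80 L_max, descending); any excitation or contraction
   abnormality at any length rejects the model.
3. **LF_curve** — peak isometric force, normalized to the 0.93 L_max value,
   must increase strictly with length (Frank-Starling); ties (within 1e-6)
   count as failure.
4. **afterload** — first afterloaded twitches at 0.25/0.5/0.75 of the
   model's F_max; any AP abnormality or failed contraction rejects, and the
   maximum shortening velocity must decrease strictly with afterload
   (force-velocity relation).

Rejected models never re-enter; per-model length-force and force-velocity
points are recorded for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cell_model import (MechanicalProtocol, ScalingVector, SimulationConfig,
                         afterloaded_twitch, simulate)
from .biomarkers import extract_biomarkers, shortening_metrics
from .abnormality import (detect_ap_abnormalities,
                          detect_contraction_abnormalities)
from .history_matching import (CalibrationCriterion, PopulationRecord,
                               load_criteria, within_minmax)

__all__ = [
    "MechStageReport", "stage_force_biomarkers", "stage_preload",
    "stage_lf_curve", "stage_afterload", "run_mechanical_calibration",
    "STAGE_ORDER",
]

STAGE_ORDER = ("force_biomarkers", "preload", "LF_curve", "afterload", "FV_curve")

#: Preload lengths tested, in descending order (fractions of L_max).
DEFAULT_PRELOADS = (0.90, 0.85, 0.80)
#: Afterload fractions of each model's peak isometric force.
DEFAULT_AFTERLOADS = (0.25, 0.5, 0.75)

_FORCE_TIE_TOL = 1e-6


@dataclass
class MechStageReport:
    """Outcome of one re-calibration stage."""

    stage: str
    models_in: int
    rejected: dict = field(default_factory=dict)    # model_id -> reason
    curves: dict = field(default_factory=dict)      # model_id -> list of points

    @property
    def models_out(self) -> int:
        return self.models_in - len(self.rejected)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"model_id": mid, "stage": self.stage, "decision": "rejected",
                 "reason": reason} for mid, reason in self.rejected.items()]
        return pd.DataFrame(rows, columns=["model_id", "stage", "decision", "reason"])


def _active(population: Sequence[PopulationRecord]):
    return [rec for rec in population if rec.accepted]


def _sv(rec: PopulationRecord) -> ScalingVector:
    return ScalingVector.from_array(rec.scaling)


def stage_force_biomarkers(population: Sequence[PopulationRecord],
                           criteria: Optional[Sequence[CalibrationCriterion]] = None,
                           config: SimulationConfig = SimulationConfig(),
                           ) -> MechStageReport:
    """Reject models whose isometric force biomarkers leave the
    re-calibration [min, max] ranges at the reference preload.

    Each model's reference isometric run is simulated (or reused from
    ``rec.biomarkers["reference"]`` when the force features are present).
    """
    criteria = criteria if criteria is not None else load_criteria(stage="recalibration")
    names = [c.biomarker for c in criteria]
    active = _active(population)
    report = MechStageReport("force_biomarkers", models_in=len(active))
    for rec in active:
        bm = rec.biomarkers.get("reference") or {}
        if not all(bm.get(nm) is not None and np.isfinite(bm.get(nm, np.nan))
                   for nm in names):
            tr = simulate(_sv(rec), MechanicalProtocol(), config)
            if not tr.ok:
                rec.reject("force_biomarkers", "integration_failed")
                report.rejected[rec.model_id] = "integration_failed"
                continue
            bm = extract_biomarkers(tr).as_dict()
            rec.biomarkers["reference"] = {**rec.biomarkers.get("reference", {}), **bm}
        if any(bm.get(nm) is None or not np.isfinite(bm.get(nm, np.nan))
               for nm in names):
            rec.reject("force_biomarkers", "no_twitch")
            report.rejected[rec.model_id] = "no_twitch"
        elif not within_minmax(bm, criteria):
            bad = [c.biomarker for c in criteria
                   if not (c.min <= bm[c.biomarker] <= c.max)]
            reason = "out_of_range:" + ",".join(bad)
            rec.reject("force_biomarkers", reason)
            report.rejected[rec.model_id] = reason
    return report


def stage_preload(population: Sequence[PopulationRecord],
                  lengths: Sequence[float] = DEFAULT_PRELOADS,
                  config: SimulationConfig = SimulationConfig(),
                  ) -> MechStageReport:
    """Steady-state isometric runs at reduced preloads; reject on any
    abnormality at any tested length.  Peak forces per length are stored for
    the following length-force stage."""
    active = _active(population)
    report = MechStageReport("preload", models_in=len(active))
    for rec in active:
        peaks = {}
        reason = None
        for L in lengths:
            tr = simulate(_sv(rec), MechanicalProtocol(initial_length=L), config)
            if not tr.ok:
                reason = f"integration_failed@{L}"
                break
            fl = detect_ap_abnormalities(tr).merge(
                detect_contraction_abnormalities(tr, "isometric"))
            if fl.any:
                which = ",".join(k for k, v in fl.as_dict().items() if v)
                reason = f"abnormal@{L}:{which}"
                break
            n = int(round(tr.cycle_length / tr.sample_dt))
            peaks[L] = float(tr.F_active[-(n + 1):].max())
            rec.biomarkers[f"isometric@{L}"] = extract_biomarkers(tr).as_dict()
        if reason is not None:
            rec.reject("preload", reason)
            report.rejected[rec.model_id] = reason
        else:
            rec.flags["preload_peaks"] = peaks
            report.curves[rec.model_id] = sorted(peaks.items())
    return report


def stage_lf_curve(population: Sequence[PopulationRecord],
                   config: SimulationConfig = SimulationConfig(),
                   reference_length: float = 0.93,
                   ) -> MechStageReport:
    """Reject models whose normalized length-force sequence is not strictly
    increasing in length (peaks normalized to the reference-length value)."""
    active = _active(population)
    report = MechStageReport("LF_curve", models_in=len(active))
    for rec in active:
        peaks = dict(rec.flags.get("preload_peaks", {}))
        if reference_length not in peaks:
            ref_bm = rec.biomarkers.get("reference") or {}
            if ref_bm.get("FTpeak") is not None:
                peaks[reference_length] = float(ref_bm["FTpeak"])
        if reference_length not in peaks:
            tr = simulate(_sv(rec), MechanicalProtocol(initial_length=reference_length),
                          config)
            if not tr.ok:
                rec.reject("LF_curve", "integration_failed")
                report.rejected[rec.model_id] = "integration_failed"
                continue
            n = int(round(tr.cycle_length / tr.sample_dt))
            peaks[reference_length] = float(tr.F_active[-(n + 1):].max())
            rec.flags.setdefault("preload_peaks", {})[reference_length] = peaks[reference_length]
        ref = peaks[reference_length]
        if ref <= 0:
            rec.reject("LF_curve", "no_reference_force")
            report.rejected[rec.model_id] = "no_reference_force"
            continue
        pairs = sorted((L, f / ref) for L, f in peaks.items())
        report.curves[rec.model_id] = pairs
        forces = [f for _, f in pairs]
        if any(b - a <= _FORCE_TIE_TOL for a, b in zip(forces, forces[1:])):
            rec.reject("LF_curve", "non_monotone_LF")
            report.rejected[rec.model_id] = "non_monotone_LF"
    return report


def stage_afterload(population: Sequence[PopulationRecord],
                    afterloads: Sequence[float] = DEFAULT_AFTERLOADS,
                    config: SimulationConfig = SimulationConfig(),
                    ) -> MechStageReport:
    """First afterloaded twitches at each afterload fraction.

    Rejects on AP abnormality or failed contraction at any afterload, and on
    a force-velocity relation that is not strictly decreasing (each check
    separately flagged).  Records (afterload, max shortening velocity)
    points per model.
    """
    active = _active(population)
    report = MechStageReport("afterload", models_in=len(active))
    for rec in active:
        baseline = simulate(_sv(rec), MechanicalProtocol(), config)
        if not baseline.ok:
            rec.reject("afterload", "integration_failed")
            report.rejected[rec.model_id] = "integration_failed"
            continue
        vels = []
        reason = None
        for a in sorted(afterloads):
            tw = afterloaded_twitch(_sv(rec), a, config, baseline=baseline)
            if tw.status == "integration_failed":
                reason = f"integration_failed@{a}"
                break
            fl = detect_ap_abnormalities(tw).merge(
                detect_contraction_abnormalities(tw, "afterloaded"))
            if fl.any:
                which = ",".join(k for k, v in fl.as_dict().items() if v)
                reason = f"abnormal@{a}:{which}"
                break
            _, vel = shortening_metrics(tw)
            vels.append((a, vel))
        if reason is None and vels:
            report.curves[rec.model_id] = vels
            v = [x for _, x in vels]
            if any(b >= a for a, b in zip(v, v[1:])):
                reason = "non_monotone_FV"
        if reason is not None:
            rec.reject("afterload", reason)
            report.rejected[rec.model_id] = reason
        else:
            rec.flags["fv_points"] = vels
    return report


def run_mechanical_calibration(population: Sequence[PopulationRecord],
                               criteria: Optional[Sequence[CalibrationCriterion]] = None,
                               preloads: Sequence[float] = DEFAULT_PRELOADS,
                               afterloads: Sequence[float] = DEFAULT_AFTERLOADS,
                               config: SimulationConfig = SimulationConfig(),
                               ):
    """Apply all stages in order; returns (accepted records, stage reports).

    Every record keeps its final status; |accepted| plus the per-stage
    rejections always equals the input size.
    """
    reports = [
        stage_force_biomarkers(population, criteria, config),
        stage_preload(population, preloads, config),
        stage_lf_curve(population, config),
        stage_afterload(population, afterloads, config),
    ]
    return _active(population), reports
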