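"""Biomarker extraction from paced traces.

Extracts the action-potential, calcium-transient, force and shortening
features used to calibrate and re-calibrate the model population:

* AP: resting membrane potential (RMP, minimum V over the 50 ms preceding the
  last stimulus), peak voltage, maximum upstroke velocity, APD at 20/40/50/90 %
  repolarization measured from the activation time (time of max dV/dt), and
  triangulation Tri9040 = APD90 - APD40.
* Ca2+ transient: diastolic and peak levels (CTmin, CTmax), time to peak from
  the 10 %-of-amplitude upstroke onset (CaTTP), and durations CTD50/CTD80 from
  that onset to 50 %/80 % decay from peak toward CTmin.
* Isometric force: diastolic and peak levels (FTd, FTpeak, in units of the
  reference model's peak force), time to peak from the tangent-intercept
  twitch onset (FTTP), time from peak to 90 % decay (FTTr), and twitch
  duration FTD (force above diastolic + 5 % of twitch amplitude).
* Afterloaded shortening: amplitude (L_init - L_min)/L_init and maximum
  shortening velocity in L_max/s (central differences).

All threshold crossings are linearly interpolated; ties break toward the
earlier sample.  Missing events set flags instead of numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .cell_model import Trace

__all__ = ["BiomarkerSet", "extract_biomarkers", "apd", "shortening_metrics"]

#: Minimum AP amplitude (mV) for an AP to be considered present.
AP_AMPLITUDE_MIN = 30.0
#: Minimum Ca2+ transient amplitude (uM) for a transient to be present.
CA_AMPLITUDE_MIN = 0.05
#: Minimum force twitch amplitude (normalized) for a twitch to be present.
FORCE_AMPLITUDE_MIN = 0.01


@dataclass
class BiomarkerSet:
    """Flat record of per-model biomarkers for one protocol run.

    Fields are ``None`` (with the matching flag set) when the respective
    signal shows no event.
    """

    RMP: Optional[float] = None          # mV
    Vpeak: Optional[float] = None        # mV
    dVdtmax: Optional[float] = None      # mV/ms
    APD20: Optional[float] = None        # ms
    APD40: Optional[float] = None
    APD50: Optional[float] = None
    APD90: Optional[float] = None
    Tri9040: Optional[float] = None
    CTmin: Optional[float] = None        # uM
    CTmax: Optional[float] = None
    CaTTP: Optional[float] = None        # ms
    CTD50: Optional[float] = None
    CTD80: Optional[float] = None
    FTd: Optional[float] = None          # normalized force
    FTpeak: Optional[float] = None
    FTTP: Optional[float] = None         # ms
    FTTr: Optional[float] = None
    FTD: Optional[float] = None
    shortening_amplitude: Optional[float] = None   # fraction of initial length
    max_shortening_velocity: Optional[float] = None  # L_max/s
    flags: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = asdict(self)
        d.pop("flags")
        return d

    def get(self, name: str):
        return getattr(self, name)


def _interp_crossing_down(t, y, level, start):
    """First time at/after index ``start`` where y falls to <= level."""
    idx = np.nonzero(y[start:] <= level)[0]
    if idx.size == 0:
        return None
    j = start + idx[0]
    if j == start or y[j - 1] <= level:
        return t[j] if y[j] < level else t[j]
    y1, y2 = y[j - 1], y[j]
    fr = (y1 - level) / (y1 - y2)
    return t[j - 1] + fr * (t[j] - t[j - 1])


def _interp_crossing_up(t, y, level, start, stop=None):
    """First time at/after ``start`` where y rises to >= level."""
    seg = y[start:stop]
    idx = np.nonzero(seg >= level)[0]
    if idx.size == 0:
        return None
    j = start + idx[0]
    if j == start or y[j - 1] >= level:
        return t[j]
    y1, y2 = y[j - 1], y[j]
    fr = (level - y1) / (y2 - y1)
    return t[j - 1] + fr * (t[j] - t[j - 1])


def _last_cycle(trace: Trace):
    """Indices of the final full cycle and of the pre-stimulus baseline."""
    if trace.time.size < 2:
        raise ValueError("trace shorter than one cycle")
    dt = np.diff(trace.time)
    if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-9):
        raise ValueError("non-uniform timebase")
    if trace.stim_times.size < 1:
        raise ValueError("trace has no stimulus markers")
    t_stim = trace.stim_times[-1]
    i_stim = int(np.searchsorted(trace.time, t_stim - 1e-9))
    if trace.time.size - i_stim < 2:
        raise ValueError("trace shorter than one cycle after last stimulus")
    return i_stim


def apd(trace: Trace, repolarization_fraction: float) -> Optional[float]:
    """AP duration of the final cycle at the given repolarization fraction.

    Measured from the activation time (max dV/dt within the cycle) to the
    first post-peak time where V falls to
    ``Vpeak - fraction * (Vpeak - RMP)``, linearly interpolated.  Returns
    ``None`` when the AP never repolarizes to that level before the trace
    ends (failed repolarization) or when there is no AP.
    """
    bm = extract_biomarkers(trace, _ap_only=True)
    if bm.flags.get("no_AP"):
        return None
    return _apd_from_cycle(trace, repolarization_fraction)


def _apd_from_cycle(trace: Trace, frac: float) -> Optional[float]:
    i0 = _last_cycle(trace)
    t = trace.time[i0:]
    v = trace.V[i0:]
    dv = np.diff(v)
    iact = int(np.argmax(dv))
    ipk = iact + int(np.argmax(v[iact:]))
    rmp = _rmp(trace, i0)
    vpeak = v[ipk]
    level = vpeak - frac * (vpeak - rmp)
    tc = _interp_crossing_down(t, v, level, ipk)
    if tc is None:
        return None
    return float(tc - t[iact])


def _rmp(trace: Trace, i_stim: int) -> float:
    """Minimum V over the 50 ms preceding the last stimulus."""
    n50 = max(1, int(round(50.0 / trace.sample_dt)))
    lo = max(0, i_stim - n50)
    return float(trace.V[lo:i_stim + 1].min())


def shortening_metrics(trace: Trace):
    """(amplitude, max velocity) of an afterloaded twitch.

    Amplitude is the relative shortening (L_init - L_min)/L_init; velocity is
    the maximum of -dL/dt over the shortening phase in L_max/s, estimated
    with central differences.  An isometric (constant-length) trace yields
    (0.0, 0.0).
    """
    L = trace.L
    L_init = float(L[0])
    L_min = float(L.min())
    if L_min >= L_init - 1e-12:
        return 0.0, 0.0
    amplitude = (L_init - L_min) / L_init
    dLdt = np.gradient(L, trace.sample_dt)          # frac/ms
    vel = float(np.max(-dLdt)) * 1000.0             # L_max/s
    return amplitude, max(vel, 0.0)


def extract_biomarkers(trace: Trace, _ap_only: bool = False) -> BiomarkerSet:
    """Extract the full biomarker set from the final cycle of a trace.

    Flags set instead of numbers: ``no_AP``, ``failed_repolarization``,
    ``no_transient``, ``no_twitch``.
    """
    bm = BiomarkerSet()
    i0 = _last_cycle(trace)
    t = trace.time[i0:]
    dt = trace.sample_dt

    # ---- action potential ----
    v = trace.V[i0:]
    rmp = _rmp(trace, i0)
    bm.RMP = rmp
    vpeak = float(v.max())
    if vpeak - rmp < AP_AMPLITUDE_MIN:
        bm.flags["no_AP"] = True
        bm.RMP = rmp
        bm.Vpeak = None
    else:
        bm.Vpeak = vpeak
        dvdt = np.diff(v) / dt
        sum_dv = trace.summaries.get("dVdt_max") if trace.summaries else None
        if sum_dv is not None and np.ndim(sum_dv) and np.isfinite(sum_dv[-1]):
            bm.dVdtmax = float(sum_dv[-1])
        else:
            bm.dVdtmax = float(dvdt.max())
        apds = {}
        for frac, nm in ((0.2, "APD20"), (0.4, "APD40"), (0.5, "APD50"), (0.9, "APD90")):
            val = _apd_from_cycle(trace, frac)
            apds[nm] = val
            setattr(bm, nm, val)
        if apds["APD90"] is None:
            bm.flags["failed_repolarization"] = True
        if apds["APD90"] is not None and apds["APD40"] is not None:
            bm.Tri9040 = apds["APD90"] - apds["APD40"]
    if _ap_only:
        return bm

    # ---- calcium transient ----
    ca = trace.Cai[i0:]
    ctmin = float(ca.min())
    ctmax = float(ca.max())
    bm.CTmin = ctmin
    bm.CTmax = ctmax
    amp_ca = ctmax - ctmin
    if amp_ca < CA_AMPLITUDE_MIN:
        bm.flags["no_transient"] = True
    else:
        ipk = int(np.argmax(ca))
        t_on = _interp_crossing_up(t, ca, ctmin + 0.1 * amp_ca, 0, ipk + 1)
        if t_on is not None:
            bm.CaTTP = float(t[ipk] - t_on)
            for frac, nm in ((0.5, "CTD50"), (0.8, "CTD80")):
                level = ctmax - frac * amp_ca
                tc = _interp_crossing_down(t, ca, level, ipk)
                if tc is not None:
                    setattr(bm, nm, float(tc - t_on))

    # ---- isometric force twitch ----
    fa = trace.F_active[i0:]
    fd = float(fa.min())
    fpk = float(fa.max())
    bm.FTd = fd
    bm.FTpeak = fpk
    amp_f = fpk - fd
    if amp_f < FORCE_AMPLITUDE_MIN:
        bm.flags["no_twitch"] = True
    else:
        ipk = int(np.argmax(fa))
        # tangent-intercept onset: steepest rise before the peak projected
        # back to the diastolic level (exact for a linear rise)
        dfdt = np.diff(fa[:ipk + 1]) / dt
        if dfdt.size and dfdt.max() > 0:
            imx = int(np.argmax(dfdt))
            slope = dfdt[imx]
            t_mid = t[imx] + 0.5 * dt
            f_mid = 0.5 * (fa[imx] + fa[imx + 1])
            t_on = t_mid - (f_mid - fd) / slope
            bm.FTTP = float(t[ipk] - t_on)
        level90 = fpk - 0.9 * amp_f
        tc = _interp_crossing_down(t, fa, level90, ipk)
        if tc is not None:
            bm.FTTr = float(tc - t[ipk])
        # twitch duration: force above diastolic + 5 % of amplitude
        level5 = fd + 0.05 * amp_f
        t_up = _interp_crossing_up(t, fa, level5, 0, ipk + 1)
        t_dn = _interp_crossing_down(t, fa, level5, ipk)
        if t_up is not None and t_dn is not None:
            bm.FTD = float(t_dn - t_up)

    # ---- shortening (afterloaded runs) ----
    amp, vel = shortening_metrics(trace)
    bm.shortening_amplitude = amp
    bm.max_shortening_velocity = vel
    return bm
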