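"""Excitation and contraction abnormality detectors.

These are the rejection criteria applied throughout the population pipeline:
early and delayed afterdepolarizations (EAD/DAD), premature action
potentials, failed repolarization, APD alternans, spontaneous diastolic SR
Ca2+ release, double-peak contractions, and failed (<1 % shortening)
afterloaded contractions.  Detectors are pure functions of the trace,
evaluated over the last two paced cycles.

The abnormality classes come from the experimental-rejection protocol of the
population study; the numeric thresholds below are this package's documented
operational defaults (the classes themselves carry no published criteria).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.signal import find_peaks

from .cell_model import Trace, _quick_apd
from . import biomarkers as bmk

__all__ = [
    "AbnormalityThresholds",
    "AbnormalityFlags",
    "detect_ap_abnormalities",
    "detect_contraction_abnormalities",
    "check_steady_state",
    "DEFAULT_THRESHOLDS",
]


@dataclass(frozen=True)
class AbnormalityThresholds:
    """Operational thresholds of the detectors (package defaults, frozen)."""

    ead_min_rise_mV: float = 2.0        # secondary rise amplitude
    ead_min_duration_ms: float = 5.0    # sustained positive dV/dt
    dad_min_rise_mV: float = 2.0        # rise above diastolic baseline
    premature_level_mV: float = -20.0   # upstroke crossing outside stimulus
    stim_window_ms: float = 25.0        # window attributed to the stimulus
    alternans_dAPD90_ms: float = 5.0
    diastole_max_mV: float = -60.0      # pre-stimulus V above this = failed repol.
    double_peak_prominence: float = 0.10   # fraction of twitch amplitude
    failed_contraction_amp: float = 0.01   # isotonic shortening < 1 %
    spont_ca_prominence: float = 0.05      # fraction of transient amplitude
    steady_state_rtol: float = 0.01


DEFAULT_THRESHOLDS = AbnormalityThresholds()


@dataclass
class AbnormalityFlags:
    """Boolean abnormality flags plus free-text detail per firing flag."""

    EAD: bool = False
    DAD: bool = False
    premature_AP: bool = False
    failed_repolarization: bool = False
    APD_alternans: bool = False
    double_peak_contraction: bool = False
    failed_contraction: bool = False
    spontaneous_Ca_release: bool = False
    failed_excitation: bool = False
    detail: dict = field(default_factory=dict)

    @property
    def any(self) -> bool:
        return any(
            getattr(self, k)
            for k in (
                "EAD", "DAD", "premature_AP", "failed_repolarization",
                "APD_alternans", "double_peak_contraction",
                "failed_contraction", "spontaneous_Ca_release",
                "failed_excitation",
            )
        )

    def as_dict(self) -> dict:
        d = asdict(self)
        d.pop("detail")
        return d

    def merge(self, other: "AbnormalityFlags") -> "AbnormalityFlags":
        out = AbnormalityFlags()
        for k in out.as_dict():
            setattr(out, k, getattr(self, k) or getattr(other, k))
        out.detail = {**self.detail, **other.detail}
        return out


def _cycle_bounds(trace: Trace):
    """(start, stop) sample indices of the last two cycles (or the single
    cycle for one-cycle traces such as afterloaded twitches)."""
    n = int(round(trace.cycle_length / trace.sample_dt))
    total = trace.V.size
    if total < n + 1:
        raise ValueError("trace must hold at least 1 full paced cycle")
    if total < 2 * n + 1:
        return [(total - 1 - n, total - 1)]
    return [(total - 1 - 2 * n, total - 1 - n), (total - 1 - n, total - 1)]


def _sustained_rises(v, dt, min_rise, min_dur):
    """Segments of (cumulative rise, duration) for runs of positive dV/dt."""
    dv = np.diff(v)
    rises = []
    i = 0
    while i < dv.size:
        if dv[i] > 0:
            j = i
            while j < dv.size and dv[j] > -1e-12:
                j += 1
            rise = float(v[j] - v[i])
            dur = (j - i) * dt
            if rise >= min_rise and dur >= min_dur:
                rises.append((rise, dur, i))
            i = j
        else:
            i += 1
    return rises


def detect_ap_abnormalities(trace: Trace,
                            thresholds: AbnormalityThresholds = DEFAULT_THRESHOLDS,
                            ) -> AbnormalityFlags:
    """Detect AP abnormalities over the last two paced cycles.

    EAD: a secondary sustained depolarization between 10 % and 90 %
    repolarization.  DAD: a rise above the diastolic baseline after 90 %
    repolarization and before the next stimulus.  Premature AP: an upward
    crossing of the premature level outside any stimulus window.  Failed
    repolarization: the AP never reaches 90 % repolarization before the next
    stimulus, or the pre-stimulus potential stays depolarized.  Alternans:
    APD90 differs by more than the threshold between the last two cycles.
    """
    th = thresholds
    flags = AbnormalityFlags()
    dt = trace.sample_dt

    bm = bmk.extract_biomarkers(trace, _ap_only=True)
    if bm.flags.get("no_AP"):
        # distinguish an unexcitable cell from one stuck depolarized
        if bm.RMP is not None and bm.RMP > th.diastole_max_mV:
            flags.failed_repolarization = True
            flags.detail["failed_repolarization"] = (
                f"diastolic V {bm.RMP:.1f} mV above {th.diastole_max_mV} mV")
        else:
            flags.failed_excitation = True
            flags.detail["failed_excitation"] = "no AP fired"
        return flags

    apd90s = []
    for (lo, hi) in _cycle_bounds(trace):
        v = trace.V[lo:hi + 1]
        vrest = float(v.min())
        dv = np.diff(v)
        iact = int(np.argmax(dv))
        ipk = iact + int(np.argmax(v[iact:]))
        vpeak = float(v[ipk])
        amp = vpeak - vrest
        if amp < bmk.AP_AMPLITUDE_MIN:
            continue
        lev10 = vpeak - 0.1 * amp
        lev90 = vpeak - 0.9 * amp

        # repolarization window: first fall below 10 % level to first fall
        # below the 90 % level
        post = v[ipk:]
        i10 = np.nonzero(post <= lev10)[0]
        i90 = np.nonzero(post <= lev90)[0]
        apd90s.append(_quick_apd(v, dt, 0.9))
        if i90.size == 0:
            flags.failed_repolarization = True
            flags.detail["failed_repolarization"] = "never reached 90% repolarization"
            continue
        if i10.size:
            a = ipk + int(i10[0])
            b = ipk + int(i90[0])
            if b > a + 1:
                for rise, dur, off in _sustained_rises(
                        v[a:b + 1], dt, th.ead_min_rise_mV, th.ead_min_duration_ms):
                    flags.EAD = True
                    flags.detail["EAD"] = (
                        f"rise {rise:.1f} mV over {dur:.0f} ms during repolarization")
                    break

        # diastolic segment: after 90 % repolarization up to cycle end
        b = ipk + int(i90[0])
        dia = v[b:]
        if dia.size > 2:
            baseline = np.minimum.accumulate(dia)
            exc = dia - baseline
            if float(exc.max()) >= th.dad_min_rise_mV:
                # exclude the next stimulus artifact: the diastolic segment
                # ends at the cycle boundary, so any rise here is unstimulated
                flags.DAD = True
                flags.detail["DAD"] = f"diastolic rise {float(exc.max()):.1f} mV"

        # premature AP: upward crossings of the premature level outside the
        # stimulus window at the cycle start
        t_rel = np.arange(v.size) * dt
        crossings = np.nonzero((v[:-1] < th.premature_level_mV)
                               & (v[1:] >= th.premature_level_mV))[0]
        for c in crossings:
            if t_rel[c] > th.stim_window_ms:
                flags.premature_AP = True
                flags.detail["premature_AP"] = f"upstroke at +{t_rel[c]:.0f} ms"
                break

        # depolarized diastole right before the next stimulus
        n50 = max(1, int(round(50.0 / dt)))
        if float(v[-n50:].min()) > th.diastole_max_mV:
            flags.failed_repolarization = True
            flags.detail["failed_repolarization"] = "depolarized pre-stimulus diastole"

    if len(apd90s) == 2 and all(a is not None and np.isfinite(a) for a in apd90s):
        if abs(apd90s[1] - apd90s[0]) > th.alternans_dAPD90_ms:
            flags.APD_alternans = True
            flags.detail["APD_alternans"] = (
                f"APD90 {apd90s[0]:.0f} -> {apd90s[1]:.0f} ms")

    # spontaneous SR Ca release: secondary Cai peak during decay or diastole
    lo, hi = _cycle_bounds(trace)[-1]
    ca = trace.Cai[lo:hi + 1]
    amp_ca = float(ca.max() - ca.min())
    if amp_ca >= bmk.CA_AMPLITUDE_MIN:
        ipk = int(np.argmax(ca))
        tail = ca[ipk:]
        pk, _ = find_peaks(tail, prominence=th.spont_ca_prominence * amp_ca)
        if pk.size:
            flags.spontaneous_Ca_release = True
            flags.detail["spontaneous_Ca_release"] = (
                f"{pk.size} secondary Cai peak(s) after the transient peak")
    return flags


def detect_contraction_abnormalities(trace: Trace, mode: str = "isometric",
                                     thresholds: AbnormalityThresholds = DEFAULT_THRESHOLDS,
                                     ) -> AbnormalityFlags:
    """Detect contraction abnormalities.

    Double-peak contraction: two or more local maxima of the twitch signal
    (force in isometric mode, shortening in afterloaded mode) with prominence
    of at least 10 % of the twitch amplitude within one cycle.  Failed
    contraction (afterloaded mode): isotonic shortening amplitude below 1 %.
    """
    th = thresholds
    flags = AbnormalityFlags()
    lo, hi = _cycle_bounds(trace)[-1] if trace.V.size >= 2 * int(
        round(trace.cycle_length / trace.sample_dt)) else (0, trace.V.size - 1)
    if mode == "afterloaded":
        signal = trace.L[0] - trace.L  # shortening, positive downward
        amp, _ = bmk.shortening_metrics(trace)
        if amp < th.failed_contraction_amp:
            flags.failed_contraction = True
            flags.detail["failed_contraction"] = f"shortening {amp:.4f} < 1%"
    else:
        signal = trace.F_active[lo:hi + 1]
    s_amp = float(signal.max() - signal.min())
    if s_amp > 0:
        pk, _ = find_peaks(signal, prominence=th.double_peak_prominence * s_amp)
        if pk.size >= 2:
            flags.double_peak_contraction = True
            flags.detail["double_peak_contraction"] = f"{pk.size} peaks"
    return flags


def check_steady_state(summaries: dict, tolerance: float = 0.01) -> bool:
    """True iff APD90, peak Cai and peak force each changed by less than
    ``tolerance`` (relative) between the last two cycles."""
    for key in ("APD90", "peak_Cai", "peak_F"):
        vals = np.asarray(summaries[key], dtype=float)
        if vals.size < 2:
            raise ValueError("need summaries of at least 2 cycles")
        a, b = vals[-2], vals[-1]
        if not (np.isfinite(a) and np.isfinite(b)):
            return False
        denom = max(abs(a), 1e-12)
        if abs(b - a) / denom >= tolerance:
            return False
    return True
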