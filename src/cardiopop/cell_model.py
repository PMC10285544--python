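"""Paced electro-mechanical ventricular cardiomyocyte simulator.

The simulator is a phenomenological surrogate of a human ventricular
excitation-contraction model.  It exposes the same parameter interface as the
full published model family it stands in for: eleven multiplicatively scaled
parameters (five ionic conductances, the NKX and NCX maximal currents, the
SERCA uptake rate, and three ryanodine-receptor rate constants) plus a
per-channel pore-block vector for drug studies.  The electrophysiology block is
a reduced Hodgkin-Huxley formulation (I_Na, I_CaL, I_Kr, I_Ks, I_K1, I_NaK,
I_NCX and a small background current); SR calcium release goes through an
explicit Markov ryanodine-receptor gate (open/inactivated states, rates k_s,
k_im, k_om).  The mechanics block is an Ekaterinburg-style contractile element:
calcium-troponin C (CaTnC) buffering with cooperative slow-down of CaTnC decay
when many cross-bridges are attached, a cross-bridge attachment ODE whose
attach rate depends on sarcomere overlap, a linear force-velocity factor, and
an exponential parallel elastic element.  TnC buffering feeds back into the
cytosolic Ca2+ ODE, closing the mechano-calcium-electric loop.

Supported protocols: steady-state isometric twitches at a fixed cell length
(fraction of L_max, reference 0.93 L_max), and afterloaded isotonic twitches
launched from the isometric steady state, where the cell shortens under a
constant external load once active force reaches the afterload and
re-lengthens back to the initial length during relaxation.

Rate constants of the surrogate are tuned once so the all-ones (reference)
model satisfies every calibration range of the packaged experimental biomarker
table; the tuned values are frozen in ``REFERENCE_PARAMS`` (also shipped as
``data/reference_model.json``).

Integration uses a fixed-step classical Runge-Kutta scheme compiled with
numba: 0.02 ms steps during the first 10 ms of each pacing cycle (upstroke),
0.1 ms elsewhere, dense output resampled at the configured sampling step.
Halving both steps moves APD90 of the reference model by well under 0.1 ms.
The fixed step makes repeated runs bit-identical, which the population
pipeline relies on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from importlib import resources
from typing import Optional

import numpy as np
from numba import njit

__all__ = [
    "PARAM_NAMES",
    "REFERENCE_PARAMS",
    "ScalingVector",
    "DrugBlockVector",
    "MechanicalProtocol",
    "SimulationConfig",
    "CellState",
    "Trace",
    "simulate",
    "afterloaded_twitch",
    "peak_isometric_force",
    "isometric_steady_state",
    "REFERENCE_PEAK_FORCE",
]

# ---------------------------------------------------------------------------
# Scaled parameters and reference constants
# ---------------------------------------------------------------------------

#: The 11 multiplicatively scaled parameters, in canonical order.
PARAM_NAMES = (
    "gNa", "gCaL", "gK1", "gKs", "gKr",
    "Vmaxup", "KNaCa", "PNaK", "ks", "kim", "kom",
)


def _load_reference_params() -> dict:
    with resources.files("cardiopop").joinpath("data/reference_model.json").open() as fh:
        return json.load(fh)["parameters"]


#: Frozen reference constants of the surrogate (units in data file).
REFERENCE_PARAMS = _load_reference_params()

#: Peak active isometric force of the reference model at 0.93 L_max, in raw
#: model units; all reported forces are normalized by this value.
REFERENCE_PEAK_FORCE = REFERENCE_PARAMS["reference_peak_force"]

# Indices into the packed parameter vector handed to the numba kernel.
_NP = 37
(_I_GNA, _I_GCAL, _I_GK1, _I_GKS, _I_GKR, _I_VUP, _I_VNCX, _I_PNAK,
 _I_KS, _I_KIM, _I_KOM, _I_GNAB, _I_KCAL, _I_KLEAK, _I_VSR, _I_KACT,
 _I_KACTH, _I_EC50SR, _I_KICA, _I_BTOT, _I_AON, _I_AOFF, _I_ALPHAX,
 _I_KPX, _I_KMX, _I_BH, _I_NH, _I_V0, _I_FSCALE, _I_CPAS, _I_SPAS,
 _I_CVDET, _I_FREEZE, _I_OV0, _I_FCAH, _I_KUP, _I_KBGCA) = range(_NP)

_PACK_ORDER = (
    "gNa", "gCaL", "gK1", "gKs", "gKr", "Vmaxup", "KNaCa", "PNaK",
    "ks", "kim", "kom", "gNab", "kcal", "kleak", "vsr_ratio", "kact",
    "kact_half", "ec50_sr", "ki_ca", "Btot", "a_on", "a_off", "alpha_xb",
    "kp_xb", "km_xb", "B_half", "n_hill", "v0", "f_scale", "c_pas",
    "s_pas", "cv_detach", "_freeze", "overlap_zero", "fca_half", "K_up",
    "k_bgca",
)

_N_STATE = 14  # V, m, h, d, f, xr, xs, Cai, CaSR, O, Iry, B, N, L


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScalingVector:
    """Dimensionless multiplicative factors on the 11 varied parameters.

    The all-ones vector reproduces the reference model exactly.  Factors are
    restricted to [0, 2], the sampling interval of the population study.
    """

    gNa: float = 1.0
    gCaL: float = 1.0
    gK1: float = 1.0
    gKs: float = 1.0
    gKr: float = 1.0
    Vmaxup: float = 1.0
    KNaCa: float = 1.0
    PNaK: float = 1.0
    ks: float = 1.0
    kim: float = 1.0
    kom: float = 1.0

    def __post_init__(self):
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0.0 or v > 2.0:
                raise ValueError(f"scaling factor {name}={v!r} outside [0, 2]")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "ScalingVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected {len(PARAM_NAMES)} factors, got shape {arr.shape}")
        return cls(**dict(zip(PARAM_NAMES, arr.tolist())))


@dataclass(frozen=True)
class DrugBlockVector:
    """Remaining-conductance factors of the pore-block drug model.

    Each factor lies in [0, 1] and multiplies the corresponding channel
    conductance on top of the scaling vector; 1.0 everywhere is drug-free.
    """

    INa: float = 1.0
    ICaL: float = 1.0
    IKr: float = 1.0
    IKs: float = 1.0

    def __post_init__(self):
        for name in ("INa", "ICaL", "IKr", "IKs"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"block factor {name}={v!r} outside [0, 1]")


@dataclass(frozen=True)
class MechanicalProtocol:
    """Mechanical boundary conditions of a paced run.

    mode
        "isometric": cell length clamped at ``initial_length`` (fraction of
        L_max, where L_max maps to a sarcomere length of 2.23 um).
        "afterloaded": isometric until active force reaches the afterload,
        then isotonic shortening at constant total force, then isometric
        again once the initial length is re-attained.
    afterload
        Fraction of the model's own peak isometric force F_max (afterloaded
        mode only).
    """

    mode: str = "isometric"
    initial_length: float = 0.93
    afterload: Optional[float] = None

    def __post_init__(self):
        if self.mode not in ("isometric", "afterloaded"):
            raise ValueError(f"unknown protocol mode {self.mode!r}")
        if not 0.80 <= self.initial_length <= 0.95:
            raise ValueError("initial_length must be within [0.80, 0.95] L_max")
        if (self.afterload is not None) != (self.mode == "afterloaded"):
            raise ValueError("afterload must be given iff mode='afterloaded'")
        if self.afterload is not None and not 0.0 < self.afterload <= 1.0:
            raise ValueError("afterload must lie in (0, 1] of F_max")


@dataclass(frozen=True)
class SimulationConfig:
    """Pacing, sampling and solver settings.

    Defaults follow the population protocol: 200 cycles at 1 Hz pacing to
    reach steady-state contractions, output resampled at 0.5 ms.
    """

    pacing_hz: float = 1.0
    n_cycles: int = 200
    sample_dt: float = 0.5          # ms
    stim_amplitude: float = 112.0   # mV/ms, 2x the diastolic threshold
    stim_duration: float = 1.0      # ms
    dt_fast: float = 0.02           # ms, first 10 ms of each cycle
    dt_slow: float = 0.1            # ms, remainder of the cycle
    steady_state_tol: float = 0.01  # relative cycle-to-cycle tolerance

    def __post_init__(self):
        if self.n_cycles < 2:
            raise ValueError("n_cycles must be >= 2")
        if self.dt_fast <= 0 or self.dt_slow <= 0 or self.sample_dt <= 0:
            raise ValueError("step sizes must be positive")
        cl = self.cycle_length
        if abs(cl / self.sample_dt - round(cl / self.sample_dt)) > 1e-9:
            raise ValueError("sample_dt must divide the cycle length")

    @property
    def cycle_length(self) -> float:
        return 1000.0 / self.pacing_hz


class CellState:
    """Opaque, serializable snapshot of the ODE state vector."""

    __slots__ = ("values",)

    def __init__(self, values):
        arr = np.asarray(values, dtype=float)
        if arr.shape != (_N_STATE,):
            raise ValueError(f"state must have {_N_STATE} entries")
        self.values = arr.copy()

    def to_json(self) -> str:
        # repr-level floats round-trip bit-exactly through json
        return json.dumps({"state": self.values.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "CellState":
        return cls(json.loads(text)["state"])

    def __eq__(self, other):
        return isinstance(other, CellState) and np.array_equal(self.values, other.values)


@dataclass
class Trace:
    """Uniformly sampled output of a paced simulation.

    Arrays cover the last two full cycles (``time`` in ms from the start of
    the run); ``summaries`` holds per-cycle scalars for every cycle.  Force is
    normalized to the reference model's peak isometric force at 0.93 L_max;
    cell length is a fraction of L_max.
    """

    time: np.ndarray
    V: np.ndarray
    Cai: np.ndarray
    F_active: np.ndarray
    F_total: np.ndarray
    L: np.ndarray
    stim_times: np.ndarray          # onsets within the returned window
    cycle_length: float
    sample_dt: float
    summaries: dict                 # arrays keyed by cycle-scalar name
    status: str = "ok"              # "ok" | "integration_failed" | "never_lifted"
    final_state: Optional[CellState] = None
    meta: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status in ("ok", "never_lifted")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_ms": self.time,
                "V_mV": self.V,
                "Cai_uM": self.Cai,
                "F_active": self.F_active,
                "F_total": self.F_total,
                "L_frac": self.L,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_npz(self, path) -> None:
        np.savez_compressed(
            path,
            time=self.time, V=self.V, Cai=self.Cai,
            F_active=self.F_active, F_total=self.F_total, L=self.L,
            stim_times=self.stim_times,
            cycle_length=self.cycle_length, sample_dt=self.sample_dt,
        )

    @classmethod
    def from_csv(cls, path, cycle_length: float) -> "Trace":
        import pandas as pd

        df = pd.read_csv(path)
        t = df["time_ms"].to_numpy()
        dt = float(t[1] - t[0])
        t0 = t[0]
        stim = np.arange(np.ceil(t0 / cycle_length) * cycle_length, t[-1], cycle_length)
        return cls(
            time=t, V=df["V_mV"].to_numpy(), Cai=df["Cai_uM"].to_numpy(),
            F_active=df["F_active"].to_numpy(), F_total=df["F_total"].to_numpy(),
            L=df["L_frac"].to_numpy(), stim_times=stim,
            cycle_length=cycle_length, sample_dt=dt, summaries={},
        )


# ---------------------------------------------------------------------------
# Numba kernel
# ---------------------------------------------------------------------------

_E_NA = 65.0
_E_K = -88.0
_E_CA = 60.0


@njit(cache=True, fastmath=False)
def _rhs(y, P, stim, phase, F_aft, dy):
    """Time derivative; returns (F_active, F_total, v_shortening)."""
    V = y[0]; m = y[1]; h = y[2]; d = y[3]; f = y[4]
    xr = y[5]; xs = y[6]; Cai = y[7]; CaSR = y[8]
    O = y[9]; Iry = y[10]; B = y[11]; N = y[12]; L = y[13]

    # --- mechanics first (force needed for isotonic velocity) ---
    ov = (L - P[_I_OV0]) / (0.93 - P[_I_OV0])
    if ov < 0.0:
        ov = 0.0
    elif ov > 1.2:
        ov = 1.2
    Fp = P[_I_CPAS] * (np.exp(P[_I_SPAS] * (L - 0.78)) - 1.0)
    v0 = P[_I_V0]
    if phase == 1:
        Fdrive = P[_I_FSCALE] * N
        if Fdrive > 1e-12:
            v = v0 * (1.0 - (F_aft - Fp) / Fdrive)
        else:
            v = -0.008
        if v > v0:
            v = v0
        elif v < -0.008:
            v = -0.008
    else:
        v = 0.0
    lamv = 1.0 - v / v0
    if lamv > 1.4:
        lamv = 1.4
    elif lamv < 0.0:
        lamv = 0.0
    Fa = P[_I_FSCALE] * N * lamv
    Ft = Fa + Fp

    # --- ionic currents ---
    minf = 1.0 / (1.0 + np.exp(-(V + 40.0) / 6.0))
    hinf = 1.0 / (1.0 + np.exp((V + 70.0) / 6.0))
    tauh = 0.8 + 7.0 / (1.0 + np.exp((V + 40.0) / 8.0))
    dinf = 1.0 / (1.0 + np.exp(-(V + 10.0) / 6.0))
    finf = 1.0 / (1.0 + np.exp((V + 25.0) / 6.0))
    tauf = 30.0 + 170.0 / (1.0 + np.exp(-(V + 20.0) / 7.0))
    xrinf = 1.0 / (1.0 + np.exp(-(V + 20.0) / 7.0))
    xsinf = 1.0 / (1.0 + np.exp(-(V - 5.0) / 14.0))
    fca = 1.0 / (1.0 + (Cai / P[_I_FCAH]) * (Cai / P[_I_FCAH]))
    k1inf = 1.0 / (1.0 + np.exp((V + 60.0) / 10.0))

    INa = P[_I_GNA] * m * m * m * h * (V - _E_NA)
    ICaL = P[_I_GCAL] * d * f * fca * (V - _E_CA)
    IKr = P[_I_GKR] * xr * (V - _E_K)
    IKs = P[_I_GKS] * xs * (V - _E_K)
    IK1 = P[_I_GK1] * k1inf * (V - _E_K)
    INaK = P[_I_PNAK] * 0.3 / (1.0 + 0.25 * np.exp(-(V + 80.0) / 25.0))
    Jncx = P[_I_VNCX] * Cai / (Cai + 0.5)
    INCX = -10.0 * Jncx
    INab = P[_I_GNAB] * (V - _E_NA)
    freeze = P[_I_FREEZE] > 0.5
    if freeze:
        Jncx = 0.0
        INCX = 0.0

    dy[0] = -(INa + ICaL + IKr + IKs + IK1 + INaK + INCX + INab) + stim
    dy[1] = (minf - m) / 0.12
    dy[2] = (hinf - h) / tauh
    dy[3] = (dinf - d) / 2.0
    dy[4] = (finf - f) / tauf
    dy[5] = (xrinf - xr) / 160.0
    dy[6] = (xsinf - xs) / 500.0

    # --- calcium handling ---
    JCaL = -P[_I_KCAL] * ICaL
    if JCaL < 0.0:
        JCaL = 0.0
    Jbg = P[_I_KBGCA]
    if freeze:
        JCaL = 0.0
        Jbg = 0.0
    Kup = P[_I_KUP]
    Jup = P[_I_VUP] * Cai * Cai / (Cai * Cai + Kup * Kup)
    srs = CaSR * CaSR / (CaSR * CaSR + P[_I_EC50SR] * P[_I_EC50SR])
    # RyR opening: triggered by L-type channel opening (CICR) plus a
    # Ca-overload-sensitive spontaneous term enabling diastolic SR release
    kah = P[_I_KACTH]
    c4 = (Cai / kah) ** 4
    spont = c4 / (c4 + 1.0)
    trig = d * f * fca
    kopen = P[_I_KACT] * (trig + spont) * srs
    Jrel = P[_I_KS] * O * (CaSR - Cai)
    Jleak = P[_I_KLEAK] * (CaSR - Cai)
    R = 1.0 - O - Iry
    dy[9] = kopen * R - (P[_I_KOM] + P[_I_KICA] * Cai) * O
    dy[10] = P[_I_KICA] * Cai * O - P[_I_KIM] * Iry

    # CaTnC kinetics with cooperative decay slow-down (more Xbs / more CaTnC
    # in the vicinity -> slower dissociation)
    Bn = B ** P[_I_NH]
    hillB = Bn / (Bn + P[_I_BH] ** P[_I_NH])
    pi_nb = np.exp(-P[_I_ALPHAX] * N) * (1.0 - 0.5 * B / P[_I_BTOT])
    # CaTnC affinity falls with shorter sarcomere length (length-dependent
    # activation); at the reference overlap the factor is 1
    aon_eff = P[_I_AON] * (0.6 + 0.4 * ov)
    dB = aon_eff * Cai * (P[_I_BTOT] - B) - P[_I_AOFF] * pi_nb * B
    dy[11] = dB

    dy[7] = JCaL + Jbg + Jrel + Jleak - Jup - Jncx - dB
    dy[8] = P[_I_VSR] * (Jup - Jrel - Jleak)

    # --- cross-bridges ---
    # detachment accelerates during shortening and when CaTnC support
    # collapses (cooperative deactivation sharpens the twitch tail)
    offb = 1.0 - hillB
    kme = P[_I_KMX] * (1.0 + P[_I_CVDET] * (v if v > 0.0 else 0.0) / v0
                       + 3.0 * offb * offb * offb * offb)
    dy[12] = P[_I_KPX] * ov * ov * hillB * (1.0 - N) - kme * N
    dy[13] = -v

    return Fa, Ft, v


@njit(cache=True, fastmath=False)
def _run(y, P, mode, L0, F_aft, n_cycles, cl, sample_dt, dt_fast, dt_slow,
         stim_amp, stim_dur, outV, outCa, outFa, outFt, outL, cyc_dvdtmax,
         start_phase):
    """Integrate n_cycles; fill sampled outputs.

    Returns (status, phase, lifted) with status 0 ok / 1 numerical failure.
    mode: 0 isometric, 1 afterloaded.
    """
    n_samp_cyc = int(round(cl / sample_dt))
    dy = np.empty(_N_STATE)
    k1 = np.empty(_N_STATE)
    k2 = np.empty(_N_STATE)
    k3 = np.empty(_N_STATE)
    k4 = np.empty(_N_STATE)
    yt = np.empty(_N_STATE)

    phase = start_phase
    lifted = False
    hyst = 0  # one-step hysteresis counter for phase switching

    # record t = 0 sample
    Fa0, Ft0, _ = _rhs(y, P, 0.0, phase, F_aft, dy)
    outV[0] = y[0]; outCa[0] = y[7]; outFa[0] = Fa0; outFt[0] = Ft0; outL[0] = y[13]
    idx = 1

    for c in range(n_cycles):
        dvmax = -1.0e30
        for s in range(n_samp_cyc):
            t_in = s * sample_dt
            dt = dt_fast if t_in < 10.0 else dt_slow
            nsub = int(round(sample_dt / dt))
            for _ in range(nsub):
                stim = stim_amp if t_in < stim_dur else 0.0
                _rhs(y, P, stim, phase, F_aft, k1)
                for i in range(_N_STATE):
                    yt[i] = y[i] + 0.5 * dt * k1[i]
                _rhs(yt, P, stim, phase, F_aft, k2)
                for i in range(_N_STATE):
                    yt[i] = y[i] + 0.5 * dt * k2[i]
                _rhs(yt, P, stim, phase, F_aft, k3)
                for i in range(_N_STATE):
                    yt[i] = y[i] + dt * k3[i]
                _rhs(yt, P, stim, phase, F_aft, k4)
                for i in range(_N_STATE):
                    y[i] += dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
                if k1[0] > dvmax:
                    dvmax = k1[0]
                t_in += dt
                # clamp fractions
                for i in (9, 10, 12):
                    if y[i] < 0.0:
                        y[i] = 0.0
                    elif y[i] > 1.0:
                        y[i] = 1.0
                if y[7] < 1.0e-6:
                    y[7] = 1.0e-6
                if y[8] < 1.0:
                    y[8] = 1.0
                if y[11] < 0.0:
                    y[11] = 0.0
                # phase switching (afterloaded mode only), one-step hysteresis
                if mode == 1:
                    if hyst > 0:
                        hyst -= 1
                    else:
                        Fa, Ft, _ = _rhs(y, P, 0.0, phase, F_aft, dy)
                        if phase == 0 and Ft >= F_aft:
                            phase = 1
                            lifted = True
                            hyst = 1
                        elif phase == 1 and y[13] >= L0:
                            y[13] = L0
                            phase = 2
                            hyst = 1
            if not np.isfinite(y[0]) or not np.isfinite(y[7]):
                return 1, phase, lifted
            Fa, Ft, _ = _rhs(y, P, 0.0, phase, F_aft, dy)
            outV[idx] = y[0]; outCa[idx] = y[7]
            outFa[idx] = Fa; outFt[idx] = Ft; outL[idx] = y[13]
            idx += 1
        cyc_dvdtmax[c] = dvmax
    return 0, phase, lifted


# ---------------------------------------------------------------------------
# Python-level API
# ---------------------------------------------------------------------------


def _pack_params(scaling: ScalingVector, block: Optional[DrugBlockVector],
                 freeze_membrane_ca: bool = False) -> np.ndarray:
    P = np.empty(_NP)
    rp = REFERENCE_PARAMS
    for i, name in enumerate(_PACK_ORDER):
        if name == "_freeze":
            P[i] = 1.0 if freeze_membrane_ca else 0.0
        else:
            P[i] = rp[name]
    s = scaling
    P[_I_GNA] *= s.gNa
    P[_I_GCAL] *= s.gCaL
    P[_I_GK1] *= s.gK1
    P[_I_GKS] *= s.gKs
    P[_I_GKR] *= s.gKr
    P[_I_VUP] *= s.Vmaxup
    P[_I_VNCX] *= s.KNaCa
    P[_I_PNAK] *= s.PNaK
    P[_I_KS] *= s.ks
    P[_I_KIM] *= s.kim
    P[_I_KOM] *= s.kom
    if block is not None:
        P[_I_GNA] *= block.INa
        P[_I_GCAL] *= block.ICaL
        P[_I_GKR] *= block.IKr
        P[_I_GKS] *= block.IKs
    return P


def _default_state(L0: float) -> np.ndarray:
    y = np.zeros(_N_STATE)
    y[0] = -86.0   # V
    y[2] = 0.9     # h
    y[4] = 1.0     # f
    y[7] = 0.1     # Cai
    y[8] = float(REFERENCE_PARAMS["CaSR_init"])
    y[11] = 5.0    # B
    y[12] = 0.005  # N
    y[13] = L0
    return y


def _cycle_summaries(time, V, Cai, Fa, n_cycles, cl, sample_dt, cyc_dvdtmax):
    n = int(round(cl / sample_dt))
    peak_V = np.empty(n_cycles)
    min_V = np.empty(n_cycles)
    peak_Cai = np.empty(n_cycles)
    min_Cai = np.empty(n_cycles)
    peak_F = np.empty(n_cycles)
    apd90 = np.full(n_cycles, np.nan)
    for c in range(n_cycles):
        lo, hi = c * n, (c + 1) * n + 1
        v = V[lo:hi]
        ca = Cai[lo:hi]
        peak_V[c] = v.max()
        min_V[c] = v.min()
        peak_Cai[c] = ca.max()
        min_Cai[c] = ca.min()
        peak_F[c] = Fa[lo:hi].max()
        apd90[c] = _quick_apd(v, sample_dt, 0.9)
    return {
        "cycle": np.arange(n_cycles),
        "peak_V": peak_V, "min_V": min_V,
        "peak_Cai": peak_Cai, "min_Cai": min_Cai,
        "peak_F": peak_F, "dVdt_max": cyc_dvdtmax, "APD90": apd90,
    }


def _quick_apd(v, dt, frac):
    """APD within one cycle slice: max-dV/dt upstroke to frac repolarization."""
    dv = np.diff(v)
    if dv.size == 0 or (v.max() - v.min()) < 30.0:
        return np.nan
    iact = int(np.argmax(dv))
    ipk = iact + int(np.argmax(v[iact:]))
    vrest = v.min()
    thr = v[ipk] - frac * (v[ipk] - vrest)
    below = np.nonzero(v[ipk:] <= thr)[0]
    if below.size == 0:
        return np.nan
    j = ipk + below[0]
    if j == ipk:
        return 0.0
    # linear interpolation between j-1 and j
    v1, v2 = v[j - 1], v[j]
    fr = 0.0 if v2 == v1 else (v1 - thr) / (v1 - v2)
    return (j - 1 + fr - iact) * dt


def simulate(scaling: ScalingVector,
             protocol: MechanicalProtocol = MechanicalProtocol(),
             config: SimulationConfig = SimulationConfig(),
             block: Optional[DrugBlockVector] = None,
             *,
             initial_state: Optional[CellState] = None,
             _freeze_membrane_ca: bool = False) -> Trace:
    """Run a paced simulation and return the last two cycles plus summaries.

    Deterministic: identical inputs give bit-identical traces.  Numerical
    failure is reported through ``Trace.status == "integration_failed"``,
    never an exception.
    """
    if protocol.mode != "isometric":
        raise ValueError("simulate() handles isometric runs; use afterloaded_twitch()")
    P = _pack_params(scaling, block, _freeze_membrane_ca)
    cl = config.cycle_length
    L0 = protocol.initial_length
    y = (_default_state(L0) if initial_state is None
         else initial_state.values.copy())
    y[13] = L0
    nc = config.n_cycles
    nsamp = nc * int(round(cl / config.sample_dt)) + 1
    outV = np.empty(nsamp); outCa = np.empty(nsamp)
    outFa = np.empty(nsamp); outFt = np.empty(nsamp); outL = np.empty(nsamp)
    cyc_dvdtmax = np.empty(nc)
    status, _, _ = _run(y, P, 0, L0, 0.0, nc, cl, config.sample_dt,
                        config.dt_fast, config.dt_slow,
                        config.stim_amplitude, config.stim_duration,
                        outV, outCa, outFa, outFt, outL, cyc_dvdtmax, 0)
    t = np.arange(nsamp) * config.sample_dt
    fnorm = REFERENCE_PEAK_FORCE
    summaries = _cycle_summaries(t, outV, outCa, outFa / fnorm, nc, cl,
                                 config.sample_dt, cyc_dvdtmax)
    # keep the last two full cycles
    n = int(round(cl / config.sample_dt))
    lo = (nc - 2) * n
    stim = np.array([(nc - 2) * cl, (nc - 1) * cl])
    return Trace(
        time=t[lo:], V=outV[lo:], Cai=outCa[lo:],
        F_active=outFa[lo:] / fnorm, F_total=outFt[lo:] / fnorm,
        L=outL[lo:], stim_times=stim, cycle_length=cl,
        sample_dt=config.sample_dt, summaries=summaries,
        status="integration_failed" if status else "ok",
        final_state=None if status else CellState(y),
        meta={"protocol": asdict(protocol), "scaling": asdict(scaling)},
    )


def isometric_steady_state(scaling: ScalingVector,
                           initial_length: float = 0.93,
                           config: SimulationConfig = SimulationConfig(),
                           block: Optional[DrugBlockVector] = None) -> Trace:
    """Steady-state isometric run at the given length (convenience wrapper)."""
    proto = MechanicalProtocol(mode="isometric", initial_length=initial_length)
    return simulate(scaling, proto, config, block)


def peak_isometric_force(scaling: ScalingVector,
                         initial_length: float = 0.93,
                         config: SimulationConfig = SimulationConfig(),
                         block: Optional[DrugBlockVector] = None) -> float:
    """Peak active force over the last steady-state cycle (normalized units).

    Raises RuntimeError if the integration failed.
    """
    tr = isometric_steady_state(scaling, initial_length, config, block)
    if not tr.ok:
        raise RuntimeError("integration_failed")
    n = int(round(tr.cycle_length / tr.sample_dt))
    return float(tr.F_active[-(n + 1):].max())


def afterloaded_twitch(scaling: ScalingVector,
                       afterload_fraction: float,
                       config: SimulationConfig = SimulationConfig(),
                       block: Optional[DrugBlockVector] = None,
                       *,
                       baseline: Optional[Trace] = None,
                       f_max: Optional[float] = None) -> Trace:
    """First afterloaded isotonic twitch after the isometric steady state.

    ``baseline`` is a completed isometric steady-state trace at the working
    preload (computed on demand when omitted); it supplies the starting
    CellState and, unless ``f_max`` (normalized units) is given explicitly,
    the model's F_max.  An explicit ``f_max`` expresses the afterload against
    a different reference — e.g. the drug-free peak force when the baseline
    is a drug run, so the external load stays fixed while the cell weakens.
    The total force held during the isotonic phase is
    ``afterload_fraction * F_max + passive force`` at the initial length, so
    a fraction of 1.0 (with the default f_max) reproduces the isometric
    twitch.
    """
    if not 0.0 < afterload_fraction <= 1.0:
        raise ValueError("afterload_fraction must lie in (0, 1]")
    if baseline is None:
        baseline = isometric_steady_state(scaling, 0.93, config, block)
    if not baseline.ok or baseline.final_state is None:
        return replace(baseline, status="integration_failed")
    L0 = float(baseline.L[-1])
    n = int(round(baseline.cycle_length / baseline.sample_dt))
    if f_max is not None:
        F_max = f_max * REFERENCE_PEAK_FORCE
    else:
        F_max = float(baseline.F_active[-(n + 1):].max()) * REFERENCE_PEAK_FORCE
    Fp0 = float(baseline.F_total[-1] - baseline.F_active[-1]) * REFERENCE_PEAK_FORCE
    F_aft = afterload_fraction * F_max + Fp0

    P = _pack_params(scaling, block)
    cl = config.cycle_length
    y = baseline.final_state.values.copy()
    nc = 1
    nsamp = nc * int(round(cl / config.sample_dt)) + 1
    outV = np.empty(nsamp); outCa = np.empty(nsamp)
    outFa = np.empty(nsamp); outFt = np.empty(nsamp); outL = np.empty(nsamp)
    cyc_dvdtmax = np.empty(nc)
    status, phase, lifted = _run(
        y, P, 1, L0, F_aft, nc, cl, config.sample_dt,
        config.dt_fast, config.dt_slow,
        config.stim_amplitude, config.stim_duration,
        outV, outCa, outFa, outFt, outL, cyc_dvdtmax, 0)
    t = np.arange(nsamp) * config.sample_dt
    fnorm = REFERENCE_PEAK_FORCE
    summaries = _cycle_summaries(t, outV, outCa, outFa / fnorm, nc, cl,
                                 config.sample_dt, cyc_dvdtmax)
    if status:
        st = "integration_failed"
    elif not lifted:
        st = "never_lifted"
    else:
        st = "ok"
    return Trace(
        time=t, V=outV, Cai=outCa, F_active=outFa / fnorm,
        F_total=outFt / fnorm, L=outL, stim_times=np.array([0.0]),
        cycle_length=cl, sample_dt=config.sample_dt, summaries=summaries,
        status=st, final_state=None if status else CellState(y),
        meta={"mode": "afterloaded", "afterload_fraction": afterload_fraction,
              "F_max": F_max / fnorm, "initial_length": L0,
              "scaling": asdict(scaling)},
    )
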