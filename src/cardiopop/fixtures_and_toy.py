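"""Deterministic synthetic inputs: analytic trace fixtures and a toy simulator.

Two families of test doubles make the rest of the package testable in
seconds without integrating the ODE model:

* **Trace fixtures** — piecewise-linear or raised-cosine segment descriptions
  for voltage, calcium, force and length, sampled onto a uniform timebase
  with stimulus markers.  Their biomarkers follow in closed form from the
  segment geometry, so extractor and detector outputs can be checked against
  exact values.

* **Toy simulator** — a smooth analytic map from an 11-dimensional scaling
  point in [0, 2]^11 to the ten calibrated AP/Ca biomarkers (affine plus mild
  quadratic terms with frozen coefficients).  The all-ones point maps exactly
  onto the calibration-criteria centers, and the coefficients are scaled so
  that the true plausible region (all criteria satisfied) occupies roughly
  10-20 % of the sampling box, which makes the history-matching acceptance
  trajectory reproducible at desk scale.  The true region is computable by
  brute-force evaluation, providing ground truth for emulator-recall tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cell_model import Trace

__all__ = [
    "Segment",
    "TraceFixtureSpec",
    "make_trace",
    "ToySimulatorSpec",
    "ToySimulator",
    "make_toy_simulator",
    "TOY_BIOMARKERS",
]


# ---------------------------------------------------------------------------
# Trace fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Segment:
    """One signal segment: linear ramp or raised cosine between two levels."""

    t0: float
    t1: float
    y0: float
    y1: float
    shape: str = "linear"  # "linear" | "cosine"

    def sample(self, t):
        u = np.clip((t - self.t0) / max(self.t1 - self.t0, 1e-12), 0.0, 1.0)
        if self.shape == "cosine":
            u = 0.5 - 0.5 * np.cos(np.pi * u)
        return self.y0 + (self.y1 - self.y0) * u


@dataclass
class TraceFixtureSpec:
    """Segment descriptions per signal plus sampling step and cycle length.

    Unlisted signals stay at their baseline.  Segments of one signal must be
    time-ordered and non-overlapping; between segments the signal holds the
    last level.
    """

    cycle_length: float = 1000.0
    n_cycles: int = 2
    sample_dt: float = 0.5
    baseline: dict = field(default_factory=lambda: {
        "V": -85.0, "Cai": 0.1, "F_active": 0.0, "L": 0.93})
    segments: dict = field(default_factory=dict)  # signal -> [Segment] within one cycle


def _sample_signal(t_cycle, baseline, segments: Sequence[Segment]):
    y = np.full_like(t_cycle, baseline)
    level = baseline
    for seg in segments:
        if seg.t0 < 0 or seg.t1 <= seg.t0:
            raise ValueError("segments must be time-ordered with t1 > t0")
        y[t_cycle >= seg.t0] = np.nan  # mark; filled below
        level = seg.y1
    # second pass: piecewise evaluation
    y = np.full_like(t_cycle, baseline)
    for seg in segments:
        m = (t_cycle >= seg.t0) & (t_cycle <= seg.t1)
        y[m] = seg.sample(t_cycle[m])
        y[t_cycle > seg.t1] = seg.y1
    return y


def make_trace(spec: TraceFixtureSpec) -> Trace:
    """Build a uniformly sampled Trace from a fixture spec.

    Stimulus markers are placed at every cycle start.  The same within-cycle
    segment program repeats in every cycle.
    """
    n = int(round(spec.cycle_length / spec.sample_dt))
    t = np.arange(spec.n_cycles * n + 1) * spec.sample_dt
    t_cycle = np.mod(t, spec.cycle_length)
    # the final sample closes the last cycle
    t_cycle[-1] = spec.cycle_length
    out = {}
    for name in ("V", "Cai", "F_active", "L"):
        segs = spec.segments.get(name, [])
        base = spec.baseline.get(name, 0.0)
        cyc_specs = sorted(segs, key=lambda s: s.t0)
        out[name] = _sample_signal(t_cycle, base, cyc_specs)
    stim = np.arange(spec.n_cycles) * spec.cycle_length
    return Trace(
        time=t, V=out["V"], Cai=out["Cai"], F_active=out["F_active"],
        F_total=out["F_active"], L=out["L"], stim_times=stim,
        cycle_length=spec.cycle_length, sample_dt=spec.sample_dt,
        summaries={}, status="ok", meta={"fixture": True},
    )


# ---------------------------------------------------------------------------
# Toy simulator
# ---------------------------------------------------------------------------

#: Biomarkers produced by the toy simulator (the calibrated AP/Ca set).
TOY_BIOMARKERS = ("RMP", "APD20", "APD50", "APD90", "Tri9040",
                  "CTmin", "CTmax", "CaTTP", "CTD50", "CTD80")

#: Centers of the packaged calibration criteria (implausibility criteria:
#: experimental mean; min-max criteria: interval midpoint).
_TOY_CENTERS = {
    "RMP": -85.0, "APD20": 172.0, "APD50": 230.0, "APD90": 311.0,
    "Tri9040": 135.0, "CTmin": 0.121, "CTmax": 1.120, "CaTTP": 165.0,
    "CTD50": 162.5, "CTD80": 292.5,
}

#: Acceptance half-widths (implausibility: 3 sigma; min-max: half-range).
_TOY_TOL = {
    "RMP": 15.0, "APD20": 87.0, "APD50": 117.0, "APD90": 147.0,
    "Tri9040": 117.0, "CTmin": 0.121, "CTmax": 0.384, "CaTTP": 135.0,
    "CTD50": 107.5, "CTD80": 172.5,
}

#: Frozen coefficient seed and global amplitude; chosen once so the true
#: plausible region covers ~10-20 % of [0, 2]^11.
_TOY_COEF_SEED = 20260925
_TOY_GAMMA = 1.0 / 1.35


@dataclass(frozen=True)
class ToySimulatorSpec:
    """Configuration of the analytic toy simulator.

    noise_sd maps biomarker name to an observation-noise standard deviation
    (zero/absent = exact closed form); seed drives the noise stream only —
    the map coefficients are frozen package constants.
    """

    n_dims: int = 11
    noise_sd: dict = field(default_factory=dict)
    seed: int = 0


class ToySimulator:
    """Smooth analytic stand-in for the ODE simulator in calibration tests.

    ``f_n(x) = c_n + s_n * (A_n . u + Q_n . u^2)`` with ``u = x - 1`` in
    [-1, 1]^11; evaluation cost is O(d) per biomarker.  The all-ones point
    returns exactly the criteria centers.
    """

    def __init__(self, spec: ToySimulatorSpec = ToySimulatorSpec()):
        self.spec = spec
        d = spec.n_dims
        rng = np.random.default_rng(_TOY_COEF_SEED)
        self.A = {}
        self.Q = {}
        for name in TOY_BIOMARKERS:
            a = rng.normal(size=d) * (rng.random(d) < 0.5)  # sparse-ish
            q = 0.4 * rng.normal(size=d) * (rng.random(d) < 0.3)
            raw_sd = np.sqrt(np.sum(a ** 2) / 3.0 + np.sum(q ** 2) * (4.0 / 45.0))
            scale = _TOY_GAMMA * _TOY_TOL[name] / max(raw_sd, 1e-12)
            self.A[name] = a * scale
            self.Q[name] = q * scale
        self._noise_rng = np.random.default_rng(spec.seed)

    def __call__(self, x) -> dict:
        """Biomarker dict for one point (or (n, d) array -> dict of arrays)."""
        x = np.asarray(x, dtype=float)
        u = x - 1.0
        single = u.ndim == 1
        if single:
            u = u[None, :]
        out = {}
        for name in TOY_BIOMARKERS:
            val = _TOY_CENTERS[name] + u @ self.A[name] + (u ** 2) @ self.Q[name]
            sd = self.spec.noise_sd.get(name, 0.0)
            if sd > 0:
                val = val + self._noise_rng.normal(scale=sd, size=val.shape)
            out[name] = float(val[0]) if single else val
        return out

    def true_plausible_mask(self, X) -> np.ndarray:
        """Ground-truth acceptance of each row of X (noise-free evaluation)."""
        X = np.asarray(X, dtype=float)
        u = X - 1.0
        ok = np.ones(X.shape[0], dtype=bool)
        for name in TOY_BIOMARKERS:
            val = _TOY_CENTERS[name] + u @ self.A[name] + (u ** 2) @ self.Q[name]
            ok &= np.abs(val - _TOY_CENTERS[name]) <= _TOY_TOL[name]
        return ok

    def true_plausible_fraction(self, n: int = 100_000, seed: int = 0) -> float:
        """Monte-Carlo volume fraction of the true plausible region."""
        rng = np.random.default_rng(seed)
        X = rng.uniform(0.0, 2.0, size=(n, self.spec.n_dims))
        return float(self.true_plausible_mask(X).mean())


def make_toy_simulator(spec: Optional[ToySimulatorSpec] = None) -> ToySimulator:
    """Factory mirroring the simulator interface used by history matching."""
    return ToySimulator(spec or ToySimulatorSpec())
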