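"""Wave-based history-matching calibration with Gaussian-process emulators.

History matching iteratively shrinks the 11-dimensional scaling-factor space
toward the not-ruled-out-yet (NROY) region:

1. Sample simulator points (Latin hypercube in wave 1, uniform draws from the
   NROY cloud afterwards; 300 per wave by default) and run the simulator for
   each, rejecting runs with abnormalities.
2. Train one Gaussian-process emulator per calibrated biomarker on the
   accepted simulator results of up to the last four waves.
3. Evaluate the emulators on the candidate cloud (10^6 Latin-hypercube points
   in wave 1, the surviving cloud afterwards) and discard points whose
   implausibility

       I_n(x) = |E[f_n(x)] - z_n| / sqrt(Var[f_n(x)] + Var(e_n))

   exceeds 3 for any biomarker with known experimental mean/variance
   (three-sigma rule), or whose predicted mean leaves the [min, max] interval
   for biomarkers calibrated by cutoff borders only.
4. If fewer than 10^5 candidates survive, augment by drawing from
   N(point, 0.05 I) around random surviving points (redrawing out-of-bound
   draws) until the floor is reached.
5. Stop when the surviving-cloud size changes by less than 0.1 % between
   waves, or at the wave cap.

Finally, models are drawn from the converged cloud, simulated, and rejected
if any biomarker leaves its [min, max] range or any abnormality fires,
yielding the electrically calibrated initial population.

A *simulator* here is any callable ``point -> SimResult``; the ODE-backed
simulator (``ode_simulator``) and the analytic toy simulator both satisfy the
contract.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from .cell_model import PARAM_NAMES, MechanicalProtocol, ScalingVector, SimulationConfig, simulate
from .biomarkers import extract_biomarkers
from .abnormality import detect_ap_abnormalities, detect_contraction_abnormalities

__all__ = [
    "CalibrationCriterion", "load_criteria", "SimResult", "ode_simulator",
    "EmulatorModel", "WaveState", "PopulationRecord", "HMConfig",
    "lhs_sample", "implausibility", "filter_points", "train_emulators",
    "augment_points", "run_wave", "has_converged",
    "finalize_initial_population", "run_history_matching",
]


# ---------------------------------------------------------------------------
# Criteria
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationCriterion:
    """One biomarker calibration rule.

    mode "implausibility": compare to the experimental mean ``mean`` with
    observation variance ``sd**2`` through the implausibility measure.
    mode "minmax": require the predicted mean inside [min, max].
    Both modes carry [min, max], used when calibrating simulator outputs.
    """

    biomarker: str
    mode: str
    mean: Optional[float] = None
    sd: Optional[float] = None
    min: Optional[float] = None
    max: Optional[float] = None
    units: str = ""
    stage: str = "calibration"

    def __post_init__(self):
        if self.mode not in ("implausibility", "minmax"):
            raise ValueError(f"unknown criterion mode {self.mode!r}")
        if self.mode == "implausibility":
            if self.mean is None or self.sd is None or self.sd <= 0:
                raise ValueError(
                    f"{self.biomarker}: implausibility mode needs mean and sd > 0")
        if self.mode == "minmax":
            if self.min is None or self.max is None or not self.min < self.max:
                raise ValueError(f"{self.biomarker}: minmax mode needs min < max")


def load_criteria(path=None, stage: Optional[str] = "calibration"):
    """Load calibration criteria from CSV (packaged defaults when path=None).

    ``stage`` filters rows ("calibration", "recalibration", or None for all).
    """
    if path is None:
        with resources.files("cardiopop").joinpath(
                "data/calibration_criteria.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    crits = []
    for _, row in df.iterrows():
        if stage is not None and row.get("stage", "calibration") != stage:
            continue
        crits.append(CalibrationCriterion(
            biomarker=row["biomarker"], mode=row["mode"],
            mean=None if pd.isna(row.get("mean")) else float(row["mean"]),
            sd=None if pd.isna(row.get("sd")) else float(row["sd"]),
            min=None if pd.isna(row.get("min")) else float(row["min"]),
            max=None if pd.isna(row.get("max")) else float(row["max"]),
            units=str(row.get("units", "")),
            stage=str(row.get("stage", "calibration")),
        ))
    return crits


# ---------------------------------------------------------------------------
# Simulators
# ---------------------------------------------------------------------------


@dataclass
class SimResult:
    """Outcome of one simulator evaluation at a parameter point."""

    biomarkers: dict
    abnormal: bool = False
    reason: Optional[str] = None


def ode_simulator(config: Optional[SimulationConfig] = None,
                  protocol: Optional[MechanicalProtocol] = None) -> Callable:
    """Simulator backed by the electro-mechanical ODE model.

    Runs the paced protocol to steady state, extracts biomarkers, and runs
    the AP/contraction abnormality detectors on the last two cycles.
    """
    cfg = config or SimulationConfig()
    proto = protocol or MechanicalProtocol()

    def _sim(point) -> SimResult:
        sv = ScalingVector.from_array(point)
        tr = simulate(sv, proto, cfg)
        if not tr.ok:
            return SimResult({}, abnormal=True, reason="integration_failed")
        bm = extract_biomarkers(tr)
        fl = detect_ap_abnormalities(tr).merge(
            detect_contraction_abnormalities(tr, "isometric"))
        if fl.any:
            reason = ",".join(k for k, v in fl.as_dict().items() if v)
            return SimResult(bm.as_dict(), abnormal=True, reason=reason)
        return SimResult(bm.as_dict())

    return _sim


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


def lhs_sample(n_points: int, bounds=None, seed: int = 0,
               n_candidates: int = 5) -> np.ndarray:
    """Latin hypercube sample, maximin variant.

    Each coordinate column has exactly one point per stratum.  For small
    designs (n <= 1000) several candidate hypercubes are drawn and the one
    with the largest minimum pairwise distance is kept; large designs use a
    single scrambled hypercube.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    bounds = _as_bounds(bounds)
    d = bounds.shape[0]
    rng = np.random.default_rng(seed)
    if n_points > 1000 or n_candidates <= 1:
        sampler = qmc.LatinHypercube(d=d, seed=rng)
        u = sampler.random(n_points)
    else:
        best, best_score = None, -np.inf
        for _ in range(n_candidates):
            cand = qmc.LatinHypercube(d=d, seed=rng).random(n_points)
            if n_points == 1:
                best = cand
                break
            dist = np.linalg.norm(cand[:, None, :] - cand[None, :, :], axis=-1)
            np.fill_diagonal(dist, np.inf)
            score = dist.min()
            if score > best_score:
                best, best_score = cand, score
        u = best
    return qmc.scale(u, bounds[:, 0], bounds[:, 1])


def _as_bounds(bounds, d: int = len(PARAM_NAMES)) -> np.ndarray:
    if bounds is None:
        return np.tile([0.0, 2.0], (d, 1))
    b = np.asarray(bounds, dtype=float)
    if b.ndim != 2 or b.shape[1] != 2 or np.any(b[:, 0] >= b[:, 1]):
        raise ValueError("bounds must be (d, 2) with lower < upper")
    return b


def augment_points(accepted_points: np.ndarray, target: int, seed: int = 0,
                   cov_scale: float = 0.05, bounds=None) -> np.ndarray:
    """Grow a point cloud to ``target`` by Gaussian jitter around members.

    Draws from N(center, cov_scale * I) around uniformly chosen accepted
    points; draws falling outside the bounds are redrawn.  Returns the input
    unchanged when it already meets the target.
    """
    pts = np.asarray(accepted_points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] == 0:
        raise ValueError("accepted_points must be a non-empty (n, d) array")
    if pts.shape[0] >= target:
        return pts
    bounds = _as_bounds(bounds, pts.shape[1])
    rng = np.random.default_rng(seed)
    sd = np.sqrt(cov_scale)
    need = target - pts.shape[0]
    new = np.empty((need, pts.shape[1]))
    filled = 0
    while filled < need:
        m = need - filled
        centers = pts[rng.integers(0, pts.shape[0], size=m)]
        draws = centers + rng.normal(scale=sd, size=centers.shape)
        ok = np.all((draws >= bounds[:, 0]) & (draws <= bounds[:, 1]), axis=1)
        k = int(ok.sum())
        new[filled:filled + k] = draws[ok]
        filled += k
    return np.vstack([pts, new])


# ---------------------------------------------------------------------------
# Implausibility and filtering
# ---------------------------------------------------------------------------


def implausibility(pred_mean, pred_var, criterion: CalibrationCriterion):
    """I(x) = |E[f(x)] - z| / sqrt(Var[f(x)] + Var(e)).

    ``pred_var`` is the emulator predictive variance (0 for
    simulator-computed values).
    """
    if criterion.mode != "implausibility":
        raise ValueError(f"{criterion.biomarker} is not an implausibility criterion")
    pred_mean = np.asarray(pred_mean, dtype=float)
    pred_var = np.asarray(pred_var, dtype=float)
    denom = pred_var + criterion.sd ** 2
    if np.any(denom <= 0):
        raise ValueError("degenerate criterion: zero total variance")
    return np.abs(pred_mean - criterion.mean) / np.sqrt(denom)


def passes_simulator_calibration(biomarkers: dict,
                                 criteria: Sequence[CalibrationCriterion],
                                 I_threshold: float = 3.0) -> bool:
    """Calibration check on simulator outputs (zero predictive variance)."""
    for c in criteria:
        val = biomarkers.get(c.biomarker)
        if val is None or not np.isfinite(val):
            return False
        if c.mode == "implausibility":
            if float(implausibility(val, 0.0, c)) > I_threshold:
                return False
        else:
            if not (c.min <= val <= c.max):
                return False
    return True


def within_minmax(biomarkers: dict, criteria: Sequence[CalibrationCriterion]) -> bool:
    """True iff every biomarker lies inside its criterion's [min, max]."""
    for c in criteria:
        val = biomarkers.get(c.biomarker)
        if val is None or not np.isfinite(val):
            return False
        if c.min is not None and val < c.min:
            return False
        if c.max is not None and val > c.max:
            return False
    return True


def filter_points(points: np.ndarray, emulators: dict,
                  criteria: Sequence[CalibrationCriterion],
                  I_threshold: float = 3.0,
                  chunk: int = 20000):
    """Keep candidate points that no criterion rules out.

    A point survives iff its maximum implausibility over the
    implausibility-mode criteria is <= I_threshold (strictly greater is
    rejected) and every minmax-mode criterion's predicted mean lies inside
    [min, max].  Returns (surviving points, boolean mask).
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    mask = np.ones(n, dtype=bool)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        sub = points[lo:hi]
        m = mask[lo:hi]
        for c in criteria:
            if not m.any():
                break
            em = emulators[c.biomarker]
            mean, var = em.predict(sub)
            if c.mode == "implausibility":
                m &= implausibility(mean, var, c) <= I_threshold
            else:
                m &= (mean >= c.min) & (mean <= c.max)
        mask[lo:hi] = m
    return points[mask], mask


# ---------------------------------------------------------------------------
# Emulators
# ---------------------------------------------------------------------------


class EmulatorModel:
    """Gaussian-process regressor for one biomarker.

    RBF kernel with a constant amplitude and a white-noise term;
    hyperparameters fit by marginal-likelihood optimization with one restart
    from a fixed seed.  Inputs are standardized to the sampling box, outputs
    centered and scaled internally by sklearn (normalize_y).
    """

    def __init__(self, biomarker: str, bounds=None, seed: int = 0):
        self.biomarker = biomarker
        self.bounds = _as_bounds(bounds)
        self.seed = seed
        self.gp: Optional[GaussianProcessRegressor] = None
        self.loo_rmse: Optional[float] = None
        self.training_waves: tuple = ()

    def _scale(self, X):
        b = self.bounds
        return (np.asarray(X, dtype=float) - b[:, 0]) / (b[:, 1] - b[:, 0])

    def fit(self, X, y, waves=(), init_theta=None):
        Xs = self._scale(X)
        kernel = (ConstantKernel(1.0, (1e-3, 1e3))
                  * RBF(length_scale=np.full(Xs.shape[1], 0.5),
                        length_scale_bounds=(1e-2, 1e2))
                  + WhiteKernel(1e-6, (1e-10, 1e-1)))
        restarts = 1
        if init_theta is not None:
            # warm start from the previous wave's hyperparameters
            kernel.theta = np.asarray(init_theta, dtype=float)
            restarts = 0
        self.gp = GaussianProcessRegressor(
            kernel=kernel, normalize_y=True, n_restarts_optimizer=restarts,
            random_state=self.seed, alpha=1e-10)
        with warnings.catch_warnings():
            # flat likelihood directions (biomarkers insensitive to some
            # inputs) trip benign lbfgs/bound warnings
            warnings.simplefilter("ignore")
            self.gp.fit(Xs, np.asarray(y, dtype=float))
        self.training_waves = tuple(waves)
        self.loo_rmse = self._loo_rmse(np.asarray(y, dtype=float))
        return self

    @property
    def theta(self):
        return self.gp.kernel_.theta.tolist()

    def _loo_rmse(self, y) -> float:
        """Closed-form leave-one-out RMSE of the fitted GP."""
        gp = self.gp
        K = gp.kernel_(gp.X_train_)
        K[np.diag_indices_from(K)] += gp.alpha
        Kinv = np.linalg.inv(K)
        alpha = Kinv @ gp.y_train_
        resid = alpha / np.diag(Kinv)
        return float(np.sqrt(np.mean(resid ** 2)) * gp._y_train_std)

    def predict(self, X):
        """(mean, variance) at X."""
        mean, std = self.gp.predict(self._scale(X), return_std=True)
        return mean, std ** 2


def train_emulators(training_set, current_wave: int, window: int = 4,
                    biomarkers=None, bounds=None, seed: int = 0,
                    init_thetas: Optional[dict] = None) -> dict:
    """One GP emulator per biomarker from the windowed training data.

    ``training_set`` maps wave index -> (X, {biomarker: y}).  Only waves in
    (current_wave - window, current_wave] contribute.  Raises ValueError when
    fewer than 10 training points remain.
    """
    use = sorted(w for w in training_set if current_wave - window < w <= current_wave)
    Xs, Ys = [], []
    for w in use:
        X, ydict = training_set[w]
        Xs.append(np.asarray(X, dtype=float))
        Ys.append(ydict)
    if not Xs or sum(x.shape[0] for x in Xs) < 10:
        raise ValueError("need at least 10 training points")
    X = np.vstack(Xs)
    names = biomarkers or sorted(Ys[0].keys())
    emus = {}
    for name in names:
        y = np.concatenate([np.asarray(yd[name], dtype=float) for yd in Ys])
        theta = (init_thetas or {}).get(name)
        emus[name] = EmulatorModel(name, bounds=bounds, seed=seed).fit(
            X, y, waves=use, init_theta=theta)
    return emus


# ---------------------------------------------------------------------------
# Waves
# ---------------------------------------------------------------------------


@dataclass
class HMConfig:
    """History-matching settings (defaults mirror the full-scale protocol)."""

    n_simulators_per_wave: int = 300
    candidate_cloud_size: int = 1_000_000
    augment_floor: int = 100_000
    I_threshold: float = 3.0
    window: int = 4
    wave_cap: int = 60
    converge_rtol: float = 0.001
    bounds: Optional[np.ndarray] = None
    seed: int = 0


@dataclass
class WaveState:
    """State after one history-matching wave."""

    wave: int
    training_set: dict                 # wave -> (X, {biomarker: y})
    cloud: np.ndarray                  # current NROY candidate cloud
    counts: dict = field(default_factory=dict)
    seed: int = 0
    status: str = "ok"                 # "ok" | "empty_nroy"
    kernel_thetas: dict = field(default_factory=dict)

    def save(self, directory):
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        arrays = {"cloud": self.cloud}
        meta = {"wave": self.wave, "counts": self.counts, "seed": self.seed,
                "status": self.status, "training_waves": sorted(self.training_set),
                "kernel_thetas": self.kernel_thetas}
        for w, (X, ydict) in self.training_set.items():
            arrays[f"X_{w}"] = np.asarray(X)
            for k, v in ydict.items():
                arrays[f"y_{w}_{k}"] = np.asarray(v)
        np.savez_compressed(d / f"wave_{self.wave:03d}.npz", **arrays)
        (d / f"wave_{self.wave:03d}.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory, wave: int) -> "WaveState":
        d = Path(directory)
        meta = json.loads((d / f"wave_{wave:03d}.json").read_text())
        arrays = np.load(d / f"wave_{wave:03d}.npz")
        training = {}
        for w in meta["training_waves"]:
            ydict = {}
            prefix = f"y_{w}_"
            for k in arrays.files:
                if k.startswith(prefix):
                    ydict[k[len(prefix):]] = arrays[k]
            training[w] = (arrays[f"X_{w}"], ydict)
        return cls(wave=meta["wave"], training_set=training,
                   cloud=arrays["cloud"], counts=meta["counts"],
                   seed=meta["seed"], status=meta["status"],
                   kernel_thetas=meta.get("kernel_thetas", {}))


def _simulate_batch(points, simulator, criteria, I_threshold):
    """Run the simulator on each point; split accepted/abnormal, count
    calibration passes."""
    X_ok, Y_ok = [], []
    n_pass = 0
    names = [c.biomarker for c in criteria]
    for p in points:
        res = simulator(p)
        if isinstance(res, dict):
            res = SimResult(res)
        if res.abnormal:
            continue
        bm = res.biomarkers
        if any(bm.get(nm) is None or not np.isfinite(bm.get(nm, np.nan))
               for nm in names):
            continue
        X_ok.append(p)
        Y_ok.append(bm)
        if passes_simulator_calibration(bm, criteria, I_threshold):
            n_pass += 1
    ydict = {nm: np.array([bm[nm] for bm in Y_ok]) for nm in names}
    X = np.asarray(X_ok, dtype=float).reshape(len(X_ok), -1)
    return X, ydict, n_pass


def run_wave(state: Optional[WaveState], simulator,
             criteria: Sequence[CalibrationCriterion],
             config: HMConfig = HMConfig()) -> WaveState:
    """Execute one history-matching wave (pass state=None for wave 1)."""
    names = [c.biomarker for c in criteria]
    if state is None:
        wave = 1
        seed = config.seed
        sim_points = lhs_sample(config.n_simulators_per_wave, config.bounds,
                                seed=seed * 1000 + wave)
        cloud = lhs_sample(config.candidate_cloud_size, config.bounds,
                           seed=seed * 1000 + 500 + wave)
        training = {}
    else:
        if state.status != "ok":
            raise ValueError(f"cannot continue from state with status {state.status!r}")
        wave = state.wave + 1
        seed = state.seed
        rng = np.random.default_rng(seed * 1000 + wave)
        idx = rng.choice(state.cloud.shape[0],
                         size=min(config.n_simulators_per_wave,
                                  state.cloud.shape[0]),
                         replace=False)
        sim_points = state.cloud[idx]
        cloud = state.cloud
        training = dict(state.training_set)

    X, ydict, n_pass = _simulate_batch(sim_points, simulator, criteria,
                                       config.I_threshold)
    if X.shape[0]:
        training[wave] = (X, ydict)
    emus = train_emulators(training, wave, window=config.window,
                           biomarkers=names, bounds=config.bounds, seed=seed,
                           init_thetas=state.kernel_thetas if state else None)
    cloud_in = cloud.shape[0]
    survivors, _ = filter_points(cloud, emus, criteria, config.I_threshold)
    n_surv = survivors.shape[0]
    counts = {
        "wave": wave,
        "simulators_run": int(sim_points.shape[0]),
        "simulators_accepted": int(X.shape[0]),
        "simulator_calibration_pass": int(n_pass),
        "acceptance_rate": float(n_pass / max(sim_points.shape[0], 1)),
        "cloud_in": int(cloud_in),
        "cloud_surviving": int(n_surv),
        "survival_ratio": float(n_surv / max(cloud_in, 1)),
        "loo_rmse": {nm: emus[nm].loo_rmse for nm in names},
    }
    thetas = {nm: emus[nm].theta for nm in names}
    if n_surv == 0:
        return WaveState(wave=wave, training_set=training,
                         cloud=survivors, counts=counts, seed=seed,
                         status="empty_nroy", kernel_thetas=thetas)
    if n_surv < config.augment_floor:
        survivors = augment_points(survivors, config.augment_floor,
                                   seed=seed * 1000 + 250 + wave,
                                   bounds=config.bounds)
        counts["cloud_after_augment"] = int(survivors.shape[0])
    return WaveState(wave=wave, training_set=training, cloud=survivors,
                     counts=counts, seed=seed, kernel_thetas=thetas)


def has_converged(wave_history: Sequence[WaveState],
                  rtol: float = 0.001, wave_cap: int = 60) -> bool:
    """Converged when the surviving-cloud size changes by < rtol between the
    last two waves, or the wave cap is reached."""
    if not wave_history:
        return False
    if wave_history[-1].wave >= wave_cap:
        return True
    if len(wave_history) < 2:
        return False
    a = wave_history[-2].counts["cloud_surviving"]
    b = wave_history[-1].counts["cloud_surviving"]
    if a == 0:
        return True
    return abs(b - a) / a < rtol


def run_history_matching(simulator, criteria, config: HMConfig = HMConfig(),
                         max_waves: Optional[int] = None,
                         checkpoint_dir=None, log=None):
    """Run waves until convergence (or max_waves); returns the wave history."""
    history = []
    state = None
    cap = max_waves or config.wave_cap
    while True:
        state = run_wave(state, simulator, criteria, config)
        history.append(state)
        if checkpoint_dir is not None:
            state.save(checkpoint_dir)
        if log is not None:
            c = state.counts
            log(f"wave {c['wave']}: cloud {c['cloud_in']} -> "
                f"{c['cloud_surviving']} (survival {c['survival_ratio']:.3f}), "
                f"simulator acceptance {c['acceptance_rate']:.2f}")
        if state.status != "ok":
            break
        if has_converged(history, config.converge_rtol, cap):
            break
        if state.wave >= cap:
            break
    return history


# ---------------------------------------------------------------------------
# Final population
# ---------------------------------------------------------------------------


@dataclass
class PopulationRecord:
    """One model of the population with its evaluation bookkeeping."""

    model_id: int
    scaling: np.ndarray
    biomarkers: dict = field(default_factory=dict)   # protocol -> biomarker dict
    flags: dict = field(default_factory=dict)
    status: str = "accepted"                          # or "rejected:<stage>"

    @property
    def accepted(self) -> bool:
        return self.status == "accepted"

    def reject(self, stage: str, reason: str = ""):
        if self.accepted:
            self.status = f"rejected:{stage}"
            if reason:
                self.flags[stage] = reason


def finalize_initial_population(nroy_cloud: np.ndarray, n: int,
                                simulator, criteria,
                                seed: int = 0):
    """Draw n points from the NROY cloud, simulate, and calibrate.

    Models whose biomarkers leave any [min, max] range or that show
    abnormalities are rejected; returns (records, acceptance_rate).
    """
    cloud = np.asarray(nroy_cloud, dtype=float)
    records = []
    if n == 0:
        return records, float("nan")
    rng = np.random.default_rng(seed)
    idx = rng.choice(cloud.shape[0], size=n, replace=n > cloud.shape[0])
    n_acc = 0
    for i, p in enumerate(cloud[idx]):
        rec = PopulationRecord(model_id=i, scaling=np.asarray(p, dtype=float))
        res = simulator(p)
        if isinstance(res, dict):
            res = SimResult(res)
        rec.biomarkers["reference"] = res.biomarkers
        if res.abnormal:
            rec.reject("abnormality", res.reason or "abnormal")
        elif not within_minmax(res.biomarkers, criteria):
            rec.reject("calibration", "biomarker outside min-max range")
        else:
            n_acc += 1
        records.append(rec)
    return records, n_acc / len(records)
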