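"""Pore-block drug trials over the model population.

Drug action on ionic currents follows the simple pore-block model: at
concentration C a channel with half-blocking concentration IC50 and Hill
coefficient h retains the conductance fraction

    b(C) = 1 / (1 + (C / IC50)^h),

applied multiplicatively on top of the model's scaling factors.  Packaged
drug tables cover Dofetilide (high torsadogenic risk, dominant I_Kr block)
and Verapamil (no-risk L-type Ca2+ blocker).  The Dofetilide EFTPCmax in the
packaged file (0.002 uM) is an editorial reconstruction — the source table
truncates the value to "0.00" — so Dofetilide studies should prefer absolute
concentrations.

``drug_sweep`` reproduces the population stress test: every model is paced
to steady state at each (concentration multiplier, initial length) condition
and checked for repolarization abnormalities; a subsequent afterloaded
twitch at half the model's drug-free peak isometric force is checked for
failed contraction (<1 % shortening).  Cell counts per condition form an
event heatmap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cell_model import (DrugBlockVector, MechanicalProtocol, ScalingVector,
                         SimulationConfig, afterloaded_twitch, simulate)
from .abnormality import (detect_ap_abnormalities,
                          detect_contraction_abnormalities)

__all__ = [
    "ChannelBlock", "DrugSpec", "load_drugs", "block_factor", "apply_drug",
    "EventHeatmap", "drug_sweep", "DEFAULT_MULTIPLIERS", "DEFAULT_LENGTHS",
]

#: Concentration multipliers of EFTPCmax used by default (range endpoints
#: follow the published protocol; intermediate points are package defaults).
DEFAULT_MULTIPLIERS = (0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0)

#: Initial lengths (fractions of L_max) of the mechanical sweep.
DEFAULT_LENGTHS = (0.93, 0.90, 0.85, 0.80)

_CHANNELS = ("INa", "ICaL", "IKr", "IKs")


@dataclass(frozen=True)
class ChannelBlock:
    """IC50 (uM) and Hill coefficient of one channel entry."""

    ic50: float
    hill: float = 1.0

    def __post_init__(self):
        if self.ic50 <= 0 or self.hill <= 0:
            raise ValueError("IC50 and Hill coefficient must be positive")


@dataclass(frozen=True)
class DrugSpec:
    """Per-channel pore-block parameters of one compound.

    Channels without an entry are not blocked.  ``eftpc`` is the maximal
    effective free therapeutic plasma concentration (uM); ``risk_category``
    is the clinical torsade-de-pointes class label (1 = high risk, 0 = safe).
    """

    name: str
    channels: dict                      # channel -> ChannelBlock
    eftpc: Optional[float] = None       # uM
    risk_category: Optional[int] = None

    def __post_init__(self):
        for ch in self.channels:
            if ch not in _CHANNELS:
                raise ValueError(f"unknown channel {ch!r}")


def load_drugs(path=None) -> dict:
    """Load drug specs from CSV (packaged defaults when path=None)."""
    if path is None:
        with resources.files("cardiopop").joinpath("data/drug_specs.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    drugs = {}
    for name, g in df.groupby("drug", sort=False):
        channels = {row["channel"]: ChannelBlock(float(row["ic50_uM"]),
                                                 float(row["hill"]))
                    for _, row in g.iterrows()}
        eftpc = g["eftpc_uM"].iloc[0]
        risk = g["risk_category"].iloc[0]
        drugs[name] = DrugSpec(
            name=name, channels=channels,
            eftpc=None if pd.isna(eftpc) else float(eftpc),
            risk_category=None if pd.isna(risk) else int(risk))
    return drugs


def save_drugs(drugs: dict, path) -> None:
    """Serialize drug specs back to the CSV schema (lossless round trip)."""
    rows = []
    for d in drugs.values():
        for ch, blk in d.channels.items():
            rows.append({"drug": d.name, "channel": ch, "ic50_uM": blk.ic50,
                         "hill": blk.hill, "eftpc_uM": d.eftpc,
                         "risk_category": d.risk_category})
    pd.DataFrame(rows).to_csv(path, index=False)


def block_factor(concentration: float, ic50: float, hill: float = 1.0) -> float:
    """Remaining conductance fraction 1 / (1 + (C/IC50)^h)."""
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    if concentration == 0:
        return 1.0
    return 1.0 / (1.0 + (concentration / ic50) ** hill)


def apply_drug(spec: DrugSpec, concentration_multiplier: Optional[float] = None,
               concentration: Optional[float] = None) -> DrugBlockVector:
    """Per-channel block vector at a concentration.

    Give either ``concentration_multiplier`` (times EFTPCmax) or an absolute
    ``concentration`` in uM.  A multiplier requires a positive EFTPCmax on
    the spec.
    """
    if (concentration is None) == (concentration_multiplier is None):
        raise ValueError("give exactly one of multiplier or absolute concentration")
    if concentration is None:
        if spec.eftpc is None or spec.eftpc <= 0:
            raise ValueError(
                f"{spec.name}: EFTPCmax unavailable; use an absolute concentration")
        if concentration_multiplier < 0:
            raise ValueError("multiplier must be non-negative")
        concentration = concentration_multiplier * spec.eftpc
    factors = {}
    for ch in _CHANNELS:
        blk = spec.channels.get(ch)
        factors[ch] = 1.0 if blk is None else block_factor(concentration,
                                                           blk.ic50, blk.hill)
    return DrugBlockVector(**factors)


@dataclass
class EventHeatmap:
    """Abnormality-event counts per (concentration multiplier, length) cell."""

    drug: str
    multipliers: tuple
    lengths: tuple
    n_repol_abnormal: np.ndarray        # shape (n_multipliers, n_lengths)
    n_failed_contraction: np.ndarray
    population_size: int
    details: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, m in enumerate(self.multipliers):
            for j, L in enumerate(self.lengths):
                rows.append({
                    "drug": self.drug, "multiplier": m, "length": L,
                    "n_repol_abnormal": int(self.n_repol_abnormal[i, j]),
                    "n_failed_contraction": int(self.n_failed_contraction[i, j]),
                    "n_total": self.population_size,
                })
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def drug_sweep(population: Sequence[ScalingVector], spec: DrugSpec,
               multipliers: Sequence[float] = DEFAULT_MULTIPLIERS,
               lengths: Sequence[float] = DEFAULT_LENGTHS,
               config: SimulationConfig = SimulationConfig(),
               afterload_fraction: float = 0.5) -> EventHeatmap:
    """Count abnormal events over concentration x initial-length conditions.

    For each condition and model: a steady-state isometric run is checked
    for repolarization abnormalities (EAD, DAD, premature AP, failed
    repolarization, alternans; integration failures count as abnormal), and
    the first afterloaded twitch at ``afterload_fraction`` of that model's
    drug-free F_max at the same length — the external load is fixed while
    the drug weakens the cell — is checked for failed contraction (<1 %
    shortening, including twitches that never lift the load).
    """
    multipliers = tuple(multipliers)
    lengths = tuple(lengths)
    n_rep = np.zeros((len(multipliers), len(lengths)), dtype=int)
    n_fail = np.zeros_like(n_rep)
    details = []
    # drug-free peak forces per (model, length): the reference loads
    fmax_free = {}
    for j, L in enumerate(lengths):
        proto = MechanicalProtocol(mode="isometric", initial_length=L)
        for k, sv in enumerate(population):
            tr0 = simulate(sv, proto, config)
            if tr0.ok:
                ncyc = int(round(tr0.cycle_length / tr0.sample_dt))
                fmax_free[(k, L)] = float(tr0.F_active[-(ncyc + 1):].max())
    for i, mult in enumerate(multipliers):
        block = apply_drug(spec, concentration_multiplier=mult)
        for j, L in enumerate(lengths):
            proto = MechanicalProtocol(mode="isometric", initial_length=L)
            for k, sv in enumerate(population):
                tr = simulate(sv, proto, config, block)
                if not tr.ok:
                    n_rep[i, j] += 1
                    details.append((mult, L, k, "integration_failed"))
                    continue
                fl = detect_ap_abnormalities(tr)
                repol = (fl.EAD or fl.DAD or fl.premature_AP
                         or fl.failed_repolarization or fl.APD_alternans)
                if repol:
                    n_rep[i, j] += 1
                    details.append((mult, L, k, ",".join(
                        n for n, v in fl.as_dict().items() if v)))
                tw = afterloaded_twitch(sv, afterload_fraction, config, block,
                                        baseline=tr,
                                        f_max=fmax_free.get((k, L)))
                if not tw.ok:
                    n_fail[i, j] += 1
                    details.append((mult, L, k, "twitch_integration_failed"))
                    continue
                fc = detect_contraction_abnormalities(tw, "afterloaded")
                if fc.failed_contraction or tw.status == "never_lifted":
                    n_fail[i, j] += 1
                    details.append((mult, L, k, "failed_contraction"))
    return EventHeatmap(
        drug=spec.name, multipliers=multipliers, lengths=lengths,
        n_repol_abnormal=n_rep, n_failed_contraction=n_fail,
        population_size=len(population), details=details)
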