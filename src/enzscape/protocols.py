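"""Measurement protocols: multi-replica experiments over conditions.

These functions wrap :func:`enzscape.integrator.run_simulation` into the
repeated measurements the kinetic analyses need — closed-population
estimates over fresh seeds, turnover rates at given crowding and substrate
conditions — and are shared by the command-line tools, the test suite and
the reproduction script.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .adk import EnzymeSystem
from .analysis import (
    completed_cycles,
    count_transitions,
    estimate_pclosed,
    label_trace,
    turnover_rate,
)
from .crowding import CrowderSystem
from .integrator import SimulationConfig, run_simulation

__all__ = ["PClosedMeasurement", "TurnoverMeasurement",
           "measure_pclosed", "measure_turnover"]


@dataclass
class PClosedMeasurement:
    p_closed: float
    se: float
    per_seed: list
    n_transitions: int
    total_steps: int

    @property
    def transitions_per_mapped_ms(self) -> float:
        from .constants import STEPS_PER_MS

        return self.n_transitions / (self.total_steps / STEPS_PER_MS)


@dataclass
class TurnoverMeasurement:
    v: float  # 1/ms
    se: float
    n_cycles: int
    per_replica_v: list
    cycle_durations_ms: np.ndarray


def measure_pclosed(
    system: EnzymeSystem,
    seeds,
    n_steps_per_seed: int,
    phi: float = 0.0,
    concentrations: dict | None = None,
    burn_in_frac: float = 0.05,
) -> PClosedMeasurement:
    """Closed-state population pooled over fresh-seed trajectories."""
    conc = concentrations or {"ATP": 0.0, "AMP": 0.0, "ADP": 0.0}
    per_seed = []
    all_labels = []
    n_trans = 0
    for seed in seeds:
        cfg = SimulationConfig(n_steps=int(n_steps_per_seed), seed=int(seed),
                               concentrations=conc)
        crowders = CrowderSystem.for_fraction(phi) if phi > 0 else None
        sites = system.sites if conc.get("ATP", 0) or conc.get("AMP", 0) else None
        res = run_simulation(system.model, cfg, sites,
                             system.chemistry if sites else None, crowders)
        labels = label_trace(res.trace, system.model.r_star_lid,
                             system.model.r_star_nmp)
        burn = int(burn_in_frac * len(labels))
        p, _ = estimate_pclosed(labels, burn_in=burn)
        per_seed.append(p)
        n_trans += count_transitions(labels[burn:])
        all_labels.append(labels[burn:])
    pooled = np.concatenate(all_labels)
    p_pooled = float((pooled == 1).mean())
    se = float(np.std(per_seed, ddof=1) / np.sqrt(len(per_seed))) if len(per_seed) > 1 else np.nan
    return PClosedMeasurement(
        p_closed=p_pooled, se=se, per_seed=per_seed, n_transitions=n_trans,
        total_steps=int(len(seeds) * n_steps_per_seed * (1 - burn_in_frac)),
    )


def measure_turnover(
    system: EnzymeSystem,
    seeds,
    n_steps_per_seed: int,
    phi: float = 0.0,
    atp: float = 300.0,
    amp: float = 300.0,
) -> TurnoverMeasurement:
    """Turnover rate from completed catalytic cycles pooled over replicas."""
    conc = {"ATP": float(atp), "AMP": float(amp), "ADP": 0.0}
    all_cycles = []
    per_replica = []
    for seed in seeds:
        cfg = SimulationConfig(n_steps=int(n_steps_per_seed), seed=int(seed),
                               concentrations=conc)
        crowders = CrowderSystem.for_fraction(phi) if phi > 0 else None
        res = run_simulation(system.model, cfg, system.sites, system.chemistry,
                             crowders)
        cycles = completed_cycles(res.events, cfg.steps_per_ms)
        all_cycles.append(cycles)
        if len(cycles):
            per_replica.append(1.0 / cycles.mean())
    pooled = np.concatenate(all_cycles) if all_cycles else np.empty(0)
    v, se = turnover_rate(pooled)  # raises when no cycle completed
    return TurnoverMeasurement(
        v=v, se=se, n_cycles=len(pooled), per_replica_v=per_replica,
        cycle_durations_ms=pooled,
    )
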