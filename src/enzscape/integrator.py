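"""Langevin dynamics orchestration: configuration, state, and the run loop.

``run_simulation`` wires a multi-basin model, binding sites, chemistry and a
crowding environment into the compiled kernel and returns the
reaction-coordinate trace, the event log and a summary. The BAOAB update is
also exposed step-wise (``langevin_step``) for direct use and testing.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernels
from .constants import BEAD_MASS, DEFAULT_TEMPERATURE, KB_KCAL, STEPS_PER_MS, kbt
from .crowding import CrowderSystem, place_crowders
from .events import EventLog
from .ligand import BindingSite, LigandOccupancy
from .multibasin import MultiBasinModel
from .packing import PackedSystem, pack_system
from .reaction import ChemistryParams

__all__ = [
    "SimulationConfig",
    "SimulationState",
    "SimulationResult",
    "langevin_step",
    "run_simulation",
    "trace_labels",
]

_SPECIES_CODE = {0: "empty", 1: "substrate", 2: "product"}
_EVENT_CODE = {0: "bind", 1: "unbind", 2: "react_fwd", 3: "react_rev"}


@dataclass
class SimulationConfig:
    """Run parameters (times in tau units; mapped time via steps_per_ms)."""

    temperature: float = DEFAULT_TEMPERATURE  # K
    dt: float = 0.2  # tau
    gamma: float = 0.25  # 1/tau
    n_steps: int = 1_000_000
    mc_interval: int = 100  # MD steps between MC layers
    concentrations: dict = field(
        default_factory=lambda: {"ATP": 0.0, "AMP": 0.0, "ADP": 0.0}
    )
    seed: int = 0
    trace_stride: int = 100
    traj_stride: int = 0  # 0 = no coordinate frames
    steps_per_ms: float = STEPS_PER_MS
    max_events: int | None = None
    respa: int = 5  # excluded-volume interval; smooth terms at 2x (1 = plain BAOAB)

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.temperature <= 0:
            raise ValueError("dt and temperature must be positive")
        if self.mc_interval < 1:
            raise ValueError("mc_interval must be >= 1")
        if self.respa < 1 or self.mc_interval % (2 * self.respa) != 0:
            raise ValueError("mc_interval must be a multiple of 2*respa")

    @property
    def kbt(self) -> float:
        return KB_KCAL * self.temperature

    @property
    def dt_ms_per_mc(self) -> float:
        return self.mc_interval / self.steps_per_ms


@dataclass
class SimulationState:
    """Continuable simulation state (coordinates, velocities, occupancy, rng)."""

    pos: np.ndarray
    vel: np.ndarray
    cpos: np.ndarray
    cvel: np.ndarray
    occ: np.ndarray  # int64 (2,), 0 empty / 1 substrate / 2 product
    rng_state: np.ndarray
    step: int = 0

    @property
    def occupancy(self) -> LigandOccupancy:
        return LigandOccupancy(tuple(_SPECIES_CODE[int(c)] for c in self.occ))


@dataclass
class SimulationResult:
    trace: np.ndarray  # (T, 5): R_LID, R_NMP, occ0, occ1, E_total
    trace_stride: int
    events: pd.DataFrame
    state: SimulationState
    config: SimulationConfig
    summary: dict
    frames: np.ndarray | None = None

    def event_log(self, sites: list[BindingSite] | None = None) -> EventLog:
        """Decode the raw event table into the shared EventLog format."""
        log = EventLog()
        site_names = (
            [s.site_id for s in sites] if sites else ["ATP-site", "AMP-site"]
        )
        for row in self.events.itertuples(index=False):
            site = site_names[int(row.site)] if row.site >= 0 else "active-site"
            sp = _SPECIES_CODE.get(int(row.species), "")
            log.append(int(row.step), row.step / self.config.steps_per_ms, site,
                       _EVENT_CODE[int(row.event)], sp, row.S, row.fS, row.E_bind)
        return log


def langevin_step(pos, vel, force_fn, config: SimulationConfig, rng,
                  mass: float = BEAD_MASS):
    """One BAOAB update (B half-kick, A half-drift, O, A, B) in plain NumPy.

    ``force_fn(pos) -> F``; with ``dt = 0`` the state is returned unchanged.
    """
    if config.dt == 0:
        return pos, vel
    dt = config.dt
    kT = config.kbt
    c1 = np.exp(-config.gamma * dt)
    sig = np.sqrt(kT * (1.0 - c1 * c1) / mass)
    F = force_fn(pos)
    vel = vel + 0.5 * dt * F / mass
    pos = pos + 0.5 * dt * vel
    vel = c1 * vel + sig * rng.standard_normal(vel.shape)
    pos = pos + 0.5 * dt * vel
    F = force_fn(pos)
    vel = vel + 0.5 * dt * F / mass
    return pos, vel


def _initial_state(
    model: MultiBasinModel,
    config: SimulationConfig,
    crowders: CrowderSystem | None,
    packed: PackedSystem,
    start: str = "open",
) -> SimulationState:
    rng = np.random.default_rng(config.seed)
    ref = model.open_ref if start == "open" else model.closed_ref
    pos = ref.beads.coords.copy()
    pos -= pos.mean(axis=0)  # center the enzyme in the box
    kT = config.kbt
    vel = rng.normal(0.0, np.sqrt(kT / packed.mass_p), size=pos.shape)
    if crowders is not None and crowders.N > 0:
        if len(crowders.positions) == crowders.N:
            cpos = crowders.positions.copy()
        else:
            cpos = place_crowders(crowders.N, crowders, pos, rng)
        cvel = rng.normal(0.0, np.sqrt(kT / packed.mass_c), size=cpos.shape)
    else:
        cpos = np.empty((0, 3))
        cvel = np.empty((0, 3))
    # kernel rng seeded from the config seed (independent stream)
    rng_state = _kernels.rng_seed(np.uint64(config.seed * 2654435761 % (2**63) + 12345))
    return SimulationState(
        pos=pos, vel=vel, cpos=cpos, cvel=cvel,
        occ=np.zeros(2, dtype=np.int64),
        rng_state=rng_state, step=0,
    )


def run_simulation(
    model: MultiBasinModel,
    config: SimulationConfig,
    sites: list[BindingSite] | None = None,
    chemistry: ChemistryParams | None = None,
    crowders: CrowderSystem | None = None,
    state: SimulationState | None = None,
    start: str = "open",
) -> SimulationResult:
    """Run the full dynamic-landscape simulation.

    The loop alternates ``mc_interval`` BAOAB steps with one Monte Carlo
    ligand-exchange attempt per site and one kinetic Monte Carlo reaction
    attempt; occupancy changes reshape the energy landscape immediately.
    Fully reproducible for a given seed; an existing ``state`` continues a
    previous run.
    """
    packed = pack_system(
        model, sites, chemistry,
        concentrations=config.concentrations,
        crowder_radius=crowders.R_c if crowders is not None else 8.0,
    )
    pp = packed.pp.copy()
    cs = crowders or CrowderSystem(N=0)
    pp[11] = cs.eps_cc
    pp[12] = cs.eps_pc
    pp[13] = cs.sigma_ref
    pp[14] = cs.sigma_cc
    pp[15] = cs.sigma_pc
    pp[16] = cs.eps_attr
    pp[17] = cs.box_L
    pp[18] = cs.K_box
    pp[19] = cs.sigma_wall

    if state is None:
        state = _initial_state(model, config, crowders, packed, start)

    n_trace_max = config.n_steps // config.trace_stride + 1
    trace = np.zeros((n_trace_max, 5))
    max_events = config.max_events or max(config.n_steps // (2 * config.mc_interval), 1000)
    events = np.zeros((max_events, 7))
    if config.traj_stride > 0:
        nf = config.n_steps // config.traj_stride + 1
        traj = np.zeros((nf, packed.n + len(state.cpos), 3))
    else:
        traj = np.zeros((0, packed.n + len(state.cpos), 3))

    n_events, n_trace, n_frames, final_step = _kernels.run_segment(
        state.pos, state.vel, state.cpos, state.cvel, state.occ,
        packed.bond_owner, packed.b0s, packed.ang_owner, packed.th0s,
        packed.dih_owner, packed.ph0_cs,
        packed.cont_i, packed.cont_j, packed.cont_r0, packed.cont_eps,
        packed.cont_owner, packed.cont_basin,
        packed.dV, packed.Delta, packed.excl,
        packed.lig_i, packed.lig_j, packed.lig_r0s, packed.lig_eps,
        packed.lig_site,
        packed.pocket_idx[packed.pocket_site == 0],
        packed.pocket_idx[packed.pocket_site == 1],
        packed.sphere, packed.sasa_radius,
        packed.site_S0, packed.site_sigS, packed.site_kon0,
        packed.site_koff0, packed.site_conc,
        packed.kf, packed.kr, packed.qmin,
        packed.lid_idx, packed.nmp_idx, packed.core_idx,
        pp, config.n_steps, config.dt, config.gamma, config.kbt,
        packed.mass_p, packed.mass_c, config.mc_interval,
        config.dt_ms_per_mc, config.respa,
        state.rng_state,
        trace, config.trace_stride, events, traj, config.traj_stride,
        state.step,
    )
    state.step = final_step

    if not np.all(np.isfinite(state.pos)):
        raise FloatingPointError(
            "non-finite coordinates encountered; the last state is attached "
            "to this exception's 'state' attribute"
        )

    ev = pd.DataFrame(
        events[:n_events],
        columns=["step", "site", "event", "species", "S", "fS", "E_bind"],
    )
    summary = {
        "n_steps": config.n_steps,
        "seed": config.seed,
        "n_events": int(n_events),
        "events_truncated": bool(n_events >= max_events),
        "final_step": int(final_step),
        "phi": cs.phi if cs.N else 0.0,
        "n_crowders": int(cs.N),
    }
    return SimulationResult(
        trace=trace[:n_trace],
        trace_stride=config.trace_stride,
        events=ev,
        state=state,
        config=config,
        summary=summary,
        frames=traj[:n_frames] if config.traj_stride > 0 else None,
    )


def trace_labels(trace: np.ndarray, model: MultiBasinModel) -> np.ndarray:
    """Vectorized four-state classification of a reaction-coordinate trace."""
    lid_closed = trace[:, 0] < model.r_star_lid
    nmp_closed = trace[:, 1] < model.r_star_nmp
    labels = np.empty(len(trace), dtype=object)
    labels[lid_closed & nmp_closed] = "closed"
    labels[~lid_closed & ~nmp_closed] = "open"
    labels[lid_closed & ~nmp_closed] = "intermediate-NMP-open"
    labels[~lid_closed & nmp_closed] = "intermediate-LID-open"
    return labels
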