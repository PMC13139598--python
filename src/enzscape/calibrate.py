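"""Calibration loops for the multi-basin model.

Two iterative procedures tie the model to its target observables:

* :func:`calibrate_energy_gap` adjusts the per-term energy gaps ``dV`` until
  apo dilute sampling reproduces a target closed-state population
  ``P_closed`` (larger gaps penalize the closed basin). The update is a
  damped step proportional to ``log(P_hat / P_target)`` in units of kB*T,
  bounded per iteration.
* :func:`calibrate_barrier` adjusts the shared barrier parameter ``Delta``
  until the apo open<->closed transition frequency matches a target rate
  per step (the time-mapping calibration).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analysis import count_transitions, estimate_pclosed, label_trace
from .constants import KBT_300, STEPS_PER_MS
from .integrator import SimulationConfig, run_simulation
from .multibasin import MultiBasinModel

__all__ = ["CalibrationReport", "calibrate_energy_gap", "calibrate_barrier",
           "sample_apo"]

#: Default transition-interval target: one open<->closed transition per this
#: many MD steps (7.0 transitions per mapped ms at the standard time mapping).
TRANSITION_INTERVAL_TARGET = STEPS_PER_MS / 7.0


@dataclass
class CalibrationReport:
    converged: bool
    iterations: int
    history: list = field(default_factory=list)  # (param value(s), estimate, se)
    final_estimate: float = np.nan
    message: str = ""


def sample_apo(
    model: MultiBasinModel,
    n_steps: int,
    seed: int,
    respa: int = 5,
):
    """Apo dilute sampling run; returns (labels, n_transitions, trace)."""
    cfg = SimulationConfig(
        n_steps=int(n_steps), seed=int(seed),
        concentrations={"ATP": 0.0, "AMP": 0.0, "ADP": 0.0},
        respa=respa,
    )
    res = run_simulation(model, cfg)
    labels = label_trace(res.trace, model.r_star_lid, model.r_star_nmp)
    return labels, count_transitions(labels), res.trace


def calibrate_energy_gap(
    model: MultiBasinModel,
    target_pclosed: float,
    n_steps: int = 10_000_000,
    tolerance: float = 0.05,
    max_iter: int = 8,
    seed: int = 1234,
    damping: float = 0.5,
    max_step: float = 2.0,
    kbt: float = KBT_300,
    burn_in_frac: float = 0.05,
) -> CalibrationReport:
    """Iterate dV until apo sampling matches the target closed population.

    Each iteration runs an apo dilute trajectory, estimates P_closed, and
    shifts every term's gap by ``damping * kBT * log(P_hat / P_target)``
    (clipped to ``max_step * kBT``); a population above target raises the
    gaps (penalizing the closed state). The model is modified in place; the
    report carries the (dV, P_hat) history. Non-convergence is flagged, not
    silent.
    """
    if not (0.0 < target_pclosed < 1.0):
        raise ValueError("target P_closed must be in (0, 1)")
    history = []
    p_hat = np.nan
    for it in range(max_iter):
        labels, _, _ = sample_apo(model, n_steps, seed + 101 * it)
        burn = int(burn_in_frac * len(labels))
        p_hat, se = estimate_pclosed(labels, burn_in=burn)
        history.append((dict(model.energy_gaps()), p_hat, se))
        if abs(p_hat - target_pclosed) <= tolerance:
            return CalibrationReport(
                converged=True, iterations=it + 1, history=history,
                final_estimate=p_hat,
                message=f"converged: P_closed = {p_hat:.3f} (target {target_pclosed})",
            )
        # guard the log for one-sided estimates
        p_eff = min(max(p_hat, 1e-4), 1.0 - 1e-4)
        step = damping * kbt * np.log(p_eff / target_pclosed)
        step = float(np.clip(step, -max_step * kbt, max_step * kbt))
        for t in model.terms:
            t.dV += step
    return CalibrationReport(
        converged=False, iterations=max_iter, history=history,
        final_estimate=p_hat,
        message=f"did not converge within {max_iter} iterations "
                f"(last P_closed = {p_hat:.3f}, target {target_pclosed})",
    )


def calibrate_barrier(
    model: MultiBasinModel,
    target_interval: float = TRANSITION_INTERVAL_TARGET,
    n_steps: int = 10_000_000,
    rel_tolerance: float = 0.3,
    max_iter: int = 8,
    seed: int = 4321,
    damping: float = 0.35,
    kbt: float = KBT_300,
) -> CalibrationReport:
    """Iterate the shared Delta until the apo transition interval matches.

    The measured interval is ``n_steps / n_transitions``; Delta moves by a
    damped multiplicative-log step (larger Delta lowers the barrier and
    speeds transitions). Updates all three terms to a single shared value.
    """
    history = []
    interval = np.nan
    for it in range(max_iter):
        _, n_trans, _ = sample_apo(model, n_steps, seed + 77 * it)
        interval = n_steps / max(n_trans, 1)
        delta = model.terms[0].Delta
        history.append((delta, interval, n_trans))
        if n_trans >= 5 and abs(np.log(interval / target_interval)) <= rel_tolerance:
            return CalibrationReport(
                converged=True, iterations=it + 1, history=history,
                final_estimate=interval,
                message=f"converged: one transition per {interval:.3g} steps",
            )
        # too few transitions (interval too long) -> raise Delta
        step = damping * kbt * np.log(interval / target_interval)
        new_delta = max(delta + step, 0.05)
        model.set_barrier(new_delta)
    return CalibrationReport(
        converged=False, iterations=max_iter, history=history,
        final_estimate=interval,
        message=f"did not converge (last interval {interval:.3g} steps, "
                f"target {target_interval:.3g})",
    )
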