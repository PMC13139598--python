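"""Kinetic and thermodynamic observables from traces and event logs.

All estimators are pure functions of recorded trajectories/event tables, so
analyses are replayable: re-running them on the same inputs gives identical
numbers.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .constants import KBT_300, STEPS_PER_MS

__all__ = [
    "label_trace",
    "count_transitions",
    "estimate_pclosed",
    "completed_cycles",
    "turnover_rate",
    "fit_michaelis_menten",
    "first_passage_times",
    "mfpt",
    "fes_2d",
    "KineticsResult",
]


@dataclass
class KineticsResult:
    """Bundle of kinetic observables for one condition."""

    v: float = np.nan  # turnover rate, 1/ms
    v_se: float = np.nan
    n_cycles: int = 0
    k_cat: float = np.nan  # 1/ms
    K_M: float = np.nan  # uM
    k_cat_ci: tuple = (np.nan, np.nan)
    K_M_ci: tuple = (np.nan, np.nan)
    mfpt_bind: float = np.nan  # ms
    mfpt_release: float = np.nan  # ms
    p_closed: float = np.nan
    p_closed_se: float = np.nan
    extra: dict = field(default_factory=dict)


# --------------------------------------------------------------- states ---


def label_trace(trace: np.ndarray, r_star_lid: float, r_star_nmp: float) -> np.ndarray:
    """Integer state labels per frame: 0 open, 1 closed, 2 LID-open, 3 NMP-open."""
    lid_closed = trace[:, 0] < r_star_lid
    nmp_closed = trace[:, 1] < r_star_nmp
    out = np.zeros(len(trace), dtype=np.int64)
    out[lid_closed & nmp_closed] = 1
    out[~lid_closed & nmp_closed] = 2  # LID open, NMP closed
    out[lid_closed & ~nmp_closed] = 3  # NMP open, LID closed
    return out


def count_transitions(labels: np.ndarray) -> int:
    """Open <-> closed transitions, tracking the last definite macro-state.

    Intermediate frames (one domain open) belong to neither macro-state; a
    transition is counted each time the trajectory reaches the macro-state
    opposite to the last one visited.
    """
    definite = labels[(labels == 0) | (labels == 1)]
    if len(definite) == 0:
        return 0
    return int(np.sum(np.abs(np.diff(definite)) > 0))


def estimate_pclosed(
    labels: np.ndarray,
    burn_in: int = 0,
    block: int | None = None,
):
    """Closed-state fraction with a block-bootstrap standard error.

    ``block`` is the block length in frames (autocorrelation-aware); by
    default one tenth of the post-burn-in trace, capped at 2000 frames.
    """
    lab = labels[burn_in:]
    if len(lab) == 0:
        raise ValueError("empty trace after burn-in")
    x = (lab == 1).astype(float)
    p = float(x.mean())
    if block is None:
        block = max(1, min(len(x) // 10, 2000))
    nblocks = len(x) // block
    if nblocks < 2:
        return p, float("nan")
    means = x[: nblocks * block].reshape(nblocks, block).mean(axis=1)
    se = float(means.std(ddof=1) / np.sqrt(nblocks))
    return p, se


# -------------------------------------------------------------- turnover --


def completed_cycles(events: pd.DataFrame, steps_per_ms: float = STEPS_PER_MS):
    """Durations (ms) of completed catalytic cycles from an event table.

    A cycle completes when the second product is released after a forward
    reaction; a reverse reaction rolls the cycle state back. The event table
    uses the kernel's raw schema (columns step/site/event/species with codes
    0=bind 1=unbind 2=react_fwd 3=react_rev).
    """
    durations = []
    cycle_start = 0.0
    reacted = False
    products_out = 0
    for row in events.itertuples(index=False):
        code = int(row.event)
        if code == 2:  # forward reaction
            reacted = True
            products_out = 0
        elif code == 3:  # reverse: roll back
            reacted = False
        elif code == 1 and reacted and int(row.species) == 2:
            products_out += 1
            if products_out >= 2:
                t = row.step / steps_per_ms
                durations.append(t - cycle_start)
                cycle_start = t
                reacted = False
                products_out = 0
        elif code == 0 and reacted and int(row.species) == 2:
            # a released product rebound before full release
            products_out = max(0, products_out - 1)
    return np.asarray(durations)


def turnover_rate(cycle_durations: np.ndarray):
    """Turnover rate 1/mean(cycle time) with a delta-method standard error.

    Raises ``ValueError`` when no completed cycle exists (the rate is
    undefined, not zero).
    """
    d = np.asarray(cycle_durations, dtype=float)
    if len(d) == 0:
        raise ValueError("no completed catalytic cycles: turnover undefined")
    mean = d.mean()
    v = 1.0 / mean
    if len(d) > 1:
        se = d.std(ddof=1) / np.sqrt(len(d)) / mean**2
    else:
        se = np.nan
    return float(v), float(se)


# ------------------------------------------------------ Michaelis-Menten --


def _mm(s, kcat, km):
    return kcat * s / (km + s)


def fit_michaelis_menten(
    concentrations: np.ndarray,
    rates: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    replica_rates: "list[np.ndarray] | None" = None,
):
    """Nonlinear least-squares fit of v = k_cat [S] / (K_M + [S]).

    ``rates`` holds the mean rate per concentration. When ``replica_rates``
    (list of per-concentration arrays of replica estimates) is given, the
    bootstrap resamples replicas within each concentration; otherwise it
    resamples residuals. Percentile confidence intervals are returned as
    ``(kcat, km, (kcat_lo, kcat_hi), (km_lo, km_hi))``.
    """
    s = np.asarray(concentrations, dtype=float)
    v = np.asarray(rates, dtype=float)
    if len(s) < 3:
        raise ValueError("at least 3 concentration points are required")
    p0 = (max(v.max(), 1e-9), max(np.median(s), 1.0))
    popt, _ = curve_fit(_mm, s, v, p0=p0, maxfev=20000,
                        bounds=([0.0, 0.0], [np.inf, np.inf]))
    kcat, km = float(popt[0]), float(popt[1])

    rng = np.random.default_rng(seed)
    boots = []
    resid = v - _mm(s, kcat, km)
    for _ in range(n_boot):
        if replica_rates is not None:
            vb = np.array([
                rng.choice(r, size=len(r), replace=True).mean()
                for r in replica_rates
            ])
        else:
            vb = _mm(s, kcat, km) + rng.choice(resid, size=len(s), replace=True)
        try:
            pb, _ = curve_fit(_mm, s, np.maximum(vb, 0.0), p0=popt, maxfev=5000,
                              bounds=([0.0, 0.0], [np.inf, np.inf]))
            boots.append(pb)
        except RuntimeError:
            continue
    if boots:
        boots = np.asarray(boots)
        kcat_ci = tuple(np.percentile(boots[:, 0], [2.5, 97.5]))
        km_ci = tuple(np.percentile(boots[:, 1], [2.5, 97.5]))
    else:  # pragma: no cover - pathological data
        kcat_ci = (np.nan, np.nan)
        km_ci = (np.nan, np.nan)
    return kcat, km, kcat_ci, km_ci


# ----------------------------------------------------------------- MFPT ---


def first_passage_times(
    start_mask: np.ndarray,
    end_mask: np.ndarray,
    frame_ms: float,
):
    """First-passage durations (ms) from every qualifying start.

    A passage begins at each frame where ``start_mask`` holds while no
    passage is in progress, and completes at the next frame where
    ``end_mask`` holds.
    """
    times = []
    in_passage = False
    t0 = 0
    for k in range(len(start_mask)):
        if not in_passage and start_mask[k]:
            in_passage = True
            t0 = k
        elif in_passage and end_mask[k]:
            times.append((k - t0) * frame_ms)
            in_passage = False
    return np.asarray(times)


def mfpt(passages: np.ndarray, n_boot: int = 1000, seed: int = 0):
    """Mean first-passage time with a bootstrap CI over individual passages."""
    p = np.asarray(passages, dtype=float)
    if len(p) == 0:
        raise ValueError("no qualifying passages: MFPT undefined")
    rng = np.random.default_rng(seed)
    boots = np.array([
        rng.choice(p, size=len(p), replace=True).mean() for _ in range(n_boot)
    ])
    return float(p.mean()), (float(np.percentile(boots, 2.5)),
                             float(np.percentile(boots, 97.5)))


# ------------------------------------------------------------------ FES ---


def fes_2d(
    trace: np.ndarray,
    bin_width: float = 1.0,
    kbt: float = KBT_300,
    ranges: "tuple | None" = None,
):
    """2D free-energy surface over (R_LID-CORE, R_NMP-CORE).

    Returns ``(F, lid_edges, nmp_edges)`` with F in units of kB*T, minimum
    shifted to zero and empty bins set to +inf.
    """
    if len(trace) < 1:
        raise ValueError("empty trace")
    x = trace[:, 0]
    y = trace[:, 1]
    if ranges is None:
        ranges = ((x.min(), x.max() + 1e-9), (y.min(), y.max() + 1e-9))
    nx = max(1, int(np.ceil((ranges[0][1] - ranges[0][0]) / bin_width)))
    ny = max(1, int(np.ceil((ranges[1][1] - ranges[1][0]) / bin_width)))
    H, xe, ye = np.histogram2d(x, y, bins=(nx, ny), range=ranges)
    with np.errstate(divide="ignore"):
        F = -np.log(H / H.sum())
    F[np.isinf(F)] = np.inf
    F -= F[np.isfinite(F)].min()
    return F, xe, ye
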