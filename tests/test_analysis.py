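"""Kinetic estimators: turnover, Michaelis-Menten, MFPT, FES, P_closed."""
import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from enzscape.analysis import (
    completed_cycles,
    count_transitions,
    estimate_pclosed,
    fes_2d,
    first_passage_times,
    fit_michaelis_menten,
    label_trace,
    mfpt,
    turnover_rate,
)
from enzscape.constants import STEPS_PER_MS


def _event_frame(rows):
    """rows: (step, event_code, species_code)"""
    return pd.DataFrame(
        [(s, 0, e, sp, 0.0, 0.0, 0.0) for s, e, sp in rows],
        columns=["step", "site", "event", "species", "S", "fS", "E_bind"],
    )


def _cycle_rows(start_step, period):
    """bind, bind, react, unbind(product) x2 -> one completed cycle."""
    return [
        (start_step + 0.1 * period, 0, 1),
        (start_step + 0.2 * period, 0, 1),
        (start_step + 0.5 * period, 2, 0),
        (start_step + 0.8 * period, 1, 2),
        (start_step + 1.0 * period, 1, 2),
    ]


class TestTurnover:
    def test_uniform_cycles(self):
        period = 2.0 * STEPS_PER_MS  # 2 ms per cycle
        rows = []
        for k in range(5):
            rows += _cycle_rows(k * period, period)
        cycles = completed_cycles(_event_frame(rows))
        assert len(cycles) == 5
        v, _ = turnover_rate(cycles)
        assert v == pytest.approx(0.5, rel=1e-9)

    def test_mean_time_definition(self):
        # durations 1 ms and 3 ms: v = 1/mean = 0.5, not mean of rates
        rows = _cycle_rows(0.0, 1.0 * STEPS_PER_MS)
        rows += _cycle_rows(1.0 * STEPS_PER_MS, 3.0 * STEPS_PER_MS)
        cycles = completed_cycles(_event_frame(rows))
        np.testing.assert_allclose(cycles, [1.0, 3.0], rtol=1e-9)
        v, _ = turnover_rate(cycles)
        assert v == pytest.approx(0.5)

    def test_empty_log_flagged(self):
        cycles = completed_cycles(_event_frame([]))
        assert len(cycles) == 0
        with pytest.raises(ValueError, match="undefined"):
            turnover_rate(cycles)

    def test_reverse_reaction_rolls_back(self):
        period = STEPS_PER_MS
        rows = [
            (0.1 * period, 0, 1), (0.2 * period, 0, 1),
            (0.3 * period, 2, 0),          # forward
            (0.4 * period, 3, 0),          # reverse: no product release counts
            (0.5 * period, 1, 1),          # substrates leave instead
            (0.6 * period, 1, 1),
        ]
        assert len(completed_cycles(_event_frame(rows))) == 0


class TestMichaelisMenten:
    def test_exact_recovery_on_noise_free_points(self):
        s = np.array([10.0, 50.0, 100.0, 300.0, 1000.0])
        v = 200.0 * s / (50.0 + s)
        kcat, km, _, _ = fit_michaelis_menten(s, v, n_boot=10)
        assert kcat == pytest.approx(200.0, rel=1e-6)
        assert km == pytest.approx(50.0, rel=1e-6)

    def test_concentration_independent_rates_flag_km_boundary(self):
        s = np.array([10.0, 100.0, 1000.0])
        v = np.full(3, 5.0)
        kcat, km, _, _ = fit_michaelis_menten(s, v, n_boot=10)
        assert km < 1.0  # saturated everywhere: K_M collapses to ~0

    def test_bootstrap_coverage_with_noise(self):
        """True parameters fall inside the 95% CI in >= 90% of repetitions
        (5% multiplicative noise, 20 replicas per concentration)."""
        s = np.array([10.0, 50.0, 100.0, 300.0, 1000.0])
        true = 200.0 * s / (50.0 + s)
        master = np.random.default_rng(2024)
        hits_kcat = 0
        hits_km = 0
        n_rep = 70
        for rep in range(n_rep):
            reps = [true[i] * (1 + master.normal(0, 0.05, 20)) for i in range(len(s))]
            v = np.array([r.mean() for r in reps])
            kcat, km, kcat_ci, km_ci = fit_michaelis_menten(
                s, v, n_boot=150, seed=rep, replica_rates=reps
            )
            hits_kcat += kcat_ci[0] <= 200.0 <= kcat_ci[1]
            hits_km += km_ci[0] <= 50.0 <= km_ci[1]
        assert hits_kcat >= 0.9 * n_rep
        assert hits_km >= 0.9 * n_rep

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_michaelis_menten(np.array([1.0, 2.0]), np.array([0.1, 0.2]))


class TestMFPT:
    def test_explicit_passages(self):
        m, ci = mfpt(np.array([1.0, 2.0, 3.0]), n_boot=200)
        assert m == pytest.approx(2.0)
        assert ci[0] <= m <= ci[1]

    def test_no_passages_flagged(self):
        with pytest.raises(ValueError, match="undefined"):
            mfpt(np.array([]))

    def test_first_passage_extraction(self):
        start = np.array([1, 0, 0, 1, 0, 0, 0, 0], dtype=bool)
        end = np.array([0, 0, 1, 0, 0, 1, 0, 0], dtype=bool)
        times = first_passage_times(start, end, frame_ms=0.5)
        np.testing.assert_allclose(times, [1.0, 1.0])

    def test_double_well_matches_smoluchowski_quadrature(self):
        """Overdamped 1D double well: simulated MFPT agrees with the double
        integral of the Smoluchowski mean-first-passage formula within 20%."""
        # V(x) = h ((x/a)^2 - 1)^2, barrier h at x = 0
        h_bar, a = 1.2, 1.0
        kT = 0.6
        gamma_m = 20.0  # friction * mass: overdamped
        D = kT / gamma_m

        def V(x):
            return h_bar * ((x / a) ** 2 - 1.0) ** 2

        def dV(x):
            return 4.0 * h_bar * x * ((x / a) ** 2 - 1.0) / a**2

        x_start, x_end = -a, 0.6 * a
        # MFPT(x0 -> b) = (1/D) int_x0^b dy e^{V(y)/kT} int_{-inf}^y dz e^{-V(z)/kT}
        inner = lambda y: integrate.quad(
            lambda z: np.exp(-V(z) / kT), -4 * a, y)[0]
        oracle = integrate.quad(
            lambda y: np.exp(V(y) / kT) * inner(y) / D, x_start, x_end)[0]

        # overdamped (Euler-Maruyama) simulation of many walkers
        rng = np.random.default_rng(5)
        n_walk = 400
        dt = 2e-3
        x = np.full(n_walk, x_start)
        alive = np.ones(n_walk, dtype=bool)
        t_hit = np.zeros(n_walk)
        steps = 0
        while alive.any() and steps < 2_000_000:
            steps += 1
            xa = x[alive]
            xa = xa - dV(xa) / gamma_m * dt + np.sqrt(2 * D * dt) * rng.normal(size=len(xa))
            x[alive] = xa
            hit = np.zeros_like(alive)
            hit[alive] = xa >= x_end
            t_hit[hit] = steps * dt
            alive &= ~hit
        sim = t_hit[t_hit > 0].mean()
        assert sim == pytest.approx(oracle, rel=0.20)


class TestFES:
    def test_single_bin(self):
        trace = np.tile([[10.0, 12.0, 0, 0, 0.0]], (50, 1))
        F, xe, ye = fes_2d(trace, bin_width=1.0)
        finite = F[np.isfinite(F)]
        assert len(finite) == 1 and finite[0] == 0.0

    def test_seventy_thirty_split(self):
        trace = np.zeros((100, 5))
        trace[:70, 0], trace[:70, 1] = 10.0, 10.0
        trace[70:, 0], trace[70:, 1] = 20.0, 20.0
        F, _, _ = fes_2d(trace, bin_width=1.0)
        finite = np.sort(F[np.isfinite(F)])
        assert finite[0] == 0.0
        assert finite[1] == pytest.approx(np.log(7.0 / 3.0), abs=1e-12)

    def test_renormalized_weights_recover_bin_probabilities(self):
        rng = np.random.default_rng(0)
        trace = np.zeros((5000, 5))
        trace[:, 0] = rng.normal(25, 2, 5000)
        trace[:, 1] = rng.normal(20, 2, 5000)
        F, xe, ye = fes_2d(trace, bin_width=0.5)
        w = np.exp(-F)
        w[~np.isfinite(F)] = 0.0
        w /= w.sum()
        H, _, _ = np.histogram2d(trace[:, 0], trace[:, 1], bins=(xe, ye))
        np.testing.assert_allclose(w, H / H.sum(), atol=1e-9)
        assert w.sum() == pytest.approx(1.0, abs=1e-9)


class TestPclosed:
    def test_all_closed(self):
        labels = np.ones(100, dtype=np.int64)
        p, _ = estimate_pclosed(labels)
        assert p == 1.0

    def test_alternating(self):
        labels = np.tile([0, 1], 500)
        p, _ = estimate_pclosed(labels)
        assert p == 0.5

    def test_transition_counting_ignores_intermediates(self):
        labels = np.array([0, 0, 2, 1, 1, 3, 3, 0, 2, 2, 1])
        # macro sequence: open -> closed -> open -> closed = 3 transitions
        assert count_transitions(labels) == 3

    def test_label_trace_quadrants(self):
        trace = np.array([
            [30.0, 26.0, 0, 0, 0],  # both open
            [20.0, 18.0, 0, 0, 0],  # both closed
            [30.0, 18.0, 0, 0, 0],  # LID open only
            [20.0, 26.0, 0, 0, 0],  # NMP open only
        ])
        labels = label_trace(trace, r_star_lid=25.0, r_star_nmp=22.0)
        np.testing.assert_array_equal(labels, [0, 1, 2, 3])

    def test_boltzmann_two_state_weights(self):
        """Sampling a two-level system with 7:3 open:closed Boltzmann
        weights reproduces P_closed = 0.3 within 3 SE."""
        rng = np.random.default_rng(9)
        # Metropolis chain on two states with energy gap kT ln(7/3)
        p_closed = 0.3
        labels = np.empty(200_000, dtype=np.int64)
        state = 0
        for k in range(len(labels)):
            prop = 1 - state
            ratio = (p_closed / (1 - p_closed)) if prop == 1 else ((1 - p_closed) / p_closed)
            if rng.random() < min(1.0, ratio):
                state = prop
            labels[k] = state
        p, se = estimate_pclosed(labels, block=200)
        assert abs(p - 0.3) < 3 * se + 0.005


class TestEnzymeMFPT:
    def test_substrate_binding_mfpt_falls_with_concentration(self):
        """The mean first-passage time from the open apo state to the closed
        state with both substrates bound decreases at higher substrate
        concentration (binding is concentration-limited; conformational
        release is not)."""
        from enzscape.adk import build_enzyme_model
        from enzscape.integrator import SimulationConfig, run_simulation

        system = build_enzyme_model()
        m = system.model
        out = {}
        for conc in (100.0, 1200.0):
            passages = []
            for seed in (31, 32):
                cfg = SimulationConfig(
                    n_steps=2_000_000, seed=seed,
                    concentrations={"ATP": conc, "AMP": conc, "ADP": 0.0},
                )
                res = run_simulation(m, cfg, system.sites, system.chemistry)
                tr = res.trace
                labels = label_trace(tr, m.r_star_lid, m.r_star_nmp)
                apo_open = (labels == 0) & (tr[:, 2] == 0) & (tr[:, 3] == 0)
                competent = (labels == 1) & (tr[:, 2] == 1) & (tr[:, 3] == 1)
                frame_ms = cfg.trace_stride / cfg.steps_per_ms
                passages.extend(first_passage_times(apo_open, competent, frame_ms))
            out[conc] = mfpt(np.asarray(passages), n_boot=200)[0]
        assert out[1200.0] < out[100.0]
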