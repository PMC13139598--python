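# enzscape

Residue-resolved **dynamic energy landscape** simulations of a full enzymatic
catalytic cycle under macromolecular crowding.

Enzymes like adenylate kinase catalyze by moving: two arms (LID and NMP)
close over a rigid CORE to form the catalytically competent state, the
chemical step fires, and the arms must reopen to release products. Inside
cells this happens in a medium ~30% occupied by other macromolecules.
`enzscape` is a simulation package for studying how such crowding reshapes
the *whole* cycle — conformational dynamics, substrate binding, chemistry
and product release together — at a resolution (one bead per residue) where
hundreds of milliseconds of mapped time are tractable on a laptop.

The model couples three layers:

* **Conformational dynamics** — Langevin dynamics on a multi-basin
  structure-based potential. Each moving subsystem i (LID–CORE, NMP–CORE,
  LID–NMP) mixes an open and a closed Gō-type sub-potential,

  ```
  V_DB = (V_open + V_closed + ΔV)/2 − sqrt(((V_open − V_closed − ΔV)/2)² + Δ²)
  ```

  where ΔV_i sets the open/closed energy gap (calibrated so the apo enzyme
  spends P_closed ≈ 0.3 of its time closed) and Δ the barrier.
* **Implicit ligand exchange** — bound ligands are sets of attractive
  pocket restraints, switched on and off by a Metropolis Monte Carlo layer
  with rates `k_on = f(S)·k_on⁰·[L]` and
  `k_off = f(S)·k_off⁰·exp(V_bind/kBT)`, gated by the pocket's
  solvent-accessible surface area S through a logistic f(S).
* **Chemistry** — a kinetic Monte Carlo step converts
  (ATP, AMP) → (ADP, ADP) with rate k_f (reverse k_r) only from the
  competent state: closed, both substrates bound, pocket contacts formed.

Crowders are inert repulsive spheres (radius 8 Å) in a soft-walled box;
their count sets the occupied volume fraction φ via
`N = φV/(4/3 πR_c³)` (140 crowders at φ = 0.3 in the standard 10⁶ Å³ box).
Turnover rates, Michaelis–Menten fits with bootstrap errors, mean
first-passage times and 2-D free-energy surfaces are computed from the
recorded traces and event logs.

Because two-conformation crystal pairs cannot be bundled, the package
generates its own fully synthetic test enzyme: a deterministic 214-residue,
three-domain helix-bundle protein with hinged LID/NMP arms (clearly labelled
synthetic — it reproduces the *architecture* and *mechanisms* of the real
system, not its coordinates). `load_calpha_model` reads any real CA-only or
full PDB file if you have one.

## Worked example

```python
from enzscape import build_enzyme_model, run_simulation, SimulationConfig, CrowderSystem
from enzscape.analysis import completed_cycles, turnover_rate, label_trace, estimate_pclosed

system = build_enzyme_model()          # calibrated wild-type-like enzyme
cfg = SimulationConfig(
    n_steps=2_000_000, seed=1,
    concentrations={"ATP": 300.0, "AMP": 300.0, "ADP": 0.0},
)
res = run_simulation(system.model, cfg, system.sites, system.chemistry,
                     crowders=CrowderSystem.for_fraction(0.3))

cycles = completed_cycles(res.events, cfg.steps_per_ms)
v, se = turnover_rate(cycles)
labels = label_trace(res.trace, system.model.r_star_lid, system.model.r_star_nmp)
p, pse = estimate_pclosed(labels, burn_in=500)
print(f"{len(cycles)} cycles, turnover {v:.1f}/ms, P_closed {p:.2f}")
```

Output from this exact snippet:

```
26 cycles, turnover 23.6/ms, P_closed 0.55
```

meaning: in ~1.1 mapped milliseconds at φ = 0.3 the enzyme completed 26
catalytic cycles (bind, bind, react, release, release) and spent 55% of its
time in the closed conformation. A single run this short is a fluctuating
snapshot — the apo conformational modes of the model relax over millions of
steps, so populations and rates from individual seeds scatter widely and
production measurements pool many replicas (see `docs/methods.md`). Across
such pooled measurements, crowding compacts the ensemble and raises the
closed population, slightly slows this wild-type-like model, and — after an
open-biased gap shift (`build_enzyme_model(dV=+8.0)`) — *accelerates*
turnover severalfold, because reaching the closed competent state is then
rate-limiting.

The same workflows are available from the shell:

```bash
enzscape fixture --enzyme            # write the synthetic open/closed PDB pair
enzscape run --steps 2000000 --phi 0.3 --atp 300 --amp 300 --seed 1
enzscape analyze run_trace.tsv run_events.tsv
enzscape calibrate --target-pclosed 0.3
```

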