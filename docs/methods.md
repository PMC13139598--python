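# Methods

`enzscape` simulates the full catalytic cycle of a two-domain-armed
phosphotransferase — modeled on adenylate kinase's CORE/LID/NMP
architecture — as residue-resolved Langevin dynamics on a *dynamic* energy
landscape: a multi-basin structure-based potential whose composition changes
whenever the implicit ligand state changes through binding, unbinding or the
chemical step. This note documents the model, its parameters, the numerical
choices, and what the synthetic test system does and does not establish.

## The conformational model

Each residue is one bead at its Cα position. A single conformational basin
is a structure-based (Gō-type) potential built from a reference structure:

* harmonic bonds, `V_bond = Σ k_b (b − b⁰)²` with `k_b = 100 kcal/mol/Å²`;
* Gaussian restraints on bond angles and dihedrals,
  `−ε exp(−(x − x⁰)²/2w²)`, with `ε_θ = ε_φ = 1.0 kcal/mol`,
  `w_θ = 0.15 rad`, `w_φ = 0.3 rad` (dihedral differences wrapped to
  (−π, π]);
* a *flexible-local prior*: a second, weak and broad Gaussian
  (`ε_flp = 0.1`, doubled widths) on every angle and dihedral. It is a
  deliberately simplified stand-in for sequence-dependent coil-library
  statistics: uniform across the chain, centered on the open-reference
  natives, and evaluated once globally (not per basin). `ε_flp = 0`
  disables it;
* Gaussian native-contact attractions between residue pairs more than four
  apart in sequence and within 8.0 Å in the reference
  (`ε_c = 0.5 kcal/mol` per contact, width `w_c = 2.5 Å`). The width is a
  load-bearing choice: narrow contact Gaussians have no basin of
  attraction, leaving the reference interfaces kinetically unreachable
  ("golf-hole" landscape); 2.5 Å restores a funnel so docked states
  actually form. Cross-domain (interface) contacts are down-weighted by
  0.5 relative to intra-domain ones so docked states remain kinetically
  escapable, and closed-interface contacts carry a structural
  strengthening factor (1.5 by default) that sets the baseline
  closed-state stability the energy-gap loop fine-tunes around;
* a truncated-and-shifted `ε(σ/r)¹²` repulsion (σ = 4 Å, cutoff 2.5 σ)
  between all remaining pairs more than four apart in sequence; native
  contacts of either reference are excluded from it.

Two reference conformations (open and closed) define two such potentials.
The protein is decomposed into a rigid core term (all elements and contacts
internal to CORE, using open-reference natives) plus three double-basin
terms — LID–CORE, NMP–CORE, and the LID–NMP coupling — with unique
ownership: every bonded element or contact belongs to exactly one term.
Each double-basin term mixes its open/closed restricted sub-potentials as

    V_DB = (V₁ + V₂ + ΔV)/2 − sqrt(((V₁ − V₂ − ΔV)/2)² + Δ²)

`ΔV` (per term) sets the open/closed energy gap — positive values penalize
the closed basin — and `Δ` lowers and smooths the transition barrier.
Forces follow by the chain rule; the basin-1 weight `(1 − u/√(u²+Δ²))/2`
lies in [0, 1]. Since `V_DB(V₁+c, V₂+c) = V_DB(V₁,V₂) + c`, elements whose
open and closed natives coincide can be moved losslessly into the unmixed
core term; the simulation engine does this automatically.

Conformations are classified by the LID–CORE and NMP–CORE center-of-mass
distances (uniform masses) against parameter-free midpoint thresholds
`R* = (R_open + R_closed)/2`, giving four states: open, closed, and the two
single-arm-open intermediates.

## Calibration

Two loops tie the free parameters to observables, mirroring how such models
are tuned against experiment:

* the **energy gap** loop shifts all three `ΔV` by damped steps
  `0.5 kBT ln(P̂/P_target)` (clipped at 2 kBT per iteration) until apo
  dilute sampling reproduces the target closed-state population, 0.3 for
  the wild-type-like model;
* the **barrier** loop adjusts the shared `Δ` until the apo open↔closed
  transition interval matches the time mapping (below).

Variant models with other intrinsic closed propensities are seeded from an
empirical gap shift, `δ = Δlogit(P)/s` with the measured sensitivity
`s ≈ −0.13 logit per kcal/mol`, optionally refined by the gap loop. The
sensitivity is far weaker than the naive `−3/kBT` because the open
macrostate is an entropically broad ensemble whose statistical weight
barely involves the closed sub-potentials; only the docked fraction
responds to the gap.

## Time mapping

Coarse-grained dynamics do not preserve absolute time. Physical time is
assigned by the standard calibration for this enzyme: 2×10⁸ MD steps ↔
≈112 ms, chosen so the calibrated apo model shows ≈7 open↔closed
transitions per mapped millisecond (one per ≈2.55×10⁵ steps). All rate
constants (binding, catalysis) are expressed per mapped millisecond.

## Implicit ligands and the chemical step

Ligands are not particles. A bound species at a pocket adds attractive
Gaussian restraints (width 1 Å) between pocket residue pairs at their
holo-structure distances. Pairs come in two groups: *closure* pairs bridge
the arm–core interface at separations just beyond the native-contact cutoff
(8–11 Å in the closed structure — residues that interact through the
bridging ligand), so a bound ligand stabilizes closure; *anchor* pairs lie
within one domain of the pocket region and hold the ligand regardless of
conformation. The restraint width is 1.5 Å: thermal fluctuations of the
8–11 Å pocket distances are ±1–2 Å, and a narrower width would blur away
most of the nominal binding free energy. Default depths split evenly over pairs: substrates 3 + 3
kcal/mol (anchor + closure), products 1.5 + 1.5 — products bind more weakly,
making release feasible, and [ADP] = 0 in all standard runs so released
products never rebind.

Exchange is Metropolis MC every 100 MD steps per site, with rates
`k_on = f(S) k_on⁰ [L]` and `k_off = f(S) k_off⁰ exp(V_bind/kBT)`
(`V_bind ≤ 0`: deeper stabilization releases slower), event probability
`1 − exp(−k Δt)`. The gate `f(S) = 1/(1+exp(−(S−S₀)/σ_S))` uses the
Shrake–Rupley solvent-accessible area of the pocket beads (sphere radius
3.4 Å + 1.4 Å probe, 240 deterministic golden-spiral points). `S₀` sits at
the midpoint of the open- and closed-reference pocket areas with
`σ_S = 0.12 (S_open − S_closed)`: the synthetic pockets bury less area on
closing than a real active-site cleft, so the midpoint (not a fraction of
the open area alone) is what separates the accessible and shut states. `k_on⁰ = 10 µM⁻¹ms⁻¹` (diffusion-limited);
`k_off⁰` per species reproduces configurable dissociation constants
(ATP-site 50 µM, AMP-site 200 µM, products 500 µM) through the frozen-pocket
two-state relation `K_d = (k_off⁰/k_on⁰) exp(−A/kBT)` with `A` the anchor
depth.

Chemistry is a kinetic MC step, attempted at the same cadence: forward
(substrate, substrate) → (product, product) with probability
`1 − exp(−k_f Δt)`, reverse with `k_r`, mutually exclusive, and only from
the catalytically competent state — classifier-closed, correct occupancy,
and ≥ 60 % of each pocket's pairs within 1.5 σ of their holo distance
(preorganization; the closed classifier already gates the conformation, so
this threshold marks thermally docked pockets rather than crystallographic
rigidity). Defaults `k_f = 500 ms⁻¹`, `k_r = 40 ms⁻¹` keep
chemistry fast relative to conformational motion, so conformational steps
(closure with substrates bound, reopening with products) — never the
chemical event itself — limit the cycle. In the synthetic wild-type the
closure and release steps are of comparable weight, which places it near
the crossover between crowding-activation and crowding-inhibition; the
open-biased variants are decisively closure-limited.

## Crowding environment

Crowders are inert spheres (radius 8 Å, mass scaled as the cubed radius
ratio to a bead) with steep shifted repulsions
`ε (σ_ref/(r − σ_kind + σ_ref))¹²` (ε = 1 kcal/mol, σ_ref = 6 Å,
σ_cc = 16 Å, σ_pc = 10 Å) and an optional soft attraction
`−ε_attr(...)⁶` to the protein for the sticky-crowder variant. The system
sits in a cubic soft-walled box (side 115 Å, three-branch wall potential,
K = 10 kcal/mol, σ = 5 Å, effective volume 10⁶ Å³) rather than periodic
boundaries. Crowder counts follow `N = φV/(4/3 πR_c³)` rounded to nearest,
with the printed standard counts (47/93/140/186 for φ = 0.1…0.4) honored
exactly via an override — the φ = 0.4 value rounds down. Crowders are
placed by rejection sampling with full separation constraints; dense
packings that defeat rejection sampling raise an error rather than loop
forever.

## Integration

Dynamics are Langevin at 300 K (`kB = 0.0019872 kcal/mol/K`), time step
0.2 τ, friction 0.25 τ⁻¹, uniform bead mass 110 amu (an average residue;
τ is then ≈49 fs of raw time, but see the time mapping). The arm motions
of this model are diffusion- as much as barrier-limited, so the transition
frequency is set jointly by the friction and the barrier parameter; with
the defaults the calibrated model shows ≈7-9 open↔closed transitions per
mapped millisecond. The propagator is
a multiple-time-step splitting of BAOAB: harmonic bonds integrate every
step (velocity Verlet core); protein excluded volume kicks every 5 steps;
all smooth terms — angle/dihedral Gaussians, contacts, ligand restraints,
crowders, walls, and the double-basin mixing-weight update — kick every 10
steps; the thermostat (O step) applies at the 5-step boundaries with the
correspondingly adjusted coefficient, which is itself a valid splitting of
the same SDE. The class periods sit far below the stiffest smooth-term
frequencies (ωh ≲ 0.8). Setting `respa = 1` recovers plain per-step BAOAB.
Gaussian noise comes from an internal xoshiro256** + ziggurat generator, so
trajectories are bit-reproducible for a given seed across NumPy versions;
checkpointed states continue exactly when segment lengths are multiples of
the neighbor-list period (50 steps).

Near-collinear bead triples make angle/dihedral gradients diverge; both
implementations floor the geometric factors (sin θ ≥ 0.05,
|bᵢ×bᵢ₊₁|² ≥ 2 Å⁴). The floors cap forces without altering energies, and
the synthetic structures are built so native geometry never engages them.

## Synthetic reference structures

Real two-conformation crystal pairs are not bundled; the package generates
its own. The 214-residue synthetic enzyme is a helix-bundle core with two
hinged towers (NMP = residues 30–67, LID = 118–160, CORE the rest — the
standard partition). The closed form tips the NMP tower steeply over the
core and reclines the LID above it by exact rigid hinge rotations about
axes through the hinge residues, so both conformations share bond lengths;
closing forms 42 LID–CORE, 42 NMP–CORE and 13 LID–NMP interface contacts
and buries both pockets (open-pocket SASA exceeds closed at both sites).
The small toy generator builds a three-segment zig-zag chain whose arms
fold by a prescribed center-of-mass displacement.

What this emulates: two-state arm closure over buried interfaces, pocket
burial on closing, entropic opening vs enthalpic docking. What it does not:
real AdK coordinates, sequence-specific energetics, side-chain packing, or
quantitative experimental rates — so passing tests demonstrate the
*mechanisms* (conformational selection, crowding-induced population shift,
release-limited turnover) rather than agreement with any particular enzyme.
The apo landscape is deliberately "soft": the open state is an entropically
broad ensemble rather than a narrow minimum, which matches the physical
picture of an undocked arm.

## Estimators

* **P_closed**: closed-frame fraction after burn-in, block-bootstrap SE.
* **Transitions**: open↔closed macro-state changes tracking the last
  definite state (intermediates belong to neither).
* **Turnover**: cycles delimited by release of the second product after a
  forward reaction (reverse reactions roll the cycle back);
  `v = 1/mean(cycle time)`, delta-method SE over cycles.
* **Michaelis–Menten**: nonlinear least squares of `v = k_cat[S]/(K_M+[S])`;
  bootstrap resamples replicas within concentrations (percentile CIs).
* **MFPT**: first-passage durations over all qualifying segments; bootstrap
  over passages.
* **2-D free-energy surface**: `−ln(count/total)` over 1 Å bins of the two
  COM distances, minimum at zero, empty bins +∞.

## Problem sizes

Production-scale runs in the reproduction script and the heavier tests use
trajectory lengths chosen as this package's standard study conditions:
calibration iterations of 1–2×10⁷ steps, closed-population measurements of
≥5×10⁷ pooled steps over ≥5 fresh seeds, and turnover measurements of ≥5
replicas per condition accumulating ≥20 completed cycles. These lengths put
the statistical error of pooled P_closed near ±0.03–0.06 (the apo ensemble
carries conformational modes with multi-million-step relaxation times, so
seed-level estimates scatter far more than naive counting suggests) and of
scaled-down turnover rates near ±15–30 %. Observables defined as ratios of
turnover rates between conditions inherit both errors.

## Known limitations

* The flexible-local prior is uniform, not sequence-derived.
* One enzyme copy; crowders are monodisperse spheres; no hydrodynamics,
  no electrostatics, no substrate-diffusion slowdown (ligand arrival is
  concentration-limited by construction).
* K_M under crowding carries large fitting uncertainty at the scaled-down
  problem sizes (few low-concentration points); no K_M trends are asserted.
* The chemical step is a two-rate kMC gate; no transition-state detail.
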