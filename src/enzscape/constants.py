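"""Physical constants and unit conventions.

Internal unit system (CafeMol-like coarse-grained conventions):

* length   -- angstrom (A)
* energy   -- kcal/mol
* mass     -- amu (uniform bead mass, default 110 amu, an average residue)
* time     -- tau = sqrt(amu * A^2 / (kcal/mol)) ~ 48.9 fs of "raw" time;
              physical time is assigned only through an empirical mapping
              constant (see ``STEPS_PER_MS``), because coarse-grained
              dynamics do not preserve absolute time scales.
"""

#: Boltzmann constant in kcal/mol/K.
KB_KCAL: float = 0.0019872

#: Default simulation temperature (K).
DEFAULT_TEMPERATURE: float = 300.0

#: kB*T at 300 K, kcal/mol.
KBT_300: float = KB_KCAL * DEFAULT_TEMPERATURE

#: Uniform bead mass (amu).
BEAD_MASS: float = 110.0

#: Time-mapping constant: MD steps per millisecond of mapped physical time.
#: Calibrated so that 2e8 MD steps correspond to ~112 ms, i.e. the apo
#: open<->closed transition rate of the wild-type-like model (~7 / ms)
#: is reproduced by construction of the barrier-height calibration.
STEPS_PER_MS: float = 2.0e8 / 112.0


def kbt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy kB*T in kcal/mol."""
    return KB_KCAL * temperature
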