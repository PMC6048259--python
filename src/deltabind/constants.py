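"""Physical constants and unit conversions.

Internal unit system: length in angstrom (A), energy in kcal/mol, mass in
amu, time in fs, charge in elementary charges, temperature in K.
"""

#: Boltzmann constant, kcal/(mol K).
KB = 1.9872e-3

#: Coulomb constant, kcal A / (mol e^2): E = COULOMB * q1*q2 / r.
COULOMB = 332.0637

#: 1 kcal/mol expressed in amu A^2 / fs^2 (converts forces to accelerations).
KCAL_PER_MOL_AKMA = 4.184e-4

#: Default simulation temperature (K) used throughout the pipeline.
DEFAULT_TEMPERATURE = 310.0
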