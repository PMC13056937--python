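"""Physical constants (CODATA 2018) and unit-conversion factors.

All internal quantities are SI; the factors below are the only place where
non-SI input units (cm^-1, elementary charge, amu, Angstrom) are converted.
"""

#: Vacuum permittivity, F/m.
EPSILON_0 = 8.8541878128e-12

#: Speed of light in vacuum, m/s.
SPEED_OF_LIGHT = 2.99792458e8

#: Avogadro constant, 1/mol.
AVOGADRO = 6.02214076e23

#: Elementary charge, C.
ELEMENTARY_CHARGE = 1.602176634e-19

#: Atomic mass unit, kg.
ATOMIC_MASS = 1.66053906660e-27

#: Wavenumber (cm^-1) to linear frequency (Hz): nu = c * 100 * nu_tilde.
CM1_TO_HZ = 2.99792458e10

#: Boltzmann constant, J/K (unused in spectra; kept for completeness).
BOLTZMANN = 1.380649e-23

#: Default bulk-water molarity, mol/L (0.997 g/mL at 25 C, M = 18.015 g/mol).
WATER_MOLARITY = 55.345

CONSTANTS_VERSION = "CODATA-2018"
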