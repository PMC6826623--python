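"""Physical constants and unit conversions used across the package.

All internal energies are kcal/mol (thermodynamics) or cm^-1 / eV
(spectroscopy); lengths are Angstrom; dipoles are Debye.
"""

# CODATA-derived conversions
EV_TO_CM = 8065.543937  # 1 eV in wavenumbers (cm^-1)
NM_EV = 1239.841984  # lambda[nm] * E[eV] = NM_EV

# Point-dipole coupling prefactor: Debye^2 / Angstrom^3 expressed in cm^-1.
# mu^2/r^3 in Gaussian units (1 D = 1e-18 esu cm, 1 A = 1e-8 cm) divided by hc.
DIPOLE_COUPLING_CM = 5034.12

# Gas constant, kcal mol^-1 K^-1
R_KCAL = 1.98720e-3

# Boltzmann constant in molar energy units equals R
KB_KCAL = R_KCAL

# Standard-state volume (1 M), Angstrom^3 per molecule
V0_STANDARD_A3 = 1661.0
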