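"""Physical constants and unit conventions used throughout the package.

Energies are carried in kJ/mol, entropies and heat capacities in J/mol/K,
temperatures in K, pressures in Pa, and concentrations in mol/m^3.
The standard-state pressure is 1 atm, matching the convention under which
the packaged thermochemical tables were produced (not the 1 bar ATcT
convention).
"""

from scipy import constants as _sc

#: Molar gas constant, J/mol/K.
R = _sc.R

#: Boltzmann constant, J/K.
K_B = _sc.k

#: Planck constant, J s.
H_PLANCK = _sc.h

#: Speed of light, m/s.
C_LIGHT = _sc.c

#: Avogadro constant, 1/mol.
N_A = _sc.N_A

#: Standard-state pressure, Pa (1 atm).
P_REF = _sc.atm

#: Second radiation constant h*c/k_B expressed per wavenumber, cm*K.
#: theta = HC_K * nu[cm^-1] is the characteristic temperature of a mode.
HC_K = H_PLANCK * C_LIGHT * 100.0 / K_B

#: Energy of one wavenumber per mole, kJ/mol per cm^-1.
WAVENUMBER_KJ = H_PLANCK * C_LIGHT * 100.0 * N_A / 1000.0

#: Reference temperature for standard-state property anchors, K.
T_STANDARD = 298.15
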