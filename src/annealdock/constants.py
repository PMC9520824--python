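"""Physical constants in the unit system used throughout the package.

Lengths are in Å, energies in kJ/mol, charges in units of the proton
charge |e|, temperatures in K.
"""

#: Boltzmann constant, kJ/(mol·K) (i.e. the molar gas constant R).
KB = 0.00831446261815324

#: Coulomb constant e²·N_A/(4πε₀), in kJ·Å/(mol·e²).  Dividing by a relative
#: permittivity and a distance in Å gives an interaction energy in kJ/mol
#: for unit charges.
COULOMB_KJ_A = 1389.35

#: Elementary charge, C.
E_CHARGE_SI = 1.602176634e-19

#: Avogadro constant, 1/mol.
N_AVOGADRO = 6.02214076e23

#: Boltzmann constant, J/K.
KB_SI = 1.380649e-23

#: Vacuum permittivity, F/m.
EPS0_SI = 8.8541878128e-12
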