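"""Physical constants and default parameters shared across the package.

All distances are in angstroms, angles in degrees at public interfaces,
energies in J/mol and temperatures in kelvin.
"""

#: Molar gas constant, J/(K mol). Used exactly; no CODATA refinement.
R_GAS = 8.314

#: Bondi van der Waals radii (angstrom) for the halogen-bond donor/acceptor pair.
VDW_RADII = {"I": 1.98, "O": 1.52}

#: Sum of vdW radii for the I...O contact criterion.
VDW_SUM_IO = VDW_RADII["I"] + VDW_RADII["O"]

#: Minimum C-I...O angle (degrees) for a geometry to count as halogen bonded.
#: Spans both preferred ranges observed for XBs in protein-like environments
#: (~160-170 deg and ~145-150 deg).
XB_ANGLE_MIN = 140.0

#: Maximal dipolar coupling (Hz) of a directly bonded C-H at r = 1.09 A.
#: Negative sign follows the 1D(CH) convention; the alignment tensor absorbs
#: the overall scale, so only the tensor's physical magnitude depends on it.
DMAX_CH = -22700.0

#: Karplus coefficients (A, B, C) in Hz for 3J(HN, HA) with phase (phi - 60 deg),
#: Vuister-Bax parametrisation.
KARPLUS_HN_HA = (6.51, -1.76, 1.60)

# --- ideal covalent geometry used by the synthetic chain builder -------------

BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_N_H = 1.010
BOND_C_H = 1.090
BOND_CA_CB = 1.530
BOND_C_I = 2.100
BOND_C_OE = 1.430

ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 117.0
ANGLE_C_N_CA = 121.0
ANGLE_CA_C_O = 121.0
ANGLE_C_N_H = 119.0
ANGLE_N_CA_HA = 109.5
ANGLE_N_CA_CB = 110.5
ANGLE_CA_CB_HB = 109.5
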