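"""Physical constants and unit conversions used across the package.

Internal unit conventions: lengths in Å, energies in kJ/mol, times in ps,
temperatures in K, pressures in bar unless a function states otherwise.
"""

# CODATA 2018
N_AVOGADRO = 6.02214076e23  # 1/mol
R_GAS = 8.31446261815324  # J/(mol K)
R_GAS_KJ = R_GAS / 1000.0  # kJ/(mol K)

# Coulomb prefactor e^2/(4 pi eps0) in kJ/mol * Å per e^2
COULOMB_KJ_A = 1389.35457644382

# Standard atomic masses (amu)
ATOMIC_MASSES = {"H": 1.008, "C": 12.011, "O": 15.999}

# Atomic numbers (for X-ray form-factor sanity checks)
ATOMIC_NUMBERS = {"H": 1, "C": 6, "O": 8}

# Bondi van der Waals radii (Å), default hard radii for FFV / ASA probes
BONDI_RADII = {"H": 1.20, "C": 1.70, "O": 1.52}

# Unit conversions
A2_PER_PS_TO_CM2_PER_S = 1.0e-4  # Å²/ps -> cm²/s
BAR_TO_PA = 1.0e5
CM3_TO_M3 = 1.0e-6

# Molar volume of an ideal gas at STP (0 °C, 1 atm), cm³/mol
V_STP_CM3 = 22413.97

# 1 Barrer = 1e-10 cm³(STP)·cm / (cm²·s·cmHg), expressed in mol/(m·s·Pa)
CMHG_TO_PA = 1333.223874
BARRER_SI = 1.0e-10 / V_STP_CM3 / CMHG_TO_PA * 1.0e4 * 1.0e-2  # mol/(m s Pa)

# Penetrant molar masses (g/mol)
M_CO2 = 44.010
M_CH4 = 16.043
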