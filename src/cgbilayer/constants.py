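"""Physical constants and unit conventions.

Internal unit system (consistent, GROMACS-like but with angstroms):

========= ==============================
length    angstrom (A)
time      picosecond (ps)
mass      atomic mass unit (amu)
energy    kJ/mol
charge    elementary charge (e)
========= ==============================

With these units an acceleration in A/ps^2 is ``ACC_CONV * F[kJ/mol/A] / m[amu]``.
Analysis-facing diffusion coefficients are reported in cm^2/s; trajectory
times are carried in ns.
"""

# Boltzmann constant, kJ mol^-1 K^-1
KB = 0.008314462618

# Coulomb constant 1/(4 pi eps0) in kJ mol^-1 A e^-2
# (138.935458 kJ mol^-1 nm e^-2 * 10 A/nm)
COULOMB = 1389.35458

# F [kJ/mol/A] / m [amu] -> a [A/ps^2]
ACC_CONV = 100.0

# m [amu] * v^2 [A^2/ps^2] -> energy [kJ/mol]
KE_CONV = 0.01

# 1 bar in kJ mol^-1 A^-3
BAR_TO_KJMOL_A3 = 6.02214076e-5

# 1 A^2/ns = 1e-16 cm^2 / 1e-9 s
A2_PER_NS_TO_CM2_PER_S = 1.0e-7

# CG dynamics run on a smoothed energy landscape; sampled dynamics are
# conventionally rescaled by this factor to map onto real time.
EFFECTIVE_TIME_FACTOR = 4.0

# 4:1 mapping of the CG water bead
REAL_WATERS_PER_BEAD = 4

PS_PER_NS = 1000.0
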