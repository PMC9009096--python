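"""Physical constants and unit conversions.

Internal unit system: length Å, time ps, mass g/mol (= amu), charge e,
energy kJ/mol, temperature K, pressure bar.  In these units
1 amu·Å²/ps² = 0.01 kJ/mol exactly (since amu·N_A = 1 g/mol).
"""

import numpy as np

#: Coulomb constant, kJ·mol⁻¹·Å·e⁻² (CODATA-consistent).
KE_COULOMB = 1389.35458

#: Boltzmann constant, kJ·mol⁻¹·K⁻¹ (CODATA 2018, exact).
KB = 0.00831446261815324

#: amu·Å²/ps² expressed in kJ/mol (exact).
KE_UNIT = 0.01

#: acceleration prefactor: a[Å/ps²] = ACC_UNIT · F[kJ/mol/Å] / m[amu]
ACC_UNIT = 100.0

#: kJ·mol⁻¹·Å⁻³ expressed in bar (1e33 / N_A / 1e5).
PRESSURE_UNIT = 1.0e33 / 6.02214076e23 / 1.0e5

#: e·Å expressed in Debye.
DEBYE_PER_EA = 4.80320425

#: Avogadro constant scaled for g/cm³ conversions: ρ[g/cm³] = mass[g/mol] / (AVOGADRO_VOL · V[Å³])
AVOGADRO_VOL = 0.602214076


def maxwell_mean_speed(temperature: float, mass: float) -> float:
    """Mean Maxwell–Boltzmann speed sqrt(8 k_B T / (π m)) in Å/ps."""
    return np.sqrt(8.0 * KB * temperature / (np.pi * mass) / KE_UNIT)
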