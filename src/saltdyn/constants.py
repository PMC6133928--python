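"""Physical constants in the package unit system (nm, ps, kJ/mol, e, K).

CODATA 2018 values. The Coulomb prefactor is
``e^2 N_A / (4 pi eps_0 * 1e-9 m)`` expressed in kJ mol^-1 nm e^-2 and is
frozen so the screened-Coulomb reference curve is bit-stable.
"""

AVOGADRO = 6.02214076e23
"""Avogadro constant, mol^-1."""

BOLTZMANN_KJ_MOL = 0.00831446261815324
"""Boltzmann constant times Avogadro, kJ mol^-1 K^-1."""

COULOMB_KJ_MOL_NM = 138.935458
"""Coulomb prefactor f_C, kJ mol^-1 nm e^-2."""

PER_MOLAR_PER_NM3 = AVOGADRO * 1e-24
"""Number density of a 1 mol/L solution, nm^-3 (= N_A / 1e24)."""
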