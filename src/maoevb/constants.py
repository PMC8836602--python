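"""Physical constants and unit conversions.

Internal unit system: kcal/mol (energy), Å (length), amu (mass), fs (time),
elementary charge e (charge), Debye (dipole), Kelvin (temperature).
"""

#: Boltzmann constant, kcal/(mol K)
KB = 1.987204e-3

#: kB*T/h prefactor at T = 1 K, in s^-1 (CODATA kB = 1.380649e-23 J/K,
#: h = 6.62607015e-34 J s); multiply by T to get the Eyring prefactor.
KB_OVER_H = 1.380649e-23 / 6.62607015e-34

#: Debye per (e * Å)
DEBYE_PER_E_ANGSTROM = 4.80320

#: Converts kcal/mol to amu Å^2 / fs^2 (4184 J/mol divided by
#: 1 amu Å^2/fs^2 = 1.66054e-27 kg * 1e10 m^2/s^2 * NA ≈ 1e7 J/mol).
KCAL_TO_INTERNAL = 4.184e-4

#: Natural-log to log10 factor used in the deprotonation correction.
LN10 = 2.303
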