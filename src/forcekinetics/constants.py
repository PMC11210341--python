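"""Physical constants and unit conventions.

Internal units throughout the package: force in pN, length in nm, time in s,
stiffness in pN/nm, loading rate in pN/s.  Concentrations are mol/L.
"""

#: Thermal energy at room temperature (298 K) in pN*nm.
KBT_PN_NM: float = 4.114

#: Avogadro constant, 1/mol.
AVOGADRO: float = 6.02214076e23

#: nm^3 -> L conversion (1 nm^3 = 1e-24 L).
NM3_TO_L: float = 1e-24

#: Angstrom per nm, for table-style reporting of barrier widths.
ANGSTROM_PER_NM: float = 10.0
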