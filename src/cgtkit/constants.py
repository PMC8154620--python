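"""Physical constants and unit conventions.

Internal units throughout the package: length nm, energy kJ/mol,
entropy J/(mol K), angles rad, time ns.
"""

#: Ideal gas constant, J/(mol K).
R_GAS = 8.314462

#: Ideal gas constant, kJ/(mol K) — convenient for free energies in kJ/mol.
R_GAS_KJ = R_GAS / 1000.0
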