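"""Physical constants and unit conversion factors (SI base)."""

BOLTZMANN_J_PER_K = 1.380649e-23
AVOGADRO_PER_MOL = 6.02214e23

NM_TO_M = 1e-9
M_TO_NM = 1e9
ANGSTROM2_TO_NM2 = 1e-2  # 1 A^2 = 0.01 nm^2
NM2_TO_M2 = 1e-18
NM3_TO_L = 1e-24  # 1 nm^3 = 1e-24 litres

ROOM_TEMPERATURE_K = 298.15
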