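"""Physical constants shared across the package.

Energies are expressed in kcal/mol-equivalent units and temperatures in
kelvin throughout, so the same protocol code runs on toy landscapes and
(in principle) on atomistic backends without unit translation.
"""

#: Gas constant in kcal/(mol K).
R_GAS = 1.987e-3

#: Default temperature (K) of the high-temperature canonical seed run.
T_SEED_DEFAULT = 700.0

#: Default temperature (K) the weight function is re-expressed at after the
#: first multicanonical iteration; a low temperature makes ln P_c(E, T)
#: smoother and better suited to a polynomial representation.
T_RESET_DEFAULT = 200.0

#: Default target temperature (K) for reconstructed canonical ensembles.
T_TARGET_DEFAULT = 315.0
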