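"""Package-wide unit conventions and physical constants.

All quantities use one fixed unit system; no unit inference anywhere:

* time            seconds (s)
* counts          molecules cell^-1 (continuous, fractional values allowed)
* rates           monomers s^-1 (polymerases), reactions s^-1 (enzymes),
                  ATP s^-1 (ETC), substrate s^-1 (transporters)
* mass            Dalton (Da) for molecules, gram (g) for whole cells
* length          micrometre (um)
* area            um^2 for whole-cell surfaces, nm^2 for per-molecule
                  membrane footprints
* volume          um^3
"""

#: grams per Dalton (CODATA atomic mass constant)
GRAMS_PER_DALTON = 1.66053906660e-24

#: nm^2 in one um^2
NM2_PER_UM2 = 1.0e6

#: um^3 in one cm^3
UM3_PER_CM3 = 1.0e12
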