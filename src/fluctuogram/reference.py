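"""Reference residue sets for subtilisin Carlsberg (274-residue mature enzyme).

The mutation-site list compiles the gain-of-function positions reported in
the directed-evolution literature on subtilisin: thermostabilization of
subtilisin E (Zhao & Arnold), stabilization of calcium-free subtilisin
BPN' variants (Strausberg et al., Rollence et al.) and activity in a polar
organic solvent (Chen & Arnold), mapped onto the numbering of the mature
274-residue enzyme.  These 28 positions serve as the reference set for
hit-rate and coverage statistics of residue selections.
"""

#: Number of residues in mature subtilisin Carlsberg.
SUBTILISIN_N_RESIDUES = 274

#: The 28 gain-of-function mutation sites (1-based residue numbers).
SUBTILISIN_MUTATION_SITES = (
    2, 3, 5, 9, 14, 43, 50, 59, 72, 75,
    96, 102, 103, 107, 117, 128, 131, 160, 165, 169,
    180, 188, 193, 206, 212, 217, 218, 255,
)

#: The 9 thermostabilization sites of the subtilisin E study (subset above).
ZHAO_ARNOLD_SITES = (9, 14, 75, 117, 160, 165, 180, 193, 217)
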