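# Atomic solvation parameters, kcal/mol/A^2, applied as G = sigma * SASA.
# Apolar elements carry positive sigma (burial is favourable), polar elements
# negative, after the atomic-solvation-parameter formalism of
# Eisenberg & McLachlan-style tables. "BD" is the coarse-bead pseudo-element
# used by the synthetic lattice fixtures.
# element	sigma
C	0.016
S	0.021
N	-0.006
O	-0.006
H	0.0
P	0.0
BD	0.020
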