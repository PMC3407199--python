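# Sequence-dependent corrections to the 8 M urea random-coil shifts.
# Semantics: the correction is ADDED to the reference shift of residue i when a
# residue of neighbor_type occupies position i+offset (offset in -2..+2, not 0).
# This file carries only the dominant, well-established nearest-neighbour
# effect — the upfield shift of the residue PRECEDING a proline — and treats
# all other corrections as zero; supply a complete table for production
# referencing work. Units: ppm.
# columns: neighbor_type	offset	nucleus	correction_ppm
P	1	CA	-2.0
P	1	C	-0.5
P	1	CB	0.1
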