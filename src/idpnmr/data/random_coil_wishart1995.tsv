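# Alternative random-coil 13C shift set: Wishart et al. 1995 (GGXAGG peptides,
# aqueous, near-neutral pH), transcribed to working precision, DSS-referenced.
# Asp/Glu values are for the deprotonated side chains. Units: ppm.
# columns: residue_type	nucleus	shift_ppm
A	CA	52.5
A	CB	19.1
A	C	177.8
C	CA	58.2
C	CB	28.0
C	C	174.6
D	CA	54.2
D	CB	41.1
D	C	176.3
E	CA	56.6
E	CB	29.9
E	C	176.6
F	CA	57.7
F	CB	39.6
F	C	175.8
G	CA	45.1
G	C	174.9
H	CA	55.0
H	CB	29.0
H	C	174.1
I	CA	61.1
I	CB	38.8
I	C	176.4
K	CA	56.2
K	CB	33.1
K	C	176.6
L	CA	55.1
L	CB	42.4
L	C	177.6
M	CA	55.4
M	CB	32.9
M	C	176.3
N	CA	53.1
N	CB	38.9
N	C	175.2
P	CA	63.3
P	CB	31.7
P	C	177.3
Q	CA	55.7
Q	CB	29.4
Q	C	176.0
R	CA	56.0
R	CB	30.9
R	C	176.3
S	CA	58.3
S	CB	63.8
S	C	174.6
T	CA	61.8
T	CB	69.8
T	C	174.7
V	CA	62.2
V	CB	32.9
V	C	176.3
W	CA	57.5
W	CB	29.6
W	C	176.1
Y	CA	57.9
Y	CB	38.8
Y	C	175.9
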