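# Random-coil 13C chemical shifts of Xaa in Ac-GGXGG-NH2 peptides in 8 M urea,
# pH 2.5, referenced to DSS (Schwarzinger et al. 2000/2001 set, transcribed to
# working precision). Asp/Glu/His carry their low-pH (protonated) values.
# Gly has no CB. Units: ppm.
# columns: residue_type	nucleus	shift_ppm
A	CA	52.8
A	CB	19.3
A	C	178.5
C	CA	58.6
C	CB	28.3
C	C	175.3
D	CA	53.0
D	CB	38.3
D	C	175.9
E	CA	56.1
E	CB	28.9
E	C	176.8
F	CA	57.9
F	CB	39.8
F	C	176.6
G	CA	45.4
G	C	174.9
H	CA	55.4
H	CB	29.1
H	C	175.1
I	CA	61.6
I	CB	38.9
I	C	177.1
K	CA	56.7
K	CB	33.2
K	C	177.4
L	CA	55.5
L	CB	42.5
L	C	178.2
M	CA	55.8
M	CB	32.9
M	C	177.1
N	CA	53.3
N	CB	39.1
N	C	176.1
P	CA	63.7
P	CB	32.2
P	C	177.8
Q	CA	56.2
Q	CB	29.5
Q	C	176.8
R	CA	56.5
R	CB	30.9
R	C	177.1
S	CA	58.7
S	CB	64.1
S	C	175.4
T	CA	62.0
T	CB	70.0
T	C	175.6
V	CA	62.6
V	CB	31.8
V	C	177.0
W	CA	57.6
W	CB	29.8
W	C	177.1
Y	CA	58.3
Y	CB	38.9
Y	C	176.7
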