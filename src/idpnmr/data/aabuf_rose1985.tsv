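# Average area buried upon folding (AABUF) per residue, A^2
# (Rose, Geselowitz, Lesser, Lee & Zehfus 1985; the ProtScale "average area
# buried on transfer from the standard state to the folded protein" scale).
# columns: residue_type	aabuf
A	86.6
R	162.2
N	103.3
D	97.8
C	132.3
Q	119.2
E	113.9
G	62.9
H	155.8
I	158.0
L	164.1
K	115.5
M	172.9
F	194.1
P	92.9
S	85.6
T	106.5
W	224.6
Y	177.7
V	141.0
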