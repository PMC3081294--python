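residue	volume
A	91.5
C	114.4
D	135.2
E	154.6
F	198.8
G	67.5
H	163.2
I	162.6
K	162.5
L	163.4
M	165.9
N	138.3
P	123.4
Q	156.4
R	196.1
S	102.0
T	126.0
V	138.4
W	237.2
Y	209.8
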