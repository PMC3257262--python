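aa	j_hz
A	6.9
C	7.2
D	7.2
E	7.1
F	7.4
G	6.8
H	7.3
I	7.3
K	7.1
L	7.1
M	7.1
N	7.3
P	7.0
Q	7.1
R	7.1
S	7.1
T	7.4
V	7.3
W	7.3
Y	7.4
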