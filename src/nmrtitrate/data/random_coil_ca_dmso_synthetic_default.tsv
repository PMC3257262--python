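aa	shift_ppm	medium
A	51.0	dmso
C	56.7	dmso
D	52.7	dmso
E	55.1	dmso
F	56.2	dmso
G	43.6	dmso
H	53.5	dmso
I	59.6	dmso
K	54.7	dmso
L	53.6	dmso
M	53.9	dmso
N	51.6	dmso
P	61.8	dmso
Q	54.2	dmso
R	54.5	dmso
S	56.8	dmso
T	60.3	dmso
V	60.7	dmso
W	56.0	dmso
Y	56.4	dmso
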