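aa	shift_ppm	medium
A	52.5	aqueous
C	58.2	aqueous
D	54.2	aqueous
E	56.6	aqueous
F	57.7	aqueous
G	45.1	aqueous
H	55.0	aqueous
I	61.1	aqueous
K	56.2	aqueous
L	55.1	aqueous
M	55.4	aqueous
N	53.1	aqueous
P	63.3	aqueous
Q	55.7	aqueous
R	56.0	aqueous
S	58.3	aqueous
T	61.8	aqueous
V	62.2	aqueous
W	57.5	aqueous
Y	57.9	aqueous
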