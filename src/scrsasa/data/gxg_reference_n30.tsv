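# gly-x-gly reference accessibilities (A^2)
# ensemble_size=30 seed=42 radii=chothia-united-atom
residue	mean_sidechain_sasa
A	63.746882
C	95.214305
D	107.625384
E	131.692803
F	175.890633
G	83.754293
H	154.135876
I	141.849994
K	151.482000
L	136.843743
M	143.995233
N	113.272637
P	98.053464
Q	136.293779
R	188.514114
S	73.732156
T	104.046277
V	117.551248
W	215.986276
Y	185.275634
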