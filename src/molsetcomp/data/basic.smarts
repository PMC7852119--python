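# Basic group patterns, one SMARTS + label per line.
# Aliphatic amines (excluding amides and other acylated N), amidines,
# guanidines and pyridine-type aromatic nitrogen.
[NX3;H2,H1,H0;+0;!$(N-C=O);!$(N-S=O);!$(N-[!#6]);!$(N-c);!a]	aliphatic_amine
[NX2;+0]=[CX3][NX3;+0]	amidine
[NX2;+0]=[CX3]([NX3;+0])[NX3;+0]	guanidine
[nX2;H0;+0]	pyridine_like_nitrogen
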