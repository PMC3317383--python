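# Constructed per-predictor Arg/Lys methylation call sets (see fixtures
# module docstring): 2-of-3 consensus reproduces the curated 9 sites.
predictor	position	residue
bpbppms	149	K
bpbppms	207	K
bpbppms	248	R
bpbppms	250	R
bpbppms	264	R
bpbppms	266	R
bpbppms	270	K
bpbppms	271	K
masa	149	K
masa	207	K
masa	248	R
masa	250	R
masa	262	K
masa	264	R
masa	266	R
masa	270	K
masa	271	K
masa	569	K
memo	149	K
memo	153	R
memo	207	K
memo	248	R
memo	250	R
memo	264	R
memo	266	R
memo	270	K
memo	271	K
memo	569	K
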