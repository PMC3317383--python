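name	start	end
DBD	148	257
NLS	249	251
NLS	269	271
NES	386	396
TAD	258	673
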