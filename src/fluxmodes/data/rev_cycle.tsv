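metabolite	A	internal
metabolite	B	internal
reaction	R1	reversible	-1 A 1 B
reaction	R2	reversible	-1 B 1 A
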