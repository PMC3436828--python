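metabolite	X	external
metabolite	A	internal
metabolite	B	internal
metabolite	Y	external
reaction	R1	irreversible	-1 X 1 A
reaction	R2	irreversible	-1 A 1 B
reaction	R3	irreversible	-1 A 1 B
reaction	R4	irreversible	-1 B 1 Y
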