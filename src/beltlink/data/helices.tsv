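id	start	end
H1	44	65
H2	66	87
H3	88	98
H4	99	120
H5	121	142
H6	143	164
H7	165	186
H8	187	208
H9	209	219
H10	220	241
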