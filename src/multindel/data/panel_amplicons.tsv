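marker_id	amplicon_size
5	128
7	176
9	147
13	251
17	192
24	160
29	228
30	247
31	250
38	244
46	101
52	239
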