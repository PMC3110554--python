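structure_id	start
2CFP	8
2CFP	30
2CFP	42
2CFP	59
2CFP	87
2CFP	104
2CFP	120
2CFP	143
2CFP	177
2CFP	210
2CFP	220
2CFP	235
2CFP	244
2CFP	257
2CFP	269
2CFP	288
2CFP	312
2CFP	325
2CFP	357
2CFP	377
2CFQ	7
2CFQ	29
2CFQ	45
2CFQ	63
2CFQ	75
2CFQ	86
2CFQ	95
2CFQ	104
2CFQ	115
2CFQ	149
2CFQ	166
2CFQ	179
2CFQ	210
2CFQ	220
2CFQ	257
2CFQ	288
2CFQ	312
2CFQ	343
2CFQ	378
2V8N	7
2V8N	45
2V8N	60
2V8N	75
2V8N	94
2V8N	104
2V8N	121
2V8N	147
2V8N	166
2V8N	210
2V8N	220
2V8N	232
2V8N	243
2V8N	254
2V8N	265
2V8N	288
2V8N	312
2V8N	325
2V8N	346
2V8N	358
2V8N	378
1PV6	2
1PV6	7
1PV6	42
1PV6	74
1PV6	104
1PV6	120
1PV6	140
1PV6	166
1PV6	210
1PV6	220
1PV6	254
1PV6	288
1PV6	312
1PV6	346
1PV6	357
1PV6	378
1PV6	408
1PV7	2
1PV7	7
1PV7	42
1PV7	74
1PV7	104
1PV7	120
1PV7	140
1PV7	166
1PV7	210
1PV7	220
1PV7	254
1PV7	288
1PV7	312
1PV7	346
1PV7	357
1PV7	378
1PV7	408
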