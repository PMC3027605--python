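clone_id	chromosome	position_bp	in_lm_classifier
GS-82-O2	20	1000000	0
GS-1061-L1	20	2250000	0
RP5-852M4	20	3500000	0
RP11-314N13	20	4750000	0
RP4-686C3	20	6000000	0
RP4-741H3	20	7250000	0
RP4-599I11	20	8500000	0
RP4-764O22	20	9750000	0
RP5-1140M3	20	11000000	0
RP4-811H13	20	12250000	0
RP11-204H22	20	13500000	0
RP4-742J24	20	14750000	0
RP11-104O6	20	16000000	0
RP11-526K24	20	17250000	0
RP5-822J19	20	18500000	0
RP3-348M17	20	19750000	0
RP11-504H3	20	21000000	0
RP1-167O22	20	22250000	0
RP4-788L20	20	23500000	0
RP1-234M6	20	24750000	0
RP5-1025A1	20	26000000	0
RP11-348I14	20	29000000	1
RP3-324O17	20	29750000	0
RP5-857M17	20	30500000	0
RP1-310O13	20	31250000	0
RP11-410N8	20	32000000	0
RP5-1085F17	20	32750000	1
RP4-733O23	20	33500000	0
RP5-1137F22	20	34250000	1
RP11-353C18	20	35000000	1
RP11-234K24	20	35750000	1
RP3-469A13	20	36500000	1
RP4-633O20	20	37250000	1
RP11-122O1	20	38000000	1
RP4-600E6	20	38750000	1
RP5-892M9	20	39500000	1
RP4-796I11	20	40250000	1
RP1-128O17	20	41000000	1
RP1-232N11	20	41750000	1
RP1-138B7	20	42500000	1
RP5-1028D15	20	43250000	1
RP3-337O18	20	44000000	1
RP5-1005L2	20	44750000	0
RP11-347D21	20	45500000	1
RP1-155G6	20	46250000	1
RP3-470L14	20	47000000	1
RP4-791K14	20	47750000	1
RP5-1185N5	20	48500000	0
RP4-530I15	20	49250000	0
RP5-994O24	20	50000000	1
RP4-715N11	20	50750000	1
RP4-724E16	20	51500000	0
RP5-1075G21	20	52250000	1
RP5-1162C3	20	53000000	1
RP11-6L15	20	53750000	1
RP5-1167H4	20	54500000	1
RP5-1153D9	20	55250000	0
RP11-46O3	20	56000000	1
RP13-379L11	20	56750000	1
RP1-309F20	20	57500000	1
RP5-827E24	20	58250000	1
RP5-1107C24	20	59000000	1
RP4-563E14	20	59750000	1
RP13-152O15	20	60500000	1
GS-81-F12	20	61250000	1
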